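"""Per-area ambulance-use rate estimators.

The survey gives, per neighborhood, how many ED attendees arrived by
ambulance.  Three estimators turn those sparse counts into a city-level
rate ``delta``:

* **naive** — the unweighted mean of the per-neighborhood proportions,
  i.e. every neighborhood counts equally regardless of population;
* **weighted naive** — the mean of per-neighborhood proportions weighted by
  daytime population share;
* **simulation** — a parametric binomial bootstrap: each replicate redraws
  every neighborhood's ambulance count from Binomial(n_i, p_i) at the
  observed proportion p_i, and ``delta`` is the mean of the replicate means
  of resampled proportions.  By the central limit theorem the replicate
  means are approximately normal, so a 95% CI and a one-sample t-test
  against the naive values are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateDistributionError, EstimationError, InputError

COUNT_COLUMNS = ["neighborhood_id", "n_total", "n_ambulance"]


@dataclass(frozen=True)
class AmbulanceRateEstimate:
    """A city-level ambulance-use rate from one estimation method.

    ``ci_low``/``ci_high`` and ``replicate_means`` are populated only by the
    simulation method.
    """

    method: str
    delta: float
    ci_low: float | None = None
    ci_high: float | None = None
    replicate_means: np.ndarray | None = None
    n_replicates: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise EstimationError(f"delta out of [0, 1]: {self.delta}")
        if self.replicate_means is not None and len(self.replicate_means) != self.n_replicates:
            raise EstimationError("replicate_means length must equal n_replicates")


@dataclass(frozen=True)
class ComparisonResult:
    """One-sample t-test of simulation replicate means against a reference rate."""

    reference_method: str
    t_statistic: float
    p_value: float
    significant_at: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.significant_at


def aggregate_survey(survey: pd.DataFrame) -> pd.DataFrame:
    """Collapse patient records to per-neighborhood (n_total, n_ambulance) counts."""
    if len(survey) == 0:
        return pd.DataFrame(columns=COUNT_COLUMNS)
    grouped = (
        survey.groupby("neighborhood_id", sort=True)["used_ambulance"]
        .agg(n_total="size", n_ambulance="sum")
        .reset_index()
    )
    return grouped[COUNT_COLUMNS]


def _eligible(counts: pd.DataFrame) -> pd.DataFrame:
    if np.any(counts["n_ambulance"] > counts["n_total"]) or np.any(counts["n_ambulance"] < 0):
        raise InputError("need 0 <= n_ambulance <= n_total in every row")
    return counts[counts["n_total"] >= 1]


def pooled_rate(counts: pd.DataFrame) -> float:
    """Total ambulance users over total surveyed patients."""
    total = counts["n_total"].sum()
    if total < 1:
        raise EstimationError("no surveyed patients to pool")
    return float(counts["n_ambulance"].sum() / total)


def naive_rate(counts: pd.DataFrame) -> AmbulanceRateEstimate:
    """Unweighted mean of per-neighborhood ambulance-use proportions."""
    rows = _eligible(counts)
    if len(rows) == 0:
        raise EstimationError("no neighborhood has surveyed patients")
    props = rows["n_ambulance"] / rows["n_total"]
    return AmbulanceRateEstimate(method="naive", delta=float(props.mean()))


def weighted_naive_rate(counts: pd.DataFrame, registry: pd.DataFrame) -> AmbulanceRateEstimate:
    """Daytime-population-weighted mean of per-neighborhood proportions."""
    rows = _eligible(counts)
    if len(rows) == 0:
        raise EstimationError("no neighborhood has surveyed patients")
    pop = registry.set_index("id")["pop_day"]
    missing = set(rows["neighborhood_id"]) - set(pop.index)
    if missing:
        raise InputError(f"no registry population for neighborhoods: {sorted(missing)[:5]}")
    weights = pop.loc[rows["neighborhood_id"]].to_numpy(dtype=float)
    props = (rows["n_ambulance"] / rows["n_total"]).to_numpy()
    delta = float(np.average(props, weights=weights))
    return AmbulanceRateEstimate(method="weighted_naive", delta=delta)


def monte_carlo_rate(
    counts: pd.DataFrame,
    n_replicates: int = 10_000,
    seed: int = 0,
    ci_multiplier: float = 1.96,
) -> AmbulanceRateEstimate:
    """Parametric binomial bootstrap of the per-neighborhood proportions.

    Each replicate resamples every eligible neighborhood's ambulance count
    from Binomial(n_i, p_i) at the observed proportion p_i and takes the
    mean of resampled proportions; ``delta`` is the mean of replicate means
    and the CI is the normal-approximation interval
    ``delta +/- ci_multiplier * sd / sqrt(n_replicates)``.
    """
    if n_replicates < 2:
        raise ConfigurationError("need at least 2 replicates")
    rows = _eligible(counts)
    if len(rows) == 0:
        raise EstimationError("no neighborhood has surveyed patients")
    rng = np.random.default_rng(seed)
    n = rows["n_total"].to_numpy(dtype=np.int64)
    p = (rows["n_ambulance"] / rows["n_total"]).to_numpy(dtype=float)
    draws = rng.binomial(n[np.newaxis, :], p[np.newaxis, :], size=(n_replicates, len(rows)))
    replicate_means = (draws / n[np.newaxis, :]).mean(axis=1)
    delta = float(replicate_means.mean())
    se = float(replicate_means.std(ddof=1)) / np.sqrt(n_replicates)
    return AmbulanceRateEstimate(
        method="simulation",
        delta=delta,
        ci_low=delta - ci_multiplier * se,
        ci_high=delta + ci_multiplier * se,
        replicate_means=replicate_means,
        n_replicates=n_replicates,
        seed=seed,
    )


def compare_to_reference(
    estimate: AmbulanceRateEstimate,
    reference: float,
    reference_method: str = "naive",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-sided one-sample t-test of the replicate means against a reference rate."""
    if estimate.replicate_means is None or len(estimate.replicate_means) == 0:
        raise EstimationError("estimate has no replicate means to test")
    if float(np.std(estimate.replicate_means, ddof=1)) == 0.0:
        raise DegenerateDistributionError(
            "replicate means have zero variance; the t-test is undefined"
        )
    res = stats.ttest_1samp(estimate.replicate_means, popmean=reference)
    return ComparisonResult(
        reference_method=reference_method,
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant_at=alpha,
    )
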