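"""Estimation of the demand-model parameters from registry, survey, and
hospital-sample inputs.

Three quantities feed the annual demand formula:

* day/night populations ``P_ij`` per neighborhood, obtained by adding each
  municipality's net commuter inflow to its nighttime census population,
  spread across neighborhoods proportionally to where people live;
* the period probabilities ``eps_j`` that an emergency falls in the daytime
  (06:00-17:59) or nighttime (18:00-05:59) window, estimated from surveyed
  call times;
* the annual per-capita emergency-department visit rate ``lambda``, assumed
  uniform over the region, estimated by scaling the quartiles of a small
  hospital ED-volume sample up to the full count of ED-equipped hospitals
  and dividing by the baseline population.

Registries and surveys are plain :class:`pandas.DataFrame` objects; the
column schemas are documented in :mod:`emsdemand.synthetic_data`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import allocate_integer, round_half_up
from .errors import EstimationError, InputError

#: Hour at which the daytime period opens (inclusive).
DAY_START_HOUR = 6
#: Hour at which the nighttime period opens (inclusive); daytime is the
#: half-open interval [06:00, 18:00).
NIGHT_START_HOUR = 18

REGISTRY_COLUMNS = ["id", "district", "municipality", "pop_night", "pop_day"]
SURVEY_COLUMNS = ["patient_id", "neighborhood_id", "period", "used_ambulance"]


@dataclass(frozen=True)
class PeriodProbabilities:
    """Probability that an emergency occurs by period of day.

    ``eps_day + eps_night == 1`` by construction; both lie in [0, 1].
    """

    eps_day: float
    eps_night: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.eps_day <= 1.0 and 0.0 <= self.eps_night <= 1.0):
            raise InputError("period probabilities must lie in [0, 1]")
        if abs(self.eps_day + self.eps_night - 1.0) > 1e-12:
            raise InputError("period probabilities must sum to 1")


@dataclass(frozen=True)
class PerCapitaRateScenario:
    """One per-capita ED-visit rate scenario (low / mid / high).

    ``lam`` is the unrounded annual visits per person;
    ``implied_total_visits`` is the region-wide annual visit count it was
    derived from (sample quantile x number of ED-equipped hospitals).
    """

    label: str
    lam: float
    implied_total_visits: float

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise InputError("per-capita rate must be positive")

    @property
    def lam_rounded(self) -> float:
        """Two-decimal rate used for report labels (half-up)."""
        return round_half_up(self.lam, 2)


def five_number_summary(volumes: Sequence[float]) -> dict[str, float]:
    """Min, quartiles, max and sum of a volume sample.

    Quartiles use linear interpolation between order statistics, so for an
    even-sized sample the median is the mean of the two central values.
    """
    v = np.asarray(volumes, dtype=float)
    if v.size == 0:
        raise InputError("cannot summarise an empty volume sample")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return {
        "min": float(v.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(v.max()),
        "sum": float(v.sum()),
    }


@dataclass(frozen=True)
class HospitalVolumeSample:
    """Annual ED visit counts for a sample of hospitals.

    ``summary`` is always consistent with ``volumes`` when raw volumes are
    available; :meth:`from_summary` supports the published-summary-only case.
    """

    volumes: tuple[int, ...] | None
    summary: Mapping[str, float] = field(default_factory=dict)

    @classmethod
    def from_volumes(cls, volumes: Sequence[int]) -> "HospitalVolumeSample":
        vols = tuple(int(v) for v in volumes)
        if any(v < 0 for v in vols):
            raise InputError("hospital volumes must be nonnegative")
        return cls(volumes=vols, summary=five_number_summary(vols))

    @classmethod
    def from_summary(cls, summary: Mapping[str, float]) -> "HospitalVolumeSample":
        required = {"min", "q1", "median", "q3", "max", "sum"}
        missing = required - set(summary)
        if missing:
            raise InputError(f"summary is missing keys: {sorted(missing)}")
        return cls(volumes=None, summary=dict(summary))

    @property
    def n(self) -> int:
        return len(self.volumes) if self.volumes is not None else 0


def split_day_night_population(
    registry: pd.DataFrame, municipal_inflows: Mapping[str, int]
) -> pd.DataFrame:
    """Fill ``pop_day`` from ``pop_night`` plus commuter inflows.

    Each municipality's signed net inflow is split across its neighborhoods
    proportionally to nighttime population with largest-remainder integer
    apportionment, so municipality and region totals are conserved exactly.
    """
    if "pop_night" not in registry.columns:
        raise InputError("registry must provide a pop_night column")
    known = set(registry["municipality"].unique())
    unknown = set(municipal_inflows) - known
    if unknown:
        raise InputError(f"inflows given for unknown municipalities: {sorted(unknown)}")
    out = registry.copy()
    pop_day = out["pop_night"].to_numpy(dtype=np.int64).copy()
    for muni, inflow in municipal_inflows.items():
        mask = (out["municipality"] == muni).to_numpy()
        pop_day[mask] += allocate_integer(int(inflow), out.loc[mask, "pop_night"])
    if np.any(pop_day <= 0):
        raise InputError("commuter outflow exceeds nighttime population in some area")
    out["pop_day"] = pop_day
    return out


def period_of_hour(hour: int) -> str:
    """Classify an hour of day into the 'day' or 'night' period."""
    return "day" if DAY_START_HOUR <= hour < NIGHT_START_HOUR else "night"


def estimate_period_probabilities(survey: pd.DataFrame) -> PeriodProbabilities:
    """Estimate the day/night emergency probabilities from a patient survey.

    Uses the ``period`` column when present; otherwise derives the period
    from an ``arrival_time`` timestamp column using the half-open daytime
    window [06:00, 18:00).
    """
    if len(survey) == 0:
        raise EstimationError("cannot estimate period probabilities from an empty survey")
    if "period" in survey.columns:
        periods = survey["period"]
    elif "arrival_time" in survey.columns:
        hours = pd.to_datetime(survey["arrival_time"]).dt.hour
        periods = hours.map(period_of_hour)
    else:
        raise InputError("survey needs a 'period' or 'arrival_time' column")
    bad = set(periods.unique()) - {"day", "night"}
    if bad:
        raise InputError(f"unrecognised period labels: {sorted(bad)}")
    n_day = int((periods == "day").sum())
    eps_day = n_day / len(periods)
    return PeriodProbabilities(eps_day=eps_day, eps_night=1.0 - eps_day)


def estimate_per_capita_scenarios(
    hospitals: HospitalVolumeSample,
    n_hospitals_with_ed: int = 86,
    population: float = 10_500_000,
) -> list[PerCapitaRateScenario]:
    """Turn a hospital ED-volume sample into low/mid/high per-capita rates.

    Each of the sample's quartiles (q1, median, q3) is multiplied by the
    number of ED-equipped hospitals in the region to give an implied annual
    visit total, then divided by the baseline population.  The rate is
    assumed uniform across neighborhoods.
    """
    if n_hospitals_with_ed < 1:
        raise InputError("need at least one ED-equipped hospital")
    if population <= 0:
        raise InputError("population must be positive")
    scenarios = []
    for label, key in (("low", "q1"), ("mid", "median"), ("high", "q3")):
        total = hospitals.summary[key] * n_hospitals_with_ed
        scenarios.append(
            PerCapitaRateScenario(
                label=label, lam=total / population, implied_total_visits=total
            )
        )
    return scenarios
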