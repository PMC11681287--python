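"""End-to-end orchestration: inputs -> parameters -> rates -> demand -> report.

``run_pipeline`` executes the whole estimation chain from a single
:class:`PipelineConfig`, writing every intermediate table as CSV plus a JSON
manifest that records the seed, configuration, and all scenario totals.  The
same config and seed always produce byte-identical outputs, and every
output can be regenerated from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import DegenerateDistributionError, EmsDemandError, InputError
from .parameters import (
    HospitalVolumeSample,
    estimate_per_capita_scenarios,
    estimate_period_probabilities,
)
from .synthetic_data import (
    CityTemplate,
    GeneratorConfig,
    generate_hospital_volumes,
    generate_registry,
    generate_survey,
    hospital_sample_frame,
)
from .ambulance_rates import (
    aggregate_survey,
    compare_to_reference,
    monte_carlo_rate,
    naive_rate,
    pooled_rate,
    weighted_naive_rate,
)
from .demand import build_scenario_table

logger = logging.getLogger("emsdemand")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class PipelineConfig:
    """Configuration of one full pipeline run.

    When the three input CSV paths are None, the synthetic-data module
    generates them under ``out_dir``; otherwise they are read as-is.
    """

    seed: int = 0
    out_dir: str = "emsdemand_out"
    neighborhoods_csv: str | None = None
    survey_csv: str | None = None
    hospitals_csv: str | None = None
    n_hospitals_with_ed: int = 86
    population_baseline: int = 10_500_000
    usage_rate: float = 0.093
    n_replicates: int = 10_000
    use_rounded_rates: bool = False
    survey_n: int = 1964
    true_ambulance_rate: float = 0.093
    true_day_share: float = 0.625

    def __post_init__(self) -> None:
        if min(self.n_hospitals_with_ed, self.population_baseline, self.n_replicates) <= 0:
            raise InputError("counts in the pipeline config must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _read_csv(path: str, stage: str) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise InputError(f"[{stage}] input file not found: {p}")
    return pd.read_csv(p)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the full estimation pipeline; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        if config.neighborhoods_csv is None:
            logger.info("[%s] generating synthetic city and survey", stage)
            registry = generate_registry(CityTemplate(), seed=config.seed)
            gen = GeneratorConfig(
                seed=config.seed,
                survey_n=config.survey_n,
                true_ambulance_rate=config.true_ambulance_rate,
                true_day_share=config.true_day_share,
            )
            survey = generate_survey(registry, gen)
            hospitals = generate_hospital_volumes(gen)
            registry.to_csv(out / "neighborhoods.csv", index=False)
            survey.to_csv(out / "survey.csv", index=False)
            hospital_sample_frame(hospitals).to_csv(out / "hospitals.csv", index=False)
        else:
            logger.info("[%s] reading input tables", stage)
            registry = _read_csv(config.neighborhoods_csv, stage)
            if config.survey_csv is None or config.hospitals_csv is None:
                raise InputError(f"[{stage}] survey_csv and hospitals_csv are required "
                                 "when neighborhoods_csv is given")
            survey = _read_csv(config.survey_csv, stage)
            hosp_df = _read_csv(config.hospitals_csv, stage)
            hospitals = HospitalVolumeSample.from_volumes(hosp_df["annual_ed_visits"])

        stage = "parameters"
        logger.info("[%s] estimating period probabilities and per-capita rates", stage)
        eps = estimate_period_probabilities(survey)
        scenarios = estimate_per_capita_scenarios(
            hospitals, config.n_hospitals_with_ed, config.population_baseline
        )

        stage = "rates"
        logger.info("[%s] estimating ambulance-use rates (%d replicates)",
                    stage, config.n_replicates)
        counts = aggregate_survey(survey)
        pooled = pooled_rate(counts)
        naive = naive_rate(counts)
        weighted = weighted_naive_rate(counts, registry)
        sim = monte_carlo_rate(counts, n_replicates=config.n_replicates, seed=config.seed)
        comparisons = {}
        for ref in (naive, weighted):
            try:
                cmp_res = compare_to_reference(sim, ref.delta, reference_method=ref.method)
                comparisons[ref.method] = {
                    "t_statistic": cmp_res.t_statistic,
                    "p_value": cmp_res.p_value,
                }
            except DegenerateDistributionError:
                comparisons[ref.method] = {"t_statistic": None, "p_value": None,
                                           "note": "degenerate replicate distribution"}
        rates_df = pd.DataFrame(
            [
                {"method": e.method, "delta": e.delta, "ci_low": e.ci_low,
                 "ci_high": e.ci_high, "n_replicates": e.n_replicates, "seed": e.seed}
                for e in (naive, weighted, sim)
            ]
        )
        rates_df.to_csv(out / "rates.csv", index=False)
        pd.DataFrame({"replicate_mean": sim.replicate_means}).to_csv(
            out / "replicates.csv", index=False
        )

        stage = "demand"
        logger.info("[%s] building scenario demand tables", stage)
        summary, detail = build_scenario_table(
            registry, eps, scenarios, [naive, weighted, sim],
            usage_rate=config.usage_rate, use_rounded_rates=config.use_rounded_rates,
        )
        summary.to_csv(out / "demand_summary.csv", index=False)
        detail.to_csv(out / "demand_by_neighborhood.csv", index=False)
    except EmsDemandError:
        raise
    except Exception as exc:  # pragma: no cover - defensive wrapping
        raise EmsDemandError(f"[{stage}] stage failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "eps": {"day": eps.eps_day, "night": eps.eps_night},
        "pooled_usage_rate": pooled,
        "per_capita_scenarios": {
            s.label: {"lam": s.lam, "lam_rounded": s.lam_rounded,
                      "implied_total_visits": s.implied_total_visits}
            for s in scenarios
        },
        "rates": {
            e.method: {"delta": e.delta, "ci_low": e.ci_low, "ci_high": e.ci_high}
            for e in (naive, weighted, sim)
        },
        "comparisons": comparisons,
        "scenario_totals": [
            {k: row[k] for k in ("method", "rate_label", "rate_per_capita",
                                 "rate_ambulance", "nighttime", "daytime",
                                 "total_ambulance", "total_emergency")}
            for row in summary.to_dict("records")
        ],
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("[manifest] wrote %s", out / "manifest.json")
    return manifest


def render_report(out_dir: str | Path) -> Path:
    """Render a markdown report (and replicate-mean figure) from a run directory.

    Produces ``report.md`` with the 9-row scenario table; when
    ``replicates.csv`` is present, also writes ``replicate_means.png`` — a
    histogram/density of the simulation replicate means with vertical
    markers at the naive and weighted-naive rates.  Degenerate replicate
    distributions produce a warning line instead of a figure.
    """
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise InputError(f"no manifest found at {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)

    lines = ["# Annual ambulance and emergency-care demand", ""]
    eps = manifest["eps"]
    lines.append(
        f"Period probabilities: day {eps['day']:.3f}, night {eps['night']:.3f}; "
        f"pooled ambulance usage {manifest['pooled_usage_rate']:.3f}."
    )
    lines += ["", "| Model | Rate per capita | Rate ambulance | Nighttime | Daytime | "
              "Total ambulance | Total emergency care |",
              "|---|---|---|---|---|---|---|"]
    for row in manifest["scenario_totals"]:
        lines.append(
            f"| {row['method']} | {row['rate_per_capita']:.2f} | "
            f"{row['rate_ambulance']:.5f} | {row['nighttime']:,} | {row['daytime']:,} | "
            f"{row['total_ambulance']:,} | {row['total_emergency']:,} |"
        )

    replicates_path = out / "replicates.csv"
    if replicates_path.exists():
        reps = pd.read_csv(replicates_path)["replicate_mean"].to_numpy()
        if np.std(reps) == 0.0:
            lines += ["", "Warning: replicate means are degenerate (zero variance); "
                      "no distribution figure was drawn."]
        else:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(7, 4))
            ax.hist(reps, bins=60, density=True, color="#7aa6c2", alpha=0.8)
            for method, style in (("naive", "--"), ("weighted_naive", ":")):
                if method in manifest["rates"]:
                    ax.axvline(manifest["rates"][method]["delta"], color="k",
                               linestyle=style, label=method)
            ax.set_xlabel("replicate mean ambulance-use rate")
            ax.set_ylabel("density")
            ax.legend()
            fig.tight_layout()
            fig.savefig(out / "replicate_means.png", dpi=120)
            plt.close(fig)
            lines += ["", "![Replicate mean distribution](replicate_means.png)"]
    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    logger.info("[report] wrote %s", report)
    return report
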