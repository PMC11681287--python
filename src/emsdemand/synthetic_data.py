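"""Synthetic city, survey, and hospital-sample generators.

The downstream estimators only ever see three tables (a neighborhood
registry, a patient-level survey, a hospital ED-volume sample).  No
per-neighborhood census or survey microdata are published for the study
region, so this module generates tables with the statistical structure the
analysis assumes:

* a five-municipality city of 42 districts and 261 neighborhoods whose
  nighttime populations sum to 10.5 million, with 1.1 million net daytime
  commuters concentrated in the central and southern municipalities;
* a ~1,964-patient ED-arrival survey with neighborhood of origin, a
  day/night arrival flag, and an ambulance-used flag;
* a 10-hospital sample of annual ED visit volumes from a right-skewed law.

All generators are deterministic under their seed.

Column schemas
--------------
``neighborhoods.csv``: id, district, municipality, pop_night, pop_day
``survey.csv``: patient_id, neighborhood_id, period ('day'|'night'),
used_ambulance (0/1)
``hospitals.csv``: hospital_id, annual_ed_visits
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import allocate_integer
from .errors import ConfigurationError, InputError
from .parameters import HospitalVolumeSample, split_day_night_population

MUNICIPALITIES = ("Central", "North", "West", "South", "East")

# Administrative structure of the five mainland municipalities
# (districts and neighborhoods per municipality) and 2019 census-scale
# population weights, in MUNICIPALITIES order.
_DEFAULT_DISTRICTS = (8, 6, 8, 10, 10)
_DEFAULT_NEIGHBORHOODS = (44, 31, 56, 65, 65)
_DEFAULT_POP_WEIGHTS = (0.92, 1.80, 2.56, 2.23, 2.94)

# Net daytime commuter inflow per municipality (persons).  The two largest
# flows (Central, South) are reported municipal statistics; the remaining
# 158k of the 1.1M regional total is split across the other three.
_DEFAULT_INFLOWS = {
    "Central": 524_000,
    "South": 418_000,
    "East": 70_000,
    "West": 60_000,
    "North": 28_000,
}

# Synthetic reconstruction of the 10-hospital annual ED-volume sample: ten
# integers whose linear-interpolation five-number summary and sum reproduce
# the published summary (min 1,080; q1 12,522; median 24,628.5; q3 35,729.5;
# max 66,899; sum 266,931).  The raw volumes were not published.
_REFERENCE_VOLUMES = (1080, 8000, 12522, 12522, 24000, 25257, 35728, 35730, 45193, 66899)


def _spread_evenly(total: int, cells: int) -> tuple[int, ...]:
    return tuple(int(x) for x in allocate_integer(total, np.ones(cells)))


@dataclass(frozen=True)
class CityTemplate:
    """Administrative skeleton of the synthetic city.

    ``neighborhoods_per_district`` is a flat tuple over all districts, in
    municipality order; ``municipality_population_weights`` sets the relative
    nighttime population of each municipality before Dirichlet variation is
    applied within it.
    """

    municipalities: tuple[str, ...] = MUNICIPALITIES
    districts_per_municipality: tuple[int, ...] = _DEFAULT_DISTRICTS
    neighborhoods_per_district: tuple[int, ...] = field(default=())
    base_population: int = 10_500_000
    commuter_net_inflow_by_municipality: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_INFLOWS)
    )
    municipality_population_weights: tuple[float, ...] = _DEFAULT_POP_WEIGHTS

    def __post_init__(self) -> None:
        if self.base_population <= 0:
            raise ConfigurationError("base_population must be positive")
        if len(self.districts_per_municipality) != len(self.municipalities):
            raise ConfigurationError("one district count needed per municipality")
        if not self.neighborhoods_per_district:
            # default: each municipality's neighborhood count spread evenly
            flat: list[int] = []
            for n_d, n_k in zip(self.districts_per_municipality, _DEFAULT_NEIGHBORHOODS):
                flat.extend(_spread_evenly(n_k, n_d))
            object.__setattr__(self, "neighborhoods_per_district", tuple(flat))
        if len(self.neighborhoods_per_district) != sum(self.districts_per_municipality):
            raise ConfigurationError("one neighborhood count needed per district")
        if any(n < 1 for n in self.neighborhoods_per_district):
            raise ConfigurationError("every district needs at least one neighborhood")
        unknown = set(self.commuter_net_inflow_by_municipality) - set(self.municipalities)
        if unknown:
            raise ConfigurationError(f"inflow for unknown municipalities: {sorted(unknown)}")

    @property
    def total_neighborhoods(self) -> int:
        return sum(self.neighborhoods_per_district)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the survey and hospital-sample generators.

    Defaults mirror the observed study quantities: a 1,964-patient survey
    with a 9.3% ambulance-use rate and a 62.5% daytime share, and a
    10-hospital volume sample.  ``true_ambulance_rate`` may be a scalar or a
    per-neighborhood mapping keyed by neighborhood id.
    """

    seed: int = 0
    survey_n: int = 1964
    true_ambulance_rate: float | Mapping[str, float] = 0.093
    true_day_share: float = 0.625
    hospital_sample_size: int = 10
    hospital_volume_location: float = math.log(20_000)
    hospital_volume_spread: float = 1.2

    def __post_init__(self) -> None:
        if self.survey_n < 1:
            raise ConfigurationError("survey_n must be at least 1")
        if not 0.0 <= self.true_day_share <= 1.0:
            raise ConfigurationError("true_day_share must be a probability")
        rates = (
            self.true_ambulance_rate.values()
            if isinstance(self.true_ambulance_rate, Mapping)
            else [self.true_ambulance_rate]
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ConfigurationError("ambulance rates must be probabilities")
        if self.hospital_sample_size < 1:
            raise ConfigurationError("hospital_sample_size must be at least 1")
        if self.hospital_volume_spread <= 0:
            raise ConfigurationError("hospital_volume_spread must be positive")


def generate_registry(
    template: CityTemplate | None = None,
    seed: int = 0,
    concentration: float = 50.0,
) -> pd.DataFrame:
    """Generate a neighborhood registry with day and night populations.

    Nighttime population is split municipality -> district -> neighborhood
    with Dirichlet-distributed shares (concentration high enough that areas
    within a district stay comparable), then converted to integers by
    largest-remainder apportionment so the city total is conserved exactly.
    Daytime population adds each municipality's net commuter inflow,
    distributed proportionally to nighttime population.
    """
    template = template or CityTemplate()
    rng = np.random.default_rng(seed)

    muni_pops = allocate_integer(
        template.base_population, template.municipality_population_weights
    )
    rows: list[dict] = []
    district_no = 0
    neigh_no = 0
    d_cursor = 0
    for m_idx, muni in enumerate(template.municipalities):
        n_districts = template.districts_per_municipality[m_idx]
        neigh_counts = template.neighborhoods_per_district[d_cursor : d_cursor + n_districts]
        d_cursor += n_districts
        # district share ~ Dirichlet with mean proportional to neighborhood count
        alpha_d = concentration * np.asarray(neigh_counts, dtype=float)
        district_pops = allocate_integer(int(muni_pops[m_idx]), rng.dirichlet(alpha_d))
        for d_idx, n_neigh in enumerate(neigh_counts):
            district_no += 1
            shares = rng.dirichlet(np.full(n_neigh, concentration))
            neigh_pops = allocate_integer(int(district_pops[d_idx]), shares)
            # guard the strictly-positive invariant for extreme templates
            while np.any(neigh_pops == 0):
                neigh_pops[np.argmin(neigh_pops)] += 1
                neigh_pops[np.argmax(neigh_pops)] -= 1
            for pop in neigh_pops:
                neigh_no += 1
                rows.append(
                    {
                        "id": f"K{neigh_no:03d}",
                        "district": f"D{district_no:02d}",
                        "municipality": muni,
                        "pop_night": int(pop),
                    }
                )
    registry = pd.DataFrame(rows)
    return split_day_night_population(
        registry, template.commuter_net_inflow_by_municipality
    )


def generate_survey(registry: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Generate a patient-level ED-arrival survey.

    Each patient's neighborhood is drawn proportionally to daytime
    population (ED attendance scales with exposed population), the arrival
    period is Bernoulli(true_day_share) for daytime, and ambulance use is
    Bernoulli at that neighborhood's true rate.
    """
    if len(registry) == 0:
        raise InputError("registry must be nonempty")
    rng = np.random.default_rng(config.seed)
    pop_day = registry["pop_day"].to_numpy(dtype=float)
    idx = rng.choice(len(registry), size=config.survey_n, p=pop_day / pop_day.sum())
    neigh_ids = registry["id"].to_numpy()[idx]
    period = np.where(rng.random(config.survey_n) < config.true_day_share, "day", "night")
    if isinstance(config.true_ambulance_rate, Mapping):
        missing = set(neigh_ids) - set(config.true_ambulance_rate)
        if missing:
            raise InputError(f"no ambulance rate for neighborhoods: {sorted(missing)[:5]}")
        rates = np.array([config.true_ambulance_rate[i] for i in neigh_ids])
    else:
        rates = np.full(config.survey_n, float(config.true_ambulance_rate))
    used = (rng.random(config.survey_n) < rates).astype(int)
    return pd.DataFrame(
        {
            "patient_id": np.arange(1, config.survey_n + 1),
            "neighborhood_id": neigh_ids,
            "period": period,
            "used_ambulance": used,
        }
    )


def generate_hospital_volumes(config: GeneratorConfig) -> HospitalVolumeSample:
    """Draw annual ED volumes for a hospital sample from a log-normal law.

    Log-normality gives the right-skewed positive counts seen in real
    hospital volumes; location/spread are on the log scale.
    """
    rng = np.random.default_rng(config.seed)
    draws = rng.lognormal(
        mean=config.hospital_volume_location,
        sigma=config.hospital_volume_spread,
        size=config.hospital_sample_size,
    )
    volumes = np.maximum(np.rint(draws).astype(int), 1)
    return HospitalVolumeSample.from_volumes(volumes)


def reference_hospital_volumes() -> HospitalVolumeSample:
    """Synthetic 10-hospital volume sample matching the published summary.

    The real per-hospital volumes were not published; these ten synthetic
    integers are constructed so that their five-number summary (linear
    interpolation) and total reproduce the published values exactly:
    min 1,080; q1 12,522; median 24,628.5; q3 35,729.5; max 66,899;
    sum 266,931.
    """
    return HospitalVolumeSample.from_volumes(_REFERENCE_VOLUMES)


def hospital_sample_frame(sample: HospitalVolumeSample) -> pd.DataFrame:
    """Tabulate a hospital-volume sample for CSV output."""
    if sample.volumes is None:
        raise InputError("sample has no raw volumes to tabulate")
    return pd.DataFrame(
        {
            "hospital_id": [f"H{i:02d}" for i in range(1, len(sample.volumes) + 1)],
            "annual_ed_visits": list(sample.volumes),
        }
    )
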