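"""Annual ambulance-need and emergency-care demand tables.

The demand model multiplies four factors per neighborhood i and period j
(day/night):

    need_ij = P_ij * eps_j * lambda * delta_i

where P_ij is the period population, eps_j the probability an emergency
falls in period j, lambda the annual per-capita ED-visit rate, and delta_i
the proportion of ED arrivals that used an ambulance.  The regional total
is the sum over neighborhoods and periods; dividing the ambulance total by
the pooled survey usage rate converts it to total emergency-care need.

Full precision is kept throughout; integers are produced only at report
time by half-up rounding of the aggregates (never of per-row values), so
the printed day + night = total identity holds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .errors import ConfigurationError, InputError
from .parameters import PeriodProbabilities, PerCapitaRateScenario
from .ambulance_rates import AmbulanceRateEstimate

#: Pooled survey ambulance-usage rate used to convert ambulance needs into
#: total emergency-care need.
DEFAULT_USAGE_RATE = 0.093


@dataclass(frozen=True)
class DemandTable:
    """Per-neighborhood annual ambulance needs plus regional aggregates.

    ``per_neighborhood`` has columns id, night_need, day_need, total_need
    (unrounded ambulances/year).  Aggregates are exact floats; the
    ``*_reported`` properties give the half-up rounded integers.
    """

    per_neighborhood: pd.DataFrame
    night_total: float
    day_total: float
    ambulance_total: float
    emergency_care_total: float
    usage_rate: float = DEFAULT_USAGE_RATE

    @property
    def night_reported(self) -> int:
        return int(round_half_up(self.night_total))

    @property
    def day_reported(self) -> int:
        return int(round_half_up(self.day_total))

    @property
    def ambulance_reported(self) -> int:
        # sum of the reported period entries, so the printed day + night =
        # total identity always holds
        return self.night_reported + self.day_reported

    @property
    def emergency_reported(self) -> int:
        # converts the reported ambulance total, mirroring published-table
        # arithmetic (rounded total / usage rate, then half-up)
        return int(round_half_up(self.ambulance_reported / self.usage_rate))


def neighborhood_demand(
    area: Mapping[str, float],
    eps: PeriodProbabilities,
    lam: float,
    delta: float,
) -> tuple[float, float]:
    """Expected annual ambulance needs (night, day) for one neighborhood."""
    pop_day, pop_night = float(area["pop_day"]), float(area["pop_night"])
    if min(pop_day, pop_night, lam, delta) < 0:
        raise InputError("populations and rates must be nonnegative")
    return (
        pop_night * eps.eps_night * lam * delta,
        pop_day * eps.eps_day * lam * delta,
    )


def aggregate_demand(rows: pd.DataFrame) -> dict[str, float]:
    """Sum per-neighborhood night/day needs into regional aggregates.

    Returns exact totals plus half-up rounded report integers; the integers
    satisfy the additive identity only because rounding happens after
    aggregation.
    """
    if len(rows) == 0:
        raise InputError("cannot aggregate an empty demand table")
    night = float(rows["night_need"].sum())
    day = float(rows["day_need"].sum())
    return {
        "night_total": night,
        "day_total": day,
        "ambulance_total": night + day,
        "night_reported": int(round_half_up(night)),
        "day_reported": int(round_half_up(day)),
        "ambulance_reported": int(round_half_up(night)) + int(round_half_up(day)),
    }


def emergency_care_total(ambulance_total: float, usage_rate: float = DEFAULT_USAGE_RATE) -> float:
    """Convert an ambulance-need total into total emergency-care visits.

    Only a fraction ``usage_rate`` of ED attendees arrive by ambulance, so
    the full demand is the ambulance total scaled up by 1/usage_rate.
    """
    if not 0.0 < usage_rate <= 1.0:
        raise InputError("usage_rate must lie in (0, 1]")
    return ambulance_total / usage_rate


def demand_table(
    registry: pd.DataFrame,
    eps: PeriodProbabilities,
    lam: float,
    delta: float | Mapping[str, float],
    usage_rate: float = DEFAULT_USAGE_RATE,
) -> DemandTable:
    """Compute the full per-neighborhood demand table for one (lam, delta).

    ``delta`` may be a city-level scalar (the published-table convention) or
    a per-neighborhood mapping keyed by id; areas missing from the mapping
    raise an error.
    """
    if lam < 0:
        raise InputError("per-capita rate must be nonnegative")
    if isinstance(delta, Mapping):
        missing = set(registry["id"]) - set(delta)
        if missing:
            raise InputError(f"no delta for neighborhoods: {sorted(missing)[:5]}")
        d = np.array([delta[i] for i in registry["id"]], dtype=float)
    else:
        d = np.full(len(registry), float(delta))
    if np.any(d < 0):
        raise InputError("delta must be nonnegative")
    night = registry["pop_night"].to_numpy(float) * eps.eps_night * lam * d
    day = registry["pop_day"].to_numpy(float) * eps.eps_day * lam * d
    per = pd.DataFrame(
        {
            "id": registry["id"].to_numpy(),
            "night_need": night,
            "day_need": day,
            "total_need": night + day,
        }
    )
    night_total, day_total = float(night.sum()), float(day.sum())
    amb = night_total + day_total
    return DemandTable(
        per_neighborhood=per,
        night_total=night_total,
        day_total=day_total,
        ambulance_total=amb,
        emergency_care_total=emergency_care_total(amb, usage_rate),
        usage_rate=usage_rate,
    )


def build_scenario_table(
    registry: pd.DataFrame,
    eps: PeriodProbabilities,
    scenarios: Sequence[PerCapitaRateScenario],
    rate_estimates: Sequence[AmbulanceRateEstimate],
    usage_rate: float = DEFAULT_USAGE_RATE,
    use_rounded_rates: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross every per-capita scenario with every rate estimate.

    Returns ``(summary, detail)``: one summary row per (scenario x method)
    with reported integer totals, and the per-neighborhood detail in long
    format.  ``use_rounded_rates`` switches lambda to its two-decimal label
    value, mimicking published-table arithmetic.
    """
    if not scenarios or not rate_estimates:
        raise ConfigurationError("need at least one scenario and one rate estimate")
    summary_rows = []
    detail_frames = []
    for scen in scenarios:
        lam = scen.lam_rounded if use_rounded_rates else scen.lam
        for est in rate_estimates:
            table = demand_table(registry, eps, lam, est.delta, usage_rate)
            summary_rows.append(
                {
                    "method": est.method,
                    "rate_label": scen.label,
                    "rate_per_capita": lam,
                    "rate_ambulance": est.delta,
                    "nighttime": table.night_reported,
                    "daytime": table.day_reported,
                    "total_ambulance": table.ambulance_reported,
                    "total_emergency": table.emergency_reported,
                    "total_ambulance_exact": table.ambulance_total,
                    "total_emergency_exact": table.emergency_care_total,
                }
            )
            detail = table.per_neighborhood.copy()
            detail.insert(0, "method", est.method)
            detail.insert(1, "rate_label", scen.label)
            detail_frames.append(detail)
    return pd.DataFrame(summary_rows), pd.concat(detail_frames, ignore_index=True)
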