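"""Shared numeric helpers: half-up rounding and largest-remainder allocation."""

from __future__ import annotations

import numpy as np

from .errors import InputError


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from the next-lower value (0.5 -> 1), unlike
    banker's rounding.  Reported table entries use this convention so that
    printed aggregates match the exact sums they were rounded from.
    """
    factor = 10.0**decimals
    return float(np.floor(np.asarray(x, dtype=float) * factor + 0.5) / factor)


def allocate_integer(total: int, weights) -> np.ndarray:
    """Split an integer ``total`` across cells proportionally to ``weights``
    using largest-remainder (Hamilton) apportionment.

    The result is an integer vector summing to ``total`` exactly.  Negative
    totals (net commuter outflows) are allocated symmetrically.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise InputError("weights must be a nonempty 1-d array")
    if np.any(w < 0) or not np.isfinite(w).all():
        raise InputError("weights must be finite and nonnegative")
    if w.sum() <= 0:
        raise InputError("weights must have a positive sum")
    total = int(total)
    if total < 0:
        return -allocate_integer(-total, w)
    raw = total * w / w.sum()
    base = np.floor(raw).astype(np.int64)
    shortfall = total - int(base.sum())
    if shortfall:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:shortfall]] += 1
    return base
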