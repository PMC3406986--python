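"""Half-away-from-zero rounding, matching how panel tables print percentages.

Python's built-in ``round`` is banker's rounding; published tables round
halves away from zero (69.57 -> 70 at integer precision, 12.25 -> 12.3
at one decimal), so the display layer uses this explicitly.
"""

from __future__ import annotations

import math


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with ties going away from zero, at ``decimals`` places."""
    f = 10.0**decimals
    scaled = abs(x) * f
    # relative nudge covers float error in x*f so decimal ties that land
    # a hair below .5 in binary (e.g. 68.85 * 10) still round up
    r = math.floor(scaled + 0.5 + 1e-9 * max(scaled, 1.0))
    return math.copysign(r / f, x)


def percent(count: int, total: int, decimals: int = 1) -> float:
    """100*count/total rounded half-away-from-zero, in exact integer
    arithmetic so ties are ties regardless of float representation."""
    if total <= 0:
        raise ValueError("percent requires a positive total")
    scaled = 100 * count * 10**decimals
    q, r = divmod(scaled, total)
    return (q + (1 if 2 * r >= total else 0)) / 10**decimals
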