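"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_up(x: float) -> int:
    """Round a non-negative value half-up to the nearest integer.

    Python's builtin ``round`` is banker's rounding; reported percentages
    use the conventional half-up rule instead (16.55% -> 17%).
    """
    if x < 0:
        raise ValueError("round_half_up expects a non-negative value")
    return int(math.floor(x + 0.5))


def pct(numerator: float, denominator: float) -> float:
    """Percentage as a raw float; caller decides how to round."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return 100.0 * numerator / denominator
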