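"""Small shared helpers."""

from __future__ import annotations

import math

__all__ = ["round_half_up", "round_half_up_pct"]


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves going up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def round_half_up_pct(numerator: float, denominator: float) -> int:
    """``round_half_up(100 * numerator / denominator)``; 0 when the
    denominator is 0."""
    if denominator == 0:
        return 0
    return round_half_up(100.0 * numerator / denominator)
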