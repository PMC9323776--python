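"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention printed tables follow.

    Python's built-in ``round`` is banker's rounding; tables in this domain
    round 0.005 up, so comparisons against printed 2-dp values use this.
    """
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
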