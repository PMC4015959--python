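"""Display rounding, the way instrument-paper tables round.

Published tables round half away from zero (396.5 → 397), whereas Python's
built-in ``round`` rounds half to even.  Use :func:`round_half_up` whenever
a computed quantity is compared against a printed table cell.
"""

from __future__ import annotations

import math

__all__ = ["round_half_up"]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero to the given number of decimals."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
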