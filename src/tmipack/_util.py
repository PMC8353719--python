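"""Small shared numeric helpers."""

from __future__ import annotations

import math


def round_sig(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures (half-away-from-zero is
    irrelevant here; ties do not occur in the quantities we report)."""
    if sig < 1:
        raise ValueError("sig must be >= 1")
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round(x, sig - 1 - exponent)
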