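"""Report-time rounding helper.

Proportions are carried at full floating precision throughout the
pipeline; rounding happens only when a value is printed, using half-up
(so 9.65 -> 9.7, 4.95 -> 5.0), the convention of the field reports this
package mirrors.  Float noise below ~1e-10 is squashed before the half-up
step so that e.g. mean(9.6, 0.3) = 4.949999... still rounds to 5.0.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 1) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    cleaned = repr(round(float(value), max(decimals + 6, 10)))
    return float(Decimal(cleaned).quantize(quantum, rounding=ROUND_HALF_UP))
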