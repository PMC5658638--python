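"""Half-up decimal rendering.

Scores are computed and compared at full float precision; only *rendering*
rounds, and it rounds half-up (0.005 -> 0.01), the convention used when
the published score tables were typeset.  Python's built-in ``round`` is
banker's rounding, so rendering goes through :mod:`decimal`.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

__all__ = ["round_half_up", "format_fixed"]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round ``value`` to ``ndigits`` decimals, ties away from zero.

    Binary floats that are mathematically exact decimals (e.g. the sum
    25% x 7.11 + ... = 3.9075) can sit a hair below the tie point in
    IEEE-754; a pre-round at ``ndigits + 8`` decimals removes that noise
    before the decimal quantisation, which is far inside the precision
    of any two-decimal input.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    cleaned = repr(round(float(value), ndigits + 8))
    return float(Decimal(cleaned).quantize(quantum, rounding=ROUND_HALF_UP))


def format_fixed(value: float, ndigits: int = 2) -> str:
    """Render ``value`` half-up with exactly ``ndigits`` decimals."""
    return f"{round_half_up(value, ndigits):.{ndigits}f}"
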