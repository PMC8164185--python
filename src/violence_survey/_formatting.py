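"""Half-up decimal rounding and percent formatting used by all report tables."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (commercial rounding), not banker's rounding.

    Survey tables conventionally print 2.625 as 2.63; Python's built-in
    ``round`` would give 2.62.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fmt_pct(x: float, ndigits: int = 2) -> str:
    return f"{round_half_up(x, ndigits):.{ndigits}f}"
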