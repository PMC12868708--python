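"""Human-readable "1 in N" formatting for genotype and prevalence tables.

Risk-genotype and prevalence frequencies are conventionally reported as the
reciprocal "one in N": plain integers below a thousand, two significant
figures with a ``k`` suffix in the thousands, and an ``M`` suffix in the
millions (e.g. ``164``, ``2.7k``, ``16k``, ``5 M``).
"""

from __future__ import annotations

import math

__all__ = ["one_in", "format_one_in", "format_frequency_as_one_in"]


def one_in(frequency: float) -> int | None:
    """Reciprocal of a frequency, rounded to the nearest integer.

    Returns ``None`` (the "undefined" sentinel) for a zero or negative
    frequency: a class never observed has no finite "one in N".
    """
    if frequency <= 0:
        return None
    reciprocal = 1.0 / frequency
    if not math.isfinite(reciprocal):  # subnormal frequency: effectively never
        return None
    return round(reciprocal)


def _two_sig(x: float) -> float:
    """Round a positive number to two significant figures."""
    return round(x, 1 - int(math.floor(math.log10(x))))


def format_one_in(n: int | None) -> str:
    """Format a "one in N" denominator: 164, 849, '2.7k', '16k', '5 M'."""
    if n is None:
        return "inf"
    if n < 1000:
        return str(n)
    if n < 1_000_000:
        v = _two_sig(n / 1000.0)
        return f"{v:g}k"
    v = _two_sig(n / 1_000_000.0)
    return f"{v:g} M"


def format_frequency_as_one_in(frequency: float) -> str:
    """Convenience wrapper: format a frequency directly as "one in N"."""
    return format_one_in(one_in(frequency))
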