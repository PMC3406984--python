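"""Exact rounding of count-derived proportions to whole percentages.

Published validation tables print whole percents; matching them requires the
rounding convention to be explicit and exact. All arithmetic here is done in
:class:`fractions.Fraction` so that half-way cases (e.g. 84.5%) are resolved
by convention, never by binary floating-point representation.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Union

Rational = Union[int, Fraction]

#: Recognised rounding conventions.
CONVENTIONS = ("half-up", "half-even")


def round_half_up(x: Rational) -> int:
    """Round to the nearest integer, ties away from zero (for x >= 0: up)."""
    x = Fraction(x)
    if x < 0:
        return -round_half_up(-x)
    return math.floor(x + Fraction(1, 2))


def round_half_even(x: Rational) -> int:
    """Round to the nearest integer, ties to the even integer (banker's)."""
    return round(Fraction(x))


def round_convention(x: Rational, convention: str = "half-up") -> int:
    if convention == "half-up":
        return round_half_up(x)
    if convention == "half-even":
        return round_half_even(x)
    raise ValueError(f"unknown rounding convention {convention!r}; expected one of {CONVENTIONS}")


def percent(numerator: int, denominator: int, convention: str = "half-up") -> int:
    """Whole-percent rendering of ``numerator/denominator``.

    Exact rational arithmetic: ``percent(7066, 8308) == 85`` regardless of
    float representation.
    """
    if denominator <= 0:
        raise ValueError("denominator must be >= 1")
    return round_convention(Fraction(100 * numerator, denominator), convention)
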