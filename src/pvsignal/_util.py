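"""Shared plumbing: logging, half-up rounding, Preferred-Term canonicalization."""

from __future__ import annotations

import logging
import re
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

logger = logging.getLogger("pvsignal")

_WS_RUN = re.compile(r"\s+")


def canonicalize_pt(term: str) -> str:
    """Normalize a MedDRA Preferred Term string for comparison.

    Leading/trailing whitespace is stripped and internal runs of whitespace
    collapse to a single space.  Comparison elsewhere is case-insensitive
    (via :func:`pt_key`); the first-seen casing is what gets emitted.
    """
    return _WS_RUN.sub(" ", term.strip())


def pt_key(term: str) -> str:
    """Case-insensitive comparison key for a canonicalized PT."""
    return canonicalize_pt(term).casefold()


def round_half_up_ratio(num: int, den: int, digits: int = 0) -> float:
    """Round num/den half-up to ``digits`` decimals using exact integer arithmetic.

    Spontaneous-report tables round halves away from zero (44191.5 -> 44192),
    unlike banker's rounding; doing it on the exact rational avoids binary
    float artefacts on values such as 0.05.
    """
    if den == 0:
        raise ZeroDivisionError("denominator is zero")
    scaled = Fraction(num, den) * 10**digits
    q = (2 * scaled.numerator + scaled.denominator) // (2 * scaled.denominator)
    # the expression above floors (scaled + 1/2) for positive values
    if scaled < 0:
        q = -((2 * -scaled.numerator + scaled.denominator) // (2 * scaled.denominator))
    return float(q) if digits == 0 else float(q) / 10**digits


def round_half_up(x: float, digits: int = 1) -> float:
    """Half-up rounding of a float, via decimal string round-trip."""
    d = Decimal(repr(float(x))).quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_UP)
    return float(d)
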