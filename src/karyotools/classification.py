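"""Centromere-position classification (Levan system) and karyotype formulae.

Levan's nomenclature assigns a chromosome to a category from its arm
ratio AR = long/short: metacentric (m) up to 1.7, submetacentric (sm) up
to 3.0, subtelocentric (st) up to 7.0, telocentric (t) beyond.  Boundary
values fall in the lower category (closed-on-the-left convention);
Levan's strict "M" point (AR exactly 1) is folded into m.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .measurements import Karyotype

__all__ = ["levan_type", "karyotype_formula", "TYPE_ORDER"]

TYPE_ORDER = ("m", "sm", "st", "t")

# upper AR bound of each category (inclusive)
_BOUNDS = ((1.70, "m"), (3.00, "sm"), (7.00, "st"))


def levan_type(ar: float) -> str:
    """Centromere-position code for an arm ratio AR >= 1.

    >>> levan_type(1.65)
    'm'
    >>> levan_type(2.4)
    'sm'
    """
    if ar < 1:
        raise ValueError(f"arm ratio must be >= 1 (normalise long >= short), got {ar}")
    for bound, code in _BOUNDS:
        if ar <= bound:
            return code
    return "t"


def karyotype_formula(karyotype: "Karyotype") -> str:
    """Karyotype formula string, e.g. ``2n = 22 = 18m + 4m-SAT``.

    Chromosomes (2 per pair) are counted by Levan type, types ordered
    m < sm < st < t, plain before satellite-bearing within a type;
    zero-count terms are omitted.
    """
    counts: dict[tuple[str, bool], int] = {}
    for p in karyotype.pairs:
        code = p.type_code or levan_type(p.ar_mean)
        key = (code, p.satellite_arm != "none")
        counts[key] = counts.get(key, 0) + 2
    terms = []
    for code in TYPE_ORDER:
        for sat in (False, True):
            n = counts.get((code, sat), 0)
            if n:
                terms.append(f"{n}{code}{'-SAT' if sat else ''}")
    return f"2n = {karyotype.two_n} = " + " + ".join(terms)
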