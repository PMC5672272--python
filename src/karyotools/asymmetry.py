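"""Karyotype asymmetry indices.

Six complementary summaries of how far a karyotype departs from a
uniform, all-metacentric complement:

* mean centromeric index (CI) +/- SD across the haploid set,
* A1, the intrachromosomal asymmetry index (Romero Zarco 1986):
  ``A1 = 1 - mean(b_i / B_i)`` over pairs, with b/B the short/long mean
  arm lengths (equivalently ``1 - mean(1/AR_i)``),
* A2, the interchromosomal asymmetry index (Romero Zarco 1986): the
  coefficient of variation of chromosome lengths across the haploid set,
* As K%, the long-arm share of the complement (Arano's karyotype
  asymmetry), ``100 x sum(long) / sum(total)``,
* AI, Paszko's (2006) asymmetry index, ``CV_CL x CV_CI / 100``,
* the Stebbins (1971) two-way category, combining the largest/smallest
  chromosome ratio with the proportion of pairs whose AR exceeds 2.

All SDs and CVs use the sample (n-1) convention, and every index is
computed on per-pair means of the aggregated haploid karyotype, so all
six are invariant to uniform rescaling of the arm lengths.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .measurements import KaryotypePair

__all__ = [
    "AsymmetryProfile",
    "ci_stats",
    "a1_index",
    "a2_index",
    "ask_percent",
    "ai_index",
    "stebbins_category",
    "asymmetry_profile",
]


@dataclass(frozen=True)
class AsymmetryProfile:
    ci_mean: float
    ci_sd: float
    a1: float
    a2: float
    ask_percent: float
    ai: float
    stebbins: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _require(pairs: Sequence[KaryotypePair], n_min: int, what: str) -> None:
    if len(pairs) < n_min:
        raise ValueError(f"{what} requires at least {n_min} pairs, got {len(pairs)}")


def ci_stats(pairs: Sequence[KaryotypePair]) -> dict:
    """Mean and sample SD of per-pair centromeric indices.

    The distribution is across the n pairs of the haploid set (one CI per
    pair), not across metaphase plates.
    """
    _require(pairs, 1, "ci_stats")
    ci = np.array([p.ci_mean for p in pairs])
    sd = float(np.std(ci, ddof=1)) if len(ci) > 1 else 0.0
    return {"ci_mean": float(np.mean(ci)), "ci_sd": sd}


def a1_index(pairs: Sequence[KaryotypePair]) -> float:
    """Intrachromosomal asymmetry A1 = 1 - mean(1/AR) in [0, 1)."""
    _require(pairs, 1, "a1_index")
    ratios = np.array([1.0 / p.ar_mean for p in pairs])
    return float(1.0 - ratios.mean())


def a2_index(pairs: Sequence[KaryotypePair]) -> float:
    """Interchromosomal asymmetry A2 = CV of chromosome lengths (sample SD)."""
    _require(pairs, 2, "a2_index")
    rl = np.array([p.rl_total_mean for p in pairs])
    return float(np.std(rl, ddof=1) / rl.mean())


def ask_percent(pairs: Sequence[KaryotypePair]) -> float:
    """Long-arm share of the complement: 100 x sum(long) / sum(total)."""
    _require(pairs, 1, "ask_percent")
    long_sum = sum(p.rl_long_mean for p in pairs)
    total_sum = sum(p.rl_total_mean for p in pairs)
    return 100.0 * long_sum / total_sum


def ai_index(pairs: Sequence[KaryotypePair]) -> float:
    """Paszko AI = CV_CL x CV_CI / 100 (both CVs with sample SD)."""
    _require(pairs, 2, "ai_index")
    cv_cl = 100.0 * a2_index(pairs)
    ci = ci_stats(pairs)
    cv_ci = 100.0 * ci["ci_sd"] / ci["ci_mean"]
    return cv_cl * cv_ci / 100.0


def stebbins_category(pairs: Sequence[KaryotypePair]) -> str:
    """Stebbins two-way symmetry category, e.g. ``"1A"``.

    Row from the largest/smallest chromosome length ratio (1: < 2,
    2: 2..4, 3: > 4); column from the proportion of pairs with AR > 2
    (A: 0, B: up to 0.5, C: up to 0.99, D: 1).  Boundary values go to
    the lower row/column.
    """
    _require(pairs, 1, "stebbins_category")
    rl = np.array([p.rl_total_mean for p in pairs])
    size_ratio = rl.max() / rl.min()
    if size_ratio <= 2.0:
        row = "1"
    elif size_ratio <= 4.0:
        row = "2"
    else:
        row = "3"
    frac = np.mean([p.ar_mean > 2.0 for p in pairs])
    if frac == 0.0:
        col = "A"
    elif frac <= 0.5:
        col = "B"
    elif frac < 1.0:
        col = "C"
    else:
        col = "D"
    return row + col


def asymmetry_profile(pairs: Sequence[KaryotypePair]) -> AsymmetryProfile:
    """The full six-index asymmetry summary of a haploid karyotype."""
    ci = ci_stats(pairs)
    return AsymmetryProfile(
        ci_mean=ci["ci_mean"],
        ci_sd=ci["ci_sd"],
        a1=a1_index(pairs),
        a2=a2_index(pairs),
        ask_percent=ask_percent(pairs),
        ai=ai_index(pairs),
        stebbins=stebbins_category(pairs),
    )
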