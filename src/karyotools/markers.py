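"""Localized chromosomal features: rDNA sites, fluorochrome bands, GISH blocks.

A marker site is a feature on a chromosome pair described by the arm that
carries it, the distance d (um) from the centromere to the middle of the
site, and its extent (um) along the chromosome.  Two derived statistics
are the field's standard report:

* di = d x 100 / a, the percent distance from the centromere relative to
  the arm length a (satellite-inclusive, like the measurements);
* size percent = 100 x extent / TCL, the site's share of the haploid
  karyotype length.

Centromeric sites have no d; their extent contributes fully to the pair
total and is split evenly between the two arms for per-arm display
columns only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .measurements import Karyotype, ValidationError

__all__ = [
    "MarkerSite",
    "MARKER_KINDS",
    "di_percent",
    "size_percent",
    "read_markers",
    "marker_summary",
]

MARKER_KINDS = ("rDNA5S", "rDNA45S", "CPD", "sGISH")
ARMS = ("short", "long", "centromere")


@dataclass(frozen=True)
class MarkerSite:
    """One localized feature on one chromosome pair.

    Either ``extent_um`` (with a per-plate TCL supplied at summary time)
    or a pre-derived ``size_pct`` must be present; published tables often
    print only the percent.
    """

    pair_id: int
    kind: str
    arm: str
    d_um: float | None = None  # absent for centromeric sites
    extent_um: float | None = None
    size_pct: float | None = None
    plate_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in MARKER_KINDS:
            raise ValidationError(f"unknown marker kind {self.kind!r}")
        if self.arm not in ARMS:
            raise ValidationError(f"unknown arm {self.arm!r}")
        if self.arm == "centromere" and self.d_um is not None:
            raise ValidationError("centromeric sites carry no distance d")
        if self.extent_um is None and self.size_pct is None:
            raise ValidationError("site needs extent_um or size_pct")
        if self.extent_um is not None and self.extent_um <= 0:
            raise ValidationError(f"extent must be > 0, got {self.extent_um}")


def di_percent(d: float, a: float) -> float:
    """Percent distance from centromere to site middle: d x 100 / a."""
    if a <= 0:
        raise ValueError(f"arm length must be > 0, got {a}")
    if d < 0 or d > a:
        raise ValueError(f"site middle outside the arm: d = {d}, a = {a}")
    return d * 100.0 / a


def size_percent(extent: float, karyotype_length: float) -> float:
    """Site size as a percent of the haploid karyotype length (TCL)."""
    if extent <= 0:
        raise ValueError(f"extent must be > 0, got {extent}")
    if karyotype_length <= 0:
        raise ValueError(f"karyotype length must be > 0, got {karyotype_length}")
    return 100.0 * extent / karyotype_length


def read_markers(path) -> list[MarkerSite]:
    """Read a marker CSV (plate_id, pair_id, kind, arm, d_um, extent_um)."""
    df = pd.read_csv(path)
    required = ("pair_id", "kind", "arm")
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r}")
    sites = []
    for _, row in df.iterrows():
        d = row.get("d_um")
        sites.append(
            MarkerSite(
                pair_id=int(row["pair_id"]),
                kind=str(row["kind"]),
                arm=str(row["arm"]),
                d_um=None if pd.isna(d) else float(d),
                extent_um=float(row["extent_um"]) if "extent_um" in df.columns and pd.notna(row.get("extent_um")) else None,
                size_pct=float(row["size_pct"]) if "size_pct" in df.columns and pd.notna(row.get("size_pct")) else None,
                plate_id=str(row["plate_id"]) if "plate_id" in df.columns and pd.notna(row.get("plate_id")) else None,
            )
        )
    return sites


def marker_summary(
    karyotype: Karyotype,
    sites: Sequence[MarkerSite],
    plate_tcl: Mapping[str, float] | None = None,
) -> dict:
    """Aggregate marker sites into per-pair/per-arm and complement totals.

    Returns a dict with:

    * ``per_pair`` — DataFrame indexed by (kind, pair_id) with short-arm,
      long-arm and total size-percent mean +/- sample SD across plates
      (centromeric extents split evenly between arms in the per-arm
      columns only);
    * ``totals`` — DataFrame per kind with complement short/long/total
      percents (sums of the per-pair means);
    * ``di`` — DataFrame of per-site di values where d is present.
    """
    valid_pairs = {p.pair_id for p in karyotype.pairs}
    for s in sites:
        if s.pair_id not in valid_pairs:
            raise ValidationError(f"marker references unknown pair {s.pair_id}")

    if not sites:
        empty = pd.DataFrame(
            columns=["kind", "pair_id", "short_mean", "short_sd", "long_mean",
                     "long_sd", "total_mean", "total_sd"]
        )
        totals = pd.DataFrame(columns=["kind", "short_total", "long_total", "total"])
        return {"per_pair": empty, "totals": totals, "di": pd.DataFrame()}

    rows = []
    for s in sites:
        if s.size_pct is not None:
            pct = s.size_pct
        else:
            if plate_tcl is None or s.plate_id not in plate_tcl:
                raise ValidationError(
                    f"site on pair {s.pair_id} has extent in um but no TCL for "
                    f"plate {s.plate_id!r}"
                )
            pct = size_percent(s.extent_um, plate_tcl[s.plate_id])
        if s.arm == "short":
            short, long_ = pct, 0.0
        elif s.arm == "long":
            short, long_ = 0.0, pct
        else:  # centromeric: even split for the per-arm display columns
            short = long_ = pct / 2.0
        rows.append(
            {
                "kind": s.kind,
                "pair_id": s.pair_id,
                "plate_id": s.plate_id or "",
                "short": short,
                "long": long_,
                "total": pct,
            }
        )
    df = pd.DataFrame(rows)
    # mean across plates within (kind, pair); a site list without plate ids
    # (e.g. typed from a published table) aggregates over one pseudo-plate
    per_plate = df.groupby(["kind", "pair_id", "plate_id"], as_index=False)[
        ["short", "long", "total"]
    ].sum()
    g = per_plate.groupby(["kind", "pair_id"])
    per_pair = g.agg(
        short_mean=("short", "mean"),
        short_sd=("short", "std"),
        long_mean=("long", "mean"),
        long_sd=("long", "std"),
        total_mean=("total", "mean"),
        total_sd=("total", "std"),
    ).fillna(0.0).reset_index()

    totals = (
        per_pair.groupby("kind")
        .agg(
            short_total=("short_mean", "sum"),
            long_total=("long_mean", "sum"),
            total=("total_mean", "sum"),
        )
        .reset_index()
    )

    di_rows = []
    arm_lookup = {p.pair_id: p for p in karyotype.pairs}
    for s in sites:
        if s.d_um is None or s.arm == "centromere":
            continue
        pair = arm_lookup[s.pair_id]
        # mean arm length in um from the pair's RL share of the mean TCL
        a_um = None
        if karyotype.tcl_mean:
            rl_arm = pair.rl_short_mean if s.arm == "short" else pair.rl_long_mean
            a_um = rl_arm / 100.0 * karyotype.tcl_mean
        di_rows.append(
            {
                "pair_id": s.pair_id,
                "kind": s.kind,
                "arm": s.arm,
                "d_um": s.d_um,
                "di_percent": di_percent(s.d_um, a_um) if a_um else float("nan"),
            }
        )
    di = pd.DataFrame(di_rows)
    return {"per_pair": per_pair, "totals": totals, "di": di}
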