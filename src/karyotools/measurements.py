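"""Per-metaphase chromosome measurements and their aggregation.

Chromosome arm lengths are recorded per metaphase plate (one row per
homolog), normalised so the long arm is the longer one, and aggregated
across plates into a haploid karyotype table: relative lengths (RL, % of
haploid complement), arm ratios (AR, long/short), centromeric indices
(CI, 100 x short/total), each as mean +/- sample SD over plates, plus the
total haploid complement length (TCL, um).

Measurement conventions follow standard plant cytogenetic practice:
satellite lengths are included in the arm that carries them, stretched
secondary-constriction lengths are excluded by the measurer.  The reader
stores the satellite flags but performs no satellite arithmetic.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChromosomeObservation",
    "MetaphasePlate",
    "KaryotypePair",
    "Karyotype",
    "SchemaError",
    "ValidationError",
    "read_plates",
    "relative_lengths",
    "aggregate",
    "total_complement_length",
    "karyotype_to_frame",
    "karyotype_to_json",
]

SATELLITE_ARMS = ("none", "short", "long")


class SchemaError(ValueError):
    """An input table is missing a required column."""


class ValidationError(ValueError):
    """An input table violates a measurement invariant."""


@dataclass(frozen=True)
class ChromosomeObservation:
    """One measured chromosome in one metaphase plate.

    Arm lengths are in um; orientation is normalised on construction so
    ``long_arm >= short_arm`` (a swapped input is corrected, not an error,
    because homolog orientation on the slide is arbitrary).
    """

    plate_id: str
    pair_id: int
    homolog_tag: str  # "a" or "b"
    short_arm: float
    long_arm: float
    satellite_arm: str = "none"
    satellite_included: bool = True

    def __post_init__(self) -> None:
        for name in ("short_arm", "long_arm"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValidationError(
                    f"{name} must be finite and > 0, got {v!r} "
                    f"(plate {self.plate_id}, pair {self.pair_id})"
                )
        if self.satellite_arm not in SATELLITE_ARMS:
            raise ValidationError(
                f"satellite_arm must be one of {SATELLITE_ARMS}, got {self.satellite_arm!r}"
            )
        if self.short_arm > self.long_arm:
            s, l = self.short_arm, self.long_arm
            object.__setattr__(self, "short_arm", l)
            object.__setattr__(self, "long_arm", s)

    @property
    def total(self) -> float:
        return self.short_arm + self.long_arm


@dataclass(frozen=True)
class MetaphasePlate:
    """All chromosome observations of one metaphase spread (2 per pair)."""

    plate_id: str
    observations: tuple[ChromosomeObservation, ...]
    condensation_rank: int | None = None  # 1 = most condensed

    def __post_init__(self) -> None:
        counts: dict[int, int] = {}
        for obs in self.observations:
            counts[obs.pair_id] = counts.get(obs.pair_id, 0) + 1
        bad = {p: c for p, c in counts.items() if c != 2}
        if bad:
            pid, c = next(iter(sorted(bad.items())))
            raise ValidationError(
                f"pair {pid} has {c} homolog{'s' if c != 1 else ''} in plate {self.plate_id}"
            )

    @property
    def pair_ids(self) -> tuple[int, ...]:
        return tuple(sorted({o.pair_id for o in self.observations}))

    def haploid_arms(self) -> pd.DataFrame:
        """Homolog-averaged short/long arm lengths (um) per pair."""
        rows = {}
        for obs in self.observations:
            rows.setdefault(obs.pair_id, []).append(obs)
        out = []
        for pid in sorted(rows):
            a, b = rows[pid]
            out.append(
                {
                    "pair_id": pid,
                    "short_um": 0.5 * (a.short_arm + b.short_arm),
                    "long_um": 0.5 * (a.long_arm + b.long_arm),
                    "satellite_arm": a.satellite_arm if a.satellite_arm != "none" else b.satellite_arm,
                }
            )
        df = pd.DataFrame(out)
        df["total_um"] = df["short_um"] + df["long_um"]
        return df


@dataclass(frozen=True)
class KaryotypePair:
    """Aggregated per-pair statistics across plates (RL in %, AR, CI in %)."""

    pair_id: int
    rl_short_mean: float
    rl_short_sd: float
    rl_long_mean: float
    rl_long_sd: float
    rl_total_mean: float
    rl_total_sd: float
    ar_mean: float
    ar_sd: float
    ci_mean: float
    ci_sd: float
    satellite_arm: str = "none"
    type_code: str | None = None  # filled by the classification module
    source_pair_id: int | None = None  # input pair_id before size renumbering


@dataclass(frozen=True)
class Karyotype:
    """An ordered haploid karyotype: pairs sorted by decreasing size."""

    label: str
    two_n: int
    pairs: tuple[KaryotypePair, ...]
    tcl_mean: float | None = None
    tcl_sd: float | None = None
    formula: str | None = None

    def __post_init__(self) -> None:
        if self.two_n != 2 * len(self.pairs):
            raise ValidationError(
                f"two_n = {self.two_n} but karyotype has {len(self.pairs)} pairs"
            )


# ---------------------------------------------------------------------------
# reading

_DEFAULT_SCHEMA = {
    "plate_id": "plate_id",
    "pair_id": "pair_id",
    "homolog": "homolog",
    "short_arm": "short_arm_um",
    "long_arm": "long_arm_um",
    "satellite_arm": "satellite_arm",
    "condensation_rank": "condensation_rank",
}

_REQUIRED = ("plate_id", "pair_id", "homolog", "short_arm", "long_arm")


def read_plates(path, schema: Mapping[str, str] | None = None) -> list[MetaphasePlate]:
    """Read a measurement CSV into validated metaphase plates.

    Parameters
    ----------
    path
        CSV with one row per measured homolog.  Default columns:
        plate_id, pair_id, homolog, short_arm_um, long_arm_um and
        optionally satellite_arm, condensation_rank.
    schema
        Optional mapping from logical field names to column names,
        overriding the defaults above.
    """
    cols = dict(_DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    df = pd.read_csv(path)
    for key in _REQUIRED:
        if cols[key] not in df.columns:
            raise SchemaError(f"missing required column {cols[key]!r}")
    has_sat = cols["satellite_arm"] in df.columns
    has_rank = cols["condensation_rank"] in df.columns

    plates: list[MetaphasePlate] = []
    for plate_id, sub in df.groupby(cols["plate_id"], sort=True):
        obs = []
        for idx, row in sub.iterrows():
            for arm_key in ("short_arm", "long_arm"):
                v = row[cols[arm_key]]
                if not (np.isfinite(v) and v > 0):
                    raise ValidationError(
                        f"non-positive or non-finite {arm_key} in row {idx} "
                        f"(plate {plate_id}, pair {row[cols['pair_id']]})"
                    )
            sat = "none"
            if has_sat and isinstance(row[cols["satellite_arm"]], str):
                sat = row[cols["satellite_arm"]].strip() or "none"
            obs.append(
                ChromosomeObservation(
                    plate_id=str(plate_id),
                    pair_id=int(row[cols["pair_id"]]),
                    homolog_tag=str(row[cols["homolog"]]),
                    short_arm=float(row[cols["short_arm"]]),
                    long_arm=float(row[cols["long_arm"]]),
                    satellite_arm=sat,
                )
            )
        rank = None
        if has_rank:
            r = sub[cols["condensation_rank"]].iloc[0]
            if pd.notna(r):
                rank = int(r)
        plates.append(MetaphasePlate(str(plate_id), tuple(obs), rank))
    return plates


# ---------------------------------------------------------------------------
# per-plate statistics

def relative_lengths(plate: MetaphasePlate) -> pd.DataFrame:
    """Per-pair relative lengths (% of haploid complement) for one plate.

    Homologs are averaged to a haploid value per pair; each arm is then
    expressed as a percentage of the plate's haploid complement length,
    so rl_total sums to 100 exactly up to floating point.
    """
    arms = plate.haploid_arms()
    tcl = arms["total_um"].sum()
    out = arms[["pair_id", "satellite_arm"]].copy()
    out["rl_short"] = 100.0 * arms["short_um"] / tcl
    out["rl_long"] = 100.0 * arms["long_um"] / tcl
    out["rl_total"] = out["rl_short"] + out["rl_long"]
    out["ar"] = arms["long_um"] / arms["short_um"]
    out["ci"] = 100.0 * arms["short_um"] / arms["total_um"]
    return out


def aggregate(plates: Sequence[MetaphasePlate], label: str = "") -> Karyotype:
    """Aggregate plates into a karyotype of per-pair means and sample SDs.

    Per-plate AR is the ratio of homolog-averaged arms and per-plate CI is
    100 x short/(short+long); the reported means are means of the per-plate
    ratios (not ratios of means).  Pairs are renumbered 1..n in decreasing
    order of mean total relative length, ties broken by input pair_id.
    """
    if not plates:
        raise ValidationError("aggregate requires at least one plate")
    ref = plates[0].pair_ids
    for p in plates[1:]:
        if p.pair_ids != ref:
            raise ValidationError(
                f"plate {p.plate_id} has pair set {p.pair_ids}, expected {ref}"
            )
    per_plate = pd.concat(
        [relative_lengths(p).assign(plate=p.plate_id) for p in plates],
        ignore_index=True,
    )
    stats = (
        per_plate.groupby("pair_id")
        .agg(
            rl_short_mean=("rl_short", "mean"),
            rl_short_sd=("rl_short", "std"),
            rl_long_mean=("rl_long", "mean"),
            rl_long_sd=("rl_long", "std"),
            rl_total_mean=("rl_total", "mean"),
            rl_total_sd=("rl_total", "std"),
            ar_mean=("ar", "mean"),
            ar_sd=("ar", "std"),
            ci_mean=("ci", "mean"),
            ci_sd=("ci", "std"),
        )
        .fillna(0.0)  # single plate: sample SD undefined -> 0
        .reset_index()
    )
    sat = per_plate.groupby("pair_id")["satellite_arm"].agg(
        lambda s: next((x for x in s if x != "none"), "none")
    )
    stats["satellite_arm"] = stats["pair_id"].map(sat)
    stats = stats.sort_values(
        ["rl_total_mean", "pair_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)

    pairs = tuple(
        KaryotypePair(
            pair_id=i + 1,
            rl_short_mean=row.rl_short_mean,
            rl_short_sd=row.rl_short_sd,
            rl_long_mean=row.rl_long_mean,
            rl_long_sd=row.rl_long_sd,
            rl_total_mean=row.rl_total_mean,
            rl_total_sd=row.rl_total_sd,
            ar_mean=row.ar_mean,
            ar_sd=row.ar_sd,
            ci_mean=row.ci_mean,
            ci_sd=row.ci_sd,
            satellite_arm=row.satellite_arm,
            source_pair_id=int(row.pair_id),
        )
        for i, row in enumerate(stats.itertuples())
    )
    tcl = total_complement_length(plates, k=len(plates))
    kt = Karyotype(
        label=label,
        two_n=2 * len(pairs),
        pairs=pairs,
        tcl_mean=tcl["tcl_mean"],
        tcl_sd=tcl["tcl_sd"],
    )
    # classification lives in its own module; attach type codes + formula here
    from . import classification

    typed = tuple(
        replace(p, type_code=classification.levan_type(p.ar_mean)) for p in kt.pairs
    )
    kt = replace(kt, pairs=typed)
    return replace(kt, formula=classification.karyotype_formula(kt))


def total_complement_length(plates: Sequence[MetaphasePlate], k: int) -> dict:
    """TCL mean +/- sample SD (um) over the k most condensed plates.

    Plates are selected by condensation_rank (1 = most condensed); when
    ranks are absent all plates are used with a warning.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > len(plates):
        raise ValueError(f"k = {k} exceeds the number of plates ({len(plates)})")
    ranked = [p for p in plates if p.condensation_rank is not None]
    if len(ranked) == len(plates):
        selected = sorted(plates, key=lambda p: p.condensation_rank)[:k]
    else:
        if k < len(plates):
            warnings.warn(
                "condensation_rank absent; using all plates for TCL", stacklevel=2
            )
        selected = list(plates)
    tcls = np.array([p.haploid_arms()["total_um"].sum() for p in selected])
    sd = float(np.std(tcls, ddof=1)) if len(tcls) > 1 else 0.0
    return {"tcl_mean": float(np.mean(tcls)), "tcl_sd": sd}


# ---------------------------------------------------------------------------
# export

def karyotype_to_frame(karyotype: Karyotype) -> pd.DataFrame:
    """Karyotype as a table mirroring the conventional published layout."""
    rows = []
    for p in karyotype.pairs:
        rows.append(
            {
                "pair_id": p.pair_id,
                "rl_short_mean": round(p.rl_short_mean, 2),
                "rl_short_sd": round(p.rl_short_sd, 2),
                "rl_long_mean": round(p.rl_long_mean, 2),
                "rl_long_sd": round(p.rl_long_sd, 2),
                "rl_total_mean": round(p.rl_total_mean, 2),
                "rl_total_sd": round(p.rl_total_sd, 2),
                "ar_mean": round(p.ar_mean, 2),
                "ar_sd": round(p.ar_sd, 2),
                "ci_mean": round(p.ci_mean, 2),
                "ci_sd": round(p.ci_sd, 2),
                "type": (p.type_code or "") + ("-SAT" if p.satellite_arm != "none" else ""),
            }
        )
    return pd.DataFrame(rows)


def karyotype_to_json(karyotype: Karyotype) -> str:
    payload = {
        "label": karyotype.label,
        "two_n": karyotype.two_n,
        "tcl_mean": karyotype.tcl_mean,
        "tcl_sd": karyotype.tcl_sd,
        "formula": karyotype.formula,
        "pairs": karyotype_to_frame(karyotype).to_dict(orient="records"),
    }
    return json.dumps(payload, indent=2)
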