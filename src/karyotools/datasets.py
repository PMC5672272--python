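"""Published karyotype tables of the two cultivated Canavalia species.

Canavalia gladiata (sword bean) and C. ensiformis (jack bean) are the
genus's two crops; their karyotypes (2n = 22, all metacentric, satellite
pairs 6 and 7) were measured over five metaphase plates per species.
This module ships the printed per-pair table — relative lengths, arm
ratios, centromeric CPD band and sGISH signal sizes (all percents of the
haploid karyotype length) — as ready-made :class:`Karyotype` and
:class:`MarkerSite` objects, for use as fixtures and worked examples.

Values are the published rounded numbers; statistics recomputed from
them can differ from the originally reported ones (computed on raw um
measurements) in the last digit.
"""

from __future__ import annotations

from dataclasses import replace

from .classification import karyotype_formula, levan_type
from .measurements import Karyotype, KaryotypePair
from .markers import MarkerSite

__all__ = [
    "canavalia_gladiata",
    "canavalia_ensiformis",
    "gladiata_marker_sites",
    "ensiformis_marker_sites",
    "rdna_di_values",
]

# per pair: (rl_short, sd, rl_long, sd, rl_total, sd, ar, sd)
_GLADIATA_MEASUREMENTS = [
    (5.25, 0.23, 6.70, 0.24, 11.95, 0.41, 1.28, 0.05),
    (4.43, 0.10, 6.39, 0.36, 10.82, 0.31, 1.44, 0.10),
    (4.72, 0.37, 5.69, 0.19, 10.40, 0.28, 1.21, 0.12),
    (4.63, 0.20, 5.57, 0.17, 10.20, 0.17, 1.21, 0.08),
    (3.61, 0.08, 5.53, 0.09, 9.15, 0.16, 1.53, 0.02),
    (3.71, 0.46, 5.11, 0.22, 8.83, 0.61, 1.39, 0.16),
    (4.14, 0.20, 4.50, 0.26, 8.64, 0.38, 1.09, 0.06),
    (3.42, 0.25, 4.68, 0.12, 8.11, 0.21, 1.38, 0.13),
    (3.20, 0.08, 4.53, 0.20, 7.73, 0.18, 1.42, 0.08),
    (3.39, 0.10, 4.31, 0.29, 7.70, 0.38, 1.27, 0.06),
    (2.44, 0.16, 4.03, 0.21, 6.47, 0.27, 1.65, 0.13),
]

_ENSIFORMIS_MEASUREMENTS = [
    (5.58, 0.23, 7.02, 0.38, 12.60, 0.18, 1.26, 0.11),
    (4.43, 0.18, 6.62, 0.28, 11.05, 0.38, 1.50, 0.07),
    (5.02, 0.16, 5.33, 0.60, 10.35, 0.51, 1.06, 0.14),
    (4.68, 0.16, 5.35, 0.43, 10.03, 0.53, 1.14, 0.08),
    (3.49, 0.19, 5.36, 0.28, 8.85, 0.29, 1.54, 0.13),
    (3.96, 0.29, 4.80, 0.25, 8.76, 0.46, 1.22, 0.08),
    (3.65, 0.25, 4.46, 0.16, 8.11, 0.15, 1.23, 0.13),
    (3.76, 0.25, 4.25, 0.28, 8.01, 0.41, 1.13, 0.10),
    (2.99, 0.23, 4.73, 0.32, 7.72, 0.23, 1.59, 0.22),
    (3.35, 0.24, 4.34, 0.22, 7.69, 0.44, 1.30, 0.05),
    (2.59, 0.27, 4.23, 0.19, 6.82, 0.44, 1.64, 0.12),
]

# per pair: (cpd_pct, sd, sgish_short, sd, sgish_long, sd, sgish_total, sd)
_GLADIATA_SIGNALS = [
    (1.53, 0.27, 3.19, 0.19, 4.17, 0.13, 7.35, 0.22),
    (1.93, 0.15, 3.07, 0.33, 2.96, 0.19, 6.03, 0.38),
    (1.63, 0.17, 1.44, 0.28, 3.56, 0.13, 5.00, 0.28),
    (1.67, 0.14, 3.19, 0.22, 2.50, 0.15, 5.69, 0.09),
    (1.76, 0.19, 3.61, 0.08, 1.94, 0.24, 5.55, 0.31),
    (1.54, 0.10, 3.71, 0.46, 2.79, 0.26, 6.50, 0.67),
    (1.14, 0.18, 4.14, 0.20, 2.13, 0.32, 6.27, 0.50),
    (1.93, 0.27, 2.33, 0.23, 3.01, 0.14, 5.34, 0.31),
    (1.79, 0.11, 3.20, 0.08, 1.77, 0.21, 4.97, 0.25),
    (1.36, 0.16, 1.62, 0.28, 2.55, 0.32, 4.18, 0.31),
    (1.32, 0.12, 2.43, 0.18, 1.73, 0.17, 4.15, 0.33),
]

_ENSIFORMIS_SIGNALS = [
    (2.54, 0.57, 3.18, 0.17, 3.99, 0.29, 7.17, 0.36),
    (2.32, 0.63, 2.53, 0.29, 3.14, 0.20, 5.66, 0.40),
    (2.14, 0.68, 3.77, 0.24, 2.32, 0.11, 6.10, 0.29),
    (1.93, 0.40, 1.67, 0.21, 3.57, 0.19, 5.24, 0.37),
    (1.80, 0.23, 2.12, 0.17, 2.13, 0.32, 4.25, 0.31),
    (2.08, 0.51, 3.96, 0.29, 2.87, 0.24, 6.83, 0.31),
    (1.45, 0.18, 3.65, 0.25, 2.48, 0.55, 6.13, 0.57),
    (1.88, 0.33, 1.65, 0.22, 2.73, 0.15, 4.38, 0.34),
    (1.76, 0.20, 2.99, 0.23, 1.81, 0.19, 4.80, 0.35),
    (1.67, 0.18, 2.06, 0.15, 2.56, 0.26, 4.62, 0.37),
    (1.68, 0.08, 2.59, 0.27, 1.76, 0.38, 4.35, 0.61),
]

_SATELLITE_PAIRS = {6: "short", 7: "short"}  # SC on short arms of pairs 6, 7

# TCL, um, over the five most condensed plates
_TCL = {"C. gladiata": (40.46, 1.03), "C. ensiformis": (34.06, 3.87)}

# published di values (% distance from centromere) for rDNA-FISH loci
rdna_di_values = {
    "C. gladiata": {("rDNA45S", 6, "short"): 54.32, ("rDNA45S", 7, "short"): 38.67},
    "C. ensiformis": {
        ("rDNA45S", 6, "short"): 50.57,
        ("rDNA45S", 7, "short"): 26.14,
        ("rDNA45S", 10, "short"): 29.05,
        ("rDNA5S", 6, "short"): 32.07,
    },
}


def _build(label: str, measurements) -> Karyotype:
    pairs = []
    for i, (rs, rs_sd, rl, rl_sd, rt, rt_sd, ar, ar_sd) in enumerate(measurements, 1):
        ci = 100.0 / (1.0 + ar)
        pair = KaryotypePair(
            pair_id=i,
            rl_short_mean=rs, rl_short_sd=rs_sd,
            rl_long_mean=rl, rl_long_sd=rl_sd,
            rl_total_mean=rt, rl_total_sd=rt_sd,
            ar_mean=ar, ar_sd=ar_sd,
            ci_mean=ci, ci_sd=0.0,
            satellite_arm=_SATELLITE_PAIRS.get(i, "none"),
            type_code=levan_type(ar),
        )
        pairs.append(pair)
    tcl_mean, tcl_sd = _TCL[label]
    kt = Karyotype(
        label=label, two_n=2 * len(pairs), pairs=tuple(pairs),
        tcl_mean=tcl_mean, tcl_sd=tcl_sd,
    )
    return replace(kt, formula=karyotype_formula(kt))


def canavalia_gladiata() -> Karyotype:
    """The published C. gladiata karyotype (2n = 22, five plates)."""
    return _build("C. gladiata", _GLADIATA_MEASUREMENTS)


def canavalia_ensiformis() -> Karyotype:
    """The published C. ensiformis karyotype (2n = 22, five plates)."""
    return _build("C. ensiformis", _ENSIFORMIS_MEASUREMENTS)


def _sites(signals) -> list[MarkerSite]:
    out = []
    for pid, (cpd, _, sg_s, _, sg_l, _, _, _) in enumerate(signals, 1):
        out.append(MarkerSite(pair_id=pid, kind="CPD", arm="centromere", size_pct=cpd))
        out.append(MarkerSite(pair_id=pid, kind="sGISH", arm="short", size_pct=sg_s))
        out.append(MarkerSite(pair_id=pid, kind="sGISH", arm="long", size_pct=sg_l))
    return out


def gladiata_marker_sites() -> list[MarkerSite]:
    """CPD band and sGISH signal sizes of C. gladiata (percent of TCL)."""
    return _sites(_GLADIATA_SIGNALS)


def ensiformis_marker_sites() -> list[MarkerSite]:
    """CPD band and sGISH signal sizes of C. ensiformis (percent of TCL)."""
    return _sites(_ENSIFORMIS_SIGNALS)
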