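"""Synthetic metaphase measurements and 5S rDNA amplicons with ground truth.

The plate generator emulates what a measurer records from five CPD/FISH
metaphase spreads of an 11-pair metacentric complement: per-plate
condensation scales every chromosome by a common factor, and each arm of
each homolog carries independent multiplicative lognormal noise.  The
amplicon generator assembles repeat-unit amplicons (40-bp gene tail +
NTS + optional full 120-bp gene + NTS + 58-bp gene head) with GC-rich
spacers and configurable between-copy divergence.

Every draw comes from one seeded NumPy generator, so identical configs
give byte-identical outputs, and the true parameters are returned next
to the data for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .measurements import ChromosomeObservation, MetaphasePlate
from .rdna_unit import DEFAULT_GENE_CONSENSUS, FLANK3_LEN, FLANK5_LEN

__all__ = [
    "KaryotypeSimConfig",
    "RepeatSimConfig",
    "simulate_plates",
    "simulate_amplicons",
    "write_measurements_csv",
    "write_markers_csv",
    "write_ground_truth",
]

# study-condition defaults: the published C. gladiata karyotype
_DEFAULT_RL = (11.95, 10.82, 10.40, 10.20, 9.15, 8.83, 8.64, 8.11, 7.73, 7.70, 6.47)
_DEFAULT_AR = (1.28, 1.44, 1.21, 1.21, 1.53, 1.39, 1.09, 1.38, 1.42, 1.27, 1.65)


def _normalised(rl: Sequence[float]) -> tuple[float, ...]:
    total = float(sum(rl))
    return tuple(100.0 * v / total for v in rl)


@dataclass(frozen=True)
class KaryotypeSimConfig:
    """True karyotype plus measurement-noise settings.

    noise_cv is the coefficient of variation of the per-arm lognormal
    noise (0.02 matches the spread of published SD columns); plate-level
    condensation factors are uniform on [0.85, 1.15].
    """

    n_pairs: int = 11
    true_rl: tuple = _normalised(_DEFAULT_RL)
    true_ar: tuple = _DEFAULT_AR
    tcl_um: float = 40.46
    n_plates: int = 5
    noise_cv: float = 0.02
    satellite_pairs: tuple = ((6, "short"), (7, "short"))
    # (pair_id, kind, arm, true_di percent, true_size_percent)
    marker_spec: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.true_rl) != self.n_pairs or len(self.true_ar) != self.n_pairs:
            raise ValueError("true_rl / true_ar must have n_pairs entries")
        if abs(sum(self.true_rl) - 100.0) > 1e-9:
            raise ValueError(f"true_rl must sum to 100, got {sum(self.true_rl)}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_plates(config: KaryotypeSimConfig) -> tuple[list[MetaphasePlate], dict]:
    """Generate metaphase plates (and marker sites) with known truth."""
    rng = np.random.default_rng(config.seed)
    sat = dict(config.satellite_pairs)
    plates: list[MetaphasePlate] = []
    marker_rows: list[dict] = []
    plate_tcl: dict[str, float] = {}

    condensation = rng.uniform(0.85, 1.15, size=config.n_plates)
    # most condensed = shortest chromosomes: rank 1 = smallest factor
    ranks = np.empty(config.n_plates, dtype=int)
    ranks[np.argsort(condensation)] = np.arange(1, config.n_plates + 1)

    for pi in range(config.n_plates):
        plate_id = f"P{pi + 1}"
        factor = condensation[pi]
        obs = []
        arms_by_pair: dict[int, tuple[float, float]] = {}
        for pair_idx in range(config.n_pairs):
            pid = pair_idx + 1
            total = config.true_rl[pair_idx] / 100.0 * config.tcl_um * factor
            ar = config.true_ar[pair_idx]
            short_true = total / (1.0 + ar)
            long_true = total * ar / (1.0 + ar)
            noise = _lognormal_factor(rng, config.noise_cv, 4)
            for h, tag in enumerate("ab"):
                obs.append(
                    ChromosomeObservation(
                        plate_id=plate_id,
                        pair_id=pid,
                        homolog_tag=tag,
                        short_arm=short_true * noise[2 * h],
                        long_arm=long_true * noise[2 * h + 1],
                        satellite_arm=sat.get(pid, "none"),
                    )
                )
            arms_by_pair[pid] = (short_true, long_true)
        plate = MetaphasePlate(plate_id, tuple(obs), condensation_rank=int(ranks[pi]))
        plates.append(plate)
        tcl = plate.haploid_arms()["total_um"].sum()
        plate_tcl[plate_id] = float(tcl)

        for pid, kind, arm, true_di, true_size in config.marker_spec:
            arm_um = {
                "short": arms_by_pair[pid][0],
                "long": arms_by_pair[pid][1],
                "centromere": None,
            }[arm]
            d_um = None if arm == "centromere" else true_di / 100.0 * arm_um
            extent = true_size / 100.0 * tcl * _lognormal_factor(rng, config.noise_cv, 1)[0]
            marker_rows.append(
                {
                    "plate_id": plate_id,
                    "pair_id": pid,
                    "kind": kind,
                    "arm": arm,
                    "d_um": d_um,
                    "extent_um": extent,
                }
            )

    truth = {
        "true_rl": list(config.true_rl),
        "true_ar": list(config.true_ar),
        "tcl_um": config.tcl_um,
        "noise_cv": config.noise_cv,
        "satellite_pairs": [list(x) for x in config.satellite_pairs],
        "marker_spec": [list(x) for x in config.marker_spec],
        "condensation": condensation.tolist(),
        "plate_tcl": plate_tcl,
        "marker_sites": marker_rows,
        "seed": config.seed,
    }
    return plates, truth


# ---------------------------------------------------------------------------
# 5S rDNA amplicons

@dataclass(frozen=True)
class RepeatSimConfig:
    """Structure and divergence of simulated 5S repeat-unit amplicons.

    nts_gc is the target G+C percent of the spacer (5S spacers in the
    emulated system are GC-rich, around 60-63%); divergence is the
    per-site substitution probability between the two NTS copies of the
    major amplicon and indel_rate adds length-neutral 1-bp indel churn.
    """

    gene_consensus: str = DEFAULT_GENE_CONSENSUS
    nts_length_a: int = 361
    nts_length_b: int = 361
    nts_gc: float = 62.9
    divergence: float = 0.10
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.gene_consensus.startswith("AGG") and self.gene_consensus.endswith("TCC")):
            raise ValueError("gene consensus must start AGG and end TCC")
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")


_BASES = np.array(list("ACGT"))


def _random_nts(rng: np.random.Generator, length: int, gc: float) -> str:
    p_gc = gc / 100.0
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]  # A C G T
    return "".join(rng.choice(_BASES, size=length, p=probs))


def _mutate(rng: np.random.Generator, seq: str, divergence: float,
            indel_rate: float, target_length: int, gc: float) -> str:
    chars = list(seq)
    # substitutions
    for i in range(len(chars)):
        if rng.random() < divergence:
            options = [b for b in "ACGT" if b != chars[i]]
            chars[i] = options[rng.integers(3)]
    # length-neutral indel churn: paired 1-bp deletion + insertion
    n_churn = rng.binomial(len(chars), indel_rate)
    for _ in range(n_churn):
        del chars[rng.integers(len(chars))]
        pos = rng.integers(len(chars) + 1)
        chars.insert(pos, _random_nts(rng, 1, gc))
    # adjust to the target length
    while len(chars) > target_length:
        del chars[rng.integers(len(chars))]
    while len(chars) < target_length:
        pos = rng.integers(len(chars) + 1)
        chars.insert(pos, _random_nts(rng, 1, gc))
    return "".join(chars)


def simulate_amplicons(config: RepeatSimConfig) -> tuple[list[tuple[str, str]], dict]:
    """Build one major and one minor amplicon with known segment truth."""
    rng = np.random.default_rng(config.seed)
    gene = config.gene_consensus
    flank5 = gene[-FLANK5_LEN:]
    flank3 = gene[:FLANK3_LEN]
    nts1 = _random_nts(rng, config.nts_length_a, config.nts_gc)
    nts2 = _mutate(
        rng, nts1, config.divergence, config.indel_rate,
        config.nts_length_b, config.nts_gc,
    )
    major = flank5 + nts1 + gene + nts2 + flank3
    minor = flank5 + nts1 + flank3
    records = [("major_sim", major), ("minor_sim", minor)]
    truth = {
        "gene": gene,
        "nts1": nts1,
        "nts2": nts2,
        "major_segments": {
            "flank5": [0, FLANK5_LEN],
            "nts1": [FLANK5_LEN, FLANK5_LEN + len(nts1)],
            "gene": [FLANK5_LEN + len(nts1), FLANK5_LEN + len(nts1) + len(gene)],
            "nts2": [
                FLANK5_LEN + len(nts1) + len(gene),
                FLANK5_LEN + len(nts1) + len(gene) + len(nts2),
            ],
            "flank3": [len(major) - FLANK3_LEN, len(major)],
        },
        "seed": config.seed,
    }
    return records, truth


# ---------------------------------------------------------------------------
# fixture writers

def write_measurements_csv(plates: Sequence[MetaphasePlate], path) -> None:
    rows = []
    for p in plates:
        for o in p.observations:
            rows.append(
                {
                    "plate_id": o.plate_id,
                    "pair_id": o.pair_id,
                    "homolog": o.homolog_tag,
                    "short_arm_um": o.short_arm,
                    "long_arm_um": o.long_arm,
                    "satellite_arm": o.satellite_arm,
                    "condensation_rank": p.condensation_rank,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_markers_csv(marker_rows: Sequence[dict], path) -> None:
    pd.DataFrame(
        marker_rows,
        columns=["plate_id", "pair_id", "kind", "arm", "d_um", "extent_um"],
    ).to_csv(path, index=False)


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
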