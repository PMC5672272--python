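import numpy as np
import pytest

from karyotools import datasets
from karyotools.measurements import (
    ChromosomeObservation,
    KaryotypePair,
    MetaphasePlate,
)


@pytest.fixture(scope="session")
def gladiata():
    return datasets.canavalia_gladiata()


@pytest.fixture(scope="session")
def ensiformis():
    return datasets.canavalia_ensiformis()


def make_plate(haploid_arms, plate_id="P1", rank=None, satellites=None):
    """Build a plate from a list of (short, long) haploid arm pairs.

    Both homologs get identical arms, so plate-level statistics equal the
    haploid input exactly.
    """
    satellites = satellites or {}
    obs = []
    for i, (s, l) in enumerate(haploid_arms, 1):
        for tag in "ab":
            obs.append(
                ChromosomeObservation(
                    plate_id=plate_id,
                    pair_id=i,
                    homolog_tag=tag,
                    short_arm=s,
                    long_arm=l,
                    satellite_arm=satellites.get(i, "none"),
                )
            )
    return MetaphasePlate(plate_id, tuple(obs), condensation_rank=rank)


def make_pairs(arms):
    """KaryotypePair list from haploid (short, long) arm lengths."""
    arms = np.asarray(arms, dtype=float)
    totals = arms.sum(axis=1)
    tcl = totals.sum()
    pairs = []
    for i, (s, l) in enumerate(arms, 1):
        pairs.append(
            KaryotypePair(
                pair_id=i,
                rl_short_mean=100 * s / tcl,
                rl_short_sd=0.0,
                rl_long_mean=100 * l / tcl,
                rl_long_sd=0.0,
                rl_total_mean=100 * (s + l) / tcl,
                rl_total_sd=0.0,
                ar_mean=l / s,
                ar_sd=0.0,
                ci_mean=100 * s / (s + l),
                ci_sd=0.0,
            )
        )
    return pairs


def random_arms(rng, n_pairs=11):
    """Random haploid arm lengths with long >= short."""
    short = rng.uniform(1.0, 3.0, n_pairs)
    ar = rng.uniform(1.0, 2.5, n_pairs)
    return np.column_stack([short, short * ar])
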