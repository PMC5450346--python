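"""Shared fixtures: small deterministic datasets built in memory."""

import numpy as np
import pandas as pd
import pytest

from adigen.containers import PhasedGenotypeMatrix
from adigen.simulate import SimulationConfig, simulate_dataset


def make_gm(paternal, maternal, unphased_het=None, chrom=None):
    """Tiny PhasedGenotypeMatrix from allele arrays."""
    pat = np.asarray(paternal, dtype=np.int8)
    n, m = pat.shape
    chroms = chrom if chrom is not None else ["1"] * m
    variants = pd.DataFrame(
        dict(
            chrom=chroms,
            pos=[100 * (k + 1) for k in range(m)],
            id=[f"v{k + 1}" for k in range(m)],
            ref="A",
            alt="B",
        )
    )
    # restart positions per chromosome to keep them increasing within chrom
    pos = []
    counters = {}
    for c in chroms:
        counters[c] = counters.get(c, 0) + 1
        pos.append(100 * counters[c])
    variants["pos"] = pos
    return PhasedGenotypeMatrix(
        paternal=pat,
        maternal=np.asarray(maternal, dtype=np.int8),
        sample_ids=[f"ind{i + 1}" for i in range(n)],
        variants=variants,
        unphased_het=unphased_het,
    )


def gm_from_classes(classes):
    """Build a matrix from ordered-genotype class indices (0..3)."""
    cls = np.asarray(classes, dtype=np.int8)
    return make_gm(cls // 2, cls % 2)


@pytest.fixture(scope="session")
def milk_dataset():
    """Moderate milk-like simulated dataset shared across tests."""
    cfg = SimulationConfig(
        n_individuals=600,
        n_markers=1200,
        n_qtl=(500, 50, 50),
        target_fractions=(0.338, 0.040, 0.008),
        seed=20240917,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def hwe_population():
    """Unrelated population in HWE: random-mating founders only."""
    rng = np.random.default_rng(7)
    n, m = 500, 5000
    p = rng.uniform(0.05, 0.95, m)
    pat = (rng.random((n, m)) < p).astype(np.int8)
    mat = (rng.random((n, m)) < p).astype(np.int8)
    return make_gm(pat, mat)
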