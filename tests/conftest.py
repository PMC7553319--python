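"""Shared fixtures: small deterministic libraries and an independent NNLS oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phagescreen import synthetic as syn
from phagescreen.containers import CountTable


@pytest.fixture(scope="session")
def genome():
    """60 equal genes of 1 kb separated by 100 bp gaps (66 kb replicon)."""
    return syn.GenomeModel.regular(60, 1000, 100)


@pytest.fixture(scope="session")
def pool(genome):
    return syn.make_barcode_pool(genome, 600, seed=1)


@pytest.fixture(scope="session")
def fmap(genome):
    return syn.make_fragment_map(genome, 400, mean_len_bp=2500, sd_len_bp=500, seed=2)


@pytest.fixture(scope="session")
def guides(genome):
    return syn.make_guide_library(genome, guides_per_gene=3, n_promoters=10, seed=3)


def make_count_table(counts: dict, roles: dict, set_label: str = "set1") -> CountTable:
    """Hand-built CountTable; ``counts`` maps sample -> {key: n}, ``roles`` sample -> role."""
    df = pd.DataFrame(counts).fillna(0).astype(int)
    samples = pd.DataFrame(
        {
            "phage": "phageX",
            "moi": 1.0,
            "format": "liquid",
            "role": pd.Series(roles),
            "set_label": set_label,
            "replicate": 1,
        }
    )
    samples.index.name = "sample_id"
    return CountTable(df[list(samples.index)], samples)


@pytest.fixture
def count_table_factory():
    return make_count_table


def nnls_brute_force(design: np.ndarray, target: np.ndarray) -> float:
    """Minimal residual of min ||target - design @ x||, x >= 0, by subset enumeration.

    At the optimum the active (positive) coordinates solve the
    unconstrained least-squares problem on their subset, so enumerating
    every support and keeping feasible solutions is exact for small
    problems.  Independent of any NNLS solver.
    """
    n_genes = design.shape[1]
    best = float(np.sum(target**2))  # x = 0
    for k in range(1, n_genes + 1):
        for subset in itertools.combinations(range(n_genes), k):
            sub = design[:, subset]
            x, *_ = np.linalg.lstsq(sub, target, rcond=None)
            if (x < -1e-12).any():
                continue
            resid = float(np.sum((target - sub @ x) ** 2))
            best = min(best, resid)
    return best


@pytest.fixture(scope="session")
def nnls_oracle():
    return nnls_brute_force
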