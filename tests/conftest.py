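"""Shared fixtures: hand-built clone trees and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spaceclone.genome import GenomeModel, default_genome
from spaceclone.synthetic import (
    CloneTree,
    CnaEvent,
    SimulationConfig,
    Snv,
    Subclone,
)


@pytest.fixture(scope="session")
def small_genome() -> GenomeModel:
    return default_genome(n_chroms=6, max_length=100_000_000, min_length=60_000_000, seed=0)


@pytest.fixture()
def two_clone_tree(small_genome) -> CloneTree:
    """Root clone plus one subclone carrying a single-copy gain on chr1.

    Hand-built (no randomness) so expectations are closed-form: the subclone
    holds 40% of tumor cells at RBM and 60% at FL.
    """
    gain = CnaEvent("gain_1", "1", 10_000_000, 50_000_000, delta=1, owner=1)
    snv_clonal = Snv("s_clonal", "3", 5_000_001, "A", "T", owner=0, multiplicity=1)
    snv_sub = Snv("s_sub", "4", 7_000_001, "C", "G", owner=1, multiplicity=1)
    return CloneTree(
        subclones=[
            Subclone(0, None, snv_ids=["s_clonal"]),
            Subclone(1, 0, snv_ids=["s_sub"], cna_ids=["gain_1"]),
        ],
        prevalence={"RBM": {0: 0.6, 1: 0.4}, "FL": {0: 0.4, 1: 0.6}},
        snvs={"s_clonal": snv_clonal, "s_sub": snv_sub},
        cnas={"gain_1": gain},
    )


@pytest.fixture()
def base_config(small_genome) -> SimulationConfig:
    return SimulationConfig(
        seed=123,
        genome=small_genome,
        purity={"RBM": 0.5, "FL": 0.5},
        n_cells_rna=250,
        n_cells_atac=250,
        n_ref_cells=80,
        qc_fail_fraction=0.0,
    )


def make_adata(counts, obs=None, var=None):
    """Small helper to assemble an AnnData from dense counts."""
    import anndata as ad
    from scipy import sparse

    counts = np.asarray(counts)
    n_obs, n_var = counts.shape
    if obs is None:
        obs = pd.DataFrame(index=[f"c{i}" for i in range(n_obs)])
    if var is None:
        var = pd.DataFrame(
            {
                "chrom": ["1"] * n_var,
                "start": np.arange(n_var) * 1000,
                "end": np.arange(n_var) * 1000 + 100,
            },
            index=[f"f{j}" for j in range(n_var)],
        )
    return ad.AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)
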