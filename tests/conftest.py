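"""Shared fixtures: one small screen for cheap tests, one default-scale screen
(simulated once per session) for the dataset-level checks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from secscreen import enrichment as enr
from secscreen.features import build_dataset, make_folds
from secscreen.simulate import SimulationConfig, simulate_screen


@pytest.fixture(scope="session")
def small_screen():
    """A fast screen: 40 genes, modest depth, planted signal at defaults."""
    cfg = SimulationConfig(
        seed=11,
        n_genes=40,
        fragments_per_transcript=120,
        depth_unsorted=400_000,
        depth_sorted=400_000,
    )
    return simulate_screen(cfg)


@pytest.fixture(scope="session")
def default_screen():
    """The default synthetic screen (the package's standard study conditions)."""
    return simulate_screen(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_records(default_screen):
    in_frame = pd.Series(
        {f.key: f.dual_in_frame for f in default_screen.fragments}
    )
    return enr.enrich(default_screen.counts, in_frame=in_frame)


@pytest.fixture(scope="session")
def default_dataset(default_screen, default_records):
    peptides = {f.key: f.peptide for f in default_screen.fragments if f.peptide}
    genes = {f.key: f.gene_id for f in default_screen.fragments}
    return build_dataset(default_records, peptides, genes)


@pytest.fixture(scope="session")
def default_folds(default_dataset):
    return make_folds(default_dataset, k=10, seed=1)


@pytest.fixture(scope="session")
def shuffled_labels(default_dataset):
    rng = np.random.default_rng(321)
    return rng.permutation(default_dataset.labels)
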