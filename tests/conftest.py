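import logging

import numpy as np
import pandas as pd
import pytest

from xtissue.core_io import ExpressionDataset, PipelineConfig
from xtissue.synthetic_data import SyntheticConfig, generate_study

logging.getLogger("xtissue").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_dataset(
    matrix, genes=None, samples=None, diagnosis=None, name="test", **meta_cols
):
    """Small helper to build an ExpressionDataset from raw pieces."""
    matrix = np.asarray(matrix, dtype=float)
    n_genes, n_samples = matrix.shape
    genes = genes or [f"G{i}" for i in range(n_genes)]
    samples = samples or [f"s{j}" for j in range(n_samples)]
    diagnosis = diagnosis or ["case"] * (n_samples // 2) + ["control"] * (
        n_samples - n_samples // 2
    )
    meta = pd.DataFrame(
        {"diagnosis": diagnosis, **meta_cols},
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionDataset(
        matrix=matrix, gene_symbols=genes, sample_ids=samples, metadata=meta,
        name=name,
    )


@pytest.fixture
def small_config():
    """Pipeline config sized for fast unit tests."""
    return PipelineConfig(
        rng_seed=0,
        B_bags=5,
        cv_folds=3,
        lambda_grid=np.geomspace(0.5, 1e-3, 10),
        n_permutations=10,
        permutation_bags=2,
    )


@pytest.fixture(scope="session")
def tiny_study():
    """A small synthetic study shared by read-only tests."""
    cfg = SyntheticConfig(
        samples_per_cohort=[(15, 15)] * 2,
        n_cohorts=2,
        n_genes=300,
        n_categories=40,
        signature_size=30,
        cross_tissue_subset_size=12,
        rng_seed=42,
    )
    collection, cohorts, target, truth = generate_study(cfg)
    return cfg, collection, cohorts, target, truth
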