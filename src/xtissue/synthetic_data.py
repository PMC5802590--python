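"""Synthetic multi-cohort study generator.

Emulates the statistical structure of the study the pipeline targets:
several small case-control cortical cohorts (212 subjects over four cohorts
by default) with covariate confounds (age, age^2, sex, PMI, site), a planted
multi-gene case-control signature concentrated in top-ranked ontology
categories, and a second-tissue dataset (51 subjects, 9 labelled diabetic by
default) in which a subset of the signature genes loads on a latent factor
negatively coupled to an HbA1c-like trait.  Null variants (no case effect,
or no trait coupling) come from setting ``effect_size_delta`` or
``trait_coupling`` to zero.

Expression noise is Gaussian on the log2 scale, matching the approximately
Gaussian per-gene distribution of summarized array data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
    XTissueError,
    write_expression_table,
    write_gmt,
    write_metadata,
)

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Study-shape and effect-size knobs for the generator.

    Defaults mirror the target study design: four cohorts totalling 212
    subjects, 200 ranked categories of 8-20 genes (median 14), a 60-gene
    planted signature of which 22 genes carry the cross-tissue latent
    factor, a 0.8 SD case-control effect, and a negative HbA1c coupling
    calibrated so the oracle score correlates with the trait at |rho| ~ 0.6.
    The gene universe is 2000 genes (a down-scaled stand-in for a
    transcriptome-wide panel; the pipeline is size-agnostic).
    """

    n_cohorts: int = 4
    samples_per_cohort: list[tuple[int, int]] = field(
        default_factory=lambda: [(27, 26), (26, 27), (27, 26), (26, 27)]
    )
    n_genes: int = 2000
    n_categories: int = 200
    genes_per_category: tuple[int, int] = (8, 20)
    signature_size: int = 60
    cross_tissue_subset_size: int = 22
    effect_size_delta: float = 0.8
    trait_coupling: float = -0.5
    concentration: float = 1.0  # probability a signature gene lands in a top category
    top_category_window: int = 20
    covariate_effect_sizes: dict = field(
        default_factory=lambda: {"age": 0.015, "sex": 0.3, "pmi": 0.02, "site": 0.3}
    )
    covariate_gene_fraction: float = 0.1
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    n_target_samples: int = 51
    n_target_cases: int = 9
    hba1c_baseline: float = 5.5
    hba1c_noise_sd: float = 0.55
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (
            0 < self.cross_tissue_subset_size <= self.signature_size <= self.n_genes
        ):
            raise XTissueError(
                "need 0 < cross_tissue_subset_size <= signature_size <= n_genes"
            )
        if len(self.samples_per_cohort) != self.n_cohorts:
            raise XTissueError("one (cases, controls) pair per cohort required")
        if self.n_target_cases >= self.n_target_samples:
            raise XTissueError("n_target_cases must be below n_target_samples")

    def gene_symbols(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated study, sufficient to score recovery."""

    signature_genes: list[str]
    cross_tissue_genes: list[str]
    directions: dict[str, float]
    magnitudes: dict[str, float]
    category_ranks: dict[str, int] = field(default_factory=dict)
    signature_category: dict[str, str] = field(default_factory=dict)
    brain_latent: dict[str, np.ndarray] = field(default_factory=dict)
    target_latent: np.ndarray | None = None
    true_trait: np.ndarray | None = None

    def oracle_score(self, dataset: ExpressionDataset) -> np.ndarray:
        """Direction-weighted mean expression of the cross-tissue genes."""
        idx = dataset.gene_index(self.cross_tissue_genes)
        d = np.array([self.directions[g] for g in self.cross_tissue_genes])
        return (dataset.matrix[idx, :].T @ d) / len(idx)

    def to_dict(self) -> dict:
        return {
            "signature_genes": self.signature_genes,
            "cross_tissue_genes": self.cross_tissue_genes,
            "directions": {k: float(v) for k, v in self.directions.items()},
            "magnitudes": {k: float(v) for k, v in self.magnitudes.items()},
            "category_ranks": self.category_ranks,
            "signature_category": self.signature_category,
            "target_latent": None
            if self.target_latent is None
            else [float(v) for v in self.target_latent],
            "true_trait": None
            if self.true_trait is None
            else [float(v) for v in self.true_trait],
        }


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def generate_gene_sets(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[GeneSetCollection, SyntheticTruth]:
    """Ranked categories with the planted signature concentrated near the top.

    Each signature gene is hosted by a category of rank <= top_category_window
    with probability ``concentration`` and by a uniformly random category
    otherwise; non-signature genes fill categories at random (overlap between
    categories is allowed).
    """
    rng = rng or np.random.default_rng(config.rng_seed)
    genes = config.gene_symbols()
    signature = list(rng.choice(genes, size=config.signature_size, replace=False))
    cross = signature[: config.cross_tissue_subset_size]
    lo, hi = config.genes_per_category
    capacity = config.top_category_window * hi
    if config.concentration >= 1.0 and config.signature_size > capacity:
        raise XTissueError(
            f"signature ({config.signature_size}) exceeds capacity of the top "
            f"{config.top_category_window} categories ({capacity})"
        )
    non_sig = [g for g in genes if g not in set(signature)]
    host: dict[str, int] = {}
    for g in signature:
        if rng.random() < config.concentration:
            host[g] = int(rng.integers(1, config.top_category_window + 1))
        else:
            host[g] = int(rng.integers(1, config.n_categories + 1))
    sets: list[GeneSet] = []
    for rank in range(1, config.n_categories + 1):
        planted = [g for g, h in host.items() if h == rank]
        size = int(rng.integers(lo, hi + 1))
        n_fill = max(size - len(planted), 1)
        fill = list(rng.choice(non_sig, size=n_fill, replace=False))
        members = planted + fill
        sets.append(GeneSet(name=f"CAT{rank:04d}", genes=tuple(members), rank=rank))
    collection = GeneSetCollection(sets=sets)
    directions = {g: float(rng.choice([-1.0, 1.0])) for g in signature}
    magnitudes = {g: float(rng.uniform(0.5, 1.0)) for g in signature}
    truth = SyntheticTruth(
        signature_genes=signature,
        cross_tissue_genes=cross,
        directions=directions,
        magnitudes=magnitudes,
        category_ranks={s.name: s.rank for s in sets},
        signature_category={g: f"CAT{h:04d}" for g, h in host.items()},
    )
    return collection, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _covariate_loadings(
    config: SyntheticConfig, rng: np.random.Generator
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-covariate (gene indices, per-gene coefficients)."""
    out = {}
    n_affected = max(1, int(config.covariate_gene_fraction * config.n_genes))
    for cov, eff in config.covariate_effect_sizes.items():
        idx = rng.choice(config.n_genes, size=n_affected, replace=False)
        coefs = eff * rng.standard_normal(n_affected)
        out[cov] = (idx, coefs)
    return out


def generate_multicohort(
    config: SyntheticConfig,
    truth: SyntheticTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ExpressionDataset], SyntheticTruth]:
    """Simulate the case-control discovery cohorts.

    Expression = gene baseline + cohort offset + case effect on signature
    genes (delta * direction * magnitude) + covariate effects on random gene
    subsets + iid Gaussian noise.  Bit-reproducible from the seed.
    """
    rng = rng or np.random.default_rng(config.rng_seed)
    if truth is None:
        _, truth = generate_gene_sets(config, rng)
    genes = config.gene_symbols()
    baseline = config.baseline_mean + config.baseline_sd * rng.standard_normal(
        config.n_genes
    )
    cov_load = _covariate_loadings(config, rng)
    sig_idx = np.array([genes.index(g) for g in truth.signature_genes])
    sig_effect = np.array(
        [truth.directions[g] * truth.magnitudes[g] for g in truth.signature_genes]
    )
    cohorts: list[ExpressionDataset] = []
    for c, (n_case, n_ctrl) in enumerate(config.samples_per_cohort):
        name = f"cohort{c + 1}"
        n = n_case + n_ctrl
        diagnosis = np.array(["case"] * n_case + ["control"] * n_ctrl)
        perm = rng.permutation(n)
        diagnosis = diagnosis[perm]
        is_case = (diagnosis == "case").astype(float)
        age = np.clip(rng.normal(45.0, 10.0, size=n), 18.0, 90.0)
        sex = rng.choice(["male", "female"], size=n)
        pmi = rng.uniform(5.0, 30.0, size=n)
        cohort_offset = 0.2 * rng.standard_normal(config.n_genes)
        X = np.tile((baseline + cohort_offset)[:, None], (1, n))
        X[sig_idx, :] += config.effect_size_delta * np.outer(sig_effect, is_case)
        for cov, (idx, coefs) in cov_load.items():
            if cov == "age":
                val = age - 45.0
            elif cov == "sex":
                val = (sex == "female").astype(float)
            elif cov == "pmi":
                val = pmi - 17.5
            elif cov == "site":
                val = np.full(n, float(c))
            else:
                continue
            X[idx, :] += np.outer(coefs, val)
        X += config.noise_sd * rng.standard_normal((config.n_genes, n))
        sample_ids = [f"{name}_s{j:03d}" for j in range(n)]
        meta = pd.DataFrame(
            {
                "diagnosis": diagnosis,
                "age": age,
                "sex": sex,
                "pmi": pmi,
                "site": name,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        cohorts.append(
            ExpressionDataset(
                matrix=X,
                gene_symbols=list(genes),
                sample_ids=sample_ids,
                metadata=meta,
                name=name,
            )
        )
        truth.brain_latent[name] = is_case
    return cohorts, truth


# ---------------------------------------------------------------------------
# Target tissue
# ---------------------------------------------------------------------------

def generate_target_tissue(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> ExpressionDataset:
    """Second-tissue dataset whose cross-tissue genes track a latent factor.

    Per sample, the latent factor v loads on the cross-tissue signature genes
    (direction * magnitude * v) and the HbA1c-like trait is
    baseline + trait_coupling * v + noise; diabetic labels go to the
    ``n_target_cases`` samples with the highest trait values (echoing a
    fixed diagnostic threshold on the trait).
    """
    rng = rng or np.random.default_rng(config.rng_seed + 1)
    genes = config.gene_symbols()
    n = config.n_target_samples
    v = rng.standard_normal(n)
    baseline = config.baseline_mean + config.baseline_sd * rng.standard_normal(
        config.n_genes
    )
    X = np.tile(baseline[:, None], (1, n))
    cross_idx = np.array([genes.index(g) for g in truth.cross_tissue_genes])
    load = np.array(
        [truth.directions[g] * truth.magnitudes[g] for g in truth.cross_tissue_genes]
    )
    X[cross_idx, :] += np.outer(load, v)
    X += config.noise_sd * rng.standard_normal((config.n_genes, n))
    true_trait = config.hba1c_baseline + config.trait_coupling * v
    hba1c = true_trait + config.hba1c_noise_sd * rng.standard_normal(n)
    hba1c = np.clip(hba1c, 0.1, 19.9)
    order = np.argsort(-hba1c)
    diagnosis = np.array(["control"] * n, dtype=object)
    diagnosis[order[: config.n_target_cases]] = "case"
    age = np.clip(rng.normal(55.0, 10.0, size=n), 20.0, 90.0)
    sex = rng.choice(["male", "female"], size=n)
    pmi = rng.uniform(5.0, 30.0, size=n)
    sample_ids = [f"target_s{j:03d}" for j in range(n)]
    meta = pd.DataFrame(
        {
            "diagnosis": diagnosis,
            "age": age,
            "sex": sex,
            "pmi": pmi,
            "hba1c": hba1c,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth.target_latent = v
    truth.true_trait = true_trait
    return ExpressionDataset(
        matrix=X,
        gene_symbols=list(genes),
        sample_ids=sample_ids,
        metadata=meta,
        name="target",
    )


def generate_study(
    config: SyntheticConfig,
) -> tuple[GeneSetCollection, list[ExpressionDataset], ExpressionDataset, SyntheticTruth]:
    """One call for gene sets, discovery cohorts and the target tissue."""
    rng = np.random.default_rng(config.rng_seed)
    collection, truth = generate_gene_sets(config, rng)
    cohorts, truth = generate_multicohort(config, truth, rng)
    target = generate_target_tissue(config, truth, rng)
    return collection, cohorts, target, truth


def write_simulation(config: SyntheticConfig, outdir: str | Path) -> None:
    """Write cohort/metadata TSVs, the GMT and a truth JSON to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collection, cohorts, target, truth = generate_study(config)
    write_gmt(collection, outdir / "gene_sets.gmt")
    for ds in cohorts + [target]:
        write_expression_table(ds, outdir / f"{ds.name}_expression.tsv")
        write_metadata(ds.metadata, outdir / f"{ds.name}_metadata.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
    logger.info("simulation written to %s", outdir)
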