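"""Accuracy metrics, cross-tissue association tests and the permutation null.

Classification accuracy is Nagelkerke's pseudo-R^2 from a logistic
regression of diagnosis on the ensemble score.  Association with a
continuous trait (HbA1c) is Spearman's rho, with explained variance defined
as 100 * rho^2.  Specificity of the cross-tissue association is assessed by
re-running the whole training pipeline on diagnosis labels permuted within
each cohort and counting null explained-variance values at least as large as
the observed one.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionDataset, PipelineConfig, XTissueError
from .polymodel import (
    _P_CLIP,
    _glm_binomial_probs,
    bagged_train,
    oob_scores,
    predict_scores,
)

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    nagelkerke_r2: float | None = None
    spearman_rho: float | None = None
    explained_variance_pct: float | None = None
    wilcoxon_p: float | None = None
    n_samples: int = 0

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class PermutationResult:
    """Observed explained variance against its diagnosis-permutation null."""

    observed: float
    null_values: np.ndarray
    n_permutations: int
    median_null_classification_ev: float = float("nan")

    @property
    def empirical_p(self) -> float:
        return float(np.sum(self.null_values >= self.observed)) / self.n_permutations

    def format_p(self) -> str:
        exceed = int(np.sum(self.null_values >= self.observed))
        if exceed == 0:
            return f"< {1.0 / self.n_permutations:.3g}"
        return f"{exceed / self.n_permutations:.3g}"


# ---------------------------------------------------------------------------
# Nagelkerke R^2
# ---------------------------------------------------------------------------

def _bernoulli_loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _P_CLIP, 1 - _P_CLIP)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def nagelkerke_r2_from_probs(y: np.ndarray, p: np.ndarray) -> float:
    """Nagelkerke's R^2 given fitted per-sample probabilities.

    R^2_N = [1 - exp((2/n)(l0 - l1))] / [1 - exp((2/n) l0)] with l0 the
    log-likelihood of the intercept-only model (p = mean(y)).
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    n = len(y)
    l1 = _bernoulli_loglik(y, p)
    l0 = _bernoulli_loglik(y, np.full(n, y.mean()))
    cox_snell = 1.0 - math.exp((2.0 / n) * (l0 - l1))
    max_cs = 1.0 - math.exp((2.0 / n) * l0)
    return cox_snell / max_cs


def nagelkerke_r2(y: np.ndarray, scores: np.ndarray) -> float:
    """Fit logistic regression of diagnosis on the score; Nagelkerke R^2.

    Invariant to positive affine transforms of the score.  Perfect
    separation is handled by probability clipping, capping the value just
    below 1.
    """
    y = np.asarray(y, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if np.ptp(y) == 0:
        raise XTissueError("both classes required")
    if np.ptp(scores) == 0:
        return 0.0
    s = (scores - scores.mean()) / scores.std()
    p = _glm_binomial_probs(s[:, None], y)
    return nagelkerke_r2_from_probs(y, p)


# ---------------------------------------------------------------------------
# Continuous-trait association
# ---------------------------------------------------------------------------

def _exact_spearman_p(rho: float, n: int) -> float:
    """Two-sided exact p by enumerating all rank permutations (n <= 9).

    For tie-free ranks rho = 1 - 6*sum(d^2)/(n(n^2-1)), so the null
    distribution follows from the d^2 sums of every permutation.
    """
    base = np.arange(1, n + 1)
    perms = np.array(list(itertools.permutations(base)), dtype=np.int64)
    d2 = ((perms - base) ** 2).sum(axis=1)
    null_rho = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    return float(np.mean(np.abs(null_rho) >= abs(rho) - 1e-12))


def continuous_association(
    scores: np.ndarray, trait: np.ndarray
) -> tuple[float, float, float]:
    """Spearman rho, explained variance (100 * rho^2) and two-sided p.

    Uses the t-approximation for the p-value, or exact rank-permutation
    enumeration when n <= 9 and there are no ties.
    """
    scores = np.asarray(scores, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if len(scores) != len(trait):
        raise XTissueError("scores and trait must be paired")
    if len(scores) < 5:
        raise XTissueError("need at least 5 paired observations")
    if np.ptp(trait) == 0:
        raise XTissueError("trait is constant")
    if np.ptp(scores) == 0:
        raise XTissueError("scores are constant; rho undefined")
    rho, p = stats.spearmanr(scores, trait)
    rho = float(rho)
    n = len(scores)
    no_ties = len(set(scores)) == n and len(set(trait)) == n
    if n <= 9 and no_ties:
        p = _exact_spearman_p(rho, n)
    return rho, 100.0 * rho * rho, float(p)


def wilcoxon_ranksum(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Two-sided rank-sum p; exact when both n <= 10 and tie-free."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise XTissueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(set(pooled)) == len(pooled)
    if len(a) <= 10 and len(b) <= 10 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.pvalue)


def covariate_adjusted_group_test(
    scores: np.ndarray,
    labels: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> float:
    """Rank-sum test on scores OLS-residualized against covariates.

    With an empty covariate set this is the plain rank-sum test (centering
    does not change ranks).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    resid = scores
    if covariates is not None and covariates.shape[1] > 0:
        cols = [np.ones(len(scores))]
        for c in covariates.columns:
            col = covariates[c]
            if col.dtype == object or str(col.dtype) == "category":
                dummies = pd.get_dummies(col.astype(str), drop_first=True)
                cols.extend(dummies[c2].to_numpy(dtype=float) for c2 in dummies)
            else:
                cols.append(col.to_numpy(dtype=float))
        D = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(D, scores, rcond=None)
        resid = scores - D @ beta
    groups = np.unique(labels)
    if len(groups) != 2:
        raise XTissueError("labels must have exactly two groups")
    return wilcoxon_ranksum(resid[labels == groups[0]], resid[labels == groups[1]])


# ---------------------------------------------------------------------------
# Permutation specificity
# ---------------------------------------------------------------------------

def _run_once(
    cohorts: list[ExpressionDataset],
    genes: list[str],
    target: ExpressionDataset,
    trait: np.ndarray,
    config: PipelineConfig,
    n_bags: int,
    seed: int,
) -> tuple[float, float]:
    """One full train + cross-tissue predict; returns (EV%, classification EV%)."""
    ensemble = bagged_train(cohorts, genes, config, n_bags=n_bags, seed=seed)
    target_scores = predict_scores(ensemble, target)
    if np.ptp(target_scores) == 0:
        ev = 0.0  # every model collapsed to the intercept: nothing explained
    else:
        _, ev, _ = continuous_association(target_scores, trait)
    _, oob_s, oob_y = oob_scores(ensemble, cohorts)
    class_ev = 100.0 * nagelkerke_r2(oob_y, oob_s) if np.ptp(oob_y) > 0 else 0.0
    return ev, class_ev


def _permute_within_cohort(
    cohorts: list[ExpressionDataset], rng: np.random.Generator
) -> list[ExpressionDataset]:
    out = []
    for c in cohorts:
        meta = c.metadata.copy()
        diag = meta["diagnosis"].to_numpy().copy()
        rng.shuffle(diag)
        meta["diagnosis"] = diag
        out.append(
            ExpressionDataset(
                matrix=c.matrix,
                gene_symbols=c.gene_symbols,
                sample_ids=c.sample_ids,
                metadata=meta,
                name=c.name,
            )
        )
    return out


def permutation_specificity(
    cohorts: list[ExpressionDataset],
    genes: list[str],
    target_dataset: ExpressionDataset,
    trait: np.ndarray,
    config: PipelineConfig,
    observed: float | None = None,
) -> PermutationResult:
    """Diagnosis-permutation null for the cross-tissue explained variance.

    Per permutation: shuffle diagnosis within each cohort (preserving
    per-cohort case/control counts), re-run bagged training (with the
    possibly reduced ``permutation_bags``), predict into the target tissue
    and record the trait explained variance.  The empirical p is the
    frequency of null values at least as large as the observed one.
    """
    n_perm = config.n_permutations
    if n_perm < 1:
        raise XTissueError("n_permutations must be >= 1")
    n_bags = config.permutation_bags or config.B_bags
    if observed is None:
        observed, _ = _run_once(
            cohorts, genes, target_dataset, trait, config,
            n_bags=n_bags, seed=config.rng_seed,
        )
    null_vals: list[float] = []
    class_evs: list[float] = []
    failures = 0
    for b in range(n_perm):
        rng = np.random.default_rng([config.rng_seed, 104729, b])
        permuted = _permute_within_cohort(cohorts, rng)
        try:
            ev, class_ev = _run_once(
                permuted, genes, target_dataset, trait, config,
                n_bags=n_bags, seed=int(rng.integers(0, 2**31 - 1)),
            )
        except XTissueError as err:
            failures += 1
            logger.warning("permutation %d failed: %s", b, err)
            continue
        null_vals.append(ev)
        class_evs.append(class_ev)
    if failures:
        logger.warning("%d/%d permutations failed and were skipped", failures, n_perm)
    null_arr = np.asarray(null_vals)
    return PermutationResult(
        observed=float(observed),
        null_values=null_arr,
        n_permutations=len(null_arr),
        median_null_classification_ev=float(np.median(class_evs))
        if class_evs else float("nan"),
    )


# ---------------------------------------------------------------------------
# Expressed fraction (RNA-seq utility)
# ---------------------------------------------------------------------------

def expressed_fraction(
    fpkm: pd.DataFrame | np.ndarray,
    cutoff: float = 0.5,
    tissues: pd.Series | None = None,
) -> float | pd.Series:
    """Fraction of genes whose median FPKM reaches the cutoff, per tissue.

    ``fpkm`` is genes x samples; with ``tissues`` given (a label per sample
    column) the fraction is computed per tissue label.
    """
    values = np.asarray(fpkm, dtype=float)
    if (values < 0).any():
        raise XTissueError("FPKM values must be nonnegative")
    if tissues is None:
        med = np.median(values, axis=1) if values.ndim == 2 else values
        return float(np.mean(med >= cutoff))
    tissues = pd.Series(tissues)
    out = {}
    for t in tissues.unique():
        cols = np.flatnonzero((tissues == t).to_numpy())
        med = np.median(values[:, cols], axis=1)
        out[t] = float(np.mean(med >= cutoff))
    return pd.Series(out)
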