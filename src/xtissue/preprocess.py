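"""Normalization, covariate residualization, propensity matching and outlier flagging.

The pipeline ingests log2-scale expression matrices (array background
correction and summarization are assumed upstream) and applies, in order:
quantile normalization, duplicate-symbol averaging, cross-dataset gene
intersection, robust PCA outlier flagging, per-gene OLS residualization
against the study covariates (site, sex, age, age^2, PMI, optionally the
first expression principal component), and — when a cohort has more controls
than cases — 1:1 propensity-score matching beforehand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as slinalg
from sklearn.linear_model import LogisticRegression

from .core_io import ExpressionDataset, XTissueError

logger = logging.getLogger(__name__)

KNOWN_COVARIATES = ("site", "sex", "age", "age_squared", "pmi", "pc1")


@dataclass
class ResidualizationSpec:
    """Ordered covariates to regress out of every gene.

    ``age_squared`` is the second polynomial of (centered) age and is only
    valid alongside ``age``; ``pc1`` is the first principal component of the
    dataset being residualized.
    """

    covariates: tuple[str, ...] = ("site", "sex", "age", "age_squared", "pmi")

    def __post_init__(self) -> None:
        unknown = set(self.covariates) - set(KNOWN_COVARIATES)
        if unknown:
            raise XTissueError(f"unknown covariates {sorted(unknown)}")
        if "age_squared" in self.covariates and "age" not in self.covariates:
            raise XTissueError("age_squared requires age in the covariate list")


@dataclass
class MatchResult:
    matched_pairs: list[tuple[str, str]]
    propensity: pd.Series
    balance: pd.DataFrame  # per-covariate SMD before/after
    matched_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Force every column onto the common distribution of row-wise sorted means.

    Ties within a column receive the mean of the reference values at their
    tied positions.  A single-column matrix is returned unchanged with a
    warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise XTissueError("quantile_normalize expects a 2-d matrix")
    if np.isnan(matrix).any():
        raise XTissueError("quantile_normalize: missing values present")
    n_genes, n_samples = matrix.shape
    if n_samples < 2:
        logger.warning("quantile_normalize: single column, returned unchanged")
        return matrix.copy()
    reference = np.sort(matrix, axis=0).mean(axis=1)
    out = np.empty_like(matrix)
    for j in range(n_samples):
        col = matrix[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n_genes)
        assigned[order] = reference
        # average the assigned reference values within tie groups
        frame = pd.DataFrame({"v": col, "r": assigned})
        out[:, j] = frame.groupby("v", sort=False)["r"].transform("mean").to_numpy()
    return out


def quantile_normalize_dataset(dataset: ExpressionDataset) -> ExpressionDataset:
    return dataset.with_matrix(quantile_normalize(dataset.matrix))


def renormalize_together(
    reference: ExpressionDataset, target: ExpressionDataset
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Quantile-normalize two datasets jointly on their overlapping genes.

    Used to make overall expression levels comparable between the training
    tissue and a second tissue before cross-tissue prediction.
    """
    common = sorted(set(reference.gene_symbols) & set(target.gene_symbols))
    if not common:
        raise XTissueError("no overlapping genes between datasets")
    ref = reference.subset_genes(common)
    tgt = target.subset_genes(common)
    joint = np.hstack([ref.matrix, tgt.matrix])
    joint = quantile_normalize(joint)
    return (
        ref.with_matrix(joint[:, : ref.n_samples]),
        tgt.with_matrix(joint[:, ref.n_samples :]),
    )


# ---------------------------------------------------------------------------
# Duplicate symbols, gene intersection
# ---------------------------------------------------------------------------

def collapse_duplicate_symbols(dataset: ExpressionDataset) -> ExpressionDataset:
    """Average rows mapping to the same gene symbol (first-occurrence order)."""
    symbols = pd.Index(dataset.gene_symbols)
    if symbols.is_unique:
        return dataset
    frame = pd.DataFrame(dataset.matrix)
    frame["__sym"] = dataset.gene_symbols
    collapsed = frame.groupby("__sym", sort=False).mean()
    return ExpressionDataset(
        matrix=collapsed.to_numpy(),
        gene_symbols=list(collapsed.index),
        sample_ids=list(dataset.sample_ids),
        metadata=dataset.metadata.copy(),
        name=dataset.name,
    )


def intersect_genes(datasets: list[ExpressionDataset]) -> list[ExpressionDataset]:
    """Restrict every dataset to the common gene set, sorted lexicographically."""
    if len(datasets) < 2:
        raise XTissueError("intersect_genes needs >=2 datasets")
    common: set[str] = set(datasets[0].gene_symbols)
    for ds in datasets[1:]:
        common &= set(ds.gene_symbols)
    if not common:
        raise XTissueError("gene intersection across datasets is empty")
    ordered = sorted(common)
    return [ds.subset_genes(ordered) for ds in datasets]


# ---------------------------------------------------------------------------
# PCA outlier flagging
# ---------------------------------------------------------------------------

def flag_pca_outliers(
    dataset: ExpressionDataset, sd_threshold: float = 4.0
) -> list[str]:
    """Flag samples extreme on PC1/PC2 by a robust-SD rule.

    A sample is flagged when its score on either of the first two principal
    components lies more than ``sd_threshold`` robust standard deviations
    (median +/- threshold * 1.4826 * MAD) from the median.  This replaces
    visual inspection with a deterministic criterion.
    """
    if dataset.n_samples < 3:
        raise XTissueError("flag_pca_outliers needs >=3 samples")
    X = dataset.matrix.T  # samples x genes
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        logger.warning("flag_pca_outliers: zero-variance data, nothing flagged")
        return []
    # deterministic PCA via SVD of the centered matrix
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    n_pc = min(2, len(s))
    scores = U[:, :n_pc] * s[:n_pc]
    flagged = np.zeros(dataset.n_samples, dtype=bool)
    for k in range(n_pc):
        pc = scores[:, k]
        med = np.median(pc)
        mad = np.median(np.abs(pc - med))
        robust_sd = 1.4826 * mad
        if robust_sd == 0:
            flagged |= pc != med
            continue
        flagged |= np.abs(pc - med) > sd_threshold * robust_sd
    return [s_id for s_id, f in zip(dataset.sample_ids, flagged) if f]


# ---------------------------------------------------------------------------
# Covariate residualization
# ---------------------------------------------------------------------------

def _build_design(dataset: ExpressionDataset, spec: ResidualizationSpec) -> np.ndarray:
    meta = dataset.metadata
    cols: list[np.ndarray] = [np.ones(dataset.n_samples)]
    names = ["intercept"]
    for cov in spec.covariates:
        if cov == "age_squared":
            age = meta["age"].to_numpy(dtype=float)
            centered = age - age.mean()  # centering decorrelates the polynomial
            cols.append(centered**2)
            names.append(cov)
        elif cov == "pc1":
            X = dataset.matrix.T
            Xc = X - X.mean(axis=0)
            U, s, _ = np.linalg.svd(Xc, full_matrices=False)
            cols.append(U[:, 0] * s[0])
            names.append(cov)
        elif cov in ("age", "pmi"):
            if cov not in meta.columns:
                raise XTissueError(f"{dataset.name}: covariate {cov!r} missing")
            vals = meta[cov]
            if vals.isna().any():
                bad = [s for s, v in zip(dataset.sample_ids, vals) if pd.isna(v)]
                raise XTissueError(
                    f"{dataset.name}: covariate {cov!r} missing for samples {bad[:5]}"
                )
            cols.append(vals.to_numpy(dtype=float))
            names.append(cov)
        elif cov in ("sex", "site"):
            if cov not in meta.columns:
                raise XTissueError(f"{dataset.name}: covariate {cov!r} missing")
            if meta[cov].isna().any():
                raise XTissueError(f"{dataset.name}: covariate {cov!r} has missing values")
            dummies = pd.get_dummies(meta[cov].astype(str), drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(f"{cov}[{c}]")
        else:  # pragma: no cover - guarded by ResidualizationSpec
            raise XTissueError(f"unknown covariate {cov!r}")
    D = np.column_stack(cols)
    # drop collinear columns via pivoted QR (keep the intercept)
    _, R, piv = slinalg.qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(D.shape) * np.finfo(float).eps * (diag[0] if diag.size else 1.0)
    rank = int(np.sum(diag > tol))
    if rank < D.shape[1]:
        keep = sorted(piv[:rank])
        dropped = [names[i] for i in range(D.shape[1]) if i not in keep]
        logger.warning(
            "%s: design rank-deficient, dropping columns %s", dataset.name, dropped
        )
        D = D[:, keep]
    return D


def residualize_expression(
    dataset: ExpressionDataset, spec: ResidualizationSpec | None = None
) -> ExpressionDataset:
    """Replace each gene by its OLS residual on the covariate design.

    With an empty covariate list this is per-gene mean-centering.  Residuals
    are orthogonal to every design column to machine precision.
    """
    spec = spec or ResidualizationSpec()
    D = _build_design(dataset, spec)
    Y = dataset.matrix.T  # samples x genes
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ beta
    return dataset.with_matrix(resid.T)


# ---------------------------------------------------------------------------
# Propensity matching
# ---------------------------------------------------------------------------

def _smd(x_case: np.ndarray, x_ctrl: np.ndarray) -> float:
    pooled = np.sqrt((x_case.var(ddof=1) + x_ctrl.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float(abs(x_case.mean() - x_ctrl.mean()) / pooled)


def propensity_match_1to1(
    metadata: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "pmi"),
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching on the logit propensity score.

    The propensity is a logistic regression of case status on the covariates.
    Cases are processed in descending propensity order; each takes the
    unmatched control nearest on the logit scale, without replacement.
    Requires at least as many controls as cases.
    """
    diag = metadata["diagnosis"]
    case_ids = list(metadata.index[diag == "case"])
    ctrl_ids = list(metadata.index[diag == "control"])
    if not case_ids or not ctrl_ids:
        raise XTissueError("propensity matching needs both cases and controls")
    if len(ctrl_ids) < len(case_ids):
        raise XTissueError(
            "fewer controls than cases; swap roles explicitly if intended"
        )
    design_cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov not in metadata.columns:
            raise XTissueError(f"matching covariate {cov!r} missing from metadata")
        col = metadata[cov]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            for c in dummies.columns:
                design_cols.append(dummies[c].to_numpy(dtype=float))
                names.append(f"{cov}[{c}]")
        else:
            design_cols.append(col.to_numpy(dtype=float))
            names.append(cov)
    X = np.column_stack(design_cols)
    X_std = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1, X.std(axis=0))
    y = (diag == "case").to_numpy(dtype=int)
    mask = (diag == "case") | (diag == "control")
    model = LogisticRegression(C=np.inf, max_iter=1000)
    model.fit(X_std[mask.to_numpy()], y[mask.to_numpy()])
    p = np.clip(model.predict_proba(X_std)[:, 1], 1e-12, 1 - 1e-12)
    logit = np.log(p / (1 - p))
    propensity = pd.Series(p, index=metadata.index, name="propensity")
    logit_s = pd.Series(logit, index=metadata.index)

    order = sorted(case_ids, key=lambda s: (-logit_s[s], s))
    available = set(ctrl_ids)
    pairs: list[tuple[str, str]] = []
    for cid in order:
        best = min(available, key=lambda s: (abs(logit_s[s] - logit_s[cid]), s))
        available.discard(best)
        pairs.append((cid, best))

    matched_ids = [s for pair in pairs for s in pair]
    rows = []
    matched_cases = [c for c, _ in pairs]
    matched_ctrls = [c for _, c in pairs]
    for j, name in enumerate(names):
        col = pd.Series(X[:, j], index=metadata.index)
        before = _smd(
            col[case_ids].to_numpy(), col[ctrl_ids].to_numpy()
        )
        after = _smd(
            col[matched_cases].to_numpy(), col[matched_ctrls].to_numpy()
        )
        rows.append({"covariate": name, "smd_before": before, "smd_after": after})
    balance = pd.DataFrame(rows).set_index("covariate")
    return MatchResult(
        matched_pairs=pairs,
        propensity=propensity,
        balance=balance,
        matched_ids=matched_ids,
    )
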