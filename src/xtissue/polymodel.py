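"""The polygenic-score learner.

The training procedure, applied per bootstrap bag:

1. rank genes by absolute Pearson correlation with the (pseudo-)outcome and
   keep the top ``n = floor(samples / divisor)``;
2. L1-penalized binomial regression with cross-validated penalty weight to
   prune those to the strongest predictors;
3. residualize the binary outcome against the selected predictors
   (unpenalized binomial fit, deviance residuals) to form the next round's
   pseudo-outcome;
4. repeat from step 1 for ``m_rounds`` rounds in total;
5. fit a SCAD-penalized binomial model on the union of selected genes, with
   the penalty weight again chosen by cross-validated deviance;
6. predict the linear predictor into new samples.

Bagging draws a stratified two-thirds subsample from every cohort
independently, trains steps 1-5 on the combined subsample, and averages the
linear predictor over bags.

Both penalized fits run on one coordinate-descent engine: IRLS on the
binomial log-likelihood with, per working-response problem, exact univariate
updates over an active set plus a vectorized Karush-Kuhn-Tucker screen of
the inactive coordinates, warm-started along the descending penalty grid.
For the L1 penalty the univariate update is soft thresholding; for SCAD it
is the exact minimizer of the local quadratic plus the (non-convex) SCAD
penalty.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._solver import cd_path as _cd_path_kernel
from .core_io import ExpressionDataset, PipelineConfig, XTissueError

logger = logging.getLogger(__name__)

_P_CLIP = 1e-6
_W_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# Step 1: correlation ranking
# ---------------------------------------------------------------------------

def rank_genes_by_correlation(
    X: np.ndarray, symbols: list[str], y: np.ndarray, n: int
) -> list[str]:
    """Top-``n`` genes by |Pearson r| with ``y``, descending; symbol-order ties.

    Zero-variance genes get r = 0.  ``y`` may be the binary diagnosis (0/1
    coding, equivalent to the point-biserial correlation) or a continuous
    pseudo-outcome.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n < 1:
        raise XTissueError("n must be >= 1")
    if np.ptp(y) == 0:
        raise XTissueError("outcome is constant; correlation undefined")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = math.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r = np.where(sx == 0, 0.0, r)
    order = np.lexsort((np.array(symbols), -np.abs(r)))
    return [symbols[i] for i in order[: min(n, len(symbols))]]


# ---------------------------------------------------------------------------
# Penalized binomial coordinate descent engine
# ---------------------------------------------------------------------------

def scad_threshold(z, lam: float, a: float = 3.7):
    """SCAD thresholding operator (unit-curvature univariate solution).

    Soft-thresholds small inputs, interpolates in the middle region, and is
    the identity for |z| > a*lambda.  Continuous and odd in z; ``a`` must
    exceed 2.
    """
    if a <= 2:
        raise XTissueError("SCAD shape parameter a must exceed 2")
    if lam < 0:
        raise XTissueError("lambda must be nonnegative")
    z = np.asarray(z, dtype=float)
    az = np.abs(z)
    soft = np.sign(z) * np.maximum(az - lam, 0.0)
    with np.errstate(invalid="ignore"):
        middle = ((a - 1) * z - np.sign(z) * a * lam) / (a - 2)
    out = np.where(az <= 2 * lam, soft, np.where(az <= a * lam, middle, z))
    return out if out.ndim else float(out)


def _scad_penalty(b: float, lam: float, a: float) -> float:
    b = abs(b)
    if b <= lam:
        return lam * b
    if b <= a * lam:
        return (2 * a * lam * b - b * b - lam * lam) / (2 * (a - 1))
    return lam * lam * (a + 1) / 2


def _scad_univariate(t: float, v: float, lam: float, a: float) -> float:
    """Exact minimizer of v/2*b^2 - t*b + P_SCAD(|b|; lam, a) over b.

    With unit curvature (v = 1) this coincides with :func:`scad_threshold`.
    The middle SCAD region makes the problem non-convex for small v, so the
    minimizer is found by evaluating all stationary points and region
    boundaries.
    """
    if v <= 0:
        return 0.0
    if lam == 0:
        return t / v
    u = abs(t)
    if u <= lam:  # 0 always optimal inside the subdifferential
        return 0.0
    s = 1.0 if t >= 0 else -1.0
    alam = a * lam
    cands = [0.0, lam, alam]
    c1 = (u - lam) / v
    if 0.0 < c1 < lam:
        cands.append(c1)
    denom = v - 1.0 / (a - 1.0)
    if denom > 0:
        c2 = (u - alam / (a - 1.0)) / denom
        if lam < c2 < alam:
            cands.append(c2)
    c3 = u / v
    if c3 > alam:
        cands.append(c3)
    best, best_obj = 0.0, 0.0
    for b in cands:
        obj = 0.5 * v * b * b - u * b + _scad_penalty(b, lam, a)
        if obj < best_obj - 1e-15:
            best, best_obj = b, obj
    return s * best


def _soft_univariate(t: float, v: float, lam: float) -> float:
    u = abs(t) - lam
    if u <= 0:
        return 0.0
    return math.copysign(u, t) / v


def _binomial_cd_path(
    Xs: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    a: float = 3.7,
    penalty: str = "scad",
    max_iter: int = 10_000,
    tol: float = 1e-7,
):
    """Warm-started penalized binomial fits along a descending lambda path.

    ``Xs`` must be standardized (the penalty is applied on that scale); the
    intercept is unpenalized.  Each outer cycle solves the IRLS-weighted
    working-response least-squares problem plus penalty by coordinate
    descent with exact univariate updates (soft thresholding for L1, the
    exact non-convex minimizer for SCAD); if a cycle increases the penalized
    objective - possible in the non-convex SCAD middle region - it is
    retried with the global Hessian bound 1/4 as curvature, which majorizes
    the likelihood and restores monotone descent.  Inactive coordinates are
    re-screened against the penalty subdifferential after every convergent
    sweep.

    Returns (betas: len(lambdas) x p, intercepts, converged flags).
    Convergence: max coefficient change below ``tol`` with no screening
    violations; a flat likelihood (mean deviance per sample effectively
    zero, i.e. separation) or an objective stall also terminates, since
    further sweeps cannot change the fit in any statistically meaningful
    way.  The hot loop is compiled (see :mod:`xtissue._solver`).
    """
    Xs = np.ascontiguousarray(Xs, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    betas, b0s, flags = _cd_path_kernel(
        Xs, y, lambdas, float(a), penalty == "l1", int(max_iter), float(tol)
    )
    flags = flags.astype(bool)
    for lam, ok in zip(lambdas, flags):
        if not ok:
            logger.warning(
                "penalized binomial fit not converged at lambda=%.4g (%s)",
                lam, penalty,
            )
    return betas, b0s, flags


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _destandardize(beta: np.ndarray, b0: float, mu: np.ndarray, sd: np.ndarray):
    coefs = beta / sd
    return coefs, b0 - float((beta * mu / sd).sum())


def fit_penalized_binomial(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    a: float = 3.7,
    penalty: str = "scad",
    max_iter: int = 10_000,
    tol: float = 1e-7,
) -> tuple[np.ndarray, float, bool]:
    """Single-lambda penalized binomial fit on the original predictor scale."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    Xs, mu, sd = _standardize(X)
    betas, b0s, flags = _binomial_cd_path(
        Xs, y, np.array([lam]), a=a, penalty=penalty, max_iter=max_iter, tol=tol
    )
    coefs, intercept = _destandardize(betas[0], b0s[0], mu, sd)
    return coefs, float(intercept), bool(flags[0])


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _P_CLIP, 1 - _P_CLIP)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _cv_deviance_path(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    folds: int,
    seed: int,
    a: float,
    penalty: str,
    max_iter: int,
    tol: float,
) -> np.ndarray:
    """Mean out-of-fold binomial deviance per grid lambda (stratified folds)."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, len(grid)))
    # fold fits only rank lambdas by deviance; a coarser tolerance suffices
    fold_tol = max(tol, 1e-5)
    fold_iter = min(max_iter, 2000)
    for k, (tr, va) in enumerate(skf.split(X, y)):
        Xs, mu, sd = _standardize(X[tr])
        Xva = (X[va] - mu) / sd
        betas, b0s, _ = _binomial_cd_path(
            Xs, y[tr], grid, a=a, penalty=penalty, max_iter=fold_iter, tol=fold_tol
        )
        eta = Xva @ betas.T + b0s
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        for i in range(len(grid)):
            dev[k, i] = _binomial_deviance(y[va], p[:, i])
    return dev.mean(axis=0)


# ---------------------------------------------------------------------------
# Step 2: L1 binomial with CV-chosen penalty
# ---------------------------------------------------------------------------

def cv_l1_binomial(
    X: np.ndarray,
    symbols: list[str],
    y: np.ndarray,
    folds: int = 5,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
) -> list[str]:
    """Genes with nonzero L1-binomial coefficients at the CV-optimal penalty.

    The penalty weight lambda (loss averaged over samples, so lambda is per
    sample) is chosen to minimize mean out-of-fold binomial deviance over a
    descending grid, with stratified folds.  If every coefficient is zero at
    the chosen lambda, falls back to the smallest grid lambda with at least
    one nonzero coefficient (warning); if none exists, returns an empty list.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise XTissueError("outcome is constant")
    grid = np.asarray(
        lambda_grid if lambda_grid is not None else np.geomspace(1.0, 1e-3, 25)
    )
    mean_dev = _cv_deviance_path(
        X, y, grid, folds, seed, a=3.7, penalty="l1", max_iter=2000, tol=1e-6
    )
    best = int(np.argmin(mean_dev))
    Xs, mu, sd = _standardize(X)
    betas, _, _ = _binomial_cd_path(
        Xs, y, grid, a=3.7, penalty="l1", max_iter=2000, tol=1e-6
    )
    coef = betas[best]
    if not np.any(coef != 0):
        nonzero_rows = np.flatnonzero((betas != 0).any(axis=1))
        if len(nonzero_rows) == 0:
            logger.warning("cv_l1_binomial: no nonzero coefficient on the grid")
            return []
        # smallest lambda (weakest penalty) with at least one predictor
        row = int(nonzero_rows[np.argmin(grid[nonzero_rows])])
        logger.warning(
            "cv_l1_binomial: no predictor at CV-optimal lambda, "
            "fell back to lambda=%.4g", grid[row],
        )
        coef = betas[row]
    return [s for s, c in zip(symbols, coef) if c != 0]


# ---------------------------------------------------------------------------
# Step 3: outcome residualization
# ---------------------------------------------------------------------------

def _glm_binomial_probs(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fitted probabilities of an unpenalized binomial GLM (IRLS).

    Under separation the coefficients run off toward infinity; IRLS is
    allowed to push the probabilities essentially to 0/1 before the caller
    clips them.
    """
    import statsmodels.api as sm

    X1 = sm.add_constant(X, has_constant="add")
    import warnings as _w

    with np.errstate(all="ignore"), _w.catch_warnings():
        _w.simplefilter("ignore")
        res = sm.GLM(y, X1, family=sm.families.Binomial()).fit(maxiter=100)
        p = np.asarray(res.predict(X1), dtype=float)
    return p


def residualize_outcome(
    y: np.ndarray, X_selected: np.ndarray, kind: str = "deviance"
) -> np.ndarray:
    """Binomial-model residuals of ``y`` on the selected predictors.

    Fits an unpenalized binomial regression and returns deviance residuals
    (default) or Pearson residuals.  Fitted probabilities are clipped to
    [1e-6, 1 - 1e-6] so perfect separation yields finite residuals.
    """
    y = np.asarray(y, dtype=float)
    X_selected = np.atleast_2d(np.asarray(X_selected, dtype=float))
    if X_selected.shape[1] == 0:
        raise XTissueError("residualize_outcome needs a non-empty predictor set")
    p = _glm_binomial_probs(X_selected, y)
    if np.any(p <= _P_CLIP) or np.any(p >= 1 - _P_CLIP):
        logger.warning("residualize_outcome: probabilities clipped (separation)")
    p = np.clip(p, _P_CLIP, 1 - _P_CLIP)
    if kind == "deviance":
        with np.errstate(invalid="ignore"):
            d2 = -2.0 * (y * np.log(p) + (1 - y) * np.log(1 - p))
        return np.sign(y - p) * np.sqrt(np.maximum(d2, 0.0))
    if kind == "pearson":
        return (y - p) / np.sqrt(p * (1 - p))
    raise XTissueError(f"unknown residual kind {kind!r}")


# ---------------------------------------------------------------------------
# Step 4: iterative selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionState:
    """Per-round record of the iterative predictor search."""

    pseudo_outcome: np.ndarray
    selected: list[list[str]] = field(default_factory=list)
    round: int = 0

    @property
    def all_selected(self) -> list[str]:
        out: list[str] = []
        for lst in self.selected:
            out.extend(lst)
        return out


def iterative_select(
    X: np.ndarray,
    symbols: list[str],
    y: np.ndarray,
    config: PipelineConfig,
    seed: int | None = None,
) -> SelectionState:
    """Run ``m_rounds`` of rank -> L1-select -> outcome-residualize.

    Round 1 ranks genes against the case/control indicator; later rounds rank
    against the current pseudo-outcome (binomial residuals of the diagnosis
    on everything selected so far), excluding already-selected genes.  The L1
    step always models the binary diagnosis.  Returns the union of per-round
    selections (disjoint across rounds by construction).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    seed = config.rng_seed if seed is None else seed
    pos = {s: i for i, s in enumerate(symbols)}
    n_samples = X.shape[0]
    n_top = max(1, n_samples // config.genes_per_round_divisor)
    state = SelectionState(pseudo_outcome=y.astype(float))
    taken: set[str] = set()
    for rnd in range(1, config.m_rounds + 1):
        mask = [i for i, s in enumerate(symbols) if s not in taken]
        if not mask:
            logger.warning("iterative_select: no candidate genes left at round %d", rnd)
            break
        sub_symbols = [symbols[i] for i in mask]
        ranked = rank_genes_by_correlation(
            X[:, mask], sub_symbols, state.pseudo_outcome, n_top
        )
        idx = [pos[s] for s in ranked]
        selected = cv_l1_binomial(
            X[:, idx], ranked, y,
            folds=config.cv_folds,
            lambda_grid=config.lambda_grid,
            seed=seed + rnd,
        )
        if not selected:
            logger.warning("iterative_select: round %d selected nothing, stopping", rnd)
            break
        state.selected.append(selected)
        state.round = rnd
        taken.update(selected)
        if rnd < config.m_rounds:
            sel_idx = [pos[s] for s in state.all_selected]
            state.pseudo_outcome = residualize_outcome(
                y, X[:, sel_idx], kind=config.residual_type
            )
    return state


# ---------------------------------------------------------------------------
# Step 5: SCAD-penalized binomial regression
# ---------------------------------------------------------------------------

@dataclass
class ScadModel:
    """A fitted SCAD-penalized binomial model over a fixed gene list."""

    genes: list[str]
    coefficients: np.ndarray
    intercept: float
    lam: float
    a: float = 3.7
    converged: bool = True

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.genes) != len(self.coefficients):
            raise XTissueError("gene/coefficient length mismatch")
        if self.a <= 2:
            raise XTissueError("SCAD shape parameter a must exceed 2")

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients + self.intercept

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "lambda": float(self.lam),
            "a": float(self.a),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScadModel":
        return cls(
            genes=list(d["genes"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            lam=float(d["lambda"]),
            a=float(d.get("a", 3.7)),
            converged=bool(d.get("converged", True)),
        )


def fit_scad_binomial_cv(
    X: np.ndarray,
    symbols: list[str],
    y: np.ndarray,
    config: PipelineConfig,
    seed: int | None = None,
) -> ScadModel:
    """SCAD-binomial fit with lambda chosen by minimum mean CV deviance.

    Warm-starts along the descending lambda grid within each fold and for
    the final full-data refit.  The intercept is never penalized.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise XTissueError("outcome is constant")
    seed = config.rng_seed if seed is None else seed
    grid = config.lambda_grid
    mean_dev = _cv_deviance_path(
        X, y, grid, config.cv_folds, seed,
        a=config.scad_a, penalty="scad",
        max_iter=config.max_scad_iter, tol=config.scad_tol,
    )
    best = int(np.argmin(mean_dev))
    Xs, mu, sd = _standardize(X)
    betas, b0s, flags = _binomial_cd_path(
        Xs, y, grid[: best + 1], a=config.scad_a, penalty="scad",
        max_iter=config.max_scad_iter, tol=config.scad_tol,
    )
    coefs, intercept = _destandardize(betas[best], b0s[best], mu, sd)
    return ScadModel(
        genes=list(symbols),
        coefficients=coefs,
        intercept=float(intercept),
        lam=float(grid[best]),
        a=config.scad_a,
        converged=bool(flags[best]),
    )


# ---------------------------------------------------------------------------
# Bagging (step 6 across subsamples)
# ---------------------------------------------------------------------------

@dataclass
class BaggedEnsemble:
    """Bootstrap-aggregated SCAD models with subsample bookkeeping.

    ``bag_indices[b]`` holds the cohort-qualified sample ids used to train
    model ``b``; out-of-bag ids are everything else in the training pool.
    """

    models: list[ScadModel]
    bag_indices: list[list[str]]
    all_sample_ids: list[str]
    aggregation: str = "mean_linear_predictor"

    def __post_init__(self) -> None:
        if len(self.models) != len(self.bag_indices):
            raise XTissueError("one bag index list per model required")

    @property
    def genes(self) -> list[str]:
        out: set[str] = set()
        for m in self.models:
            out.update(m.genes)
        return sorted(out)

    def oob_ids(self, b: int) -> list[str]:
        used = set(self.bag_indices[b])
        return [s for s in self.all_sample_ids if s not in used]

    def to_dict(self) -> dict:
        return {
            "aggregation": self.aggregation,
            "all_sample_ids": list(self.all_sample_ids),
            "bag_indices": [list(b) for b in self.bag_indices],
            "models": [m.to_dict() for m in self.models],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BaggedEnsemble":
        return cls(
            models=[ScadModel.from_dict(m) for m in d["models"]],
            bag_indices=[list(b) for b in d["bag_indices"]],
            all_sample_ids=list(d["all_sample_ids"]),
            aggregation=d.get("aggregation", "mean_linear_predictor"),
        )


def _qualified_ids(ds: ExpressionDataset) -> list[str]:
    return [f"{ds.name}:{s}" for s in ds.sample_ids]


def bagged_train(
    cohorts: list[ExpressionDataset],
    genes: list[str],
    config: PipelineConfig,
    n_bags: int | None = None,
    seed: int | None = None,
) -> BaggedEnsemble:
    """Train the full selection + SCAD pipeline on ``n_bags`` subsamples.

    Each bag draws ceil(bag_fraction * cases) and ceil(bag_fraction *
    controls) from every cohort independently, combines them, and runs
    iterative selection followed by the CV SCAD fit.  Fully reproducible
    from the seed; bags whose fit fails are skipped with a warning, and more
    than 10% skips aborts.
    """
    if not cohorts:
        raise XTissueError("bagged_train needs at least one cohort")
    n_bags = config.B_bags if n_bags is None else n_bags
    seed = config.rng_seed if seed is None else seed
    if n_bags < 1:
        raise XTissueError("n_bags must be >= 1")
    sub = [c.subset_genes(genes) for c in cohorts]
    ys = [c.case_indicator() for c in sub]
    case_idx = [np.flatnonzero(y == 1) for y in ys]
    ctrl_idx = [np.flatnonzero(y == 0) for y in ys]
    for c, ci, oi in zip(sub, case_idx, ctrl_idx):
        if len(ci) == 0 or len(oi) == 0:
            raise XTissueError(f"cohort {c.name} lacks cases or controls")
    all_ids = [qid for c in sub for qid in _qualified_ids(c)]
    pos = {g: i for i, g in enumerate(genes)}
    models: list[ScadModel] = []
    bag_ids: list[list[str]] = []
    skipped = 0
    for b in range(n_bags):
        rng = np.random.default_rng([seed, b])
        rows: list[np.ndarray] = []
        yy: list[np.ndarray] = []
        ids: list[str] = []
        for c, y, ci, oi in zip(sub, ys, case_idx, ctrl_idx):
            n_case = math.ceil(config.bag_fraction * len(ci))
            n_ctrl = math.ceil(config.bag_fraction * len(oi))
            pick = np.concatenate([
                rng.choice(ci, size=n_case, replace=False),
                rng.choice(oi, size=n_ctrl, replace=False),
            ])
            rows.append(c.matrix[:, pick].T)
            yy.append(y[pick])
            ids.extend(f"{c.name}:{c.sample_ids[i]}" for i in pick)
        Xb = np.vstack(rows)
        yb = np.concatenate(yy)
        fold_seed = int(rng.integers(0, 2**31 - 1))
        try:
            state = iterative_select(Xb, genes, yb, config, seed=fold_seed)
            selected = state.all_selected
            if selected:
                sel_idx = [pos[s] for s in selected]
                model = fit_scad_binomial_cv(
                    Xb[:, sel_idx], selected, yb, config, seed=fold_seed
                )
            else:
                # nothing survives selection (typical under a null): an
                # intercept-only model keeps the ensemble well defined
                ybar = min(max(float(yb.mean()), _P_CLIP), 1 - _P_CLIP)
                model = ScadModel(
                    genes=[], coefficients=np.zeros(0),
                    intercept=math.log(ybar / (1 - ybar)),
                    lam=float(config.lambda_grid[0]), a=config.scad_a,
                )
        except XTissueError as err:
            skipped += 1
            logger.warning("bag %d skipped: %s", b, err)
            continue
        models.append(model)
        bag_ids.append(ids)
    if skipped > 0.1 * n_bags:
        raise XTissueError(
            f"{skipped}/{n_bags} bags failed to fit; training aborted"
        )
    return BaggedEnsemble(
        models=models,
        bag_indices=bag_ids,
        all_sample_ids=all_ids,
        aggregation=config.aggregation,
    )


def predict_scores(ensemble: BaggedEnsemble, dataset: ExpressionDataset) -> np.ndarray:
    """Per-sample ensemble score: mean linear predictor across models.

    Every gene used by any model must be present in the dataset; a missing
    gene is an error listing the symbols, never a silent drop.  With the
    ``mean_probability`` aggregation rule the per-model linear predictors
    are passed through the logistic function before averaging.
    """
    missing = sorted(set(ensemble.genes) - set(dataset.gene_symbols))
    if missing:
        raise XTissueError(f"dataset lacks model genes: {missing}")
    acc = np.zeros(dataset.n_samples)
    for m in ensemble.models:
        idx = dataset.gene_index(m.genes)
        lp = m.linear_predictor(dataset.matrix[idx, :].T)
        if ensemble.aggregation == "mean_probability":
            lp = 1.0 / (1.0 + np.exp(-np.clip(lp, -30, 30)))
        acc += lp
    return acc / len(ensemble.models)


def oob_scores(
    ensemble: BaggedEnsemble, cohorts: list[ExpressionDataset]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Out-of-bag ensemble scores over the training pool.

    Each sample's score averages only the models whose training bag excluded
    it; samples present in every bag are dropped.  Returns (qualified ids,
    scores, case indicator).
    """
    id_to_pos: dict[str, int] = {}
    xs: list[np.ndarray] = []
    ys: list[float] = []
    qids: list[str] = []
    for c in cohorts:
        y = c.case_indicator()
        for j, qid in enumerate(_qualified_ids(c)):
            id_to_pos[qid] = len(qids)
            qids.append(qid)
            xs.append(c.matrix[:, j])
            ys.append(y[j])
    gene_maps = [c.gene_symbols for c in cohorts]
    for gm in gene_maps[1:]:
        if gm != gene_maps[0]:
            raise XTissueError("cohorts must share an identical gene order")
    symbols = gene_maps[0]
    X = np.vstack(xs)  # samples x genes
    lookup = {g: i for i, g in enumerate(symbols)}
    total = np.zeros(len(qids))
    count = np.zeros(len(qids))
    for b, m in enumerate(ensemble.models):
        idx = [lookup[g] for g in m.genes]
        lp = m.linear_predictor(X[:, idx])
        if ensemble.aggregation == "mean_probability":
            lp = 1.0 / (1.0 + np.exp(-np.clip(lp, -30, 30)))
        oob = [id_to_pos[q] for q in ensemble.oob_ids(b) if q in id_to_pos]
        total[oob] += lp[oob]
        count[oob] += 1
    keep = count > 0
    scores = total[keep] / count[keep]
    return (
        [q for q, k in zip(qids, keep) if k],
        scores,
        np.asarray(ys)[keep],
    )
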