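"""Weighted co-expression network analysis on control subjects.

Builds an unsigned soft-thresholded correlation network (|r|^beta), picks
the smallest beta whose degree distribution fits a scale-free topology with
R^2 above a target, converts adjacency to topological overlap (TOM), and
cuts the average-linkage tree of the TOM dissimilarity into modules with a
configurable minimum size (default 10, deliberately small so that compact,
highly predictive gene sets can surface).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core_io import XTissueError

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionNetwork:
    beta: int
    adjacency: np.ndarray
    tom: np.ndarray
    modules: dict[str, int] = field(default_factory=dict)
    min_module_size: int = 10


def _check_adjacency(adjacency: np.ndarray) -> np.ndarray:
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise XTissueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise XTissueError("adjacency must be symmetric")
    if (A < -1e-12).any() or (A > 1 + 1e-12).any():
        raise XTissueError("adjacency entries must lie in [0, 1]")
    A = A.copy()
    np.fill_diagonal(A, 0.0)  # self-connections never count toward connectivity
    return np.clip(A, 0.0, 1.0)


def scale_free_fit_r2(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """Goodness of scale-free topology fit of the weighted degree distribution.

    Connectivities k_i = sum_j a_ij are cut into equal-width bins (the
    standard convention; empty bins dropped) and log10(frequency) is
    regressed on log10(mean k); returns the regression R^2, signed negative
    when the slope is positive, so that only decaying degree distributions
    count as scale-free.
    """
    A = _check_adjacency(adjacency)
    if A.shape[0] < 20:
        raise XTissueError("scale_free_fit_r2 needs >= 20 genes")
    k = A.sum(axis=1)
    k = k[k > 0]
    if len(k) < n_bins or np.ptp(k) == 0:
        raise XTissueError("degenerate degree distribution (all connectivities equal)")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        xs.append(np.log10(np.mean(k[mask])))
        ys.append(np.log10(np.mean(mask)))
    if len(xs) < 3:
        raise XTissueError("too few occupied bins for a scale-free fit")
    x = np.asarray(xs)
    y = np.asarray(ys)
    slope = np.polyfit(x, y, 1)[0]
    r = np.corrcoef(x, y)[0, 1]
    r2 = float(r * r)
    return -r2 if slope > 0 else r2


def adjacency_from_expression(X: np.ndarray, beta: int) -> np.ndarray:
    """Unsigned soft-thresholded adjacency |cor(i, j)|^beta (genes x samples in)."""
    X = np.asarray(X, dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    A = np.abs(corr) ** beta
    np.fill_diagonal(A, 0.0)
    return np.clip(A, 0.0, 1.0)


def pick_soft_threshold(
    X_controls: np.ndarray,
    beta_candidates: range | list[int] = range(1, 21),
    r2_target: float = 0.80,
) -> tuple[int, dict[int, float]]:
    """Smallest soft-threshold power with scale-free fit above the target.

    ``X_controls`` is genes x control samples; control-only input is the
    caller's responsibility.  If no candidate reaches the target, the argmax
    is returned with a warning.  Returns (beta, fit-per-candidate).
    """
    X = np.asarray(X_controls, dtype=float)
    if X.shape[0] < 20:
        raise XTissueError("pick_soft_threshold needs >= 20 genes")
    fits: dict[int, float] = {}
    for beta in beta_candidates:
        try:
            fits[beta] = scale_free_fit_r2(adjacency_from_expression(X, beta))
        except XTissueError:
            fits[beta] = float("-inf")
        if fits[beta] > r2_target:
            return beta, fits
    best = max(fits, key=lambda b: fits[b])
    logger.warning(
        "no soft threshold reached scale-free R^2 > %.2f; using argmax beta=%d "
        "(R^2 = %.3f)", r2_target, best, fits[best],
    )
    return best, fits


def tom_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    Diagonal set to 1 by convention.  Matches a brute-force triple loop to
    machine precision.
    """
    A = _check_adjacency(adjacency)
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    tom: np.ndarray,
    min_module_size: int = 10,
    method: str = "gap",
    height_quantile: float = 0.99,
) -> np.ndarray:
    """Average-linkage modules from the TOM dissimilarity (1 - TOM).

    The tree is cut either at the midpoint of the largest gap between
    consecutive merge heights (``method='gap'``, deterministic and robust for
    block-structured data) or at a fixed quantile of the merge heights
    (``method='height'``).  Clusters below ``min_module_size`` get label 0
    (unassigned); remaining labels are ordered by decreasing module size.
    """
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if n < 2:
        raise XTissueError("need at least 2 genes")
    dis = 1.0 - tom
    np.fill_diagonal(dis, 0.0)
    dis = (dis + dis.T) / 2.0
    condensed = squareform(np.clip(dis, 0.0, None), checks=False)
    Z = linkage(condensed, method="average")
    heights = np.sort(Z[:, 2])
    if method == "gap":
        if len(heights) == 1 or np.ptp(heights) < 1e-12:
            labels = np.ones(n, dtype=int)
        else:
            gaps = np.diff(heights)
            g = int(np.argmax(gaps))
            cut = (heights[g] + heights[g + 1]) / 2.0
            labels = fcluster(Z, t=cut, criterion="distance")
    elif method == "height":
        cut = float(np.quantile(heights, height_quantile))
        labels = fcluster(Z, t=cut * (1 - 1e-9), criterion="distance")
    else:
        raise XTissueError(f"unknown tree-cut method {method!r}")
    labels = np.asarray(labels, dtype=int)
    sizes = {lab: int(np.sum(labels == lab)) for lab in np.unique(labels)}
    keep = [lab for lab, sz in sizes.items() if sz >= min_module_size]
    if not keep:
        logger.warning("all clusters below min_module_size; everything unassigned")
        return np.zeros(n, dtype=int)
    order = sorted(keep, key=lambda lab: (-sizes[lab], lab))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    return np.array([remap.get(lab, 0) for lab in labels], dtype=int)


def build_network(
    X_controls: np.ndarray,
    gene_symbols: list[str],
    min_module_size: int = 10,
    r2_target: float = 0.80,
) -> CoexpressionNetwork:
    """Convenience wrapper: soft threshold -> adjacency -> TOM -> modules."""
    beta, _ = pick_soft_threshold(X_controls, r2_target=r2_target)
    A = adjacency_from_expression(X_controls, beta)
    tom = tom_from_adjacency(A)
    labels = detect_modules(tom, min_module_size=min_module_size)
    return CoexpressionNetwork(
        beta=beta,
        adjacency=A,
        tom=tom,
        modules={g: int(l) for g, l in zip(gene_symbols, labels)},
        min_module_size=min_module_size,
    )
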