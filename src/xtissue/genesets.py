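"""Candidate gene selection from ranked ontology categories.

The candidate universe is the union of genes in the top-K ranked categories,
intersected with the genes measured in every cohort.  The ``knockout``
operation removes genes in the top-N categories to tune the model away from
the categories most strongly associated with genetic risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import GeneSetCollection, XTissueError


@dataclass
class SelectionSummary:
    """Bookkeeping from select_signature_genes for reporting."""

    per_set_measured: dict[str, int]

    @property
    def n_nonempty_sets(self) -> int:
        return sum(1 for v in self.per_set_measured.values() if v > 0)

    @property
    def median_nonempty_size(self) -> float:
        sizes = [v for v in self.per_set_measured.values() if v > 0]
        return float(np.median(sizes)) if sizes else float("nan")


def select_signature_genes(
    collection: GeneSetCollection, K: int, measured: set[str]
) -> tuple[list[str], SelectionSummary]:
    """Union of genes in rank <= K sets, restricted to measured genes, sorted.

    Also returns per-set measured-gene counts so callers can report how many
    categories remain non-empty and their median size.
    """
    if K > len(collection):
        raise XTissueError(f"K={K} exceeds number of sets ({len(collection)})")
    top = collection.top(K)
    per_set = {s.name: len(set(s.genes) & measured) for s in top}
    genes = sorted(collection.union_genes(max_rank=K) & measured)
    if not genes:
        raise XTissueError(f"no measured genes in the top {K} categories")
    return genes, SelectionSummary(per_set_measured=per_set)


def knockout_top_categories(
    genes: list[str], collection: GeneSetCollection, N: int
) -> list[str]:
    """Remove genes belonging to the top-N ranked categories (N=0: identity)."""
    if N > len(collection):
        raise XTissueError(f"N={N} exceeds number of sets ({len(collection)})")
    if N == 0:
        return list(genes)
    removed = collection.union_genes(max_rank=N)
    out = [g for g in genes if g not in removed]
    if not out:
        raise XTissueError(f"knockout of top {N} categories empties the gene list")
    return out


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise error threshold alpha / n_tests."""
    if not (0 < alpha < 1):
        raise XTissueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise XTissueError("n_tests must be >= 1")
    return alpha / n_tests
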