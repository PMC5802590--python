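"""Leave-unit-out importance of gene categories or co-expression modules.

Each unit (an ontological category, or a network module) is removed from the
working gene list in turn; the full train + cross-tissue predict + trait
association pipeline is re-run with the same seed so that the drop in
explained variance reflects gene removal only.  Units whose drop falls
outside the Bonferroni-corrected normal band (mean +/- z * SD of all drops)
are flagged as important.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import ExpressionDataset, GeneSetCollection, PipelineConfig, XTissueError
from .evaluate import _run_once

logger = logging.getLogger(__name__)


@dataclass
class KnockoutProfile:
    unit_names: list[str]
    unit_sizes: list[int]
    delta_ev: list[float]  # baseline EV - knockout EV, percent
    band_mean: float
    band_sd: float
    z_multiplier: float
    flagged: list[str]
    baseline_ev: float
    knockout_ev: list[float]

    def to_rows(self) -> list[dict]:
        flag = set(self.flagged)
        return [
            {
                "unit": u,
                "size": s,
                "ev": e,
                "delta_ev": d,
                "flagged": u in flag,
            }
            for u, s, e, d in zip(
                self.unit_names, self.unit_sizes, self.knockout_ev, self.delta_ev
            )
        ]


def fwer_band(
    delta_ev: np.ndarray,
    alpha: float = 0.05,
    n_units: int | None = None,
    z_override: float | None = None,
) -> tuple[float, float, float]:
    """(mean, sd, z) of the family-wise knockout band.

    z is the standard-normal quantile at 1 - alpha/(2 * n_units) (two-sided
    Bonferroni), overridable when a fixed multiplier is wanted.  A zero SD
    makes the band degenerate; callers then flag every nonzero drop.
    """
    delta_ev = np.asarray(delta_ev, dtype=float)
    n_units = len(delta_ev) if n_units is None else n_units
    if n_units < 1:
        raise XTissueError("n_units must be >= 1")
    z = (
        float(z_override)
        if z_override is not None
        else float(stats.norm.ppf(1 - alpha / (2 * n_units)))
    )
    mean = float(delta_ev.mean()) if len(delta_ev) else 0.0
    sd = float(delta_ev.std(ddof=1)) if len(delta_ev) > 1 else 0.0
    if sd == 0:
        logger.warning("fwer_band: zero SD, band degenerate")
    return mean, sd, z


def _knockout_profile(
    units: list[tuple[str, set[str]]],
    cohorts: list[ExpressionDataset],
    genes: list[str],
    target: ExpressionDataset,
    trait: np.ndarray,
    config: PipelineConfig,
    n_bags: int | None = None,
    alpha: float | None = None,
    z_override: float | None = None,
) -> KnockoutProfile:
    n_bags = n_bags if n_bags is not None else (config.permutation_bags or config.B_bags)
    alpha = config.alpha_fwer if alpha is None else alpha
    gene_set = set(genes)
    baseline_ev, _ = _run_once(
        cohorts, genes, target, trait, config, n_bags=n_bags, seed=config.rng_seed
    )
    names: list[str] = []
    sizes: list[int] = []
    evs: list[float] = []
    for name, unit_genes in units:
        working = [g for g in genes if g not in unit_genes]
        if not working:
            logger.warning("knockout of %s empties the gene list; recorded missing", name)
            continue
        ev, _ = _run_once(
            cohorts, working, target, trait, config,
            n_bags=n_bags, seed=config.rng_seed,
        )
        names.append(name)
        sizes.append(len(unit_genes & gene_set))
        evs.append(ev)
    deltas = [baseline_ev - e for e in evs]
    mean, sd, z = fwer_band(
        np.asarray(deltas), alpha=alpha, n_units=len(deltas), z_override=z_override
    )
    if sd == 0:
        flagged = [n for n, d in zip(names, deltas) if d != 0]
    else:
        flagged = [
            n for n, d in zip(names, deltas) if abs(d - mean) > z * sd
        ]
    return KnockoutProfile(
        unit_names=names,
        unit_sizes=sizes,
        delta_ev=deltas,
        band_mean=mean,
        band_sd=sd,
        z_multiplier=z,
        flagged=flagged,
        baseline_ev=baseline_ev,
        knockout_ev=evs,
    )


def category_knockout_profile(
    cohorts: list[ExpressionDataset],
    genes: list[str],
    categories: GeneSetCollection,
    target: ExpressionDataset,
    trait: np.ndarray,
    config: PipelineConfig,
    n_bags: int | None = None,
    alpha: float | None = None,
    z_override: float | None = None,
) -> KnockoutProfile:
    """Per-category change in cross-tissue explained variance on removal."""
    units = [(s.name, set(s.genes)) for s in categories.by_rank()]
    return _knockout_profile(
        units, cohorts, genes, target, trait, config,
        n_bags=n_bags, alpha=alpha, z_override=z_override,
    )


def module_knockout_profile(
    cohorts: list[ExpressionDataset],
    genes: list[str],
    modules: dict[str, int],
    target: ExpressionDataset,
    trait: np.ndarray,
    config: PipelineConfig,
    n_bags: int | None = None,
    alpha: float | None = None,
    z_override: float | None = None,
) -> KnockoutProfile:
    """Per-module change in explained variance; label 0 (unassigned) skipped."""
    labels = sorted({m for m in modules.values() if m != 0})
    units = [
        (f"module_{lab}", {g for g, m in modules.items() if m == lab})
        for lab in labels
    ]
    if not units:
        raise XTissueError("no non-zero modules to knock out")
    return _knockout_profile(
        units, cohorts, genes, target, trait, config,
        n_bags=n_bags, alpha=alpha, z_override=z_override,
    )
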