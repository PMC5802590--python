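"""End-to-end experiment runner.

Chains preprocessing, gene selection, bagged training, cross-tissue
prediction and (optionally) the permutation null and knockout profiling into
a single reproducible run directory.  Every artifact is stamped with the
config hash and seed; all randomness flows from the one configured seed.
Negative-control experiments are ordinary runs on datasets lacking planted
coupling — there is no special code path for them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import genesets as gs
from . import preprocess as pp
from .core_io import (
    ExpressionDataset,
    PipelineConfig,
    XTissueError,
    align_common_samples,
    parse_gmt,
    read_expression_table,
)
from .importance import category_knockout_profile
from .polymodel import BaggedEnsemble, bagged_train, oob_scores, predict_scores

logger = logging.getLogger(__name__)


@dataclass
class Manifest:
    """Named dataset paths for one experiment."""

    cohorts: list[dict]  # each: {name, expression, metadata}
    target: dict  # {name, expression, metadata, trait}
    gene_sets: str

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Manifest":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("cohorts", "target", "gene_sets"):
            if key not in d:
                raise XTissueError(f"manifest missing required key {key!r}")
        return cls(cohorts=d["cohorts"], target=d["target"], gene_sets=d["gene_sets"])

    def validate_paths(self) -> None:
        paths = [self.gene_sets]
        for c in self.cohorts:
            paths += [c["expression"], c["metadata"]]
        paths += [self.target["expression"], self.target["metadata"]]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise XTissueError(f"manifest refers to missing files: {missing}")


@dataclass
class ExperimentResult:
    run_dir: Path
    genes: list[str]
    ensemble: BaggedEnsemble
    evaluation: dict = field(default_factory=dict)


def _default_covariates(ds: ExpressionDataset) -> pp.ResidualizationSpec:
    covs = [c for c in ("site", "sex", "age", "pmi") if c in ds.metadata.columns]
    if "site" in covs and ds.metadata["site"].nunique() < 2:
        covs.remove("site")
    if "age" in covs:
        covs.insert(covs.index("age") + 1, "age_squared")
    return pp.ResidualizationSpec(tuple(covs))


def residualize_default(ds: ExpressionDataset) -> ExpressionDataset:
    """Residualize against whichever standard covariates the metadata carries."""
    return pp.residualize_expression(ds, _default_covariates(ds))


def preprocess_cohort(
    ds: ExpressionDataset, residualize: bool = True
) -> tuple[ExpressionDataset, pp.MatchResult | None]:
    """Per-cohort chain: align, collapse, quantile-normalize, match, residualize.

    Propensity matching runs only when the cohort has more controls than
    cases; its report (pairs plus covariate balance) is returned alongside
    the dataset.
    """
    ds = align_common_samples(ds)
    ds = pp.collapse_duplicate_symbols(ds)
    ds = pp.quantile_normalize_dataset(ds)
    diag = ds.metadata["diagnosis"]
    n_case, n_ctrl = int((diag == "case").sum()), int((diag == "control").sum())
    match = None
    if n_ctrl > n_case:
        match = pp.propensity_match_1to1(ds.metadata)
        ds = ds.subset_samples(match.matched_ids)
    if residualize:
        ds = residualize_default(ds)
    return ds, match


def run_experiment(
    config: PipelineConfig,
    manifest: Manifest,
    out_dir: str | Path,
    run_permutation: bool = False,
    run_knockout: bool = False,
) -> ExperimentResult:
    """Run the full discovery + cross-tissue experiment into ``out_dir``."""
    manifest.validate_paths()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.rng_seed}
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)
    try:
        logger.info("run parameters: %s", json.dumps(config.to_dict(), sort_keys=True))
        collection = parse_gmt(manifest.gene_sets)
        cohorts = [
            read_expression_table(c["expression"], c["metadata"], name=c.get("name"))
            for c in manifest.cohorts
        ]
        target = read_expression_table(
            manifest.target["expression"],
            manifest.target["metadata"],
            name=manifest.target.get("name", "target"),
        )
        prepped = [preprocess_cohort(c, residualize=False) for c in cohorts]
        cohorts = [ds for ds, _ in prepped]
        for ds, match in prepped:
            if match is not None:
                report = match.balance.copy()
                report.to_csv(out / f"match_{ds.name}.tsv", sep="\t")
        cohorts = pp.intersect_genes(cohorts)
        target = pp.collapse_duplicate_symbols(target)
        shared = sorted(set(cohorts[0].gene_symbols) & set(target.gene_symbols))
        if not shared:
            raise XTissueError("no genes shared between cohorts and target")
        cohorts = [c.subset_genes(shared) for c in cohorts]
        target = target.subset_genes(shared)
        # joint re-quantile-normalization on the overlapping genes makes
        # overall expression levels comparable across tissues
        joint = pp.quantile_normalize(
            np.hstack([c.matrix for c in cohorts] + [target.matrix])
        )
        offset = 0
        renormed = []
        for c in cohorts:
            renormed.append(c.with_matrix(joint[:, offset : offset + c.n_samples]))
            offset += c.n_samples
        cohorts = renormed
        target = target.with_matrix(joint[:, offset:])
        cohorts = [residualize_default(c) for c in cohorts]
        target = residualize_default(target)

        genes, summary = gs.select_signature_genes(
            collection, config.K_top_categories, set(shared)
        )
        genes = gs.knockout_top_categories(genes, collection, config.N_knockout)
        (out / "genes.txt").write_text("\n".join(genes) + "\n")
        logger.info(
            "selected %d genes from %d non-empty categories (median size %.1f)",
            len(genes), summary.n_nonempty_sets, summary.median_nonempty_size,
        )

        ensemble = bagged_train(cohorts, genes, config)
        with open(out / "model.json", "w") as f:
            json.dump({**stamp, **ensemble.to_dict()}, f)

        _, oob_s, oob_y = oob_scores(ensemble, cohorts)
        classification_ev = 100.0 * ev.nagelkerke_r2(oob_y, oob_s)
        scores = predict_scores(ensemble, target)
        pd.DataFrame(
            {"sample_id": target.sample_ids, "score": scores}
        ).to_csv(out / "scores.tsv", sep="\t", index=False)

        evaluation: dict = {**stamp, "classification_ev_pct": classification_ev}
        trait_col = manifest.target.get("trait", "hba1c")
        if trait_col in target.metadata.columns:
            trait = target.metadata[trait_col].to_numpy(dtype=float)
            rho, evpct, p = ev.continuous_association(scores, trait)
            evaluation.update(
                {"spearman_rho": rho, "trait_ev_pct": evpct, "trait_p": p}
            )
        diag = target.metadata["diagnosis"].to_numpy()
        if len(np.unique(diag[diag != "unknown"])) == 2:
            evaluation["wilcoxon_p"] = ev.wilcoxon_ranksum(
                scores[diag == "case"], scores[diag == "control"]
            )
            adj_cols = [c for c in ("age", "sex") if c in target.metadata.columns]
            if adj_cols:
                evaluation["adjusted_wilcoxon_p"] = ev.covariate_adjusted_group_test(
                    scores, diag, target.metadata[adj_cols]
                )
        if run_permutation and trait_col in target.metadata.columns:
            perm = ev.permutation_specificity(
                cohorts, genes, target, trait, config,
                observed=evaluation.get("trait_ev_pct"),
            )
            evaluation["permutation_p"] = perm.format_p()
            evaluation["median_null_classification_ev"] = (
                perm.median_null_classification_ev
            )
            pd.DataFrame({"null_ev_pct": perm.null_values}).to_csv(
                out / "permutation.tsv", sep="\t", index=False
            )
        if run_knockout and trait_col in target.metadata.columns:
            profile = category_knockout_profile(
                cohorts, genes, collection, target, trait, config
            )
            pd.DataFrame(profile.to_rows()).to_csv(
                out / "knockout.tsv", sep="\t", index=False
            )
        with open(out / "evaluation.json", "w") as f:
            json.dump(evaluation, f, indent=1, sort_keys=True)
        return ExperimentResult(
            run_dir=out, genes=genes, ensemble=ensemble, evaluation=evaluation
        )
    except XTissueError as err:
        raise XTissueError(f"experiment aborted: {err}") from err
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()
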