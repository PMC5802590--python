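"""Shared domain types and readers/writers for the tabular formats the pipeline touches.

Expression matrices are gene x sample tables of log2-scale values (TSV, first
column the gene symbol).  Sample metadata is a TSV keyed by sample id with the
fixed covariate columns ``diagnosis``, ``age``, ``sex`` and the optional
``pmi``, ``site`` and ``hba1c``; extra columns are carried through untouched.
Ranked gene sets use the GMT dialect, with the line order defining the rank
(rank 1 = strongest association with genetic risk).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DIAGNOSIS_LEVELS = ("case", "control", "unknown")
METADATA_COLUMNS = ("diagnosis", "age", "sex", "pmi", "site", "hba1c")


class XTissueError(ValueError):
    """Base error for malformed inputs anywhere in the pipeline."""


@dataclass
class ExpressionDataset:
    """A gene x sample log2 expression matrix bound to aligned sample metadata.

    Invariants (checked by :meth:`validate`): no missing values, matrix shape
    matches ``gene_symbols`` x ``sample_ids``, and the metadata has exactly one
    row per sample id, in the same order.  Gene symbols may contain duplicates
    immediately after reading; they are unique after
    :func:`xtissue.preprocess.collapse_duplicate_symbols`.
    """

    matrix: np.ndarray
    gene_symbols: list[str]
    sample_ids: list[str]
    metadata: pd.DataFrame
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_symbols = list(self.gene_symbols)
        self.sample_ids = list(self.sample_ids)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self, require_unique_genes: bool = False) -> None:
        n_genes, n_samples = self.matrix.shape
        if n_genes != len(self.gene_symbols):
            raise XTissueError(
                f"{self.name}: matrix has {n_genes} rows but "
                f"{len(self.gene_symbols)} gene symbols"
            )
        if n_samples != len(self.sample_ids):
            raise XTissueError(
                f"{self.name}: matrix has {n_samples} columns but "
                f"{len(self.sample_ids)} sample ids"
            )
        if np.isnan(self.matrix).any():
            raise XTissueError(f"{self.name}: matrix contains missing values")
        if len(set(self.sample_ids)) != n_samples:
            raise XTissueError(f"{self.name}: sample ids are not unique")
        if list(self.metadata.index) != self.sample_ids:
            raise XTissueError(
                f"{self.name}: metadata index does not match sample_ids order"
            )
        if require_unique_genes and len(set(self.gene_symbols)) != n_genes:
            raise XTissueError(f"{self.name}: gene symbols are not unique")

    # -- convenience -----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def diagnosis(self) -> np.ndarray:
        return self.metadata["diagnosis"].to_numpy()

    def case_indicator(self) -> np.ndarray:
        """Diagnosis coded case=1, control=0; raises on 'unknown'."""
        diag = self.metadata["diagnosis"]
        if (diag == "unknown").any():
            raise XTissueError(
                f"{self.name}: 'unknown' diagnoses present; drop them first "
                "(align_common_samples with include_unknown=False)"
            )
        return (diag == "case").to_numpy(dtype=float)

    def gene_index(self, symbols: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_symbols)}
        missing = [s for s in symbols if s not in lookup]
        if missing:
            raise XTissueError(
                f"{self.name}: genes absent from dataset: {sorted(missing)[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        return np.array([lookup[s] for s in symbols], dtype=int)

    def subset_genes(self, symbols: Sequence[str]) -> "ExpressionDataset":
        idx = self.gene_index(symbols)
        return ExpressionDataset(
            matrix=self.matrix[idx, :].copy(),
            gene_symbols=[self.gene_symbols[i] for i in idx],
            sample_ids=list(self.sample_ids),
            metadata=self.metadata.copy(),
            name=self.name,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionDataset":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise XTissueError(f"{self.name}: unknown sample ids {missing[:10]}")
        idx = np.array([lookup[s] for s in sample_ids], dtype=int)
        return ExpressionDataset(
            matrix=self.matrix[:, idx].copy(),
            gene_symbols=list(self.gene_symbols),
            sample_ids=list(sample_ids),
            metadata=self.metadata.iloc[idx].copy(),
            name=self.name,
        )

    def with_matrix(self, matrix: np.ndarray) -> "ExpressionDataset":
        return replace(self, matrix=np.asarray(matrix, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.gene_symbols, columns=self.sample_ids
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]
    rank: int


@dataclass
class GeneSetCollection:
    """Ordered, ranked named gene sets (rank 1 = most risk-associated)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise XTissueError("gene set names are not unique")
        ranks = sorted(s.rank for s in self.sets)
        if ranks != list(range(1, len(self.sets) + 1)):
            raise XTissueError("set ranks must form a permutation of 1..n_sets")
        for s in self.sets:
            if len(s.genes) == 0:
                raise XTissueError(f"gene set {s.name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def by_rank(self) -> list[GeneSet]:
        return sorted(self.sets, key=lambda s: s.rank)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def top(self, k: int) -> list[GeneSet]:
        return [s for s in self.by_rank() if s.rank <= k]

    def union_genes(self, max_rank: int | None = None) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            if max_rank is None or s.rank <= max_rank:
                out.update(s.genes)
        return out


@dataclass
class PipelineConfig:
    """All tunable knobs of the training/evaluation pipeline.

    Defaults follow the study design: candidate genes from the top 200 ranked
    categories, per-round correlation cap ``n = floor(samples/10)``, two
    selection rounds, 5-fold CV for the penalty weight, SCAD shape a = 3.7,
    2/3 within-cohort bagging with 1000 bags, and 1000 diagnosis permutations.
    """

    K_top_categories: int = 200
    N_knockout: int = 0
    genes_per_round_divisor: int = 10
    m_rounds: int = 2
    B_bags: int = 1000
    bag_fraction: float = 2.0 / 3.0
    cv_folds: int = 5
    scad_a: float = 3.7
    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(1.0, 1e-3, 25)
    )
    alpha_fwer: float = 0.05
    n_permutations: int = 1000
    rng_seed: int = 0
    # secondary switches
    permutation_bags: int | None = None  # reduced B for permutation reruns
    residual_type: str = "deviance"  # or "pearson"
    aggregation: str = "mean_linear_predictor"  # or "mean_probability"
    max_scad_iter: int = 10_000
    scad_tol: float = 1e-7

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if not (0 < self.bag_fraction < 1):
            raise XTissueError("bag_fraction must lie in (0, 1)")
        if self.scad_a <= 2:
            raise XTissueError("SCAD shape parameter a must exceed 2")
        if self.lambda_grid.ndim != 1 or len(self.lambda_grid) == 0:
            raise XTissueError("lambda_grid must be a non-empty 1-d array")
        if np.any(self.lambda_grid <= 0) or np.any(np.diff(self.lambda_grid) >= 0):
            raise XTissueError("lambda_grid must be strictly decreasing positives")
        if self.residual_type not in ("deviance", "pearson"):
            raise XTissueError("residual_type must be 'deviance' or 'pearson'")
        if self.aggregation not in ("mean_linear_predictor", "mean_probability"):
            raise XTissueError("unknown aggregation rule")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["lambda_grid"] = [float(x) for x in self.lambda_grid]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "lambda_grid" in d and d["lambda_grid"] is not None:
            d["lambda_grid"] = np.asarray(d["lambda_grid"], dtype=float)
        else:
            d.pop("lambda_grid", None)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def parse_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name TAB description TAB gene TAB gene ...``.

    Rank is the line number (1-based); duplicate genes within a set are
    deduplicated with a warning.  Duplicate set names or empty gene lists
    raise :class:`XTissueError` naming the offending line.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        rank = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise XTissueError(
                    f"{path}, line {lineno}: gene set has an empty gene list"
                )
            name = fields[0]
            if name in seen:
                raise XTissueError(f"{path}, line {lineno}: duplicate set name {name!r}")
            seen.add(name)
            genes: list[str] = []
            gseen: set[str] = set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in gseen:
                    logger.warning(
                        "%s line %d: duplicate gene %r in set %r deduplicated",
                        path, lineno, g, name,
                    )
                    continue
                gseen.add(g)
                genes.append(g)
            if not genes:
                raise XTissueError(
                    f"{path}, line {lineno}: gene set {name!r} has no genes"
                )
            rank += 1
            sets.append(GeneSet(name=name, genes=tuple(genes), rank=rank))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection.by_rank():
            fh.write("\t".join([s.name, f"rank={s.rank}", *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise XTissueError(f"{path}: metadata must contain a 'sample_id' column")
    meta = meta.set_index("sample_id")
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()].tolist()
        raise XTissueError(f"{path}: duplicate sample ids in metadata: {dup}")
    if "diagnosis" in meta.columns:
        bad = set(meta["diagnosis"].dropna()) - set(DIAGNOSIS_LEVELS)
        if bad:
            raise XTissueError(f"{path}: unknown diagnosis levels {sorted(bad)}")
    if "age" in meta.columns and (meta["age"].dropna() < 0).any():
        raise XTissueError(f"{path}: negative ages in metadata")
    if "hba1c" in meta.columns:
        vals = meta["hba1c"].dropna()
        if ((vals <= 0) | (vals >= 20)).any():
            raise XTissueError(f"{path}: hba1c values must lie in (0, 20)")
    return meta


def read_expression_table(
    path: str | Path,
    metadata_path: str | Path,
    name: str | None = None,
) -> ExpressionDataset:
    """Read a gene x sample TSV plus its metadata TSV.

    Columns are reordered to metadata order.  Gene symbols are preserved
    verbatim (duplicates allowed at this stage).  A sample present in the
    matrix but absent from the metadata is an error naming the id; a
    non-numeric cell is an error with its coordinates.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise XTissueError(f"{path}: expected gene symbol column plus >=1 sample")
    symbols = raw.iloc[:, 0].astype(str).tolist()
    values = raw.iloc[:, 1:]
    try:
        # numpy string->float conversion is correctly rounded (round-trip safe)
        numeric = pd.DataFrame(
            values.to_numpy(dtype=float), columns=values.columns
        )
    except ValueError:
        coerced = values.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & values.notna()
        r, c = np.argwhere(bad.to_numpy())[0]
        raise XTissueError(
            f"{path}: non-numeric cell at gene {symbols[r]!r}, "
            f"sample {values.columns[c]!r}: {values.iat[r, c]!r}"
        ) from None
    meta = read_metadata(metadata_path)
    matrix_samples = list(values.columns)
    missing = [s for s in matrix_samples if s not in meta.index]
    if missing:
        raise XTissueError(
            f"{path}: samples absent from metadata: {missing}"
        )
    meta = meta.loc[[s for s in meta.index if s in set(matrix_samples)]]
    ordered = list(meta.index)
    matrix = numeric[ordered].to_numpy(dtype=float)
    return ExpressionDataset(
        matrix=matrix,
        gene_symbols=symbols,
        sample_ids=ordered,
        metadata=meta,
        name=name or Path(path).stem,
    )


def write_expression_table(dataset: ExpressionDataset, path: str | Path) -> None:
    frame = dataset.to_frame()
    frame.index.name = "gene_symbol"
    frame.to_csv(path, sep="\t")  # default repr is shortest round-trip exact


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def align_common_samples(
    dataset: ExpressionDataset, include_unknown: bool = False
) -> ExpressionDataset:
    """Restrict to samples with a usable diagnosis, following metadata order.

    Samples labelled ``unknown`` are retained only when ``include_unknown``
    is set.  Raises if no samples survive.
    """
    diag = dataset.metadata["diagnosis"]
    keep = diag.notna()
    if not include_unknown:
        keep &= diag != "unknown"
    ids = [s for s, k in zip(dataset.sample_ids, keep) if k]
    if not ids:
        raise XTissueError(f"{dataset.name}: no samples left after alignment")
    if len(ids) == dataset.n_samples:
        return dataset
    return dataset.subset_samples(ids)
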