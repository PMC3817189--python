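"""Data model and file I/O shared by every analysis stage.

Expression matrices travel as tab-delimited text (genes in rows, a header row
of sample identifiers), phenotype tables as TSV with a declared column schema,
and gene set collections — both extracted correlated gene sets and annotation
catalogs — as standard GMT. All readers validate identifiers and values on
load and preserve file order; nothing is reordered silently.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("cgsa")

MISSING_MARKERS = {"", "NA", "NaN", "nan", "N/A", "null"}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of finite values on a generalized-log scale.

    The values are assumed already variance-stabilised (glog/VSN scale);
    normalisation of raw intensities is upstream of this package.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float64

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite expression value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        keep = [idx[g] for g in genes]
        return ExpressionMatrix(
            [self.gene_ids[i] for i in keep], list(self.sample_ids), self.values[keep]
        )

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        keep = [idx[s] for s in samples]
        return ExpressionMatrix(
            list(self.gene_ids), [self.sample_ids[j] for j in keep], self.values[:, keep]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def fingerprint(self) -> str:
        """Digest of identifiers and values, used to tag derived artifacts."""
        h = hashlib.sha256()
        h.update("\t".join(self.gene_ids).encode())
        h.update("\t".join(self.sample_ids).encode())
        h.update(np.ascontiguousarray(self.values).tobytes())
        return h.hexdigest()[:16]


@dataclass
class PhenotypeTable:
    """Per-sample phenotype variables with a declared type per column.

    ``schema`` maps column name to ``"categorical"`` or ``"quantitative"``.
    Missing entries are NaN (quantitative) or pandas NA (categorical).
    """

    data: pd.DataFrame  # index: sample ids
    schema: dict[str, str]

    def __post_init__(self) -> None:
        _check_unique([str(s) for s in self.data.index], "sample")
        for col, kind in self.schema.items():
            if kind not in ("categorical", "quantitative"):
                raise FormatError(f"unknown column type {kind!r} for {col!r}")
            if col not in self.data.columns:
                raise FormatError(f"schema column {col!r} absent from table")
            if kind == "categorical":
                levels = self.data[col].dropna().unique()
                if len(levels) < 2:
                    raise FormatError(
                        f"categorical column {col!r} has fewer than 2 observed levels"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def column(self, name: str) -> pd.Series:
        return self.data[name]

    def join_samples(self, X: ExpressionMatrix) -> tuple["PhenotypeTable", list[str]]:
        """Restrict to samples shared with ``X``; returns (table, unmatched ids)."""
        shared = [s for s in X.sample_ids if s in set(self.sample_ids)]
        unmatched = sorted(set(self.sample_ids) - set(X.sample_ids))
        if unmatched:
            logger.warning(
                "phenotype table has %d samples absent from the expression matrix",
                len(unmatched),
            )
        return PhenotypeTable(self.data.loc[shared], dict(self.schema)), unmatched


@dataclass
class GeneSetRecord:
    set_id: str
    description: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.set_id!r} has an empty member list")


@dataclass
class GeneSetFile:
    """Ordered collection of gene set records as carried by a GMT file."""

    records: list[GeneSetRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([r.set_id for r in self.records], "gene set")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def as_dict(self) -> dict[str, list[str]]:
        return {r.set_id: list(r.members) for r in self.records}


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV; first row sample ids, first column gene ids.

    Raises :class:`FormatError` naming the offending identifier or cell on
    duplicates or non-numeric values. Missing values are rejected: downstream
    correlation machinery assumes complete data.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = [c for c in header[1:] if c != ""]
    _check_unique(sample_ids, "sample")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    gene_ids = [str(g) for g in df.index]
    _check_unique(gene_ids, "gene")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        raw_na = df[col].isna()
        bad = converted.isna() & ~raw_na
        if bad.any():
            gi = gene_ids[int(np.flatnonzero(bad.to_numpy())[0])]
            raise FormatError(
                f"non-numeric value at gene {gi!r}, sample {sample_ids[j]!r}"
            )
        if raw_na.any():
            gi = gene_ids[int(np.flatnonzero(raw_na.to_numpy())[0])]
            raise FormatError(f"missing value at gene {gi!r}, sample {sample_ids[j]!r}")
        values[:, j] = converted.to_numpy()
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression_table(X: ExpressionMatrix, path: str | Path) -> None:
    X.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def drop_incomplete_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Pre-load helper: drop rows with any missing entry, logging the count."""
    complete = df.dropna(axis=0)
    dropped = len(df) - len(complete)
    if dropped:
        logger.info("dropped %d genes with missing values", dropped)
    return complete


def collapse_duplicate_genes(X: ExpressionMatrix, mapping: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse probe-level rows to unique gene ids, keeping the highest-variance row.

    ``mapping`` maps row identifier -> gene identifier; rows without a mapping
    are dropped. Off by default in every pipeline stage.
    """
    var = X.values.var(axis=1, ddof=1)
    best: dict[str, int] = {}
    for i, probe in enumerate(X.gene_ids):
        gene = mapping.get(probe)
        if gene is None:
            continue
        if gene not in best or var[i] > var[best[gene]]:
            best[gene] = i
    genes = sorted(best, key=lambda g: best[g])
    rows = [best[g] for g in genes]
    return ExpressionMatrix(genes, list(X.sample_ids), X.values[rows])


def read_gmt(path: str | Path) -> GeneSetFile:
    """Read a standard GMT file (tab-separated: id, description, members...)."""
    records = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            records.append(GeneSetRecord(fields[0], fields[1], fields[2:]))
    return GeneSetFile(records)


def write_gmt(sets: GeneSetFile, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rec in sets:
            if not rec.members:
                raise FormatError(f"gene set {rec.set_id!r} has no members")
            fh.write("\t".join([rec.set_id, rec.description, *rec.members]) + "\n")


def read_phenotype_table(path: str | Path, schema: Mapping[str, str]) -> PhenotypeTable:
    """Read a sample phenotype TSV with one row per sample.

    Columns declared quantitative parse as floats; categorical columns keep
    their string levels. Empty cells and ``NA`` variants are recorded missing.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    df.index = df.index.astype(str)
    out = pd.DataFrame(index=df.index)
    for col, kind in schema.items():
        if col not in df.columns:
            raise FormatError(f"phenotype column {col!r} not in file")
        raw = df[col].where(~df[col].isin(MISSING_MARKERS), other=pd.NA)
        if kind == "quantitative":
            out[col] = pd.to_numeric(raw, errors="raise")
        else:
            out[col] = raw.astype("string")
    return PhenotypeTable(out, dict(schema))


# ---------------------------------------------------------------------------
# configuration

def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration: one mapping block per pipeline stage."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError("configuration root must be a mapping of stage blocks")
    return cfg


def merge_config(stage_cfg: Mapping | None, cli_args: Mapping) -> dict:
    """CLI flags win over their config-file twins; None CLI values defer."""
    merged = dict(stage_cfg or {})
    for key, val in cli_args.items():
        if val is not None:
            merged[key] = val
    return merged


def log_stage(stage: str, params: Mapping, inputs: Mapping[str, str] | None = None) -> None:
    """Log a stage's parameter set and input digests for reproducibility."""
    logger.info("stage=%s params=%s inputs=%s", stage, dict(params), dict(inputs or {}))
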