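"""Data model and I/O for the tables the pipeline touches.

All tabular formats are plain TSV (UTF-8, '.' decimal): expression and
fraction matrices have gene/cell-type row labels and sample-id columns;
clinical tables are one row per sample. Gene sets use the MSigDB GMT
dialect. Gene identifiers are case-sensitive symbols and are never mapped
or aliased here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("macroindex")

__all__ = [
    "ExpressionMatrix",
    "FractionSet",
    "GeneSetCollection",
    "ClinicalTable",
    "AlterationMatrix",
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "harmonize",
]


class MatrixFormatError(ValueError):
    """A TSV matrix violated the expected layout or value constraints."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of nonnegative TPM values.

    Wraps a pandas DataFrame (``values``) whose index holds unique gene
    symbols and whose columns hold unique sample ids.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate gene ids: {dupes[:5]}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate sample ids: {dupes[:5]}")
        arr = df.to_numpy()
        if not np.isfinite(arr).all():
            raise MatrixFormatError("expression values must be finite")
        if (arr < 0).any():
            raise MatrixFormatError("expression values must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)])


@dataclass
class FractionSet:
    """One cell-type x sample fraction matrix per deconvolution algorithm.

    ``fractions`` maps an algorithm label to a DataFrame of fractions in
    [0, 1]; ``pvalues`` optionally maps the label to a per-sample
    deconvolution p-value Series.
    """

    fractions: dict[str, pd.DataFrame]
    pvalues: dict[str, pd.Series] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, df in self.fractions.items():
            arr = df.to_numpy()
            if not np.isfinite(arr).all():
                raise MatrixFormatError(f"{name}: fractions must be finite")
            if (arr < -1e-9).any() or (arr > 1 + 1e-9).any():
                raise MatrixFormatError(f"{name}: fractions must lie in [0, 1]")

    @property
    def algorithm_names(self) -> list[str]:
        return list(self.fractions)

    def subset_samples(self, sample_ids) -> "FractionSet":
        ids = list(sample_ids)
        fr = {k: df.loc[:, ids] for k, df in self.fractions.items()}
        pv = {k: s.loc[ids] for k, s in self.pvalues.items()}
        return FractionSet(fr, pv)


@dataclass
class GeneSetCollection:
    """Named gene sets; duplicate genes within a set are collapsed."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            if not genes:
                raise MatrixFormatError(f"gene set {name!r} is empty")
            seen: dict[str, None] = dict.fromkeys(str(g) for g in genes)
            clean[name] = list(seen)
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)


#: clinical columns the pipeline knows about; only sample_id is mandatory
CLINICAL_COLUMNS = (
    "sample_id",
    "histology",
    "who_grade",
    "transcriptome_subtype",
    "os_time",
    "os_event",
    "pfi_time",
    "pfi_event",
    "age",
    "gender",
)


@dataclass
class ClinicalTable:
    """Per-sample clinical phenotype table.

    Missing fields are allowed at load time; operations that require a
    field raise when it is absent.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "sample_id" not in df.columns:
            raise MatrixFormatError("clinical table needs a 'sample_id' column")
        if df["sample_id"].duplicated().any():
            raise MatrixFormatError("duplicate sample ids in clinical table")
        self.data = df.set_index(df["sample_id"].astype(str), drop=False)
        for col in ("os_time", "pfi_time"):
            if col in df.columns and (pd.to_numeric(df[col], errors="coerce") < 0).any():
                raise MatrixFormatError(f"{col} must be >= 0")
        for col in ("os_event", "pfi_event"):
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="coerce").dropna()
                if not vals.isin([0, 1]).all():
                    raise MatrixFormatError(f"{col} must be binary 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def require(self, *cols: str) -> pd.DataFrame:
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise KeyError(f"clinical table lacks required column(s): {missing}")
        return self.data.loc[:, list(cols)]

    def subset_samples(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].reset_index(drop=True))


@dataclass
class AlterationMatrix:
    """Binary feature x sample indicators of mutation / copy gain / loss."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            raise MatrixFormatError("duplicate alteration feature ids")
        arr = df.to_numpy()
        if not np.isin(arr, [0, 1]).all():
            raise MatrixFormatError("alteration matrix must be strictly binary")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "AlterationMatrix":
        return AlterationMatrix(self.values.loc[:, list(sample_ids)])


def read_matrix(path, rows_are_genes: bool = True) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample ids, first column = genes).

    Duplicate gene rows are collapsed by their mean, with a warning.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):  # pandas would mangle duplicates
        raise MatrixFormatError(f"{path}: duplicate sample ids in header")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not rows_are_genes:
        df = df.T
    bad = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()[:3]
        raise MatrixFormatError(f"{path}: non-numeric value in column {col!r}, row(s) {row}")
    if df.index.duplicated().any():
        n = int(df.index.duplicated().sum())
        warnings.warn(f"{path}: {n} duplicate gene row(s) collapsed by mean")
        logger.warning("%s: %d duplicate gene row(s) collapsed by mean", path, n)
        df = df.groupby(level=0, sort=False).mean()
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float))


def write_matrix(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path) -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file: name, description, genes (tab-separated)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MatrixFormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise MatrixFormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path) -> None:
    clin.data.to_csv(path, sep="\t", index=False)


def harmonize(
    expr: ExpressionMatrix, fractions: FractionSet, clin: ClinicalTable
) -> tuple[ExpressionMatrix, FractionSet, ClinicalTable, dict]:
    """Restrict all inputs to the shared sample ids, in a common order.

    Returns the three aligned objects plus a report of dropped samples per
    input. The shared order is the expression-matrix order restricted to
    the intersection, which makes the operation idempotent.
    """
    shared = set(expr.sample_ids)
    for df in fractions.fractions.values():
        shared &= set(df.columns)
    shared &= set(clin.sample_ids)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared sample id(s); need >= 3")
    order = [s for s in expr.sample_ids if s in shared]
    report = {
        "n_shared": len(order),
        "dropped_expression": sorted(set(expr.sample_ids) - shared),
        "dropped_fractions": {
            k: sorted(set(df.columns) - shared) for k, df in fractions.fractions.items()
        },
        "dropped_clinical": sorted(set(clin.sample_ids) - shared),
    }
    for key, dropped in (
        ("expression", report["dropped_expression"]),
        ("clinical", report["dropped_clinical"]),
    ):
        if dropped:
            logger.warning("harmonize: dropped %d %s sample(s)", len(dropped), key)
    return (
        expr.subset_samples(order),
        fractions.subset_samples(order),
        clin.subset_samples(order),
        report,
    )
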