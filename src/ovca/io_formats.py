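"""Readers and writers for the external formats the pipeline touches.

Canonical dialect is TSV (UTF-8, tab-delimited, ``.`` decimal); GCT 1.2 is
supported for expression matrices. Gene identifiers are opaque strings —
no probe collapsing happens here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "GeneSetCollection",
    "ClinicalTable",
    "HairpinLibrary",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_hairpin_library",
    "write_hairpin_library",
    "read_clinical",
    "write_clinical",
    "read_counts",
    "write_counts",
]

STAGE_TOKENS = ("I", "II", "III", "IV", "unknown")
GRADE_TOKENS = ("1", "2", "3", "unknown")


class FormatError(ValueError):
    """Raised when a file violates a format contract or a type invariant."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Log2-scale gene-by-sample expression values with row/column ids.

    Invariants enforced at construction: ids unique, shape consistent with
    the id lists, no missing or non-finite values.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, cols])


@dataclass
class GeneSetCollection:
    """Named gene sets; set names unique, sets non-empty, genes unique per set."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set {name!r} contains duplicate genes")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation with survival endpoints.

    Missing fields are the explicit string ``"unknown"`` (categoricals) or
    NaN (numeric); operations that require a field must reject records
    lacking it rather than impute.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id",)
    NUMERIC = ("age", "os_time", "os_event", "pfs_time", "pfs_event")
    CATEGORICAL = ("stage", "grade", "metastasis", "histology", "subtype")

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"clinical table missing required column {col!r}")
        _check_unique(df["sample_id"].tolist(), "sample id")
        for col in self.CATEGORICAL:
            if col not in df.columns:
                df[col] = "unknown"
            df[col] = df[col].fillna("unknown").astype(str)
        for col in self.NUMERIC:
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="raise")
        bad_stage = set(df["stage"]) - set(STAGE_TOKENS)
        if bad_stage:
            raise FormatError(
                f"unknown stage token(s) {sorted(bad_stage)}; allowed: {STAGE_TOKENS}"
            )
        bad_grade = set(df["grade"]) - set(GRADE_TOKENS)
        if bad_grade:
            raise FormatError(
                f"unknown grade token(s) {sorted(bad_grade)}; allowed: {GRADE_TOKENS}"
            )
        for tcol, ecol in (("os_time", "os_event"), ("pfs_time", "pfs_event")):
            t = df[tcol]
            if (t.dropna() <= 0).any():
                raise FormatError(f"{tcol} must be > 0 where present")
            e = df[ecol].dropna()
            if not e.isin([0, 1]).all():
                raise FormatError(f"{ecol} must be 0 or 1 where present")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].astype(str).tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class HairpinLibrary:
    """shRNA hairpin library: unique ids, one target gene each, unique sequences."""

    hairpin_ids: list[str]
    target_genes: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        n = len(self.hairpin_ids)
        if not (len(self.target_genes) == len(self.sequences) == n):
            raise FormatError("library columns have unequal lengths")
        _check_unique(self.hairpin_ids, "hairpin id")
        _check_unique(self.sequences, "hairpin sequence")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise FormatError(f"hairpin sequences have mixed lengths {sorted(lengths)}")
        for s in self.sequences:
            if set(s) - set("ACGT"):
                raise FormatError(f"sequence {s!r} contains non-ACGT characters")

    def __len__(self) -> int:
        return len(self.hairpin_ids)

    @property
    def gene_to_hairpins(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for h, g in zip(self.hairpin_ids, self.target_genes):
            out.setdefault(g, []).append(h)
        return out

    def hairpins_per_gene(self) -> dict[str, int]:
        return {g: len(hs) for g, hs in self.gene_to_hairpins.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hairpin_id": self.hairpin_ids,
                "gene": self.target_genes,
                "sequence": self.sequences,
            }
        )


# ---------------------------------------------------------------------------
# expression matrices


def _parse_numeric_block(df: pd.DataFrame, path: str) -> np.ndarray:
    try:
        return df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise FormatError(
                    f"{path}: non-numeric value {df[col].iloc[i]!r} at "
                    f"row {df.index[i]!r}, column {col!r}"
                ) from None
        raise


def read_expression(path, format: str = "tsv") -> ExpressionMatrix:
    """Read a gene-by-sample expression matrix from TSV or GCT 1.2.

    TSV layout: header of sample ids, first column of gene ids. GCT adds
    the ``#1.2`` version line, a dimensions line and a Description column.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        values = _parse_numeric_block(df, str(path))
        return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)
    if format == "gct":
        with open(path, encoding="utf-8") as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            dims = fh.readline().strip().split("\t")
            if len(dims) < 2:
                raise FormatError(f"{path}: malformed GCT dimensions line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0, dtype={0: str})
        if "Description" not in df.columns:
            raise FormatError(f"{path}: GCT body lacks a Description column")
        body = df.drop(columns=["Description"])
        if body.shape != (n_genes, n_samples):
            raise FormatError(
                f"{path}: GCT dimensions line says {n_genes}x{n_samples} "
                f"but body is {body.shape[0]}x{body.shape[1]}"
            )
        values = _parse_numeric_block(body, str(path))
        return ExpressionMatrix(list(body.index.astype(str)), list(body.columns.astype(str)), values)
    raise ValueError(f"unknown expression format {format!r}")


def write_expression(expr: ExpressionMatrix, path, format: str = "tsv") -> None:
    if format == "tsv":
        expr.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")
        return
    if format == "gct":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(expr.sample_ids) + "\n")
            for g, row in zip(expr.gene_ids, expr.values):
                fh.write(g + "\tna\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
        return
    raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a line are deduplicated with a warning; duplicate
    set names are an error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno} has {len(fields)} fields, need >= 3")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise FormatError(f"{path}: duplicate set name {name!r} at line {lineno}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                warnings.warn(
                    f"{path}: line {lineno} ({name}): removed "
                    f"{len(genes) - len(deduped)} duplicate gene(s)",
                    stacklevel=2,
                )
            if not deduped:
                raise FormatError(f"{path}: set {name!r} at line {lineno} has no genes")
            sets[name] = deduped
            descriptions[name] = desc
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# hairpin libraries


def read_hairpin_library(path) -> HairpinLibrary:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("hairpin_id", "gene", "sequence"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return HairpinLibrary(
        df["hairpin_id"].tolist(), df["gene"].tolist(), df["sequence"].tolist()
    )


def write_hairpin_library(library: HairpinLibrary, path) -> None:
    library.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clinical tables


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# screen count matrices


def read_counts(path, raw: bool = True) -> pd.DataFrame:
    """Read a hairpin-by-sample count table.

    Raw counts must be non-negative integers; with ``raw=False`` any finite
    non-negative reals (normalized counts) are accepted.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    values = _parse_numeric_block(df, str(path))
    if np.any(values < 0):
        raise FormatError(f"{path}: negative count")
    if raw and not np.all(values == np.round(values)):
        i, j = np.argwhere(values != np.round(values))[0]
        raise FormatError(
            f"{path}: non-integer count {values[i, j]} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} (counts must be non-negative integers)"
        )
    _check_unique(list(df.index), "hairpin id")
    _check_unique(list(df.columns), "sample id")
    if raw:
        df = df.astype(np.int64)
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="hairpin_id")
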