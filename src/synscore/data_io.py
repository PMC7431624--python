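"""Readers, writers and the internal data model.

The pipeline consumes three kinds of input: a gene expression matrix per
batch (genes in rows, samples in columns; TSV or GCT 1.2), gene-set
collections (GMT), and a clinical table (survival time, event flag and
optional covariates). Everything downstream is rank-based, so expression is
consumed as provided — no log transform or normalization is applied, only a
units tag is recorded.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "ClinicalTable",
    "read_expression",
    "collapse_duplicates",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "align_samples",
    "load_synapse17",
    "load_selected_terms",
]


class DataFormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with unique row and column labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with sample IDs as columns.
    units
        Free-text tag describing the expression units (e.g. ``"FPKM"``,
        ``"log2 intensity"``). Informational only; scoring is rank-based.
    batch_label
        Free-text batch identifier.
    """

    values: pd.DataFrame
    units: str = "unknown"
    batch_label: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise DataFormatError("duplicate gene symbols in expression matrix")
        if v.columns.has_duplicates:
            raise DataFormatError("duplicate sample IDs in expression matrix")
        if v.empty:
            raise DataFormatError("empty expression matrix")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataFormatError("non-numeric values in expression matrix")
        if not np.isfinite(arr).all():
            raise DataFormatError("expression matrix contains NaN or infinite values")

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(sample_ids)], units=self.units, batch_label=self.batch_label
        )


@dataclass
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            # collapse silently-duplicated symbols, preserving order
            seen: dict[str, None] = {}
            for g in self.genes:
                seen.setdefault(g)
            object.__setattr__(self, "genes", tuple(seen))
        if not self.genes:
            raise DataFormatError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Ordered mapping of set name -> (description, member gene symbols)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping[str, Sequence[str]]) -> "GeneSetCollection":
        return cls({name: GeneSet(name, "", tuple(genes)) for name, genes in d.items()})

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise DataFormatError(f"duplicate gene set name {gene_set.name!r}")
        self.sets[gene_set.name] = gene_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names})

    def filter_by_size(
        self, universe: Sequence[str], min_size: int, max_size: int
    ) -> "GeneSetCollection":
        """Keep sets whose *effective* size (members present in ``universe``)
        lies in ``[min_size, max_size]``; dropped sets are logged."""
        uni = set(universe)
        kept: dict[str, GeneSet] = {}
        for gs in self:
            eff = sum(g in uni for g in gs.genes)
            if min_size <= eff <= max_size:
                kept[gs.name] = gs
        dropped = len(self.sets) - len(kept)
        if dropped:
            logger.info(
                "size filter [%d, %d]: retained %d of %d sets",
                min_size, max_size, len(kept), len(self.sets),
            )
        return GeneSetCollection(kept)


#: canonical clinical column names
CLINICAL_COLUMNS = (
    "os_time", "os_event", "grade", "idh_status", "codel_1p19q", "tissue",
)

_ALIASES: dict[str, dict[str, str]] = {
    "grade": {
        "2": "II", "ii": "II", "who ii": "II", "g2": "II",
        "3": "III", "iii": "III", "who iii": "III", "g3": "III",
        "4": "IV", "iv": "IV", "who iv": "IV", "g4": "IV",
    },
    "idh_status": {
        "mutant": "mutant", "mut": "mutant", "mutated": "mutant", "1": "mutant",
        "wildtype": "wildtype", "wt": "wildtype", "wild-type": "wildtype",
        "wild type": "wildtype", "0": "wildtype",
    },
    "codel_1p19q": {
        "codel": "codel", "codeletion": "codel", "codeleted": "codel", "1": "codel",
        "non-codel": "non-codel", "noncodel": "non-codel", "non codel": "non-codel",
        "intact": "non-codel", "0": "non-codel",
    },
    "tissue": {
        "tumor": "tumor", "tumour": "tumor", "glioma": "tumor",
        "normal": "normal", "non-tumor": "normal",
    },
}

#: header names (lower-cased) recognised for each canonical column
_HEADER_ALIASES: dict[str, str] = {
    "sample_id": "sample_id", "sample": "sample_id", "id": "sample_id",
    "os_time": "os_time", "os": "os_time", "time": "os_time",
    "survival_time": "os_time", "os.time": "os_time",
    "os_event": "os_event", "event": "os_event", "status": "os_event",
    "censor": "os_event", "os.event": "os_event", "dead": "os_event",
    "grade": "grade", "who_grade": "grade", "who grade": "grade",
    "idh_status": "idh_status", "idh": "idh_status", "idh_mutation": "idh_status",
    "codel_1p19q": "codel_1p19q", "1p19q": "codel_1p19q",
    "codel": "codel_1p19q", "1p19q_codeletion": "codel_1p19q",
    "tissue": "tissue", "tissue_type": "tissue", "sample_type": "tissue",
}


@dataclass
class ClinicalTable:
    """Per-sample survival and covariate table.

    ``data`` is indexed by unique sample ID with the canonical columns
    ``os_time`` (non-negative, may be NaN e.g. for normal tissue),
    ``os_event`` (0/1, NaN allowed alongside missing time), ``grade``
    (II/III/IV or NaN), ``idh_status`` (mutant/wildtype/NaN),
    ``codel_1p19q`` (codel/non-codel/NaN) and ``tissue`` (tumor/normal).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise DataFormatError("duplicate sample IDs in clinical table")
        for col in CLINICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        t = df["os_time"]
        if (t.dropna() < 0).any():
            raise DataFormatError("negative survival time")
        ev = df["os_event"].dropna()
        if not ev.isin([0, 1]).all():
            raise DataFormatError("os_event must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].copy())

    def survival_frame(self) -> pd.DataFrame:
        """Complete cases for (os_time, os_event)."""
        return self.data[["os_time", "os_event"]].dropna()


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def collapse_duplicates(values: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene-symbol rows to their element-wise median.

    Idempotent and invariant to the order of the duplicated rows; a symbol
    with a single row passes through unchanged. Keeps first-appearance order
    of symbols.
    """
    if not values.index.has_duplicates:
        return values
    order = values.index.drop_duplicates()
    collapsed = values.groupby(level=0, sort=False).median()
    return collapsed.loc[order]


def _read_tsv_matrix(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise DataFormatError(f"{path}: empty expression matrix")
    return df


def _read_gct_matrix(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise DataFormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split("\t")
        if len(dims) < 2:
            raise DataFormatError(f"{path}: malformed GCT dimension line")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise DataFormatError(f"{path}: malformed GCT dimension line") from exc
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if df.shape[0] != n_rows or df.shape[1] - 1 != n_cols:
        raise DataFormatError(
            f"{path}: GCT declares {n_rows}x{n_cols} but body is "
            f"{df.shape[0]}x{df.shape[1] - 1}"
        )
    return df.drop(columns=df.columns[0])  # drop Description column


def read_expression(
    path: str | Path,
    format: str | None = None,
    units: str = "unknown",
    batch_label: str = "",
) -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV or GCT 1.2.

    Duplicate gene symbols are collapsed to their element-wise median.
    ``format`` defaults from the file extension (``.gct`` -> GCT, else TSV).
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format not in ("tsv", "gct"):
        raise ValueError(f"unknown expression format {format!r}")
    df = _read_gct_matrix(path) if format == "gct" else _read_tsv_matrix(path)
    df.index = pd.Index(df.index.astype(str).str.strip())
    df.columns = pd.Index(df.columns.astype(str))
    df.index.name = None
    df.columns.name = None
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise DataFormatError(f"{path}: non-numeric expression value") from exc
    n_before = df.shape[0]
    df = collapse_duplicates(df)
    if df.shape[0] < n_before:
        logger.info("%s: collapsed %d duplicate gene rows", path, n_before - df.shape[0])
    logger.info("%s: loaded %d genes x %d samples", path, *df.shape)
    return ExpressionMatrix(df, units=units, batch_label=batch_label or path.stem)


def write_expression(matrix: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "tsv":
        matrix.values.to_csv(path, sep="\t")
        return
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
        out = matrix.values.copy()
        out.insert(0, "Description", "na")
        out.to_csv(fh, sep="\t", index_label="NAME")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name TAB description TAB genes...``."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            if not genes:
                raise DataFormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            collection.add(GeneSet(name, desc, tuple(genes)))
    if not collection.sets:
        raise DataFormatError(f"{path}: empty GMT file")
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description or "na", *gs.genes]) + "\n")


_NUMERIC_RE = re.compile(r"^-?\d+(\.\d+)?([eE][+-]?\d+)?$")


def _normalize_categorical(series: pd.Series, column: str) -> pd.Series:
    alias = _ALIASES[column]
    out = []
    for raw in series:
        if pd.isna(raw) or str(raw).strip() == "":
            out.append(np.nan)
            continue
        key = str(raw).strip().lower()
        if key in alias:
            out.append(alias[key])
        elif str(raw).strip() in ("II", "III", "IV") and column == "grade":
            out.append(str(raw).strip())
        else:
            logger.warning("unrecognised %s value %r -> missing", column, raw)
            out.append(np.nan)
    return pd.Series(out, index=series.index, dtype=object)


def read_clinical(path: str | Path, aliases: Mapping[str, str] | None = None) -> ClinicalTable:
    """Read a clinical CSV/TSV into the canonical table.

    Header names are matched case-insensitively against a built-in alias
    table (extendable via ``aliases``: raw header -> canonical field).
    Categorical values are normalized ("WT" -> wildtype, "mut" -> mutant,
    ...); unrecognised strings become missing with a warning.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    raw = pd.read_csv(path, sep=sep, dtype=object)
    header_map = dict(_HEADER_ALIASES)
    if aliases:
        header_map.update({k.lower(): v for k, v in aliases.items()})
    renamed: dict[str, str] = {}
    for col in raw.columns:
        canon = header_map.get(str(col).strip().lower())
        if canon and canon not in renamed.values():
            renamed[col] = canon
    df = raw.rename(columns=renamed)
    if "sample_id" not in df.columns:
        raise DataFormatError(f"{path}: no sample_id column found")
    df = df.set_index(df["sample_id"].astype(str).str.strip()).drop(columns=["sample_id"])
    df = df[[c for c in CLINICAL_COLUMNS if c in df.columns]]
    for col in ("os_time", "os_event"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("grade", "idh_status", "codel_1p19q", "tissue"):
        if col in df.columns:
            df[col] = _normalize_categorical(df[col], col)
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    table.data.to_csv(path, sep=sep, index_label="sample_id")


def align_samples(
    expr: ExpressionMatrix, clinical: ClinicalTable
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Intersect expression and clinical samples, preserving expression order.

    Samples present in only one of the two inputs are dropped with a logged
    count; per-analysis n therefore varies with covariate completeness, as
    in real multi-cohort studies.
    """
    common = [s for s in expr.sample_ids if s in set(clinical.sample_ids)]
    dropped = (len(expr.sample_ids) - len(common)) + (len(clinical.sample_ids) - len(common))
    if dropped:
        logger.info("align_samples: dropped %d unmatched samples (%d shared)", dropped, len(common))
    if not common:
        raise DataFormatError("no samples shared between expression and clinical inputs")
    return expr.subset_samples(common), clinical.subset(common)


# ---------------------------------------------------------------------------
# Packaged resources
# ---------------------------------------------------------------------------


def _resource_path(name: str):
    return resources.files("synscore.resources").joinpath(name)


def load_synapse17() -> GeneSet:
    """The published 17-gene synapse signature."""
    with resources.as_file(_resource_path("synapse17.gmt")) as p:
        return read_gmt(p)["SYNAPSE_17"]


def load_selected_terms() -> list[str]:
    """Names of the nine synapse-related GO terms behind the signature."""
    text = _resource_path("selected_terms.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]
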