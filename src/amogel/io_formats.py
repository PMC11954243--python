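"""Readers and writers for the external tables the pipeline consumes.

Three kinds of inputs are supported, all plain delimited text:

* per-omics expression matrices (samples x features, first column sample id),
* a STRING-style protein–protein interaction table
  (``gene_a  gene_b  combined_score`` with scores on the 0–1000 scale),
* DAVID-style functional annotation charts
  (``term  p_value  comma-separated gene list``).

Gene identifiers are canonicalized (upper-cased, whitespace-stripped) before
any cross-source matching, and features living in more than one omics layer
are later disambiguated with ``<omics>:<symbol>`` unique identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LEVEL_NAMES = ("low", "medium", "high")


class OmicsType(str, Enum):
    MRNA = "mRNA"
    METHYLATION = "methylation"
    MIRNA = "miRNA"


class ParseError(ValueError):
    """A malformed cell or table in an input file."""


def canonical_symbol(symbol: str) -> str:
    """Upper-case and strip a gene symbol for cross-source matching."""
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# Omics matrices
# ---------------------------------------------------------------------------

@dataclass
class OmicsMatrix:
    """A dense samples x features numeric matrix for one omics layer."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    omics_type: OmicsType

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample_ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicated feature_ids")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_omics_matrix(path: str | Path, omics_type: OmicsType | str,
                      samples_in_rows: bool = True) -> OmicsMatrix:
    """Load one omics matrix from delimited text.

    Duplicated sample or feature ids are aggregated by their mean.  Features
    containing any missing value (empty cell or an NA token) are dropped; a
    cell that is neither numeric nor a recognized NA token is a parse error.
    """
    omics_type = OmicsType(omics_type)
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    # header applied manually: pandas would mangle duplicated column names
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=None, skiprows=1)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: no data rows") from exc
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    if len(header) != df.shape[1]:
        raise ParseError(f"{path}: header width does not match data width")
    # coerce by position: cells pandas could not parse as numbers and did not
    # recognize as NA are reported with their row and column labels
    for pos in range(df.shape[1]):
        col = df.iloc[:, pos]
        if col.dtype == object:
            coerced = pd.to_numeric(col, errors="coerce")
            bad = coerced.isna() & col.notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise ParseError(f"{path}: malformed numeric cell at row {row!r}, "
                                 f"column {header[pos]!r}")
            df.iloc[:, pos] = coerced
    df.columns = header
    if not samples_in_rows:
        df = df.T
    df.index = df.index.astype(str).str.strip()
    df.columns = [canonical_symbol(c) for c in df.columns]
    # aggregate duplicates by mean; NaN propagates so missing cells survive
    # aggregation and the feature is dropped below
    if df.index.duplicated().any():
        df = df.groupby(level=0, sort=False).mean()
    if pd.Index(df.columns).duplicated().any():
        df = df.T.groupby(level=0, sort=False).mean().T
    n_before = df.shape[1]
    df = df.dropna(axis=1, how="any")
    if df.shape[1] < n_before:
        logger.info("%s: dropped %d features with missing values", path, n_before - df.shape[1])
    return OmicsMatrix(list(df.index), list(df.columns), df.to_numpy(dtype=float), omics_type)


def write_omics_matrix(m: OmicsMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_labels(path: str | Path) -> dict[str, str]:
    """Load the sample -> subtype label table (two columns with header)."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected (sample_id, subtype) columns")
    ids = df.iloc[:, 0].str.strip()
    if ids.duplicated().any():
        raise ParseError(f"{path}: duplicated sample ids in label table")
    return dict(zip(ids, df.iloc[:, 1].str.strip()))


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    pd.DataFrame({"sample_id": list(labels), "subtype": list(labels.values())}).to_csv(
        path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# PPI table
# ---------------------------------------------------------------------------

@dataclass
class PPITable:
    """Undirected PPI edges with STRING combined scores on the 0–1000 scale.

    Pairs are stored once in canonical (min, max) symbol order; duplicated
    pairs collapse to their maximum reported score.
    """

    edges: pd.DataFrame  # columns: gene_a, gene_b, combined_score

    def __post_init__(self):
        e = self.edges
        if ((e["combined_score"] < 0) | (e["combined_score"] > 1000)).any():
            raise ValueError("combined_score outside [0, 1000]")
        a = e["gene_a"].map(canonical_symbol)
        b = e["gene_b"].map(canonical_symbol)
        swap = a > b
        canon = pd.DataFrame({"gene_a": a.where(~swap, b), "gene_b": b.where(~swap, a),
                              "combined_score": e["combined_score"]})
        self.edges = (canon.groupby(["gene_a", "gene_b"], as_index=False, sort=True)
                      .agg({"combined_score": "max"}))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def pair_scores(self) -> dict[tuple[str, str], float]:
        return {
            (a, b): s
            for a, b, s in zip(self.edges["gene_a"], self.edges["gene_b"],
                               self.edges["combined_score"])
        }


def read_ppi_table(path: str | Path) -> PPITable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 3:
        raise ParseError(f"{path}: expected (gene_a, gene_b, combined_score) columns")
    df = df.iloc[:, :3]
    df.columns = ["gene_a", "gene_b", "combined_score"]
    df["combined_score"] = pd.to_numeric(df["combined_score"], errors="raise")
    if ((df["combined_score"] < 0) | (df["combined_score"] > 1000)).any():
        raise ParseError(f"{path}: combined_score outside [0, 1000]")
    return PPITable(df)  # canonicalization happens in the dataclass


def write_ppi_table(t: PPITable, path: str | Path) -> None:
    t.edges.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Annotation charts (KEGG / GO)
# ---------------------------------------------------------------------------

class AnnotationSource(str, Enum):
    KEGG = "KEGG"
    GO = "GO"


@dataclass
class AnnotationChart:
    """DAVID-style term -> gene-set chart with enrichment p-values."""

    records: list[tuple[str, float, frozenset[str]]] = field(default_factory=list)
    source: AnnotationSource = AnnotationSource.KEGG

    def __post_init__(self):
        for term, p, genes in self.records:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"term {term}: p-value {p} outside [0, 1]")
            if not genes:
                raise ValueError(f"term {term}: empty gene list")

    @property
    def n_terms(self) -> int:
        return len(self.records)


def read_annotation_chart(path: str | Path, source: AnnotationSource | str) -> AnnotationChart:
    source = AnnotationSource(source)
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 3:
        raise ParseError(f"{path}: expected (term, p_value, genes) columns")
    records = []
    for _, row in df.iterrows():
        term = str(row.iloc[0]).strip()
        p = float(row.iloc[1])
        raw = "" if pd.isna(row.iloc[2]) else str(row.iloc[2])
        genes = frozenset(canonical_symbol(g) for g in raw.split(",") if g.strip())
        if not genes:
            logger.warning("%s: term %s has an empty gene list; skipped", path, term)
            continue
        records.append((term, p, genes))
    records.sort(key=lambda r: r[0])
    return AnnotationChart(records, source)


def write_annotation_chart(chart: AnnotationChart, path: str | Path) -> None:
    rows = [(term, p, ",".join(sorted(genes))) for term, p, genes in chart.records]
    pd.DataFrame(rows, columns=["term", "p_value", "genes"]).to_csv(
        path, sep=_sep_for(path), index=False)
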