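"""Promoter-level mark matrices: reading, aggregation, and transforms.

The observational unit is a gene promoter; each variable is a chromatin
mark (a histone PTM or variant) whose value is the tag count in a window
around the TSS. Marks are discretized into a small number of ordinal
categories by per-mark equal-frequency binning before network inference;
the nucleosome-positioning (NucPos) track stays continuous and is moved
to logarithm scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

NUCPOS_COLUMN = "NucPos"

__all__ = [
    "MarkMatrix",
    "DiscreteMatrix",
    "read_tag_matrix",
    "write_tag_matrix",
    "aggregate_promoter_counts",
    "discretize",
    "log_transform_nucpos",
    "equal_frequency_codes",
]


@dataclass
class MarkMatrix:
    """Genes x marks table of tag counts plus an optional NucPos track.

    ``counts`` holds one row per gene and one column per mark; raw counts
    are non-negative. ``nucpos`` is per-gene and flagged exactly once as
    ``"raw"`` (non-negative tag counts) or ``"log"`` (real-valued, after
    the log transform).
    """

    gene_ids: list[str]
    mark_names: list[str]
    counts: np.ndarray
    nucpos: np.ndarray | None = None
    nucpos_scale: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D genes x marks array")
        n_genes, n_marks = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids but {n_genes} count rows"
            )
        if len(self.mark_names) != n_marks:
            raise ValidationError(
                f"{len(self.mark_names)} mark names but {n_marks} count columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicated gene ids: {dupes[:5]}")
        if np.isnan(self.counts).any():
            r, c = np.argwhere(np.isnan(self.counts))[0]
            raise ValidationError(
                f"missing count at gene {self.gene_ids[r]!r}, mark {self.mark_names[c]!r}"
            )
        if (self.counts < 0).any():
            r, c = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[r]!r}, mark {self.mark_names[c]!r}"
            )
        if self.nucpos_scale not in ("raw", "log"):
            raise ValidationError(f"nucpos_scale must be 'raw' or 'log', got {self.nucpos_scale!r}")
        if self.nucpos is not None:
            self.nucpos = np.asarray(self.nucpos, dtype=float)
            if self.nucpos.shape != (n_genes,):
                raise ValidationError("nucpos must have one value per gene")
            if self.nucpos_scale == "raw" and (self.nucpos < 0).any():
                r = int(np.argwhere(self.nucpos < 0)[0])
                raise ValidationError(f"negative raw NucPos at gene {self.gene_ids[r]!r}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_marks(self) -> int:
        return self.counts.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=pd.Index(self.gene_ids, name="gene"),
                          columns=self.mark_names)
        if self.nucpos is not None:
            df[NUCPOS_COLUMN] = self.nucpos
        return df


@dataclass
class DiscreteMatrix:
    """Ordinal codes in {0, ..., K-1} per gene and mark.

    ``bin_edges`` records, per mark, the smallest value of each category
    above the first (strictly increasing thresholds). ``n_categories``
    gives the arity actually available per mark (smaller than K when a
    mark has fewer than K distinct values).
    """

    gene_ids: list[str]
    mark_names: list[str]
    codes: np.ndarray
    K: int
    bin_edges: dict[str, np.ndarray] = field(default_factory=dict)
    n_categories: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.shape != (len(self.gene_ids), len(self.mark_names)):
            raise ValidationError("codes shape does not match gene/mark labels")
        if self.codes.min(initial=0) < 0 or self.codes.max(initial=0) > self.K - 1:
            raise ValidationError(f"codes must lie in [0, {self.K - 1}]")
        if self.n_categories is None:
            self.n_categories = np.array(
                [self.codes[:, j].max(initial=0) + 1
                 for j in range(self.codes.shape[1])]
            )

    def arity(self, mark: str) -> int:
        return int(self.n_categories[self.mark_names.index(mark)])

    def column(self, mark: str) -> np.ndarray:
        return self.codes[:, self.mark_names.index(mark)]


def read_tag_matrix(path: str | Path) -> MarkMatrix:
    """Read a TSV tag-count matrix (gene id column + one column per mark).

    A ``NucPos`` column, if present, is split out of the mark set and kept
    as the continuous conditioning track.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a gene id column plus at least one mark column")
    header = list(df.columns)
    if all(_is_number(h) for h in header[1:]):
        raise FormatError(f"{path}: missing header row (header cells are numeric)")
    gene_ids = df.iloc[:, 0].astype(str).tolist()
    body = df.iloc[:, 1:]
    values = np.empty(body.shape, dtype=float)
    for j, col in enumerate(body.columns):
        converted = pd.to_numeric(body[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            r = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: non-numeric or missing value at gene {gene_ids[r]!r}, "
                f"column {col!r} (row {r + 2})"
            )
        values[:, j] = converted.to_numpy()
    mark_names = [c for c in body.columns]
    nucpos = None
    if NUCPOS_COLUMN in mark_names:
        idx = mark_names.index(NUCPOS_COLUMN)
        nucpos = values[:, idx]
        values = np.delete(values, idx, axis=1)
        mark_names = [c for c in mark_names if c != NUCPOS_COLUMN]
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"{path}: negative count at gene {gene_ids[r]!r}, column {mark_names[c]!r}"
        )
    # a NucPos column with negative entries can only be on log scale
    scale = "log" if nucpos is not None and (nucpos < 0).any() else "raw"
    return MarkMatrix(gene_ids=gene_ids, mark_names=mark_names, counts=values,
                      nucpos=nucpos, nucpos_scale=scale,
                      meta={"source": str(path)})


def write_tag_matrix(m: MarkMatrix, path: str | Path) -> None:
    """Write a MarkMatrix as TSV; floats use 6 significant digits."""
    m.to_dataframe().to_csv(Path(path), sep="\t", float_format="%.6g")


def _is_number(s: str) -> bool:
    try:
        float(s)
    except (TypeError, ValueError):
        return False
    return True


def _read_bedgraph(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    df = df[~df["chrom"].str.startswith("track")]
    for col in ("start", "end", "value"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def _read_bed6(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=range(6),
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     dtype={"chrom": str, "name": str, "strand": str})
    return df


def aggregate_promoter_counts(signal: str | Path, tss: str | Path,
                              flank: int = 1000,
                              mark_name: str | None = None) -> MarkMatrix:
    """Sum a bedGraph signal over promoter windows (TSS +/- flank).

    Coordinates are BED-style 0-based half-open; the TSS of a ``+`` gene
    is its ``start`` and of a ``-`` gene the position ``end - 1``. The
    promoter window is the half-open interval ``[TSS - flank, TSS + flank)``
    clipped at the chromosome origin. Genes are returned in BED file order.
    """
    if flank <= 0:
        raise ValidationError("flank must be positive")
    signal = Path(signal)
    tss = Path(tss)
    sig = _read_bedgraph(signal)
    genes = _read_bed6(tss)
    bad = ~genes["strand"].isin(["+", "-"])
    if bad.any():
        row = genes[bad].iloc[0]
        raise ValidationError(
            f"{tss}: unknown strand {row['strand']!r} for gene {row['name']!r}"
        )
    by_chrom = {c: g for c, g in sig.groupby("chrom")}
    counts = np.zeros(len(genes))
    for i, row in enumerate(genes.itertuples(index=False)):
        tss_pos = row.start if row.strand == "+" else row.end - 1
        ws, we = max(0, tss_pos - flank), tss_pos + flank
        block = by_chrom.get(row.chrom)
        if block is None:
            continue
        starts = block["start"].to_numpy()
        ends = block["end"].to_numpy()
        vals = block["value"].to_numpy()
        overlap = np.minimum(ends, we) - np.maximum(starts, ws)
        counts[i] = float(np.sum(vals * np.clip(overlap, 0, None)))
    name = mark_name or signal.stem
    return MarkMatrix(
        gene_ids=genes["name"].astype(str).tolist(),
        mark_names=[name],
        counts=counts[:, None],
        meta={"flank": flank, "signal": str(signal), "tss": str(tss)},
    )


def equal_frequency_codes(values: np.ndarray, K: int) -> np.ndarray:
    """Equal-frequency (quantile) codes in {0..K-1}; ties share the lower bin.

    The code of a value is ``floor(rank_strictly_below * K / n)`` so that
    all occurrences of an input value receive the category of its first
    occurrence in sorted order.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    sv = np.sort(values)
    below = np.searchsorted(sv, values, side="left")
    return (below * K) // n


def discretize(m: MarkMatrix, K: int = 3) -> DiscreteMatrix:
    """Per-mark equal-frequency binning of tag counts into K categories.

    Rank-based, hence invariant to any strictly monotone transform of a
    mark's values. A mark with fewer than K distinct values gets one
    category per distinct value (with a logged warning).
    """
    if K < 2:
        raise ValidationError("K must be at least 2")
    n = m.n_genes
    codes = np.zeros((n, m.n_marks), dtype=np.int64)
    edges: dict[str, np.ndarray] = {}
    n_categories = np.zeros(m.n_marks, dtype=np.int64)
    for j, name in enumerate(m.mark_names):
        col = m.counts[:, j]
        distinct = np.unique(col)
        if len(distinct) < K:
            logger.warning(
                "mark %r has only %d distinct values; using %d categories",
                name, len(distinct), max(1, len(distinct)),
            )
            cj = np.searchsorted(distinct, col)
        else:
            cj = equal_frequency_codes(col, K)
        codes[:, j] = cj
        n_categories[j] = cj.max() + 1
        occupied = np.unique(cj)
        edges[name] = np.array(
            [col[cj == c].min() for c in occupied[1:]], dtype=float
        )
    return DiscreteMatrix(gene_ids=list(m.gene_ids), mark_names=list(m.mark_names),
                          codes=codes, K=K, bin_edges=edges, n_categories=n_categories)


def log_transform_nucpos(m: MarkMatrix, pseudocount: float = 1.0) -> MarkMatrix:
    """Return a copy with NucPos moved to log scale: ln(raw + pseudocount)."""
    if m.nucpos is None:
        raise ValidationError("matrix has no NucPos track")
    if m.nucpos_scale == "log":
        raise ValidationError("NucPos is already on log scale")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    return MarkMatrix(
        gene_ids=list(m.gene_ids),
        mark_names=list(m.mark_names),
        counts=m.counts.copy(),
        nucpos=np.log(m.nucpos + pseudocount),
        nucpos_scale="log",
        meta={**m.meta, "nucpos_pseudocount": pseudocount},
    )
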