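"""Fragment ingestion and the cells x bins count matrix.

The counting model is deliberately simple: each sequenced fragment is assigned
to the single bin containing its midpoint, so every molecule counts exactly
once.  Low-coverage cells are filtered, bins that are zero in most cells are
discarded (dataset-specific low-mappability regions), and per-cell counts are
GC-corrected with a LOESS fit of counts against bin GC content:

    x_gc[t] = x[t] * mean(x) / loess(x ~ gc)[t]

The correction factor is mean-preserving by construction up to LOESS fit
error, so corrected counts stay on the raw-count scale.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import BinSet

__all__ = [
    "FragmentRecord",
    "CountMatrix",
    "read_fragments",
    "read_bam_fragments",
    "count_fragments",
    "filter_cells",
    "filter_zero_bins",
    "GCCorrector",
    "gc_correct",
]

logger = logging.getLogger(__name__)


class FragmentRecord(NamedTuple):
    chrom: str
    start: int
    end: int
    barcode: str
    dup_count: int = 1


@dataclass
class CountMatrix:
    """Cells x bins read counts aligned to a :class:`BinSet`.

    ``values`` holds non-negative integers when raw and reals after GC
    correction (``corrected`` flag).  ``meta`` carries bookkeeping such as the
    number of fragments that fell outside the binned contigs.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    bins: BinSet
    corrected: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x bins)")
        if self.values.shape[0] != len(self.cell_ids):
            raise ValueError("cell_ids do not match the number of rows")
        if self.values.shape[1] != len(self.bins):
            raise ValueError("bin set does not match the number of columns")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def totals(self) -> np.ndarray:
        """Per-cell total counts."""
        return self.values.sum(axis=1)

    def to_mtx(self, prefix: str | Path) -> None:
        """Export sparse MTX plus cell/bin label sidecar TSVs."""
        from scipy import io as sio
        from scipy import sparse

        prefix = Path(prefix)
        sio.mmwrite(str(prefix) + ".mtx", sparse.csr_matrix(self.values))
        pd.Series(self.cell_ids).to_csv(
            str(prefix) + ".cells.tsv", sep="\t", index=False, header=False
        )
        pd.Series(self.bins.labels()).to_csv(
            str(prefix) + ".bins.tsv", sep="\t", index=False, header=False
        )


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fragments(
    path: str | Path, barcode_whitelist: set[str] | None = None
) -> Iterator[FragmentRecord]:
    """Stream a 10x-style fragments TSV (optionally gzipped).

    Columns: chrom, start, end, barcode[, dup_count]; ``#`` comment lines are
    skipped; a missing count column defaults to 1.  Coordinates are 0-based
    half-open, as written by Cell Ranger.
    """
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected >= 4 tab-separated columns")
            chrom, start_s, end_s, barcode = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{ln}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from exc
            if barcode_whitelist is not None and barcode not in barcode_whitelist:
                continue
            dup = int(parts[4]) if len(parts) > 4 and parts[4] != "" else 1
            yield FragmentRecord(chrom, start, end, barcode, dup)


def read_bam_fragments(
    path: str | Path,
    barcode_tag: str = "CB",
    barcode_whitelist: set[str] | None = None,
    min_mapq: int = 10,
) -> Iterator[FragmentRecord]:
    """Stream fragments from a paired-end BAM (optional input path).

    Uses the leftmost properly-paired read of each template; the fragment spans
    [reference_start, reference_start + template_length).
    """
    import pysam  # optional dependency; fragments TSV is the primary path

    with pysam.AlignmentFile(str(path), "rb") as bam:
        for read in bam:
            if (
                read.is_unmapped
                or not read.is_proper_pair
                or read.is_read2
                or read.is_secondary
                or read.is_supplementary
                or read.mapping_quality < min_mapq
                or read.template_length <= 0
            ):
                continue
            if not read.has_tag(barcode_tag):
                continue
            barcode = read.get_tag(barcode_tag)
            if barcode_whitelist is not None and barcode not in barcode_whitelist:
                continue
            yield FragmentRecord(
                read.reference_name,
                read.reference_start,
                read.reference_start + read.template_length,
                barcode,
                1,
            )


def count_fragments(
    fragments: Iterable[FragmentRecord],
    bins: BinSet,
    weight_duplicates: bool = False,
) -> CountMatrix:
    """Quantify fragments per cell per bin.

    Each fragment contributes to the bin containing its midpoint
    ``(start + end) // 2``; fragments on unbinned contigs (or in gaps left by
    filtering) are ignored and tallied in ``meta['skipped_fragments']``.  By
    default each record counts once; set ``weight_duplicates`` to weight by the
    fragment file's duplicate-count column.
    """
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    offsets: dict[str, np.ndarray] = {}
    chrom_arr = bins.df["chrom"].to_numpy()
    for chrom in bins.chroms:
        idx = np.flatnonzero(chrom_arr == chrom)
        starts[chrom] = bins.df["start"].to_numpy()[idx]
        ends[chrom] = bins.df["end"].to_numpy()[idx]
        offsets[chrom] = idx

    cell_index: dict[str, int] = {}
    triplets_cell: list[int] = []
    triplets_bin: list[int] = []
    triplets_w: list[int] = []
    skipped = 0
    for frag in fragments:
        s = starts.get(frag.chrom)
        if s is None:
            skipped += 1
            continue
        mid = (frag.start + frag.end) // 2
        j = np.searchsorted(s, mid, side="right") - 1
        if j < 0 or mid >= ends[frag.chrom][j]:
            skipped += 1
            continue
        ci = cell_index.setdefault(frag.barcode, len(cell_index))
        triplets_cell.append(ci)
        triplets_bin.append(int(offsets[frag.chrom][j]))
        triplets_w.append(frag.dup_count if weight_duplicates else 1)

    values = np.zeros((len(cell_index), len(bins)), dtype=np.int64)
    if triplets_cell:
        np.add.at(
            values,
            (np.asarray(triplets_cell), np.asarray(triplets_bin)),
            np.asarray(triplets_w),
        )
    if skipped:
        logger.info("count_fragments: %d fragments outside binned regions", skipped)
    cell_ids = np.array(list(cell_index), dtype=object)
    return CountMatrix(values, cell_ids, bins, meta={"skipped_fragments": skipped})


def filter_cells(m: CountMatrix, min_frags: int = 20_000) -> CountMatrix:
    """Drop lowly covered cells (total count < ``min_frags``); order preserved."""
    if m.corrected:
        raise ValueError("cell filtering expects raw counts")
    keep = m.totals() >= min_frags
    if not keep.any():
        raise ValueError(
            f"all {m.n_cells} cells have < {min_frags} fragments; "
            "lower min_frags for this dataset"
        )
    return CountMatrix(
        m.values[keep], m.cell_ids[keep], m.bins, corrected=False, meta=dict(m.meta)
    )


def filter_zero_bins(m: CountMatrix, zero_frac: float = 0.85) -> CountMatrix:
    """Drop bins with zero counts in more than ``zero_frac`` of cells.

    The inequality is strict: with 100 cells and the default 0.85, a bin that
    is zero in 86 cells is removed while one zero in exactly 85 is kept.
    """
    if not 0 < zero_frac <= 1:
        raise ValueError("zero_frac must be in (0, 1]")
    if m.n_cells == 0:
        raise ValueError("no cells in matrix")
    frac_zero = (m.values == 0).sum(axis=0) / m.n_cells
    keep = frac_zero <= zero_frac
    if not keep.any():
        raise ValueError("zero-bin filter removed every bin")
    return CountMatrix(
        m.values[:, keep],
        m.cell_ids,
        m.bins.subset(keep),
        corrected=False,
        meta=dict(m.meta),
    )


class GCCorrector(BaseEstimator, TransformerMixin):
    """Per-cell LOESS GC correction of binned counts.

    For every cell, raw counts are regressed on bin GC content with LOESS and
    each bin is rescaled by ``mean(x) / fit(gc_t)``, flattening the GC trend
    while preserving the cell's mean count.  Fitted values are floored at a
    small positive epsilon, and correction factors are clipped to ``clip`` to
    bound the leverage of sparse GC extremes.

    Parameters
    ----------
    span : LOESS smoothing fraction (fraction of bins in each local fit).
    clip : (low, high) bounds on the multiplicative correction factor.
    min_unique_gc : cells are only corrected when the bin set carries at least
        this many distinct GC values; otherwise the fit is ill-posed and the
        cell is passed through with a warning.

    The transformer is stateless across cells (each row is corrected
    independently); ``fit`` validates inputs and caches nothing but the bin GC
    vector supplied at construction or fit time.
    """

    def __init__(
        self,
        gc: np.ndarray | None = None,
        span: float = 0.75,
        clip: tuple[float, float] = (0.2, 5.0),
        min_unique_gc: int = 10,
    ):
        self.gc = gc
        self.span = span
        self.clip = clip
        self.min_unique_gc = min_unique_gc

    def fit(self, X, y=None, gc: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        gc_vec = gc if gc is not None else self.gc
        if gc_vec is None:
            raise ValueError("per-bin GC content is required (gc=...)")
        gc_vec = np.asarray(gc_vec, dtype=float)
        if X.ndim != 2 or X.shape[1] != gc_vec.shape[0]:
            raise ValueError("X must be cells x bins aligned with gc")
        if np.isnan(gc_vec).any():
            raise ValueError("gc contains NaN; drop unannotated bins first")
        self.gc_ = gc_vec
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "gc_"):
            raise ValueError("GCCorrector is not fitted")
        X = np.asarray(X, dtype=float)
        gc = self.gc_
        order = np.argsort(gc, kind="stable")
        gc_sorted = gc[order]
        delta = 0.01 * (gc_sorted[-1] - gc_sorted[0])
        out = np.empty_like(X)
        n_unique = len(np.unique(gc))
        lo, hi = self.clip
        for i in range(X.shape[0]):
            x = X[i]
            if n_unique < self.min_unique_gc:
                warnings.warn(
                    "fewer than %d distinct GC values; skipping GC correction "
                    "for cell %d" % (self.min_unique_gc, i),
                    stacklevel=2,
                )
                out[i] = x
                continue
            fit_sorted = lowess(
                x[order],
                gc_sorted,
                frac=self.span,
                it=0,
                delta=delta,
                return_sorted=False,
            )
            fitted = np.empty_like(fit_sorted)
            fitted[order] = fit_sorted
            mean_x = x.mean()
            eps = max(1e-6, 1e-3 * max(mean_x, 1.0))
            factor = np.clip(mean_x / np.maximum(fitted, eps), lo, hi)
            out[i] = x * factor
        return out

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, y, **fit_params).transform(X)


def gc_correct(m: CountMatrix, loess_span: float = 0.75) -> CountMatrix:
    """GC-correct a raw count matrix (thin wrapper over :class:`GCCorrector`)."""
    if m.corrected:
        raise ValueError("matrix is already GC-corrected")
    corr = GCCorrector(gc=m.bins.gc, span=loess_span)
    values = corr.fit_transform(m.values)
    return CountMatrix(values, m.cell_ids, m.bins, corrected=True, meta=dict(m.meta))
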