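"""Copy-number state assignment per segment and per cell.

Each cell's chromosomes are partitioned into segments by the pruned
breakpoints.  A segment's coverage level is summarized by the trimmed mean of
its (GC-corrected) bin counts — the lowest and highest 10% quantile bins are
excluded — and referenced against the cell's genome-wide trimmed mean.

Segments whose trimmed mean has a z-score in [-1, 1] among the cell's segment
means are first collapsed onto the genome-wide mean (they are
indistinguishable from the baseline).  Each segment then gets an integer copy
number on the diploid baseline,

    copy = round(2 * segment_mean / genome_mean),

and the state is loss (0) for copy <= 1, normal (1) for copy == 2 and gain (2)
for copy >= 3.  Rounding 2x the fold change places the decision boundaries at
fold changes 0.75 and 1.25, midway between the true monosomy / disomy /
trisomy levels 0.5 / 1 / 1.5, so calls are robust to count noise; higher
amplifications still collapse onto the single "gain" state.  Because only
fold changes enter, calls are invariant to the cell's sequencing depth — and
whole-genome duplications or deletions are invisible by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from . import segmentation as seg

__all__ = [
    "LOSS",
    "NORMAL",
    "GAIN",
    "Karyotype",
    "trimmed_segment_mean",
    "assign_states",
    "karyotype_matrix",
    "CNACaller",
]

LOSS, NORMAL, GAIN = 0, 1, 2


@dataclass
class Karyotype:
    """Cells x bins copy-number states (0 loss, 1 normal, 2 gain)."""

    states: np.ndarray
    cell_ids: np.ndarray
    bin_ids: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.bin_ids = np.asarray(self.bin_ids, dtype=object)
        if self.states.shape != (len(self.cell_ids), len(self.bin_ids)):
            raise ValueError("states shape does not match cell/bin identifiers")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.states, index=list(self.cell_ids), columns=list(self.bin_ids)
        )


def trimmed_segment_mean(values, trim: float = 0.1) -> float:
    """Mean after dropping the lowest and highest ``trim`` quantile bins.

    ``floor(trim * n)`` observations are removed from each end of the sorted
    values; if trimming would empty the vector the plain mean is returned.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty segment")
    if not 0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    k = int(np.floor(trim * v.size))
    if 2 * k >= v.size:
        return float(v.mean())
    return float(stats.trim_mean(v, trim))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def assign_states(
    segment_means: np.ndarray, genome_mean: float, z_band: float = 1.0
) -> pd.DataFrame:
    """Assign loss/normal/gain to segments of one cell.

    Parameters
    ----------
    segment_means : trimmed mean count of each segment of the cell.
    genome_mean : trimmed mean count per bin over the cell's whole genome
        (same trim as the segments).
    z_band : segments whose trimmed mean has |z| <= z_band among the cell's
        segment means are collapsed onto the genome mean before the fold
        change is computed.

    Returns a frame with columns trimmed_mean (after any collapse), zscore,
    copy_number and state.
    """
    means = np.asarray(segment_means, dtype=float)
    if genome_mean <= 0:
        raise ValueError("degenerate cell: non-positive genome-wide mean count")
    sd = means.std(ddof=0)
    z = (means - means.mean()) / sd if sd > 0 else np.zeros_like(means)
    collapsed = np.where(np.abs(z) <= z_band, genome_mean, means)
    copy = _round_half_away(2.0 * collapsed / genome_mean).astype(int)
    state = np.where(copy <= 1, LOSS, np.where(copy == 2, NORMAL, GAIN))
    return pd.DataFrame(
        {
            "trimmed_mean": collapsed,
            "zscore": z,
            "copy_number": copy,
            "state": state.astype(np.int8),
        }
    )


def karyotype_matrix(
    segments: pd.DataFrame, cell_ids, bin_ids
) -> Karyotype:
    """Assemble the cells x bins state matrix from a per-segment table.

    ``segments`` must tile each cell's binned genome with half-open
    ``[start_bin, end_bin)`` ranges in genome-wide bin indices; a coverage gap
    raises an error naming the cell.
    """
    cell_ids = np.asarray(cell_ids, dtype=object)
    bin_ids = np.asarray(bin_ids, dtype=object)
    n_bins = len(bin_ids)
    states = np.full((len(cell_ids), n_bins), -1, dtype=np.int8)
    cell_pos = {c: i for i, c in enumerate(cell_ids)}
    for row in segments.itertuples(index=False):
        states[cell_pos[row.cell_id], row.start_bin : row.end_bin] = row.state
    if (states < 0).any():
        bad_cell, bad_bin = np.argwhere(states < 0)[0]
        raise ValueError(
            f"segments do not cover bin {bin_ids[bad_bin]} of cell "
            f"{cell_ids[bad_cell]}"
        )
    return Karyotype(states, cell_ids, bin_ids)


class CNACaller(BaseEstimator, TransformerMixin):
    """Per-cell CNA caller: counts matrix in, 3-state karyotype out.

    Runs Anderson-Darling binary segmentation per cell and chromosome, prunes
    weak breakpoints against the cell's genome-wide mean breakpoint AD, and
    assigns each resulting segment to loss / normal / gain from its trimmed
    mean fold change over the cell's genome-wide trimmed mean.

    Parameters
    ----------
    k_max : maximum breakpoints per chromosome (default 15).
    min_size : minimum bins on each side of a split (default 1; single-bin
        CNAs are callable).
    trim : quantile trimmed off each end when averaging segment counts.
    z_band : half-width of the z-score band collapsed onto the genome mean.
    prune : whether to prune breakpoints below the per-cell mean AD.

    Fitted attributes
    -----------------
    breakpoints_ : table of all recorded breakpoints (with ``kept`` flags).
    segments_ : per-segment table (cell, chrom, bin range, trimmed mean,
        z-score, copy number, state).
    karyotype_ : cells x bins state codes {0, 1, 2} for the training matrix.

    The caller treats every cell independently, so ``transform`` on new data
    simply runs the same procedure with the fitted parameters.
    """

    def __init__(
        self,
        k_max: int = 15,
        min_size: int = 1,
        trim: float = 0.1,
        z_band: float = 1.0,
        prune: bool = True,
    ):
        self.k_max = k_max
        self.min_size = min_size
        self.trim = trim
        self.z_band = z_band
        self.prune = prune

    def _call(self, X, chrom, cell_ids):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a cells x bins matrix")
        n_cells, n_bins = X.shape
        if chrom is None:
            chrom = np.array(["chr1"] * n_bins, dtype=object)
        chrom = np.asarray(chrom)
        if chrom.shape[0] != n_bins:
            raise ValueError("chrom labels must align with matrix columns")
        if cell_ids is None:
            cell_ids = np.array([f"cell{i}" for i in range(n_cells)], dtype=object)

        bp = seg.segment_matrix(
            X, cell_ids, chrom, k_max=self.k_max, min_size=self.min_size
        )
        bp = seg.prune_breakpoints(bp)
        kept = bp[bp["kept"]] if self.prune else bp

        chroms = list(dict.fromkeys(chrom))
        spans = {c: np.flatnonzero(chrom == c) for c in chroms}
        seg_rows = []
        for ci, cell in enumerate(cell_ids):
            genome_mean = trimmed_segment_mean(X[ci], self.trim)
            cell_bp = kept[kept["cell_id"] == cell]
            ranges = []  # (chrom, start_bin, end_bin) genome-wide
            for c in chroms:
                idx = spans[c]
                splits = np.sort(
                    cell_bp.loc[cell_bp["chrom"] == c, "split_index"].to_numpy()
                )
                bounds = np.concatenate([[0], splits, [len(idx)]]).astype(int)
                for lo, hi in zip(bounds[:-1], bounds[1:]):
                    if hi > lo:
                        ranges.append((c, int(idx[lo]), int(idx[hi - 1]) + 1))
            means = np.array(
                [trimmed_segment_mean(X[ci, s:e], self.trim) for _, s, e in ranges]
            )
            called = assign_states(means, genome_mean, self.z_band)
            for (c, s, e), row in zip(ranges, called.itertuples(index=False)):
                seg_rows.append(
                    (
                        cell,
                        c,
                        s,
                        e,
                        row.trimmed_mean,
                        row.zscore,
                        row.copy_number,
                        row.state,
                    )
                )
        segments = pd.DataFrame(
            seg_rows,
            columns=[
                "cell_id",
                "chrom",
                "start_bin",
                "end_bin",
                "trimmed_mean",
                "zscore",
                "copy_number",
                "state",
            ],
        )
        return bp, segments, cell_ids

    def fit(self, X, y=None, *, chrom=None, cell_ids=None, bin_ids=None):
        bp, segments, cell_ids = self._call(X, chrom, cell_ids)
        n_bins = np.asarray(X).shape[1]
        if bin_ids is None:
            bin_ids = np.array([f"bin{i}" for i in range(n_bins)], dtype=object)
        self.breakpoints_ = bp
        self.segments_ = segments
        karyo = karyotype_matrix(segments, cell_ids, bin_ids)
        self.karyotype_ = karyo.states
        self.cell_ids_ = karyo.cell_ids
        self.bin_ids_ = karyo.bin_ids
        self.n_features_in_ = n_bins
        return self

    def transform(self, X, *, chrom=None, cell_ids=None) -> np.ndarray:
        """Call states on a (possibly new) counts matrix; returns states."""
        _, segments, cells = self._call(X, chrom, cell_ids)
        n_bins = np.asarray(X).shape[1]
        bin_ids = np.array([f"bin{i}" for i in range(n_bins)], dtype=object)
        return karyotype_matrix(segments, cells, bin_ids).states

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        self.fit(X, y, **fit_params)
        return self.karyotype_
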