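"""Breakpoint detection by iterative Anderson-Darling binary segmentation.

Copy-number changes shift the whole distribution of per-bin read counts, so a
candidate breakpoint is scored by the two-sample Anderson-Darling (AD)
statistic between the counts to its left and right; the AD statistic weights
the tails of the distributions, where gains and losses show up most clearly.

Per-bin counts are heavily tied, so the statistic is computed in the
tie-adjusted (midrank) form of Scholz & Stephens for two samples:

    A2 = (N-1)/N * sum_i (1/n_i) * sum_j (l_j/N) *
         (N*M_ij - n_i*B_j)^2 / (B_j*(N-B_j) - N*l_j/4)

where j runs over the distinct pooled values with multiplicities l_j,
B_j is the midrank cumulative count of the pooled sample and M_ij the midrank
cumulative count of sample i.  Degenerate pooled points (denominator <= 0,
i.e. the pooled EDF at 0 or 1) are excluded.  A2 is exactly 0 when the two
sides are identical multisets, and is invariant under within-side permutation
and under adding a common constant to both sides.

Segmentation is greedy and global: every open segment's best split is scored,
the split with the largest AD anywhere on the chromosome is accepted, and the
two children re-enter the pool, until ``k_max`` breakpoints (default 15) are
recorded or nothing is splittable.  Breakpoints whose AD falls below the
cell's genome-wide mean breakpoint AD are then pruned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Breakpoint",
    "ad_distance",
    "ad_all_splits",
    "best_split",
    "segment_chromosome",
    "segment_matrix",
    "prune_breakpoints",
]


@dataclass(frozen=True)
class Breakpoint:
    """A split position within one chromosome of one cell.

    ``split_index`` is the within-chromosome ordinal of the first bin of the
    right segment; ``depth`` is the iteration at which the split was accepted.
    """

    cell_id: str
    chrom: str
    split_index: int
    ad: float
    depth: int


def _midrank_tables(values: np.ndarray):
    """Pooled distinct values, multiplicities and midrank cumulative counts."""
    vals, inv, l = np.unique(values, return_inverse=True, return_counts=True)
    cum = np.cumsum(l)
    B = cum - l / 2.0
    return inv, l.astype(float), B


def ad_distance(left: Sequence[float], right: Sequence[float]) -> float:
    """Tie-adjusted two-sample Anderson-Darling statistic A2_nm.

    Both sides must be non-empty.  Returns exactly 0.0 for identical
    multisets.
    """
    left = np.asarray(left)
    right = np.asarray(right)
    n, m = left.size, right.size
    if n == 0 or m == 0:
        raise ValueError("both segments must be non-empty")
    pooled = np.concatenate([left, right])
    N = n + m
    inv, l, B = _midrank_tables(pooled)
    D = len(l)
    f1 = np.bincount(inv[:n], minlength=D).astype(float)
    f2 = l - f1
    M1 = np.cumsum(f1) - f1 / 2.0
    M2 = np.cumsum(f2) - f2 / 2.0
    denom = B * (N - B) - N * l / 4.0
    valid = denom > 1e-12
    w = np.where(valid, l / N, 0.0)
    d = np.where(valid, denom, 1.0)
    t1 = np.sum(w * (N * M1 - n * B) ** 2 / d)
    t2 = np.sum(w * (N * M2 - m * B) ** 2 / d)
    return float((N - 1) / N * (t1 / n + t2 / m))


def ad_all_splits(values: np.ndarray, min_size: int = 1) -> np.ndarray:
    """AD statistic of every admissible split of one segment, vectorized.

    Returns an array ``a`` of length ``len(values)`` where ``a[i]`` is
    ``ad_distance(values[:i], values[i:])`` for ``min_size <= i <=
    len - min_size`` and NaN elsewhere.  The pooled multiset is the whole
    segment for every split, so the distinct-value tables are shared and the
    statistic for all splits is computed in one O(L x D) pass.
    """
    v = np.asarray(values)
    L = v.size
    out = np.full(L, np.nan)
    if L < 2 * min_size:
        return out
    inv, l, B = _midrank_tables(v)
    D = len(l)
    N = float(L)
    # F[i, j] = count of value j among the first i elements
    onehot = np.zeros((L, D))
    onehot[np.arange(L), inv] = 1.0
    F = np.vstack([np.zeros(D), np.cumsum(onehot, axis=0)])
    Fcum = np.cumsum(F, axis=1)
    cum_total = np.cumsum(l)
    M1 = Fcum - F / 2.0  # midrank cumulative counts of the left side
    M2 = (cum_total - Fcum) - (l - F) / 2.0
    denom = B * (L - B) - L * l / 4.0
    valid = denom > 1e-12
    w = np.where(valid, l / N, 0.0)
    d = np.where(valid, denom, 1.0)
    i = np.arange(min_size, L - min_size + 1)
    n = i.astype(float)[:, None]
    m = (L - i).astype(float)[:, None]
    t1 = np.sum(w * (N * M1[i] - n * B) ** 2 / d, axis=1)
    t2 = np.sum(w * (N * M2[i] - m * B) ** 2 / d, axis=1)
    out[i] = (N - 1) / N * (t1 / n[:, 0] + t2 / m[:, 0])
    return out


def best_split(
    values: np.ndarray, min_size: int = 1
) -> tuple[int, float] | None:
    """Maximizing split of one segment, or None if it is too short.

    Evaluates every split leaving at least ``min_size`` bins on each side and
    returns ``(split_index, ad)``; ties break to the smallest index for
    determinism.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    v = np.asarray(values)
    if v.size < 2 * min_size:
        return None
    a = ad_all_splits(v, min_size)
    i = int(np.nanargmax(a))
    return i, float(a[i])


def segment_chromosome(
    values: np.ndarray, k_max: int = 15, min_size: int = 1
) -> list[tuple[int, float, int]]:
    """Iterative binary segmentation of one cell's chromosome.

    Maintains a pool of open segments (initially the whole chromosome); each
    iteration accepts the single best split with the globally largest AD,
    records it, and re-pools the two children — so the ``k_max`` breakpoint
    budget is spent on the strongest signals first.  Returns
    ``[(split_index, ad, depth), ...]`` sorted by position; ``split_index``
    is the first bin of the right segment, in within-chromosome coordinates.
    """
    v = np.asarray(values)
    pool: dict[tuple[int, int], tuple[int, float] | None] = {}

    def open_segment(lo: int, hi: int) -> None:
        sub = best_split(v[lo:hi], min_size)
        pool[(lo, hi)] = None if sub is None else (lo + sub[0], sub[1])

    open_segment(0, v.size)
    found: list[tuple[int, float, int]] = []
    for depth in range(k_max):
        cand = [
            (split, ad, lo, hi)
            for (lo, hi), res in pool.items()
            if res is not None
            for split, ad in [res]
        ]
        if not cand:
            break
        # largest AD wins; ties break to the smallest split position
        split, ad, lo, hi = max(cand, key=lambda c: (c[1], -c[0]))
        found.append((split, ad, depth))
        del pool[(lo, hi)]
        open_segment(lo, split)
        open_segment(split, hi)
    return sorted(found)


def segment_matrix(
    values: np.ndarray,
    cell_ids: Sequence[str],
    chrom_labels: np.ndarray,
    k_max: int = 15,
    min_size: int = 1,
) -> pd.DataFrame:
    """Segment every cell of a counts matrix, chromosome by chromosome.

    ``values`` should be GC-corrected counts; they are rounded to the nearest
    integer before scoring, which stabilizes tie handling in the rank-based
    statistic without materially moving the empirical distributions.

    Returns a breakpoint table with columns cell_id, chrom, split_index
    (within-chromosome), ad, depth.
    """
    chrom_labels = np.asarray(chrom_labels)
    counts = np.rint(np.asarray(values)).astype(np.int64)
    chroms = list(dict.fromkeys(chrom_labels))
    spans = {c: np.flatnonzero(chrom_labels == c) for c in chroms}
    rows = []
    for ci, cell in enumerate(cell_ids):
        for chrom in chroms:
            idx = spans[chrom]
            for split, ad, depth in segment_chromosome(
                counts[ci, idx], k_max=k_max, min_size=min_size
            ):
                rows.append((cell, chrom, split, ad, depth))
    return pd.DataFrame(
        rows, columns=["cell_id", "chrom", "split_index", "ad", "depth"]
    )


def prune_breakpoints(breakpoints: pd.DataFrame) -> pd.DataFrame:
    """Flag breakpoints below each cell's genome-wide mean AD.

    The threshold is the mean AD over all of the cell's recorded breakpoints
    across chromosomes, computed before any removal; breakpoints with
    ``ad < threshold`` (strictly) are marked ``kept = False``.  Cells with no
    breakpoints are unaffected.  Adds ``kept`` and ``threshold`` columns.
    """
    bp = breakpoints.copy()
    if len(bp) == 0:
        bp["kept"] = pd.Series(dtype=bool)
        bp["threshold"] = pd.Series(dtype=float)
        return bp
    thr = bp.groupby("cell_id")["ad"].transform("mean")
    bp["kept"] = bp["ad"] >= thr
    bp["threshold"] = thr
    return bp
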