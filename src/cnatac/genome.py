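"""Binned genome model: fixed-width windows, GC content, blacklist filtering.

Everything downstream (counting, segmentation, calling) is indexed against a
:class:`BinSet`: an ordered, non-overlapping tiling of the selected chromosomes
into equally sized windows (default 100 kb).  Windows are equally sized by
construction — trailing partial windows at chromosome ends are dropped, since
the segmentation compares read-count *distributions* across bins and unequal
widths would bias the counts.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinSet",
    "read_chrom_sizes",
    "canonical_chromosomes",
    "make_bins",
    "compute_gc",
    "read_gc_table",
    "apply_blacklist",
    "read_blacklist",
]

_CANONICAL = re.compile(r"^(chr)?([0-9]{1,2}|X)$")


@dataclass
class BinSet:
    """Ordered fixed-width genomic windows.

    Attributes
    ----------
    df : DataFrame with columns ``chrom``, ``start``, ``end`` and optionally
        ``gc`` (fraction of G+C among non-N bases, NaN if unknown).  The row
        order is the genome-wide bin index 0..n-1.
    window_size : width in bp of every bin.
    """

    df: pd.DataFrame
    window_size: int

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    @property
    def chrom_labels(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def gc(self) -> np.ndarray:
        if "gc" not in self.df.columns:
            raise ValueError("BinSet carries no GC content; run compute_gc first")
        return self.df["gc"].to_numpy(dtype=float)

    def chrom_ranges(self) -> dict[str, tuple[int, int]]:
        """Half-open index range of each chromosome in genome-wide bin indices."""
        ranges: dict[str, tuple[int, int]] = {}
        chrom = self.df["chrom"].to_numpy()
        for c in self.chroms:
            idx = np.flatnonzero(chrom == c)
            ranges[c] = (int(idx[0]), int(idx[-1]) + 1)
        return ranges

    def labels(self) -> np.ndarray:
        """Per-bin string identifiers ``chrom:start-end`` (stable across filtering)."""
        d = self.df
        return (
            d["chrom"].astype(str)
            + ":"
            + d["start"].astype(str)
            + "-"
            + d["end"].astype(str)
        ).to_numpy()

    def subset(self, keep: np.ndarray) -> "BinSet":
        """Return a re-indexed BinSet restricted to a boolean/index mask."""
        return BinSet(self.df.loc[keep].reset_index(drop=True), self.window_size)

    def to_bed(self, path: str | Path) -> None:
        """Export as BED4 (chrom, start, end, genome-wide index)."""
        out = self.df[["chrom", "start", "end"]].copy()
        out["index"] = np.arange(len(out))
        out.to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a UCSC-style two-column chrom.sizes file (name <TAB> length)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'name<TAB>length'")
            name, length = parts[0], int(parts[1])
            if name in sizes:
                raise ValueError(f"{path}:{ln}: duplicate chromosome {name!r}")
            if length <= 0:
                raise ValueError(f"{path}:{ln}: non-positive length for {name!r}")
            sizes[name] = length
    return sizes


def canonical_chromosomes(names: Iterable[str]) -> list[str]:
    """Filter to autosomes + X (with or without a ``chr`` prefix).

    Mitochondrial and non-canonical contigs (scaffolds, alts, chrY) carry
    little copy-number signal relative to their artifact load and are excluded
    by default; pass an explicit whitelist to override.
    """
    return [n for n in names if _CANONICAL.match(n)]


def make_bins(
    chrom_sizes: Mapping[str, int],
    window_size: int = 100_000,
    chroms: Sequence[str] | None = None,
) -> BinSet:
    """Tile chromosomes into fixed-width windows.

    Each chromosome contributes ``floor(length / window_size)`` bins of exactly
    ``window_size`` bp; the trailing partial window is dropped.  Bins are sorted
    by (chromosome input order, start) and indexed contiguously genome-wide.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if not chrom_sizes:
        raise ValueError("empty chromosome sizes")
    if chroms is not None:
        missing = [c for c in chroms if c not in chrom_sizes]
        if missing:
            raise KeyError(f"chromosomes not in sizes table: {missing}")
        items = [(c, chrom_sizes[c]) for c in chroms]
    else:
        items = list(chrom_sizes.items())

    rows = []
    for chrom, length in items:
        n = int(length) // window_size
        starts = np.arange(n, dtype=np.int64) * window_size
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": starts + window_size}
            )
        )
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    if len(df) == 0:
        raise ValueError(
            "no bins produced: window_size exceeds every chromosome length"
        )
    return BinSet(df, window_size)


def compute_gc(
    bins: BinSet,
    sequences: Mapping[str, str],
    max_n_frac: float = 0.5,
) -> BinSet:
    """Annotate bins with GC fraction from per-chromosome sequences.

    GC is ``(#G + #C) / (#non-N bases)`` (case-insensitive).  Bins that are
    entirely N get NaN; bins with more than ``max_n_frac`` N bases are dropped
    (their counts are unmappable artifacts) and the survivors re-indexed.

    ``sequences`` may be a plain dict of strings or any mapping with string
    slicing (e.g. a ``pyfaidx.Fasta`` wrapped accessor).
    """
    gcs = np.empty(len(bins))
    n_fracs = np.empty(len(bins))
    for i, row in enumerate(bins.df.itertuples(index=False)):
        if row.chrom not in sequences:
            raise KeyError(f"chromosome {row.chrom!r} absent from sequence set")
        seq = str(sequences[row.chrom][row.start : row.end]).upper()
        n_n = seq.count("N")
        denom = len(seq) - n_n
        gcs[i] = (seq.count("G") + seq.count("C")) / denom if denom > 0 else np.nan
        n_fracs[i] = n_n / len(seq) if len(seq) else 1.0
    df = bins.df.copy()
    df["gc"] = gcs
    keep = (n_fracs <= max_n_frac) & ~np.isnan(gcs)
    return BinSet(df.loc[keep], bins.window_size)


def read_gc_table(bins: BinSet, path: str | Path) -> BinSet:
    """Attach precomputed per-bin GC content from a TSV (chrom, start, end, gc).

    An alternative to a genome FASTA: every bin must be covered by the table.
    """
    tab = pd.read_csv(
        path, sep="\t", comment="#", names=["chrom", "start", "end", "gc"], header=None
    )
    key = tab["chrom"].astype(str) + ":" + tab["start"].astype(str)
    lut = dict(zip(key, tab["gc"]))
    df = bins.df.copy()
    bin_key = df["chrom"].astype(str) + ":" + df["start"].astype(str)
    gc = bin_key.map(lut)
    if gc.isna().any():
        missing = df.loc[gc.isna(), "chrom"].iloc[0]
        raise KeyError(f"GC table does not cover all bins (e.g. on {missing})")
    df["gc"] = gc.to_numpy(dtype=float)
    return BinSet(df, bins.window_size)


def read_blacklist(path: str | Path) -> pd.DataFrame:
    """Read a BED3 blacklist into a (chrom, start, end) frame."""
    bl = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )
    return bl


def apply_blacklist(
    bins: BinSet, blacklist: pd.DataFrame | Iterable[tuple[str, int, int]]
) -> BinSet:
    """Drop bins overlapping any blacklist interval by >= 1 bp.

    Intervals are 0-based half-open; an interval abutting a bin boundary does
    not remove it.  Idempotent; an empty blacklist is the identity.
    """
    if not isinstance(blacklist, pd.DataFrame):
        blacklist = pd.DataFrame(
            list(blacklist), columns=["chrom", "start", "end"]
        )
    if len(blacklist) == 0:
        return BinSet(bins.df.copy(), bins.window_size)
    if (blacklist["end"] <= blacklist["start"]).any():
        bad = blacklist[blacklist["end"] <= blacklist["start"]].iloc[0]
        raise ValueError(
            f"malformed blacklist interval {bad.chrom}:{bad.start}-{bad.end}"
        )
    keep = np.ones(len(bins), dtype=bool)
    starts = bins.df["start"].to_numpy()
    ends = bins.df["end"].to_numpy()
    chroms = bins.df["chrom"].to_numpy()
    for chrom, grp in blacklist.groupby("chrom", sort=False):
        sel = chroms == chrom
        if not sel.any():
            continue
        s, e = starts[sel], ends[sel]
        hit = np.zeros(sel.sum(), dtype=bool)
        for bs, be in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
            hit |= (s < be) & (bs < e)
        keep[np.flatnonzero(sel)[hit]] = False
    return bins.subset(keep)
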