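"""End-to-end orchestration: fragments file to karyotype tables.

The fixed processing order is: binning -> blacklist removal -> fragment
counting -> cell filter -> zero-bin filter -> GC correction -> segmentation
and state calling -> (optional) clone clustering.  All outputs are plain TSV
with stable ordering and formatting, so identical inputs and seeds produce
byte-identical files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import counts as cts
from . import genome as gm
from .calling import CNACaller, Karyotype
from .clustering import cluster_karyotypes, plot_karyogram
from .counts import CountMatrix

__all__ = ["CNAResult", "call_cnas", "run", "write_results"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class CNAResult:
    raw: CountMatrix
    corrected: CountMatrix
    karyotype: Karyotype
    segments: pd.DataFrame
    breakpoints: pd.DataFrame
    clones: pd.DataFrame | None = None


def call_cnas(
    m: CountMatrix,
    min_frags: int = 20_000,
    zero_frac: float = 0.85,
    loess_span: float = 0.75,
    k_max: int = 15,
    min_size: int = 1,
    trim: float = 0.1,
    z_band: float = 1.0,
    n_clusters: int | None = None,
) -> CNAResult:
    """Run the caller on a raw binned count matrix.

    GC correction is applied when the bin set carries GC annotations and is
    skipped (with a warning) otherwise.
    """
    m = cts.filter_cells(m, min_frags)
    m = cts.filter_zero_bins(m, zero_frac)
    if "gc" in m.bins.df.columns and not np.isnan(m.bins.gc).all():
        corrected = cts.gc_correct(m, loess_span)
    else:
        warnings.warn("bins carry no GC content; skipping GC correction")
        corrected = CountMatrix(
            m.values.astype(float), m.cell_ids, m.bins, corrected=True,
            meta=dict(m.meta),
        )

    caller = CNACaller(
        k_max=k_max, min_size=min_size, trim=trim, z_band=z_band
    )
    caller.fit(
        corrected.values,
        chrom=corrected.bins.chrom_labels,
        cell_ids=corrected.cell_ids,
        bin_ids=corrected.bins.labels(),
    )
    karyo = Karyotype(caller.karyotype_, caller.cell_ids_, caller.bin_ids_)
    clones = (
        cluster_karyotypes(karyo, n_clusters) if n_clusters is not None else None
    )
    return CNAResult(
        raw=m,
        corrected=corrected,
        karyotype=karyo,
        segments=caller.segments_,
        breakpoints=caller.breakpoints_,
        clones=clones,
    )


def run(
    fragments: str | Path,
    chrom_sizes: str | Path,
    fasta: str | Path | None = None,
    gc_table: str | Path | None = None,
    blacklist: str | Path | None = None,
    window_size: int = 100_000,
    canonical_only: bool = True,
    min_frags: int = 20_000,
    zero_frac: float = 0.85,
    loess_span: float = 0.75,
    k_max: int = 15,
    min_size: int = 1,
    trim: float = 0.1,
    z_band: float = 1.0,
    n_clusters: int | None = None,
    outdir: str | Path | None = None,
) -> CNAResult:
    """File-level entry point used by the command-line interface."""
    sizes = gm.read_chrom_sizes(chrom_sizes)
    chroms = gm.canonical_chromosomes(sizes) if canonical_only else None
    if canonical_only and not chroms:
        chroms = None  # fall back to every contig in the sizes table
    bins = gm.make_bins(sizes, window_size, chroms=chroms)
    if fasta is not None:
        from pyfaidx import Fasta

        bins = gm.compute_gc(bins, Fasta(str(fasta)))
    elif gc_table is not None:
        bins = gm.read_gc_table(bins, gc_table)
    if blacklist is not None:
        bins = gm.apply_blacklist(bins, gm.read_blacklist(blacklist))

    m = cts.count_fragments(cts.read_fragments(fragments), bins)
    res = call_cnas(
        m,
        min_frags=min_frags,
        zero_frac=zero_frac,
        loess_span=loess_span,
        k_max=k_max,
        min_size=min_size,
        trim=trim,
        z_band=z_band,
        n_clusters=n_clusters,
    )
    if outdir is not None:
        write_results(res, outdir)
    return res


def _breakpoint_table(res: CNAResult) -> pd.DataFrame:
    """Breakpoints with genome coordinates (start of the right segment's bin)."""
    bp = res.breakpoints.copy()
    bins = res.corrected.bins
    ranges = bins.chrom_ranges()
    starts = bins.df["start"].to_numpy()
    coord = [
        int(starts[ranges[row.chrom][0] + row.split_index])
        for row in bp.itertuples(index=False)
    ]
    bp.insert(3, "coord", coord)
    return bp


def write_results(res: CNAResult, outdir: str | Path) -> None:
    """Write karyotype, segment, breakpoint (and clone) TSVs.

    The karyotype table has one row per cell and one column per bin
    (header ``chrom:start-end``) with values 0 (loss), 1 (normal), 2 (gain).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    karyo = res.karyotype.to_frame()
    karyo.index.name = "cell_id"
    karyo.to_csv(outdir / "karyotype.tsv", sep="\t", lineterminator="\n")
    res.segments.to_csv(
        outdir / "segments.tsv",
        sep="\t",
        index=False,
        float_format=_FLOAT_FMT,
        lineterminator="\n",
    )
    _breakpoint_table(res).to_csv(
        outdir / "breakpoints.tsv",
        sep="\t",
        index=False,
        float_format=_FLOAT_FMT,
        lineterminator="\n",
    )
    if res.clones is not None:
        res.clones.to_csv(
            outdir / "clones.tsv", sep="\t", index=False, lineterminator="\n"
        )
        plot_karyogram(
            res.karyotype,
            outdir / "karyogram.png",
            chrom_labels=res.corrected.bins.chrom_labels,
            clones=res.clones,
        )
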