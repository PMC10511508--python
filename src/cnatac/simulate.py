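"""Synthetic scATAC-seq data with known clonal copy-number structure.

The generator emulates the features of real fragment data that the caller
relies on: per-cell fragment counts over fixed-width bins, cell-to-cell depth
variation, a smooth multiplicative GC bias, and clone-structured segments of
copy state 1/2/3 on a diploid baseline.  Cell ``c`` in clone ``g`` draws

    count[c, t] ~ Poisson(d_c * lambda_base * copy(g, t)/2 * bias(gc_t)),

with log-normal depth factors ``d_c`` and a unimodal quadratic GC bias.  It
does not attempt read-level realism (no Tn5 insertion-site model, no peak
structure, no chromatin confounding of copy number) — see docs/methods.md for
what that implies about test coverage.

All randomness flows from ``SimConfig.seed``; the same seed reproduces the
same matrices, fragments file and truth tables byte for byte.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import Karyotype
from .counts import CountMatrix
from .genome import BinSet, make_bins

__all__ = [
    "CloneSpec",
    "SimConfig",
    "default_clones",
    "simulate_counts",
    "write_fragments",
    "write_gc_table",
    "write_chrom_sizes",
    "downsample_counts",
]


@dataclass(frozen=True)
class CloneSpec:
    """A clone and its copy-number events on a diploid baseline.

    ``events`` are ``(chrom, start_bin, end_bin, copy_state)`` with half-open
    within-chromosome bin ranges and copy_state in {1, 2, 3} (1 = monosomy,
    3 = trisomy); unlisted regions are diploid (state 2).
    """

    label: str
    proportion: float
    events: tuple[tuple[str, int, int, int], ...] = ()


@dataclass
class SimConfig:
    """Study conditions of the synthetic reference dataset.

    Defaults give 200 cells over two 50-Mb chromosomes binned at 100 kb
    (500 bins each), a mean of 10 fragments per bin per diploid copy pair,
    ~30% log-normal depth dispersion across cells, and a mild unimodal GC
    bias peaking at GC 0.45.
    """

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 50_000_000, "chr2": 50_000_000}
    )
    window_size: int = 100_000
    n_cells: int = 200
    lambda_base: float = 10.0
    depth_sigma: float = 0.3
    gc_center: float = 0.45
    gc_curvature: float = 6.0
    gc_range: tuple[float, float] = (0.3, 0.6)
    seed: int = 0


def default_clones() -> list[CloneSpec]:
    """Two-clone reference structure: gains and losses of 100 bins each.

    Both clones carry one gain and one loss so the cohort stays close to
    diploid on average, as in a tumor with balanced subclonal events.
    """
    return [
        CloneSpec(
            "cloneA",
            0.55,
            (("chr1", 100, 200, 3), ("chr2", 300, 400, 1)),
        ),
        CloneSpec(
            "cloneB",
            0.45,
            (("chr1", 350, 450, 1), ("chr2", 50, 150, 3)),
        ),
    ]


def _gc_bias(gc: np.ndarray, cfg: SimConfig) -> np.ndarray:
    bias = 1.0 + cfg.gc_curvature * (
        0.25 * (cfg.gc_range[1] - cfg.gc_range[0]) ** 2
        - (gc - cfg.gc_center) ** 2
    )
    return np.clip(bias, 0.1, None)


def simulate_counts(
    cfg: SimConfig, clones: list[CloneSpec] | None = None
) -> tuple[CountMatrix, Karyotype, pd.DataFrame]:
    """Draw a raw count matrix with known truth.

    Returns the raw cells x bins counts (bins annotated with the simulated GC
    content), the truth karyotype (copy_state - 1 in {0,1,2}) and a
    (cell_id, clone) table.
    """
    if clones is None:
        clones = default_clones()
    total = sum(c.proportion for c in clones)
    if not np.isclose(total, 1.0):
        raise ValueError(f"clone proportions sum to {total}, expected 1")
    rng = np.random.default_rng(cfg.seed)

    bins = make_bins(cfg.chrom_sizes, cfg.window_size)
    gc = rng.uniform(*cfg.gc_range, size=len(bins))
    df = bins.df.copy()
    df["gc"] = gc
    bins = BinSet(df, cfg.window_size)

    ranges = bins.chrom_ranges()
    copy_by_clone = {}
    for clone in clones:
        copy = np.full(len(bins), 2, dtype=np.int8)
        for chrom, s, e, state in clone.events:
            if chrom not in ranges:
                raise KeyError(f"clone event on unbinned chromosome {chrom!r}")
            lo, hi = ranges[chrom]
            if not (0 <= s < e <= hi - lo):
                raise ValueError(f"event [{s},{e}) outside {chrom} bins")
            if state not in (1, 2, 3):
                raise ValueError("copy_state must be 1, 2 or 3")
            copy[lo + s : lo + e] = state
        copy_by_clone[clone.label] = copy

    # deterministic clone sizes: largest-remainder apportionment
    raw_sizes = np.array([c.proportion * cfg.n_cells for c in clones])
    sizes = np.floor(raw_sizes).astype(int)
    for i in np.argsort(-(raw_sizes - sizes))[: cfg.n_cells - sizes.sum()]:
        sizes[i] += 1
    clone_of_cell = np.repeat([c.label for c in clones], sizes)

    depth = rng.lognormal(mean=0.0, sigma=cfg.depth_sigma, size=cfg.n_cells)
    bias = _gc_bias(gc, cfg)
    values = np.empty((cfg.n_cells, len(bins)), dtype=np.int64)
    truth = np.empty((cfg.n_cells, len(bins)), dtype=np.int8)
    for i in range(cfg.n_cells):
        copy = copy_by_clone[clone_of_cell[i]]
        lam = depth[i] * cfg.lambda_base * (copy / 2.0) * bias
        values[i] = rng.poisson(lam)
        truth[i] = copy - 1

    cell_ids = np.array([f"cell{i:04d}" for i in range(cfg.n_cells)], dtype=object)
    counts = CountMatrix(values, cell_ids, bins, meta={"depth": depth})
    karyo = Karyotype(truth, cell_ids, bins.labels())
    clone_table = pd.DataFrame({"cell_id": list(cell_ids), "clone": clone_of_cell})
    return counts, karyo, clone_table


def write_fragments(
    counts: CountMatrix, path: str | Path, seed: int = 0, frag_len: int = 100
) -> None:
    """Emit a fragments TSV realizing the count matrix exactly.

    For each (cell, bin) count c, writes c fragment records whose midpoints
    fall inside the bin, so counting the file back with the same bin set
    recovers the matrix.  Records are position-sorted as in 10x fragment
    files; ``.gz`` paths are gzip-compressed.
    """
    if counts.corrected:
        raise ValueError("fragments can only be realized from raw counts")
    rng = np.random.default_rng(seed)
    half = frag_len // 2
    rows = []
    starts = counts.bins.df["start"].to_numpy()
    ends = counts.bins.df["end"].to_numpy()
    chroms = counts.bins.df["chrom"].to_numpy()
    for ci, cell in enumerate(counts.cell_ids):
        row = counts.values[ci]
        for bi in np.flatnonzero(row):
            c = int(row[bi])
            mids = rng.integers(starts[bi] + half, ends[bi] - half, size=c)
            for mid in mids:
                rows.append((chroms[bi], int(mid - half), int(mid + half), cell, 1))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def write_gc_table(bins: BinSet, path: str | Path) -> None:
    """Write the per-bin GC table (chrom, start, end, gc) used by the pipeline."""
    out = bins.df[["chrom", "start", "end", "gc"]].copy()
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6f")


def write_chrom_sizes(cfg: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in cfg.chrom_sizes.items():
            fh.write(f"{name}\t{length}\n")


def downsample_counts(m: CountMatrix, rate: float, seed: int = 0) -> CountMatrix:
    """Binomially thin every count to emulate reduced sequencing depth.

    Each count is replaced by a Binomial(count, rate) draw, so expected
    coverage scales by ``rate`` exactly as subsampling raw reads would.
    """
    if not 0 < rate <= 1:
        raise ValueError("rate must be in (0, 1]")
    if m.corrected:
        raise ValueError("downsampling applies to raw counts")
    if rate == 1:
        return CountMatrix(
            m.values.copy(), m.cell_ids, m.bins, corrected=False, meta=dict(m.meta)
        )
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(m.values, rate)
    return CountMatrix(thinned, m.cell_ids, m.bins, corrected=False, meta=dict(m.meta))
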