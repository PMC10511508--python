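# Methods

## Model and assumptions

`cnatac` treats the per-bin scATAC-seq fragment count of a cell as a noisy
proxy of local DNA copy number. The implicit model is that within a region of
constant copy number the counts of one cell are exchangeable draws from a
single distribution, and that a copy-number change shifts that whole
distribution (not merely its mean). This motivates a nonparametric
distribution-distance test rather than a mean-shift statistic: candidate
breakpoints are scored with the two-sample Anderson–Darling (AD) statistic,
which integrates the squared EDF difference weighted by 1/(H(1−H)) and is
therefore sensitive in the distribution tails where gains and losses
separate first.

Consequences of the model worth keeping in mind:

- Calls are *relative to the cell's own genome-wide mean coverage*. A
  whole-genome duplication or deletion rescales every bin equally and is
  invisible; depth differences between cells are likewise invisible
  (state calls are scale-invariant, which the tests assert).
- Accessibility confounds copy number at fine scales. The default 100-kb
  windows average over peaks so that copy number dominates, but strong
  chromatin-state differences can still masquerade as CNAs in real data.
- Only three states are distinguished. Sparse single-cell counts do not
  support integer copy numbers beyond "gain"; amplifications above trisomy
  collapse onto the gain state.

## The AD statistic with ties

Binned counts are small integers, so ties are the norm and the textbook
continuous-data form of the two-sample AD statistic is biased. The
implementation uses the midrank discrete form (the two-sample case of the
Scholz–Stephens k-sample statistic): with pooled distinct values j of
multiplicity l_j, midrank pooled cumulative B_j and midrank per-sample
cumulative M_ij,

    A² = (N−1)/N · Σ_i (1/n_i) Σ_j (l_j/N) (N·M_ij − n_i·B_j)² /
                                   (B_j(N−B_j) − N·l_j/4),

skipping degenerate pooled points where the denominator vanishes (pooled EDF
at 0 or 1). A² is exactly zero iff the two sides are identical multisets,
and is invariant under within-side permutation and common shifts. On
all-distinct data this form agrees with the continuous discrete sum only up
to O(1/N); the test suite pins the implementation to an independent
brute-force enumeration of the midrank form at 1e−10 and checks approximate
agreement with the continuous form.

For one segment, the pooled value table is shared by every candidate split,
so all splits are scored in a single vectorized O(L·D) pass (L bins, D
distinct values); `ad_distance` on explicit vectors and the vectorized
all-splits path are cross-checked against each other.

Segmentation input is the GC-corrected counts rounded to the nearest
integer: the EDF statistic tolerates reals, but integer rounding keeps the
tie structure stable across platforms.

## Segmentation and pruning

Iterative binary segmentation maintains a pool of open segments per
chromosome, accepts the split with the globally largest A² (ties break to
the smallest index), and stops after `k_max` = 15 breakpoints per chromosome
or when no segment is splittable (`min_size` = 1 bin per side, so single-bin
events remain callable). Greedy global acceptance spends the budget on the
strongest signals first, which matters because pruning is rank-free: after
all chromosomes of a cell are segmented, breakpoints with A² below the
cell's genome-wide mean breakpoint A² are discarded. With a handful of true
events among ~30 recorded breakpoints, the true events' large A² values pull
the mean far above the noise floor, so spurious splits are removed almost
surely while true ones survive. The pruning mean is per cell (cells are
segmented independently); a cohort-wide mean would couple unrelated cells.

A caveat the tests document: for an up-then-down "bump", the *first* split's
AD optimum is flat and its position can land several bins inside the bump;
the refinement splits of its children then localize both edges, so recovery
is asserted on the pruned breakpoint set, not the first split alone.

## State assignment

Segment coverage is summarized by the 10%-trimmed mean (drop
floor(0.1·n) bins from each end; plain mean when trimming would empty the
segment), and referenced to the genome-wide trimmed mean of the same cell
computed with the same trim — on a mostly diploid genome the genome-wide
trim also conveniently sheds the most extreme CNA bins. Segments whose
trimmed mean has |z| ≤ 1 among the cell's segment means (population SD;
z ≡ 0 when the SD is 0) are collapsed onto the genome mean before any fold
change is computed, absorbing baseline wobble.

Each remaining segment receives an integer copy number on the diploid
baseline, c = round(2·m_s/m_g), rounding half away from zero, with loss
c ≤ 1, normal c = 2, gain c ≥ 3. Rounding *twice* the fold change is a
deliberate design choice: the true monosomy/disomy/trisomy levels sit at
fold changes 0.5/1/1.5, so rounding the fold change itself would place the
decision thresholds exactly on the true CNA levels and make every true event
a coin flip under count noise. On the 2x scale the thresholds fall at fold
changes 0.75 and 1.25, midway between states, giving the noise margin that
the false-positive and recovery properties in the test suite rely on.

## GC correction

Per cell, counts are regressed on bin GC with LOESS (statsmodels lowess,
locally linear, span 0.75, no robustness iterations, interpolated between
fitted points) and rescaled by mean(x)/fit(gc_t). Fitted values are floored
at a small positive epsilon and factors clipped to [0.2, 5] so sparse GC
extremes cannot blow up single bins; the rescaling is mean-preserving up to
fit error (asserted within 5%). Cells facing fewer than 10 distinct GC
values are passed through with a warning. Correction is per cell, consistent
with per-cell segmentation, since GC bias strength varies between cells
(library-specific amplification).

## Synthetic data

The generator draws cell c of clone g as

    count[c,t] ~ Poisson(d_c · λ · copy(g,t)/2 · bias(gc_t)),

with d_c ~ LogNormal(0, 0.3), λ = 10 fragments per bin (diploid), bin GC ~
U(0.3, 0.6) and a unimodal quadratic multiplicative bias peaking at GC 0.45.
The reference cohort is 200 cells on two 50-Mb chromosomes at 100-kb bins
(500 bins each) with two clones (55%/45%), each carrying one 100-bin gain
and one 100-bin loss, so the cohort stays near-diploid on average. A
fragments writer realizes any count matrix as a position-sorted fragments
TSV whose midpoints land in the generating bins, so counting the file back
recovers the matrix exactly; binomial thinning emulates reduced sequencing
depth.

What the generator does *not* emulate — peak structure, Tn5 insertion
preferences, accessibility differences between cell states, doublets,
barcode errors — bounds what green tests mean: they demonstrate the
statistical machinery recovers copy number from count data with realistic
sparsity, depth variation and GC bias, not that chromatin-driven confounding
in a particular tissue is handled. The cell-filter threshold for synthetic
runs (2000 fragments) is a pipeline argument, chosen because reference cells
carry ~10k fragments; the default of 20,000 reflects typical real datasets
with ~30k bins genome-wide.

## Numerical and interface choices

- Coordinates are 0-based half-open everywhere; fragments are assigned to
  the bin containing their midpoint, once per record (duplicate-count
  weighting is available behind a flag).
- Trailing partial windows are dropped at binning so all bins have equal
  width; bins with >50% N bases are dropped with the GC annotation.
- The filter order is fixed: blacklist → cell filter → zero-bin filter
  (strictly more than 85% zeros) → GC correction.
- Ward clustering runs on the raw {0,1,2} codes; clone labels are
  renumbered by first appearance so output is deterministic given input
  order, and flat cuts only (nested sub-clones are read off the dendrogram
  manually).
- Pseudo-bulk profiles use the {1,2,3} scale (mean of state+1). The MSE
  between profiles defaults to the conventional 1/N normalization; a 1/N²
  variant used in parts of the literature is available via `paper_form`.
  Profile standardization is conventional (mean 0, SD 1). Precision/recall
  ratios that are 0/0 are reported as 0 and flagged undefined.
- All randomness flows through explicit integer seeds (numpy Generator);
  identical seeds and inputs give byte-identical TSV outputs.

## Problem sizes

Test and acceptance runs use the reference cohort (200 cells × 1000 bins),
100-cell euploid panels and 100-seed step-signal batches — sizes at which
every reported property is stable across seeds while the whole suite runs in
well under a minute per study.

## Known limitations

- Whole-genome ploidy shifts and copy numbers beyond the 3 states are out of
  scope by construction.
- Breakpoint positions are bin-resolution (100 kb by default); no sub-bin
  refinement is attempted.
- The per-cell pruning rule assumes fewer true breakpoints than `k_max` per
  chromosome; genomes more fragmented than that need a larger `k_max`.
- No mappability-track correction: low-mappability regions are handled only
  via the blacklist and the zero-bin filter.
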