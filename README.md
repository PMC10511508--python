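# cnatac

Single-cell copy-number alteration (CNA) calling from scATAC-seq fragment
counts.

scATAC-seq measures chromatin accessibility by sequencing the DNA of each
cell, so the number of fragments mapping to a large genomic window tracks the
number of DNA copies of that window — a monosomic region yields roughly half
the fragments of a disomic one, a trisomic region roughly 1.5x. `cnatac`
exploits this to infer a three-state karyotype (loss / normal / gain) for
every cell in a scATAC-seq experiment, without a matched euploid reference or
any additional data modality. It is aimed at anyone studying aneuploidy and
intratumor clonal heterogeneity who has scATAC-seq (or multi-ome) data in
hand: the output is a cells x bins state matrix, per-cell breakpoint and
segment tables, and karyotype clone clusters.

## Method

1. **Binning and filtering.** The genome is tiled into fixed windows
   (default 100 kb), blacklisted regions are removed, fragments are counted
   per cell per bin (midpoint assignment), low-coverage cells are dropped,
   and bins with zero counts in more than 85% of cells are discarded.
2. **GC correction.** Per cell, counts x_t are rescaled by a LOESS fit
   against bin GC content: x_t^GC = x_t * mean(x) / loess(x ~ GC)_t.
3. **Segmentation.** Per cell and chromosome, change points are found by
   iterative binary segmentation on the two-sample Anderson–Darling
   statistic

   A²_nm = (nm/N) ∫ {F_n(x) − G_m(x)}² / (H_N(x)[1 − H_N(x)]) dH_N(x),

   where F_n and G_m are the empirical distribution functions of the counts
   left and right of a candidate split and H_N is the pooled EDF; ties are
   handled with the midrank (Scholz–Stephens) discrete form. The split with
   the largest A² anywhere on the chromosome is accepted, its segment is
   divided, and the procedure repeats until 15 breakpoints per chromosome
   (default) are recorded. Breakpoints with A² below the cell's genome-wide
   mean breakpoint A² are pruned.
4. **State assignment.** Each segment's 10%-trimmed mean count m_s is
   compared with the cell's genome-wide trimmed mean m_g. Segments whose m_s
   has a z-score in [−1, 1] among the cell's segments are collapsed to m_g;
   each segment then receives an integer copy number
   c = round(2·m_s / m_g) and the state loss (c ≤ 1), normal (c = 2) or
   gain (c ≥ 3).
5. **Clones.** Cells are clustered on the Euclidean distance between their
   {0,1,2} state profiles with Ward linkage, and plotted as a karyogram
   heatmap (rows = cells, columns = genome).

A synthetic-data generator with clone-structured gains/losses, log-normal
depth variation and a multiplicative GC bias, plus pseudo-bulk concordance
metrics (mean copy number per bin on the {1,2,3} scale, MSE, per-state
precision/recall/F1, downsampling retention), make the whole pipeline
testable end to end with known ground truth.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score

from cnatac import SimConfig, simulate_counts, call_cnas, prf1
from cnatac.clustering import KaryotypeClusterer

# 200 cells, two 50-Mb chromosomes at 100-kb bins, two clones with
# 100-bin (10-Mb) gains and losses, ~10 fragments per bin per cell
counts, truth, clones = simulate_counts(SimConfig(seed=1))
result = call_cnas(counts, min_frags=2000, n_clusters=2)

aligned = truth.to_frame().loc[
    list(result.karyotype.cell_ids), list(result.karyotype.bin_ids)
].to_numpy()
print(prf1(result.karyotype.states, aligned)[["precision", "recall", "f1"]])

labels = KaryotypeClusterer(2).fit(result.karyotype.states).labels_
truth_labels = clones.set_index("cell_id").loc[
    list(result.karyotype.cell_ids), "clone"
]
print("ARI:", adjusted_rand_score(truth_labels, labels))
```

prints

```
        precision    recall        f1
state
loss     0.984260  0.994250  0.989230
normal   0.997935  0.993575  0.995750
gain     0.965359  0.989300  0.977183
ARI: 1.0
```

i.e. per-bin recovery of the simulated monosomies/trisomies with F1 ≥ 0.98
for every state, and perfect recovery of the two clones. The same pipeline
is available from the shell:

```sh
cnatac simulate --n-cells 200 --seed 1 --outdir sim/
cnatac run --fragments sim/fragments.tsv.gz --chrom-sizes sim/chrom.sizes \
           --gc-table sim/gc.tsv --min-frags 2000 --n-clusters 2 --outdir out/
```

which writes `karyotype.tsv` (cells x bins states), `segments.tsv`,
`breakpoints.tsv`, `clones.tsv` and a karyogram heatmap.

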