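# cellici — Index of Cell Identity

`cellici` assigns cell-type identity to single-cell expression profiles by
scoring them against marker genes learned from a labeled reference
compendium of tissue or cell-type expression profiles. Single-cell profiles
are noisy in two characteristic ways: any given marker of the cell's true
type may be absent (dropout), and markers of *other* types may show
low-level sporadic ("ectopic") expression. Diagnosing identity from one or
two canonical markers therefore fails routinely. `cellici` instead lets a
large, information-ranked marker ensemble vote, weighting each marker by how
much information it carries about its cell type.

It is aimed at anyone with (a) a reference matrix of expression profiles
with known tissue/cell-type labels (sorted bulk profiles, microarray
compendia, tumor-subtype compendia) and (b) single-cell count or FPM
matrices to classify — including cells suspected of mixed or intermediate
identity, such as doublets, regenerating or transdifferentiating cells.

## The method

**Spec scores.** For each gene g the reference values are split into a
*low* (background) and *high* (expressed) state by a per-gene cutoff. The
cutoff is found empirically: the gene's M values are binned into l = 10
equal-width bins; with null expectation e = M/l per bin, the first bin whose
occupancy falls below e marks the end of the abundant background mass.
Genes whose transition bin lies above u (default 3) show too little
separation and are dropped; the precise cutoff is the value in the
preceding bin that maximizes the Spec score. With q_t(b) the fraction of
tissue t's samples in state b, p(t|b) ∝ q_t(b), and the per-state
information I(b) = 1 + Σ_t p(t|b) ln p(t|b) / ln N,

    Spec_{g,t} = q_t(high)·I(high) − q_t(low)·I(low)  ∈ [−1, 1],

negative (absence-marker) scores clipped to 0.

**Marker sets.** Per tissue, genes are ranked by decreasing Spec (ties by
mean expression above the cutoff) and accumulated while the running Spec sum
stays below a *cumulative information threshold* (default 20, minimum Spec
0.15) — so every tissue gets the same diagnostic information, with more
distinct tissues needing fewer markers.

**ICI.** For a cell with FPM expression e_g and a tissue with n_t markers,

    ICI_t = (Σ_g e_g · s_{g,t} / n_t) · (Σ_g 1[e_g > 0] / n_t),

the Spec-weighted mean marker expression times the fraction of markers
detected. Significance per tissue comes from 1,000 permutations drawing
equally sized random gene sets from the scored gene universe (p-value with
the add-one estimator). ICIs are normalized to sum 1 per cell; exactly one
significant tissue at α = 0.05 → *single* identity, several → *mixed*
(chimeric) at the normalized proportions, none → *unclassified*.

**Threshold diagnostics.** Scanning the threshold over 5–100 exposes the
robustness/power tradeoff: *ICI variability* (Euclidean distance between a
cell's ICI vectors at consecutive thresholds) should be stable and minimal
while *ICI signal* (mean maximal ICI) stays high.

## Worked example

```python
from cellici import (SynthConfig, make_reference, make_cell, build_spec_table,
                     select_markers, score_cell)

cfg = SynthConfig(n_tissues=3, n_noise_genes=500, seed=42)
ref, truth = make_reference(cfg)          # 3 tissues x 4 replicates
table = build_spec_table(ref)             # l=10 bins, u=3
markers = select_markers(table, threshold=20.0, min_spec=0.15)
for t in markers.tissues:
    print(t, markers.n_markers(t), "markers, top:", markers.per_tissue[t][0])

cell, _ = make_cell(cfg, "T1", cell_index=0)
report = score_cell(cell, markers, universe=list(table.eligible), seed=7)
print("call:", report.call, report.call_tissues)
for t in report.tissues:
    print(f"{t}: ICI={report.norm_ici[t]:.4f}  p={report.p_value[t]:.4g}")
```

prints

```
T0 16 markers, top: ('MK_T0_5', 1.0)
T1 12 markers, top: ('MK_T1_0', 1.0)
T2 15 markers, top: ('MK_T2_8', 1.0)
call: single ('T1',)
T0: ICI=0.0021  p=1
T1: ICI=0.9955  p=0.000999
T2: ICI=0.0023  p=1
```

Each tissue ends up with 12–16 markers carrying 20 cumulative Spec units of
information (planted markers all reach Spec 1.0). The queried cell, which
was simulated from tissue T1 with 30% marker dropout, is called *single*
T1: its normalized ICI concentrates 99.6% of identity weight there and no
random marker set of equal size beat the observed score in 1,000
permutations (p = 1/1001 ≈ 0.001); the other tissues score at background
level (p = 1).

The same pipeline is available from the shell:

```sh
cellici simulate --out-prefix sim --seed 9
cellici spec --matrix sim.reference.tsv --labels sim.labels.tsv --out spec.tsv
cellici markers --spec-table spec.tsv --threshold 20 --out markers.tsv
cellici ici --cells sim.cells.tsv --counts-to-fpm --markers markers.tsv \
        --spec-table spec.tsv --seed 4 --out report.tsv
cellici optimize --cells sim.cells.tsv --counts-to-fpm --spec-table spec.tsv \
        --out scan.tsv --summary summary.tsv
```

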