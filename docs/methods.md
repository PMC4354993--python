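# Methods

## Model and procedure

The package treats cell-type identity as a supervised scoring problem: a
labeled reference compendium (genes × samples, N tissues, M samples total)
fixes, once, which genes are informative for which tissue and how much; each
query cell is then diagnosed independently against that stable reference.
The assumptions are minimal but worth stating:

- reference expression is non-negative and on a common within-gene scale
  (each gene is binned over its own range, so genes need not be comparable
  to each other, and a positive rescaling of a single gene changes nothing);
- query cells arrive as FPM (or raw counts converted per million), with
  gene identifiers matching the reference exactly;
- each reference sample carries exactly one tissue label; mixtures live in
  the query, not the reference.

### Background cutoffs and Spec scores

A gene's expression is binarized by a per-gene cutoff into background (low)
and true expression (high). Because M is typically far too small to fit a
mixture model per gene, the cutoff region is found by the occupancy
heuristic: l = 10 equal-width bins over the gene's own [min, max]; null
expectation e = M/l per bin; the transition bin m is the **smallest** bin
index with occupancy below e. The wording "highest bin satisfying o_m < e"
combined with an upper limit u on m is internally inconsistent (the topmost
sparse bin would nearly always be the last); we read the rule as the first
sub-expected bin — the end of the abundant background mass — and keep the
literal topmost-sparse-bin reading selectable (`rule="highest"`). Genes
with m > u (default u = 3; tumor-style compendia with weaker separation
warrant u = 10), constant genes, and genes with no sub-expected bin are
rejected. The precise cutoff is chosen among the distinct observed values
in bin m−1 (plus that bin's lower edge; the range minimum when m = 1) to
maximize the gene's maximum per-tissue Spec, ties resolved toward the
smallest cutoff (most inclusive high state).

The two-state Spec score uses per-tissue occupancy *fractions* q_t(b)
renormalized across tissues, not raw sample counts, so tissues with unequal
replicate numbers weigh equally. Binarization is strict (high iff value >
cutoff), matching the strict `expression > 0` convention used for cells.
The logarithm base cancels against the 1/ln N normalization; natural log is
used. Negative scores designate absence markers and are clipped to zero
since the identity index uses presence only; the signed values stay
available (`clip=False`).

Gene-level filters applied before scoring: a caller-supplied exclusion list
(e.g. genes induced by the cell-dissociation protocol that produced the
query cells) and a constitutive-expression filter dropping genes whose
across-sample median exceeds 250 (strict inequality; the default suits
microarray-intensity scales and should be rescaled for other platforms).

### Marker selection

Per tissue, genes with Spec ≥ 0.15 are ranked by decreasing Spec, ties by
decreasing mean expression in the samples above the gene's cutoff
("mean over background" — the mean of above-cutoff values, not the mean
excess), final tie by gene id for reproducibility. A gene is included
while the cumulative Spec sum *before* adding it is strictly below the
threshold (default 20). This boundary convention guarantees every tissue
with any admissible marker receives at least one, and makes the marker
count non-decreasing in the threshold. Genes may serve several tissues with
tissue-specific weights.

### Identity index and significance

ICI_t = (Σ e_g s_{g,t} / n_t) · (Σ 1[e_g > 0] / n_t). The second factor
down-weights identities supported by few detected markers, which is what
buffers sporadic ectopic expression. Markers absent from a cell's table
count as zero (absence is evidence, not an error); `strict_genes` turns
this into an error for pipelines where silent mismatches must not pass.

The permutation null redraws *gene identity only*: n_t genes uniformly
without replacement from the post-filter scored universe, carrying the
tissue's original Spec weight multiset in drawn order. Randomizing the
weights too would test the weighting scheme rather than the cell, and
drawing from the whole genome rather than the scored universe would compare
the markers against genes that could never have been markers. Draws are
independent per tissue and per cell (library size differs per cell);
p = (1 + #{null ≥ observed}) / (n_perm + 1), one-sided, never exactly zero.
Per-cell random streams are keyed on (base seed, CRC-32 of the cell id), so
a cell's report is invariant to batch composition and order.

Raw ICIs are normalized to sum 1 per cell (all-zero vectors are reported as
zeros); significance is evaluated on raw values before normalization, as
scale cancels identically in observed and null. Exactly one tissue with
p < α (default 0.05) → single; several → mixed, reported at the normalized
proportions; none → unclassified. No multiple-testing correction is applied
across cells — the threshold is per-cell by design, and a relaxed α (e.g.
0.2) is exposed for exploratory detection of weak secondary identities.

### Threshold diagnostics

The scan recomputes marker sets and normalized ICI vectors on an integer
grid (default 5–100). Variability(cell, i) = ‖ICI(i) − ICI(i+1)‖₂;
signal(i) = mean over cells of max_t ICI(i)_t, on the normalized 0–1 scale.
Permutation p-values are not recomputed per grid point by default — the
scan diagnoses the vectors, not the calls. The `recommend` heuristic
(smallest threshold whose next five grid points' median variability all sit
below 10% of the scan's maximum; a fully flat scan returns the grid
minimum, no plateau returns the grid maximum with a warning) is an
advisory convenience: the underlying qualitative rule — pick the threshold
where variability has flattened while signal is still high — is the real
guidance, and the optimum is system-specific.

## Synthetic benchmark

The generator plants, per tissue, marker genes at negative-binomial mean
`marker_floor_mean × marker_fold` (defaults 2 × 250 = 500) in their own
tissue and at the floor elsewhere, over 2,000 exchangeable noise genes at
mean 50 (dispersion 0.3) — markers sit roughly tenfold above the typical
expressed gene in their own cell type, as real cell-type markers do.
Default geometry is 5 tissues × 4 replicates with 10 planted markers each.
Synthetic cells draw multinomial reads (default library 500,000) from
gamma-perturbed rates with two noise processes: Bernoulli dropout
(default 0.3) and sporadic ectopic expression of off-tissue markers
(default probability 0.05 per gene at mean 2 — ectopic transcripts are a
regular feature of single-cell profiles, and with a much lower rate the
normalized ICI vectors degenerate to exact point masses and the
variability diagnostic has nothing to measure; the classification
benchmark in the tests uses a stricter 0.01). Read-depth effects use
multinomial resampling of a cell's counts; chimeric profiles sample reads
from two cells' count distributions (benchmarked at 10,000 reads, a
realistic shallow depth where the stringent/relaxed α contrast is
visible).

What the generator does **not** emulate: amplification bias, gene-length
effects, batch structure in the reference, correlated gene modules, or
continuous identity gradients. Passing benchmarks therefore shows the
pipeline recovers planted structure under dropout/ectopic/depth noise —
not that any particular real compendium will separate as cleanly.

## Numerical choices and degenerate inputs

- Cutoff-candidate ties break toward the smaller value (strictly-greater
  improvement test with a 1e-15 guard).
- An empty high or low state contributes zero information; a cell
  expressing no marker of a tissue scores exactly 0 for it.
- Tables are written at full double precision (`%.17g`), so write→read
  round-trips are exact.
- Permutation index sampling uses an argpartition of uniform keys
  (linear-time per permutation, without replacement by construction).
- Marker sets, Spec tables and reports are deterministically ordered
  (sorted tissues, stable sorts, lexicographic final tie keys).

## Problem sizes

Default benchmark sizes — 200 oracle genes, 200 calibration cells, 100
cells per tissue for classification (scored twice: full depth and 1%),
100 chimeric mixes, a 30-cell threshold scan — run in about a minute each
on a single CPU at n_perm = 1,000, chosen so the whole suite and the
acceptance script each complete comfortably within a coffee break while
keeping binomial confidence intervals tight enough to be meaningful.

## Known limitations

- The Spec formulation here is a two-state reconstruction of the cited
  information-theoretic specificity framework; normalization details of the
  original multi-bin algorithm may differ, so marker *lists* from other
  implementations need not match gene-for-gene even when scores correlate.
- Cross-platform use (microarray reference, RNA-seq queries) assumes the
  caller has already collapsed probes to shared gene identifiers.
- The per-gene median>250 constitutive filter is scale-dependent.
- Tissues absent from the reference cannot be detected — a truly novel
  cell type will come out unclassified or weakly mixed.
- p-values are lower-bounded at 1/(n_perm+1); at n_perm = 1000 calls at
  α ≪ 0.001 are not resolvable.
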