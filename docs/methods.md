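# Methods

This note documents the models, parameters and numerical choices behind
`lowphos`, and what the synthetic validation does and does not show.

## The design and its contrasts

The canonical experiment is 2 accessions (low-P `tolerant`, `sensitive`)
× 2 tissues (`root`, `leaf`) × 2 treatments (`normalP`, `lowP`) × 3
biological replicates — 24 arrays, 8 design cells. Twelve two-group
contrasts are defined, each comparing one cell against one cell:

* 4 treatment contrasts: lowP / normalP within each (accession, tissue);
* 4 material contrasts: tolerant / sensitive within each tissue, under
  each treatment;
* 4 tissue contrasts: root / leaf within each accession, under each
  treatment.

Orientation is fixed once (low over normal, tolerant over sensitive, root
over leaf) so the sign of a log2 ratio always means the same thing.
Gene identity is the full transcript-level identifier string; two
transcripts of one locus are distinct genes in every set operation.

## Differential expression

For one contrast with groups of sizes n1, n2, the per-gene statistic is
`d = (mean_exp − mean_ctl) / (s + s0)`, where `s` is the pooled standard
error `sqrt((1/n1 + 1/n2) · SS_pooled / (n1 + n2 − 2))`. The fudge
constant `s0` guards against tiny-variance genes dominating the ranking:
candidates are 0 and every 5th percentile of the `s` distribution, and
the winner minimizes the coefficient of variation of the per-`s`-bin
median absolute deviation of `d` (100 quantile bins; ties resolve to the
smallest candidate, so degenerate inputs give `s0 = 0`).

The null distribution pools `d` over balanced relabelings of the pooled
columns. With the canonical 3 vs 3 design all C(6,3) = 20 relabelings are
enumerated, removing Monte-Carlo noise; larger designs are subsampled
without replacement under the configured seed. Pooled permutation
p-values are `(1 + #{|d*| ≥ |d|}) / (1 + B·G)` with ties counting, so a
constant gene gets exactly p = 1.

**FDR.** Two routes are implemented.

* `fdr_method="sam"` (default): at each threshold `t = |d|` the estimated
  false-call count is the **median** over relabelings of the number of
  permuted `|d*| ≥ t`; dividing by the observed call count gives the FDR
  at `t`, and each gene's q is the cumulative minimum from liberal to
  strict thresholds (monotone nonincreasing in `|d|`, capped at 1, π0
  fixed at 1, i.e. conservative).
* `fdr_method="bh"`: Benjamini–Hochberg step-up on the pooled permutation
  p-values (delegated to statsmodels).

The SAM route is the default deliberately. At the 3 vs 3 design size the
identity relabeling and its complement always reproduce the observed |d|
exactly, so the pooled p-value of a truly differential gene at rank r is
about 2r/(B·G) and its BH q-value has a hard floor of about 2/B = 0.1 —
no gene can clear q < 0.05 however large its effect. The median-based SAM
estimate is immune (the median over the 20 relabeling counts ignores the
two degenerate ones), which is why permutation-based microarray analyses
at this sample size report SAM q-values rather than BH-adjusted
permutation p. Both routes remain available and tested.

A DEG must satisfy all of: |log2 ratio| ≥ `log2_ratio_threshold`
(default 1.0), q < `fdr_alpha` (default 0.05), and
`n_complete_replicates ≥ 3` (no missing replicate in either group — the
literal reading of the triplicate criterion).

## Pattern classification and marked DEGs

For each inter-accession / inter-tissue comparison the low-P DEGs are
classified against the matching normal-P contrast:

| normal-P behaviour | low-P fold change | category |
|---|---|---|
| DEG, same direction | any | `concordant` |
| DEG, opposite direction | any | `opposite` |
| no difference | > 4 (or < 1/4 down) | `rescued` |
| no difference | otherwise | `dropped` |

"No difference under normal P" means failing **any** of the three DEG
criteria (configurable to a pure |log2 ratio| test via
`normal_no_difference="ratio_only"`). The rescue threshold is strict
(`> 4.0` on the linear ratio, i.e. |log2 ratio| > 2) and applies to the
low-P contrast's fold change; down-regulated genes mirror it at `< 1/4`.
Marked DEGs are exactly `opposite ∪ rescued`. Set accounting reports raw
totals (with multiplicity across comparisons) and non-redundant counts,
plus a per-gene duplicate report, and the category counts satisfy the
partition identity `concordant + opposite + rescued + dropped = total`
per comparison and direction by construction (and by test).

## Normalization

Quantile normalization forces every column onto the across-column mean of
the sorted values at each rank; ties receive the mean of the reference
values over their rank span (the same convention as limma's
`normalizeQuantiles`, against which it is cross-checked in the tests).
It is idempotent and permutation-equivariant in samples. Probe-to-gene
summarization is Tukey median polish per gene block (tolerance 1e-6 on
the largest residual change, at most 20 sweeps; the gene's value per
array is overall + column effect). Probe-level background correction is
intentionally out of scope: the pipeline's substance is downstream of
normalization and the synthetic data is generated at gene level.

## Enrichment

Upper-tail hypergeometric probability via scipy's log-space survival
function, validated against exact rational summation for all N ≤ 60.
The background is the set of genes on the matrix — the measured universe —
not the annotated universe (configurable by passing any background set).
Significance is declared on the raw p < 0.05 by default, mirroring common
over-representation reports; BH adjustment is computed alongside and can
be made the flag criterion (`enrichment_adjust=True`). Terms with no
background gene after restriction are dropped with a log line.

## Clustering

Correlation distance (1 − Pearson r) for genes, Euclidean for samples,
average linkage by default (complete and single available). Items are
sorted lexicographically by id before agglomeration, which fixes the
tie-break and makes the dendrogram invariant to input row order. A
zero-variance profile has no defined correlation and raises an error
naming the offending row. Dendrograms serialize to Newick; row
standardization is a display concern and is not applied before distance
computation. Replicate coherence — each cell's three replicates forming a
clade of the sample dendrogram — is the quantitative stand-in for the
visual reliability check of a clustered heatmap.

## The synthetic-data generator

Per-gene baselines are Gaussian on the log2 scale (mean 8, sd 2 —
a typical chip dynamic range; arbitrary and configurable), per-replicate
noise is additive Gaussian (sd 0.25 by default), and differential
expression is an additive shift on designated design cells: treatment
DEGs shift the low-P cell only (normal P stays the reference), pattern
genes shift the numerator cell of their comparison with separately chosen
low-P and normal-P effects so the planted category is known exactly.
Default effect magnitudes are uniform on [2, 5] log2 (≥ 4-fold), rescued
genes on [2.8, 5] (safely beyond the 4-fold rescue boundary under noise)
and dropped genes on [1.2, 1.8] (DEG but safely below it). A second
scenario draws treatment effects from the printed fold-change intervals
of the study design being emulated ([2.00, 33.78] up, [0.11, 0.49] down).
The uniform-on-log2-range choice is a stand-in: real effect-size
distributions are long-tailed and unknown.

Because a planted shift on one cell enters every contrast touching that
cell, pattern genes also imply genuine treatment effects and vice versa.
The planted truth therefore records the full genes × cells effect matrix,
and every validation derives its expectations from those cell effects
rather than from the planted labels alone.

The generator emulates: the factorial design, additive log2 noise,
cross-contrast pattern structure and fold-change ranges. It does not
emulate: probe-level effects, intensity-dependent variance, correlated
replicates, batch effects or missing values. Passing the planted-truth
suites therefore demonstrates the correctness of the algorithms under the
stated noise model, not performance on real arrays.

Deterministic fixtures (`simulate_table2_fixture`,
`simulate_table1_fixture`, `simulate_overlap_fixture`) reproduce the
printed category multiplicities, set sizes and overlap cardinalities of
the emulated study exactly, including the single gene shared between the
root and leaf rescued sets and the two genes shared across treatment DEG
sets; the overlap fixture is explicitly synthetic membership engineered
only for its intersection arithmetic. One wrinkle of the printed tables is
carried over deliberately: the five treatment DEG sets sum to 319 with two
shared genes (317 distinct), so the root-only sets hold 301 raw / 300
distinct ids, whereas the emulated study's running text rounds this to
"310 DEGs in roots" — an inconsistency of the source tables, not of the
arithmetic here.

## Validation scales

Test and acceptance runs use 400–2000 genes, 20 seeds for the
recovery/FDR and null-control suites, 100 simulations for the enrichment
rank check and 10 for replicate coherence — sizes at which every check
completes in seconds while keeping binomial standard errors well inside
the asserted margins.

## Known limitations

* The permutation resolution at 3 vs 3 caps how small a pooled p-value
  can be; FDR control at this design size leans on the SAM estimator.
* π0 is fixed at 1 (conservative q-values); no π0 estimation is
  implemented.
* The enrichment module tests terms independently; no term hierarchy or
  topology is modelled.
* `normal_no_difference="criteria"` couples the classification to the
  full DEG criterion under normal P; with very low replicate noise this
  is sharp, but near the significance boundary the category of a gene can
  hinge on the q-value route chosen.
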