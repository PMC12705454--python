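# Methods

`ctsnet` implements a consensus framework for blood-transcriptome subtyping
of sepsis. Independently published classification systems (a 2-class, a
4-class and a 3-class labeler) each partition the same cohort; agreement
between their partitions is expressed as a weighted overlap network,
Markov clustering extracts consensus transcriptomic subtypes (CTS) from
that network, and a compact gene panel is then trained so new samples can
be assigned a CTS directly from expression. Every stage is exercisable on
a synthetic cohort with known ground truth.

## Harmonization

Input matrices are log-scale expression (log2 microarray intensity or
log-CPM). Transcript-level rows are collapsed to unique genes by the
arithmetic per-sample mean of a gene's transcripts, with a deterministic
lexicographic gene order; collapsing happens before batch adjustment, and
cross-platform merging intersects gene identifiers first.

Batch adjustment uses the parametric empirical-Bayes location/scale model:
per-gene standardization against batch-size-weighted grand means and
pooled residual variances, per-batch additive (γ) and multiplicative (δ²)
effect estimates, normal/inverse-gamma priors fit by method of moments
across genes, and iterative posterior updates before back-transformation.
Only batch enters the design (no biological covariates). Genes with zero
pooled variance are dropped with a logged count. Two consequences of the
EB model worth knowing:

- Shrinkage toward the per-batch prior mean leaves a residual per-gene
  batch difference of order sd/√n_b when the true batch effect varies
  across genes; only the gene-homogeneous component is removed exactly.
- The per-gene pooled mean is preserved approximately (to O(sd/√n)), not
  identically; the single-batch case degenerates to the identity.

The implementation is cross-checked in the test suite against an
independent EB batch-correction implementation (agreement ≲5e-3, limited
by iteration tolerance).

## Subtype overlap network

Nodes are (system, subtype) pairs carrying member-sample sets over the
shared cohort (2/4/3-class systems give 9 nodes and 26 cross-system
pairs). Each cross-system pair carries:

- Jaccard index J = |A∩B|/|A∪B|;
- a permutation p-value for J (one system's label vector permuted over
  samples; add-one estimator p = (1+#{J* ≥ J})/(B+1), so p > 0);
- a one-sided hypergeometric overlap p-value with the full co-labeled
  cohort as the universe N;
- a Benjamini–Hochberg q-value computed over the complete 26-pair family.

Edges are never pruned by default; significance is an attribute consumed
downstream (an optional prune threshold exists). Within-system pairs are
excluded (disjoint by construction).

## Markov clustering and consensus subtypes

MCL operates on the Jaccard-weighted adjacency: self-loops set to each
node's maximum incident weight, column normalization, then alternating
expansion (matrix square) and inflation (element-wise power r with
renormalization) with pruning of entries below 1e-5 until the iteration is
stationary. Clusters are read from the attractor structure; a node
attracted to several clusters goes to the one with the largest flow mass
(ties to the lowest cluster index). The inflation grid 1–7 is swept, each
setting repeated 10 times to record stability (deterministic input gives
identical partitions); the selected inflation maximizes the mean
silhouette width of the node partition, ties toward the smaller value.

Each multi-node cluster becomes a CTS. A cluster that lacks any subtype
from one of the systems is completed by that system's subtype(s) with a
significant (q < 0.05) hypergeometric overlap against a cluster member —
this is how a 2-class system's subtype can serve two CTSs. The completion
is evaluated against the frozen cluster membership; extending it to
arbitrary significantly-overlapping subtypes lets membership chain through
the shared 2-class hub and collapses the member sets, so that variant is
deliberately not offered. Unclustered singleton nodes (the low-prevalence
4th class of the 4-class system, in both the motivating study and the
default simulation) are reported separately and excluded from core
definitions unless explicitly attached.

A sample is a *core sample* of CTS k when every system's label for it lies
in CTS k's member set. With labeler errors independent across systems the
expected core fraction is approximately the product of the per-system
concordances (0.9³ ≈ 0.73 at the defaults). Samples qualifying for more
than one CTS (possible only through completed member sets) are dropped so
core sets stay disjoint.

## CTS gene classifier

Genes are ranked on core samples by one-versus-all Kruskal–Wallis tests
per CTS (tie-corrected H, χ²₁ p). The per-gene ordering aggregates the
three contrasts by smallest p, ties by largest H, then gene id; the
ranking is truncated at 5000 genes. Panel size is chosen by stratified
tenfold cross-validation over the grid {2,4,…,30,40,50}: within each
training fold the ranking is recomputed (no selection leakage), a
500-tree random forest is fit per panel size, and misclassification,
multiclass Brier score and mean correct-class posterior are accumulated.
The selected size is the smallest with CV error < 5% (otherwise the best
size, with a warning). The final forest is fit on core samples with
out-of-bag error and votes recorded, and applied to the whole cohort;
posterior rows sum to 1, argmax ties resolve to the lowest CTS index, and
the fraction of calls with maximum posterior > 0.8 is reported.

## De novo consensus clustering

90% of samples and 90% of genes are drawn (without replacement) in each of
the configured replicates; each draw is clustered by average-linkage
hierarchical clustering on 1−Pearson sample distances and cut at every k
in 2–10. The consensus matrix at k is the co-clustering count over the
co-sampling count. Reported per k: the empirical CDF of consensus values
and its area, the relative area gain over k−1, the mean silhouette on the
1−consensus distance, and the cophenetic correlation of the dendrogram
built on that distance.

k is selected by maximal cophenetic correlation. On cleanly separated
data, consensus matrices become nearly binary and every k up to the true
cluster count yields a numerically perfect ultrametric, so the cophenetic
criterion saturates; candidates within 1e-3 of the maximum are therefore
resolved by the CDF-area elbow — the largest candidate whose relative
area gain is at least 0.1. Expression is gene-median-centered before
correlation-distance clustering in the bundled checks, since the shared
per-gene baseline profile otherwise dominates sample correlations.

## Per-cell gene-set scoring

Within each cell, genes are ranked by decreasing expression; ties
(including the zero block) break uniformly at random with a per-cell
reproducible stream (seed combined with a CRC of the cell identifier, so
reordering cells permutes scores identically). A set's score is the area
under its recovery curve across the top 5% of the ranking, divided by the
maximal achievable area; scores lie in [0,1] and are invariant to
monotone within-cell transforms. Sets with no gene in the universe score
NaN with a warning.

## Clinical analysis

Propensities come from a maximum-likelihood logistic model of treatment on
covariates (categoricals dummy-coded). Matching is greedy 1:1
nearest-neighbor on the logit propensity without replacement, treated
processed in descending propensity, caliper 1.2 × sd of the logit
propensity (configurable in raw units); unmatched treated are dropped with
a count. Standardized mean differences use the pooled-sd denominator
√((s²_t+s²_c)/2). Note the design requirement this inherits from matching
theory: balance below 0.1 SMD is achievable only when control propensity
support covers the treated distribution. The bundled generator therefore
defaults to ~1/3 treated with moderate severity confounding (logit
−0.8 + 0.4·z(SOFA) + 0.4·shock + 0.05·z(age)); with near-equal arms or
stronger confounding, 1:1 matching without replacement provably cannot
balance, which manifests as a large matched-treated drop in real cohorts.

Treatment-effect heterogeneity is a logistic model of 28-day mortality on
treatment × CTS with Wald CIs and AIC (reference: lowest CTS, untreated).
Survival curves are Kaplan–Meier per group with the (g−1)-df log-rank
test. Categorical comparisons use Pearson χ² with Bonferroni-corrected
column-pair post hoc tests; continuous comparisons use Kruskal–Wallis
with Dunn's pooled-rank z post hoc (tie-corrected, Bonferroni or BH).
ROC AUC is the midrank Mann–Whitney statistic. Reclassification value is
the category-free net reclassification improvement with a bootstrap
percentile CI. Variance homogeneity is Levene's test (mean-centered by
default; median-centered variant available). Cohort tables report counts
with percentages rounded half-up to one decimal (denominator = per-group
n unless a variable-specific denominator is supplied).

## Synthetic cohort

The generator emits, for n samples (default 1000): a genes × samples
log2-scale matrix (default 2000 genes — a scaled-down stand-in for a
~7000-gene co-normalized panel) with per-gene Normal(8, 2) baselines,
Normal noise (sd 1), and 30 signature genes per subtype shifted +2 log2
units in that subtype's samples; subtype proportions (0.44, 0.19, 0.37);
multiplicative/additive platform batches (δ=1.3, γ=1.5 on the second
batch); three conditionally independent labelers with 0.9 diagonal
concordance whose modal-label structure mirrors the published consensus
map (the 2-class system's second label covers two latent subtypes; the
4-class system has a low-prevalence error-only fourth class); severity
covariates shifted by subtype; confounded treatment as above; and
exponential event times with per-(subtype, treatment) log hazard ratios
(treatment harmful in subtypes 1–2, protective in 3), administratively
censored at day 28. The optional single-cell fixture draws Poisson counts
with designated cell types over-expressing designated gene sets by a
configurable fold.

What the generator does not emulate: gene–gene correlation (beyond the
planted subtype shifts), platform-specific mean–variance relationships,
probe-level artifacts, label errors correlated across systems, informative
censoring, or competing risks. Passing recovery tests therefore
demonstrates correctness of the machinery under the stated generative
model, not performance on real cohorts.

## Problem sizes and numerical choices

The bundled checks run the full workflow on the default 1000 × 2000
cohort; the de novo k-selection study uses ten 180-sample × 300-gene
cohorts at 100 resampling replicates each, and calibration studies use
1000 replicates at small n — sizes chosen to exercise every code path at
desk scale. MCL convergence: tolerance 1e-8, pruning 1e-5, max 200
iterations (non-convergence raises). Zero-variance genes are dropped in
batch adjustment and rank last in gene ranking. Posterior argmax ties go
to the lowest CTS index. The log-rank χ² reference is mildly
anti-conservative below ~50 subjects per arm (a property of the
asymptotic approximation, verified identical to an independent survival
implementation); calibration studies use n=150.

## Known limitations

- The consensus-subtype count is structural (number of multi-node MCL
  clusters); it is validated, not imposed, and degenerate inputs (no
  multi-node cluster, or no structure across the inflation grid) raise.
- EB batch adjustment assumes the location/scale batch model; it will not
  remove batch-by-subtype interactions.
- Greedy matching is not optimal matching; with poor propensity overlap
  it trades bias for sample retention via the caliper.
- The de novo clustering concordance percentages reported in the
  motivating study depend on its restricted-access cohorts and are not
  reproduced here; `concordance_table` implements the procedure.
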