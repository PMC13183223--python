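# Methods

`nettox` implements a target-triage workflow that links a chemical
exposure's predicted protein targets to a disease transcriptome: moderated
differential expression defines disease-associated genes; curated disease
and chemical target lists are standardized, optionally context-filtered,
and intersected with the DEG list; the overlap is tested against
hypergeometric and permutation nulls; candidates are ranked by composite
network centrality; a tri-algorithm machine-learning stage selects a
consensus signature; and resampling plus a second cohort quantify how
robust that signature is. This note records the models, the defaults and
why, the numerical choices, and what the synthetic benchmark does and does
not demonstrate.

## Moderated differential expression

For gene *g* with group sizes *n₁* (case) and *n₂* (control) on the log2
scale, the pooled variance *s²_g* has residual df *d = n₁ + n₂ − 2*. We
assume the hierarchical model

    s²_g | σ²_g ~ σ²_g · χ²_d / d,      1/σ²_g ~ χ²_{d₀} / (d₀ · s₀²),

estimate the prior (d₀, s₀²) by moment-matching the mean and variance of
log s²_g against the implied scaled-F marginal (trigamma inversion by
Newton's method), and shrink

    s̃²_g = (d₀ s₀² + d s²_g) / (d₀ + d),
    t_g = log2FC_g / (s̃_g √(1/n₁ + 1/n₂))  ~  t(d₀ + d).

This is the closed-form moment variant of the empirical-Bayes moderated t;
a test cross-checks it against the Bioconductor `limma` reference on a
synthetic matrix (agreement to ~1e-4 relative on t and p, ~2% on the
prior). Degenerate inputs: genes constant across all samples are flagged,
excluded from prior estimation, and report t = 0, p = 1 when the fold
change is also zero; with a forced d₀ = 0 a zero-variance gene has
undefined t and reports NaN with a warning. DEG classification uses strict
inequalities — |log2FC| > 0.5 and p < 0.05 by default; BH-adjusted
thresholds are available but non-default, because an FDR pass at these
cohort sizes retains almost nothing and is better treated as a
supplementary sensitivity check. Probes mapping to one symbol are
collapsed by mean before testing (configurable to max).

## Target-list integration

Symbols are upper-cased, whitespace-trimmed, alias-mapped (the alias map
must be idempotent), and de-duplicated, keeping the maximum fit score and
the union of source/interaction-type labels. Context filtering keeps
CTD-sourced entries annotated as direct interactions, pharmacophore
("pharmmapper"-sourced) entries at or above the (1 − 0.2)-quantile of
their source's fit scores (linear interpolation; ties at the cutoff are
kept, since a "top 20%" rule has no canonical tie policy), and only
symbols with a positive expression value in at least one sample of a
provided cohort. Detectability is interpreted on the provided matrix
values; arrays have no counts, so "count > 0" is read as "measured and
positive". All filters are contractive and the candidate set is an exact
three-way intersection with provenance sizes recorded.

## Overlap significance

The hypergeometric tail treats the three-way design as a two-set draw:
K = |disease ∩ chemical| successes in a background of N measured genes,
n = |DEG| draws, observed k = three-way overlap. This reduction is a
modelling choice with no single canonical construction, so the
roles are arguments, not constants. The permutation null redraws all three
sets as size-matched uniform subsets of the background (a mode redrawing
only the DEG set exists), B = 10,000 by default, with
p = (1 + #{k_b ≥ k}) / (B + 1) and fold enrichment k / mean(k_b).

Calibration caveat: the permutation p of a small discrete overlap count is
conservative — when the observed overlap is 0 the p-value is identically
1. The calibration test therefore uses a fully null design large enough
that the null count has ≈20 support points (σ ≈ 7), where the p
distribution is approximately uniform (KS). At desk scale with small
decoy databases, p-values cluster near 1; this is a property of the
statistic, not a bug.

## Network hub ranking

Edge confidence is used only for thresholding (score > 0.4, strict);
shortest paths are unweighted. Degree, betweenness (undirected convention,
each unordered pair counted once) and stress (number of shortest paths
through a node) are min-max normalized per metric (a constant metric maps
to all-zeros to avoid 0/0), averaged into a composite, and sorted with
deterministic tie-breaking (higher degree, then lexicographic symbol).
Stress has no networkx implementation and is computed from BFS
shortest-path counts in O(n·n²); the intended scale is candidate networks
of at most a few hundred nodes. Both betweenness and stress are verified
against brute-force enumeration of all shortest paths on small random
graphs.

## Consensus feature selection

The candidate genes form a samples × genes feature matrix from the
training cohort.

* **L1 logistic (LASSO-style).** Features are standardized internally; a
  descending geometric lambda path (60 points, ratio 10⁻²) starts at the
  smallest lambda with an all-zero solution; lambda.min minimizes mean
  stratified 5-fold cross-validated binomial deviance (deviance, not AUC —
  the standard lambda.min convention). Selected =
  nonzero coefficients at lambda.min, reported on the original scale.
* **Gradient-boosted trees.** Shallow trees (depth 2, 100 rounds,
  learning rate 0.3), importance = total gain, selection rule "nonzero
  gain" (configurable fraction rule). Per-tree column subsampling of 0.5
  is the default: with ~17 samples and several strongly separating,
  mutually correlated candidates, full-column boosting puts all gain on
  one feature and the selection degenerates to a single gene; subsampling
  restores a non-degenerate importance profile.
* **Shadow-feature selection.** Each iteration appends a permuted shadow
  copy of every still-active feature (minimum five shadows, duplicating if
  necessary), fits a random forest (100 trees, impurity importance), and
  credits a hit to undecided features beating the best shadow; two-sided
  binomial tests of hits vs Binomial(runs, ½) with BH correction at α =
  0.01 confirm (upper tail) or reject (lower tail); the cap is 1,000
  iterations with early stop when nothing is undecided. Shadowing all
  active features, not only the undecided ones, keeps the shadow-max null
  stationary as rejections accumulate; shadowing only survivors inflates
  late-iteration hit rates (measured ~1.4 false confirms per 20 noise
  features vs ~0.8 with the stationary pool). The residual null level is
  not exactly zero: a noise feature whose chance correlation with the
  labels is fixed across iterations can consistently beat its redrawn
  shadows — a dataset-conditional property of all shadow-comparison
  wrappers, quantified in the tests. Confirmed features only are
  "selected"; tentative ones are reported separately. This is the one
  stage using a bagged forest rather than boosting, because the
  shadow-comparison null is defined against forest-style importances.

The consensus is the exact intersection of the three selected sets. It is
deliberately conservative: on synthetic cohorts at the default sample
sizes it is empty in roughly a fifth of runs, and when non-empty it
contained only planted targets in every pre-registered simulation run —
high precision, modest recall, which is the intended reading of a
consensus signature.

## Generalization and stability estimates

Nested CV: stratified 5 × 5 with 100 repetitions by default; lambda is
re-tuned inside every outer-training split; AUC, accuracy, sensitivity,
specificity, PPV and NPV are computed per outer test fold (single-class
test folds are skipped and tallied; empty confusion-matrix denominators
give NaN and are excluded from means); 95% CIs are bootstrap percentile
intervals (1,000 resamples) over per-evaluation values. On label-permuted
data at n = 17 the mean CV AUC sits slightly *below* 0.5 (measured 0.445 ±
0.017) — the familiar small-sample cross-validation anti-learning
pessimism. The calibration requirement enforced by the tests is therefore
one-sided: no optimistic bias.

Bootstrap stability: lambda is tuned once on the full data; each of B =
1,000 iterations refits the L1 model on a within-class (stratified)
bootstrap resample — unstratified resampling at n = 17 frequently produces
single-class fits — and evaluates on the out-of-bag samples; empty-OOB
iterations are skipped and tallied. Selection frequency counts LASSO
selections only (configurable).

## Two-cohort validation and sensitivity analyses

A consensus gene is a *core target* when the two-sided rank-sum p is below
0.05 in both cohorts and the case-minus-control median difference has the
same sign in both (mean-difference mode available; the median is the
rank-sum-consistent default). The rank-sum test uses the exact null by
enumeration when the combined sample is ≤ 12 without ties, otherwise the
tie-corrected normal approximation with continuity correction. The
sensitivity grid re-runs DEG thresholding and the three-way intersection
over |log2FC| ∈ {0.25, 0.50, 0.75, 1.00, 1.25, 1.50} with unadjusted p <
0.05 held fixed; because the cutoffs are strict, the DEG and candidate
sets are nested decreasing and tracked-gene retention can only switch off.
Abundance tables (e.g., 22 immune cell-type fractions) are tested
per-component by rank-sum with BH correction across the component family;
both p < 0.05 and q < 0.05 flags are reported.

## Synthetic data: what it emulates and what it does not

The generator plants recoverable structure: ~5% of 2,000 genes shifted by
1–2 log2 units (same signed effect in both cohorts, baselines and noise
redrawn), per-gene variances from a scaled inverse-χ²(4, 0.05) so the
moderated-t prior is exactly recoverable, 9 vs 8 and 6 vs 6 cohorts,
target databases covering each planted target with probability 0.8 plus
150 random decoys, chemical entries biased toward "direct" annotation and
higher fit scores for planted genes, a 200-node preferential-attachment
network whose 5 planted hubs are over-wired to ≥ 3× the median degree with
edge confidences above the 0.4 threshold, and Dirichlet(2) compositions
with the case-group "Neutrophils" concentration multiplied by 3. All
generators draw from named substreams of one seed, so adding a generator
never shifts another's stream, and every bundle is byte-reproducible.

What it does *not* emulate: probe-level artifacts, normalization and batch
effects, correlated co-expression blocks, annotation errors in the
databases, scale-free degree exponents matched to real interactomes, or
compositional immune profiles estimated (with error) by deconvolution.
Passing the recovery tests shows the pipeline's statistics behave as
designed under their own assumptions — not that the biological conclusions
of any particular real-data analysis are correct.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the full pipeline at the
default cohort design (2,000 genes, 9 vs 8 / 6 vs 6) with resampling
scaled to desk size: 10,000 overlap permutations, 25 nested-CV repeats,
300 bootstrap iterations, and a 200-iteration shadow-feature cap (early
stop usually triggers long before). Recovery-rate assertions were frozen
from pre-registered simulations (50–200 seeds each) before being written
into the tests; Monte-Carlo bands are ±3 standard errors of the frozen
estimates.

## Known limitations

* The hypergeometric reduction of a three-way overlap is one of several
  defensible constructions; results for real lists depend on the choice of
  background, which is exposed but must be chosen by the user.
* Stress centrality is cubic in node count; the implementation targets
  candidate subnetworks, not whole interactomes.
* With ≤ 20 samples, every ML-stage quantity (lambda, selections, AUCs)
  has substantial seed-to-seed variability; only the seeded, resampled
  summaries are meaningful, never a single fit.
* The series-matrix reader parses the expression block only; platform
  annotation (probe → symbol) must be supplied by the caller.
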