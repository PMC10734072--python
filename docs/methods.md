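# Methods

This note documents the models, algorithms, defaults, and design choices
behind `alssubtypes`. It is the place to look when a parameter's meaning,
unit, or default needs justifying.

## Problem setting

Bulk expression profiles of sporadic ALS cases carry heterogeneous
molecular signals: subsets of patients over-express distinct gene
programs (synaptic/neuropeptide signalling, oxidative stress and
vasculature, neuroinflammation). The package implements the full
unsupervised route from a raw gene x sample count matrix to molecular
subtypes and their phenotype associations:

1. normalize and variance-stabilize counts, keep the most variable genes;
2. cluster samples by non-smooth non-negative matrix factorization
   (nsNMF) with consensus over random restarts, and extract per-cluster
   informative-gene signatures;
3. transfer cluster membership to independent cohorts (possibly observed
   on a different gene panel) with linear discriminant analysis (LDA),
   quantifying certainty and bootstrap stability;
4. validate signatures with cross-validated logistic classifiers under
   three collinearity-handling scenarios, against a random-gene baseline;
5. test cluster-phenotype associations (chi-square for categorical
   variables, ANCOVA with Tukey post-hoc for continuous ones).

Because the motivating cohorts are access-restricted, a first-class
synthetic-data generator reproduces the statistical structure the
pipeline assumes and provides ground truth for every stage.

## Synthetic data model

Counts for gene g in sample s are negative binomial with mean

    mu[g, s] = libsize_s * base_g * 2^(log2FC * 1[g in signature of cluster(s)])

and variance `mu + alpha * mu^2`. Components:

- `base_g` — log-normal per-gene baseline mean (`baseline_log_mean` 3.5,
  `baseline_log_sd` 1.0 on the natural-log scale, i.e. median baseline
  ~33 counts with a long right tail, resembling filtered bulk RNA-seq);
- `libsize_s` — log-normal library-size factor (`libsize_log_sd` 0.2,
  ~±40% two-sigma depth variation);
- `alpha` — NB dispersion, default 0.2, a typical bulk value after
  low-count filtering;
- each of the k clusters owns a disjoint block of `signature_size`
  signature genes up-regulated by `log2_fold_change` (default 2, i.e.
  4-fold) only in its own samples.

Defaults (2000 genes, 120 samples, k = 3, 50 signature genes per
cluster) describe a discovery cohort at the scale of a single brain-bank
case series. The planted effect size is a free parameter of the model —
the real cohorts' cluster effect sizes are unknown — and is the main
knob for difficulty: at log2FC = 0 the clusters are undetectable by
construction.

The validation generator draws new samples from the same model but
observes only a random fraction of genes (emulating platform or
annotation differences) with an optional log-normal per-gene
multiplicative shift. The control generator omits all signature effects,
so control samples are exchangeable. Phenotype tables (sex, C9orf72
status, onset site, ages, duration) are drawn cluster-conditionally with
defaults mirroring the demographic profile of a three-subtype sporadic
ALS case series: a dominant earlier-onset cluster holding nearly all
C9orf72 carriers, a small later-onset cluster, and an intermediate one.

What the generator does NOT emulate: gene-gene co-expression beyond the
planted blocks, batch effects beyond the per-gene platform shift,
GC/length biases, and isoform structure. A pipeline that passes the
synthetic recovery tests has been shown to invert this generative model,
not to be robust to everything real data can do.

## Preprocessing

- **Size factors** — median-of-ratios: the per-gene reference is the
  geometric mean across samples over genes with no zero count; a
  sample's factor is the median ratio to the reference; factors are
  rescaled to geometric mean 1. Cross-checked in the tests against the
  DESeq2-lineage implementation in `pydeseq2`.
- **Gene filter** — keep genes with total count >= `min_total_count`
  (default 10; a conventional low-count screen, configurable) on
  autosomes 1-22.
- **Variance stabilization** — the default transform is
  `log2(count / sf + 1)`: monotone per sample, exactly invariant to
  depth once size factors absorb it, and approximately
  variance-stabilizing for NB counts. A parametric dispersion-trend VST
  differs in the low-count regime; the transform is pluggable
  (`vst_transform(..., transform=...)`) for callers who want to supply
  one. Downstream stages only require an approximately stabilized
  monotone transform.
- **Variable genes** — rank rows by plain MAD (no 1.4826 constant:
  ranking is scale-invariant) and keep the top `n_top`; ties break by
  gene ID so selection is deterministic. Pre-normalized input
  (microarray mode) skips size factors and the transform entirely.

## nsNMF and consensus clustering

The model is `V ~ W S H` with the k x k smoothing matrix
`S = (1 - theta) I + (theta / k) 11'`. S is symmetric doubly stochastic;
as theta grows it mixes each basis vector toward the uniform vector, and
the factors must become sparse to compensate — the property used to get
compact signatures. theta defaults to 0.5 (mid-range; the sparseness of
W is empirically non-decreasing in theta, which the tests check via
Hoyer sparseness).

Fitting: multiplicative KL-divergence updates in the Lee-Seung form,
using the effective basis `W S` for the H update and the effective
coefficients `S H` for the W update. Each update is a majorization step
for the generalized KL loss `D(V || WSH)`, so the recorded loss trace is
non-increasing (asserted to 1e-8 in the tests). After each iteration W
columns are normalized to unit sum with the compensating rescale on H
rows. Ratios are floored at 1e-12 to avoid 0/0. Initialization is
i.i.d. Uniform(0,1) scaled by mean(V); per-run seeds spawn
deterministically from the master seed, so whole consensus runs are
bit-reproducible. Convergence: relative loss change < `tol` (default
1e-5) or `max_iter` (default 1000).

Consensus/rank selection: for each candidate k, `n_runs` restarts each
yield a binary co-clustering (connectivity) matrix from the argmax basis
component per sample; the consensus is their mean. The cophenetic
correlation between `1 - consensus` and the cophenetic distances of its
average-linkage dendrogram measures how block-like the consensus is; the
chosen rank maximizes it (ties to the smaller k).

Informative genes: gene posteriors are row-normalized basis weights
`p[g, j] = W[g, j] / sum_j W[g, j]`; the feature score
`f_g = 1 + (1/log2 k) sum_j p log2 p` is 1 for a fully cluster-specific
gene and 0 for a flat one. A gene is informative iff
`f_g > median(f) + 3 * 1.4826 * MAD(f)` AND its maximum basis weight
exceeds the median of all W entries. This is the Kim-Park extraction
convention as implemented in the R NMF package's `extractFeatures`
(whose `mad` carries the normal-consistency constant); the second screen
removes low-expression genes whose posteriors are sharp only through
row normalization. Both the multiplier and the scale are exposed as
arguments. Each informative gene is assigned to its argmax component, so
signatures are disjoint by construction. All-zero W rows are flagged and
excluded rather than normalized.

## LDA transfer

The discovery matrix restricted to the signature genes shared with the
target platform trains a Gaussian LDA: class means, empirical priors,
and a pooled within-class covariance ridge-regularized by
`lambda * trace(S)/p` on the diagonal (`lambda` = 1e-3). The ridge is
required, not cosmetic: the shared-gene count routinely exceeds the
target sample count, and signature genes are collinear. Posteriors are
softmax of Gaussian log-likelihood plus log prior; the assigned cluster
is the argmax. The cluster-averaged posterior matrix (rows = assigned
cluster) summarizes assignment certainty the way a confusion-style
heatmap would.

Bootstrap stability: the target is assigned once to fix reference
labels; each of `n_iterations` (default 1000) resamples the target with
replacement, refits the LDA on the resample under the reference labels,
and scores (a) the fraction of all original samples whose refit
assignment matches the reference, and (b) the mean silhouette of the
reference partition in the refit discriminant space (Euclidean). Scoring
a fixed model on resamples would give accuracy identically 1, which
cannot express instability; the refit-and-rescore scheme can. Resamples
that lose a class are redrawn and counted. Medians and 2.5/97.5
percentiles are reported.

Reverse validation re-clusters the target de novo (preprocess + nsNMF),
matches de-novo clusters to the transferred labels by Hungarian
assignment on the contingency table (maximum total overlap; robust to
label permutations and unequal k), and reports per-reference-cluster
agreement fractions.

## Signature classifiers

Binary logistic regression (L2, C grid {0.01, 0.1, 1, 10}) under
stratified 10-fold CV with shuffling. Per fold, strictly on the training
portion: standardize, SMOTE-balance (synthetic minority points
interpolated uniformly along segments to one of the 5 nearest minority
neighbors), then scenario-specific feature selection; hyperparameters by
inner stratified 10-fold grid search on ROC AUC; metrics (ROC AUC,
precision, recall, F1) on the untouched held-out fold. The
decollinearizer ranks features by ANOVA F against the labels and accepts
greedily under pairwise |Pearson r| < 0.4; scenario 3 intersects the
per-fold accepted sets and reruns the CV on the fixed subset (an empty
intersection raises, reporting per-fold set sizes). Whether per-fold
selection may see training labels was an open design point; the
leakage-free choice (training fold only) is implemented, and the tests
verify the consequence: permuted labels stay at chance.

A caveat discovered on synthetic data and worth knowing when designing
chance-level checks: a strong common case/control shift makes *all*
signature features mutually collinear (pooled correlations above any
reasonable threshold), so scenario 3's stable subset is legitimately
empty on such data. Chance-level calibration is therefore demonstrated
on exchangeable (signature-free) samples with arbitrary balanced labels,
where all three scenarios are well defined; the planted-signal detection
check uses the shifted design under scenarios 1-2.

The random-gene baseline repeats the analysis on `n_classifiers`
(default 10) random draws of the same number of genes, optionally
excluding the signature; on data whose signal lives only in the
signature it must stay at chance.

## Phenotype statistics

- **Chi-square** — Pearson test of independence on r x c tables,
  *without* Yates continuity correction: verified to be the convention
  that reproduces the published association statistics of the
  four-cohort demographic table bundled in `cohort_tables.py` (2 x k
  category-vs-complement construction; the van Rheenen onset comparison
  is the direct limb-vs-bulbar 2 x 3 table). One published value (the
  KCL limb-onset statistic, printed as 6.05) is not reproduced by the
  same construction that reproduces every other value — it computes to
  7.22 — and is excluded from the reproduction suite; the discrepancy is
  noted rather than papered over.
- **ANCOVA** — least-squares fit of outcome ~ intercept + cluster
  dummies + covariates; the cluster F compares this against the model
  omitting the dummies (reduced-vs-full; equivalent to Type II for this
  single-factor design). Missing values are dropped listwise. An
  optional Shapiro-Wilk gate (alpha 0.05) log-transforms non-normal
  outcomes first; natural log, since any log base gives the same
  Shapiro-Wilk decision, and non-positive values raise rather than
  being shifted silently.
- **Tukey HSD** — studentized-range p-values on covariate-adjusted
  cluster means with the model residual variance; at k = 2 this
  reduces exactly to the pooled two-sample t-test (q = t * sqrt(2)),
  which the tests assert to 1e-6.

## Numerical choices and degenerate inputs

- Epsilon flooring 1e-12 in multiplicative NMF ratios; all-zero V
  columns rejected up front.
- Argmax ties (sample assignment, informative-gene assignment) break to
  the lowest index.
- Consensus cophenetic correlation is defined as 0 when all pairwise
  consensus distances are equal (degenerate dendrogram).
- LDA with duplicated features or p > n is well defined via the ridge;
  a class with fewer than 2 samples raises.
- SMOTE reduces k_neighbors with a warning when the minority class is
  small, and refuses a singleton minority.
- Chi-square refuses zero marginals; ANCOVA refuses rank-deficient
  designs naming the problem.

## Problem sizes used in the bundled checks

The recovery checks run at the generator defaults (2000 genes, 120
samples, k = 3, 4-fold signatures), with 1000 MAD-selected genes
entering the factorization, 20 restarts for consensus over k in 2..6,
and 1000 bootstrap iterations for transfer stability; classifier checks
use 10-fold CV at cohort sizes near 120. These sizes are chosen so the
full suite exercises realistic cohort scales while remaining quick on a
single CPU.

## Known limitations

- The default VST stand-in is not DESeq2's parametric VST; differences
  concentrate in low-count genes (both are monotone and depth-invariant).
- The bootstrap protocol for assignment stability is one defensible
  reading of "resample, then collect accuracy and silhouette"; the
  scheme is isolated behind `bootstrap_stability` and swappable.
- The informative-gene rule is a convention (entropy score + robust
  cutoff), not an inferential procedure; its two knobs are exposed.
- Microarray harmonization with RNA-seq scale (beyond passing
  pre-normalized intensities through) is out of scope.
- The classifier framework is binary-only, matching its intended uses
  (case/control, region-vs-region).
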