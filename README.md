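# alssubtypes

Expression-based molecular subtyping of amyotrophic lateral sclerosis
(ALS) cohorts: unsupervised discovery of patient clusters and gene
signatures from bulk expression matrices, transfer of cluster membership
to independent datasets, signature validation with cross-validated
classifiers, and cluster-phenotype association statistics. The package
is aimed at researchers who stratify heterogeneous neurodegenerative
cohorts from post-mortem brain or blood transcriptomes and need every
stage of that workflow reproducible and testable without access to the
restricted patient datasets it was designed around.

## What it computes

Given a gene x sample count matrix *V* (after median-of-ratios
normalization, autosomal/low-count filtering, a variance-stabilizing
log transform, and selection of the most variable genes by median
absolute deviation), samples are clustered with **non-smooth
non-negative matrix factorization** (nsNMF):

    V ≈ W S H,    S = (1 − θ) I + (θ/k) 11ᵀ

where the smoothing matrix *S* forces sparseness onto the basis *W*
(genes x k) and coefficients *H* (k x samples) as θ grows. Fitting uses
multiplicative Kullback-Leibler updates; the cluster count *k* is chosen
by consensus over random restarts, at the maximal cophenetic correlation
of the consensus matrix. Each sample gets the cluster of its largest
coefficient; each cluster gets a disjoint **informative-gene signature**
from the entropy-based feature score on row-normalized basis weights
(*f* = 1 for a fully cluster-specific gene, 0 for a flat one), cut at
median + 3·MAD with a basis-contribution screen.

Cluster membership transfers to an independent dataset by **linear
discriminant analysis** trained on the discovery expression restricted
to the signature genes both datasets share, reporting per-sample
posterior probabilities, the cluster-averaged posterior matrix, and
bootstrap stability (median accuracy and silhouette with 95% CIs over
resample-refit iterations). Signatures are validated with L2 logistic
regression under stratified 10-fold cross-validation — with
fold-internal standardization, SMOTE balancing, and three
multicollinearity scenarios — against a random-gene baseline.
Cluster-phenotype associations use Pearson chi-square tests (no
continuity correction), one-way ANCOVA with covariates and Tukey HSD
post-hoc, gated by a Shapiro-Wilk log-transform rule.

A synthetic-data generator (negative-binomial counts, library-size
variation, planted disjoint signature blocks, cluster-conditional
phenotypes) provides ground truth for every stage; see
`docs/methods.md` for the model and all defaults.

## Worked example

```python
import numpy as np
from alssubtypes import (SyntheticConfig, generate_discovery,
                         generate_validation, NsNMFConfig)
from alssubtypes.preprocess import preprocess_counts
from alssubtypes.nsnmf import fit_cluster_model
from alssubtypes.transfer import assign, fit_lda, intersect_genes

config = SyntheticConfig(seed=1)             # 2000 genes, 120 samples, k=3
discovery, phenotypes = generate_discovery(config)
norm, top = preprocess_counts(discovery, n_top=1000)
V = norm.to_frame().loc[top].to_numpy()

fact, model = fit_cluster_model(V, NsNMFConfig(k=3, n_runs=10, seed=7))
sizes = np.bincount(model.sample_labels)[1:]
n_info = sum(len(v) for v in model.informative_genes.values())
print("cluster sizes:", sizes, "| informative genes:", n_info)

signatures = {j: [top[i] for i in idx]
              for j, idx in model.informative_genes.items()}
validation = generate_validation(discovery, gene_keep_fraction=0.6,
                                 platform_shift_sd=0.0, n_samples=60, seed=11)
vnorm, _ = preprocess_counts(validation, n_top=validation.n_genes,
                             min_total_count=0)
shared, _ = intersect_genes(signatures, vnorm.gene_ids)
lda = fit_lda(norm.to_frame().loc[shared].to_numpy().T,
              model.sample_labels, shared_genes=shared)
result = assign(lda, vnorm.to_frame().loc[shared].to_numpy().T)
print("avg posterior diagonal:", np.round(np.diag(result.avg_posterior), 3))
```

prints

```
cluster sizes: [43 43 34] | informative genes: 158
avg posterior diagonal: [1. 1. 1.]
```

The three planted clusters are recovered with disjoint signatures
(158 informative genes over the 150 planted signature genes plus a few
borderline calls), and every validation sample is assigned to its true
cluster with posterior certainty ≈ 1 — the synthetic analogue of the
high-certainty cluster transfer seen between real ALS cohorts.

The same workflow is scriptable from the shell:

```sh
alssubtypes simulate --seed 1 --out sim/
alssubtypes preprocess --counts sim/counts.tsv --annotation sim/annotation.tsv --out prep/
alssubtypes cluster --matrix prep/vst_top.tsv --k 3 --k-scan 2:6 --runs 20 --seed 7 --out clust/
alssubtypes run --seed 3 --out pipeline_out/   # full pipeline + manifest
```

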