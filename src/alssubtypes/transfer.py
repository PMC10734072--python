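"""Cross-dataset cluster transfer via linear discriminant analysis.

Discovery cluster labels are carried to independent datasets by fitting a
Gaussian linear discriminant model on the discovery expression restricted
to the genes shared between the discovery signatures and the target
platform, then assigning each target sample to the cluster with the
highest posterior probability. Assignment certainty is summarized as the
cluster-averaged posterior matrix; stability is assessed by bootstrap
(refit on a resample, score all original samples against the reference
assignment); reverse validation re-clusters the target de novo and
measures the overlap with the transferred labels under an optimal
(Hungarian) cluster matching.

The pooled within-class covariance is ridge-regularized
(lambda * trace / p on the diagonal) because the number of shared genes
can exceed the number of samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from sklearn.metrics import silhouette_score

from .data import ExpressionDataset
from .nsnmf import NsNMFConfig, fit_cluster_model
from .preprocess import preprocess_counts

logger = logging.getLogger(__name__)


@dataclass
class LDAModel:
    shared_genes: list[str] | None
    classes: np.ndarray
    class_means: np.ndarray        # k x p
    pooled_covariance: np.ndarray  # p x p, ridge-regularized
    priors: np.ndarray
    scalings: np.ndarray           # p x (<= k-1) discriminant projection
    grand_mean: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project samples into the (<= k-1)-dimensional discriminant space."""
        return (np.asarray(X, dtype=float) - self.grand_mean) @ self.scalings


@dataclass
class AssignmentResult:
    labels: np.ndarray             # cluster values from model.classes
    posteriors: np.ndarray         # samples x k, rows sum to 1
    avg_posterior: np.ndarray      # k x k; row = assigned cluster


@dataclass
class BootstrapStability:
    n_iterations: int
    median_accuracy: float
    accuracy_ci: tuple[float, float]
    median_silhouette: float
    silhouette_ci: tuple[float, float]
    n_redrawn: int


def intersect_genes(signatures: dict[int, list[str]],
                    target_genes: list[str]) -> tuple[list[str], dict[int, int]]:
    """Signature genes present on the target platform, in signature order.

    Returns the ordered shared gene list and the per-cluster retained
    counts. Raises on an empty intersection.
    """
    target = set(target_genes)
    shared: list[str] = []
    counts: dict[int, int] = {}
    for cluster in sorted(signatures):
        kept = [g for g in signatures[cluster] if g in target]
        counts[cluster] = len(kept)
        shared.extend(kept)
    if not shared:
        raise ValueError("no signature genes present in the target dataset")
    logger.info("gene intersection per cluster: %s", counts)
    return shared, counts


def fit_lda(X: np.ndarray, labels: np.ndarray, ridge: float = 1e-3,
            shared_genes: list[str] | None = None) -> LDAModel:
    """Gaussian LDA: class means, ridge-regularized pooled covariance,
    empirical priors, and a discriminant-space projection.

    ``X`` is samples x features. Ridge adds ``ridge * trace(S)/p`` to the
    covariance diagonal, which keeps the model well defined under perfect
    feature collinearity or p > n.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes")
    n, p = X.shape
    means = np.zeros((len(classes), p))
    priors = np.zeros(len(classes))
    pooled = np.zeros((p, p))
    for i, c in enumerate(classes):
        Xi = X[labels == c]
        if Xi.shape[0] < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
        means[i] = Xi.mean(axis=0)
        priors[i] = Xi.shape[0] / n
        R = Xi - means[i]
        pooled += R.T @ R
    pooled /= (n - len(classes))
    lam = ridge * np.trace(pooled) / p
    if lam <= 0:
        lam = ridge
    pooled += lam * np.eye(p)
    scalings = _discriminant_basis(means, pooled, priors)
    return LDAModel(shared_genes=shared_genes, classes=classes,
                    class_means=means, pooled_covariance=pooled,
                    priors=priors, scalings=scalings,
                    grand_mean=priors @ means)


def _discriminant_basis(means: np.ndarray, cov: np.ndarray,
                        priors: np.ndarray) -> np.ndarray:
    """Directions maximizing between- over within-class scatter.

    Solves the generalized eigenproblem B v = lambda Sigma v for the
    prior-weighted between-class scatter B, keeping the <= k-1 leading
    eigenvectors.
    """
    k, p = means.shape
    grand = priors @ means
    B = (means - grand).T @ np.diag(priors) @ (means - grand)
    vals, vecs = eigh(B, cov)
    order = np.argsort(vals)[::-1][: k - 1]
    return vecs[:, order]


def assign(model: LDAModel, X: np.ndarray,
           gene_ids: list[str] | None = None) -> AssignmentResult:
    """Posterior cluster assignment of target samples.

    ``X`` is samples x features in the model's shared-gene order. If
    ``gene_ids`` is given it must contain every shared gene; columns are
    reordered accordingly, and missing genes raise an error naming them.
    """
    X = np.asarray(X, dtype=float)
    if gene_ids is not None and model.shared_genes is not None:
        index = {g: i for i, g in enumerate(gene_ids)}
        missing = [g for g in model.shared_genes if g not in index]
        if missing:
            raise KeyError(f"target is missing shared genes: {missing[:10]}")
        X = X[:, [index[g] for g in model.shared_genes]]
    factor = cho_factor(model.pooled_covariance)
    k = len(model.classes)
    loglik = np.empty((X.shape[0], k))
    for i in range(k):
        diff = X - model.class_means[i]
        loglik[:, i] = -0.5 * np.sum(diff * cho_solve(factor, diff.T).T, axis=1)
    logpost = loglik + np.log(model.priors)
    posteriors = np.exp(logpost - logsumexp(logpost, axis=1, keepdims=True))
    label_idx = np.argmax(posteriors, axis=1)
    labels = model.classes[label_idx]
    avg = np.full((k, k), np.nan)
    for i in range(k):
        mask = label_idx == i
        if np.any(mask):
            avg[i] = posteriors[mask].mean(axis=0)
    return AssignmentResult(labels=labels, posteriors=posteriors,
                            avg_posterior=avg)


def bootstrap_stability(model: LDAModel, X: np.ndarray,
                        n_iterations: int = 1000, seed: int = 0,
                        ridge: float = 1e-3) -> BootstrapStability:
    """Bootstrap assessment of assignment stability.

    The target is assigned once with the given model to fix reference
    labels. Each iteration resamples the target samples with replacement,
    refits the LDA on the resample using the reference labels, and scores
    (a) the fraction of all original samples whose refit assignment
    matches the reference and (b) the mean silhouette of the reference
    partition in the refit model's discriminant space (Euclidean).
    Resamples missing a class, or leaving one with a single sample, are
    redrawn and counted.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    reference = assign(model, X).labels
    classes = np.unique(reference)
    n = X.shape[0]
    accs, sils = [], []
    redrawn = 0
    for _ in range(n_iterations):
        while True:
            idx = rng.integers(n, size=n)
            ref_res = reference[idx]
            if all(np.sum(ref_res == c) >= 2 for c in classes):
                break
            redrawn += 1
        refit = fit_lda(X[idx], ref_res, ridge=ridge)
        res = assign(refit, X)
        accs.append(float(np.mean(res.labels == reference)))
        proj = refit.transform(X)
        if proj.shape[1] == 0 or len(classes) < 2:
            sils.append(0.0)
        else:
            sils.append(float(silhouette_score(proj, reference)))
    accs = np.asarray(accs)
    sils = np.asarray(sils)
    return BootstrapStability(
        n_iterations=n_iterations,
        median_accuracy=float(np.median(accs)),
        accuracy_ci=(float(np.percentile(accs, 2.5)),
                     float(np.percentile(accs, 97.5))),
        median_silhouette=float(np.median(sils)),
        silhouette_ci=(float(np.percentile(sils, 2.5)),
                       float(np.percentile(sils, 97.5))),
        n_redrawn=redrawn,
    )


def match_clusters(reference: np.ndarray, denovo: np.ndarray) -> dict:
    """Optimal (Hungarian) matching of de-novo clusters to reference ones.

    Maximizes the total overlap on the contingency table; works when the
    two partitions have different numbers of clusters (unmatched clusters
    are logged).
    """
    ref_vals = np.unique(reference)
    new_vals = np.unique(denovo)
    table = np.array([[np.sum((reference == r) & (denovo == c))
                       for c in new_vals] for r in ref_vals])
    ri, ci = linear_sum_assignment(-table)
    mapping = {int(new_vals[c]): int(ref_vals[r]) for r, c in zip(ri, ci)}
    if len(new_vals) != len(ref_vals):
        logger.warning("cluster count mismatch: %d reference vs %d de novo",
                       len(ref_vals), len(new_vals))
    return mapping


def reverse_validate(target: ExpressionDataset, config: NsNMFConfig,
                     reference_labels: np.ndarray, n_top: int = 5000,
                     min_total_count: int = 10) -> dict[int, float]:
    """Re-cluster the target de novo and report per-cluster agreement.

    The target is preprocessed and clustered with nsNMF exactly as a
    discovery dataset would be; de-novo clusters are matched to the
    reference transfer labels by Hungarian assignment, and for each
    reference cluster the fraction of its samples recovered by the matched
    de-novo cluster is returned.
    """
    reference_labels = np.asarray(reference_labels)
    if target.data_kind == "counts":
        norm, top_genes = preprocess_counts(target, n_top=n_top,
                                            min_total_count=min_total_count)
        frame = norm.to_frame().loc[top_genes]
        V = frame.to_numpy()
    else:
        V = target.values
    _, cmodel = fit_cluster_model(V, config)
    mapping = match_clusters(reference_labels, cmodel.sample_labels)
    mapped = np.array([mapping.get(int(c), -1) for c in cmodel.sample_labels])
    overlaps: dict[int, float] = {}
    for r in np.unique(reference_labels):
        mask = reference_labels == r
        overlaps[int(r)] = float(np.mean(mapped[mask] == r))
    return overlaps
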