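"""Non-smooth NMF (nsNMF) consensus clustering.

nsNMF factorizes a non-negative expression matrix V (genes x samples) as
V ~ W S H, where S = (1 - theta) I + (theta / k) 11^T is a smoothing
matrix. As theta grows, S spreads each basis vector toward the uniform
vector, which forces sparseness onto W and H — the property that makes the
factorization useful for extracting compact cluster signatures.

Fitting uses multiplicative Kullback-Leibler updates in the Lee-Seung
form, with the effective basis W S when updating H and the effective
coefficients S H when updating W. Cluster structure is assessed by
consensus over many random restarts: samples co-cluster in a run when they
share the same argmax basis component, the consensus matrix averages this
connectivity over runs, and the rank k is chosen where the cophenetic
correlation of the consensus is maximal.

Informative genes are extracted with an entropy-based feature score on
row-normalized basis weights: a gene whose weight concentrates on one
component scores near 1, a flat gene scores 0, and genes above
median + 3 MAD of the score distribution form the cluster signatures, each
uniquely assigned to its argmax component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform

from .preprocess import mad

EPS = 1e-12


@dataclass
class NsNMFConfig:
    k: int = 3
    theta: float = 0.5
    n_runs: int = 100
    max_iter: int = 1000
    tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        if self.n_runs < 1 or self.max_iter < 1:
            raise ValueError("n_runs and max_iter must be >= 1")


@dataclass
class NsNMFFactorization:
    W: np.ndarray
    H: np.ndarray
    theta: float
    loss_trace: np.ndarray
    converged: bool


@dataclass
class ConsensusResult:
    k_values: list[int]
    consensus: dict[int, np.ndarray]
    cophenetic: dict[int, float]
    silhouette: dict[int, float]
    chosen_k: int


@dataclass
class ClusterModel:
    sample_labels: np.ndarray          # 1..k per sample
    gene_posteriors: np.ndarray        # genes x k, rows sum to 1
    informative_genes: dict[int, list[int]]  # cluster -> gene row indices
    feature_scores: np.ndarray
    zero_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def smoothing_matrix(k: int, theta: float) -> np.ndarray:
    return (1.0 - theta) * np.eye(k) + (theta / k) * np.ones((k, k))


def kl_divergence(V: np.ndarray, approx: np.ndarray) -> float:
    """Generalized KL divergence D(V || approx), the nsNMF loss."""
    L = np.maximum(approx, EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(V > 0, V * np.log(np.maximum(V, EPS) / L), 0.0)
    return float(np.sum(term - V + L))


def _init_factors(V: np.ndarray, k: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    # i.i.d. Uniform(0,1) scaled by the data mean keeps the initial model
    # on the scale of V
    scale = V.mean()
    return (rng.uniform(size=(V.shape[0], k)) * scale,
            rng.uniform(size=(k, V.shape[1])) * scale)


def nsnmf_factorize(V: np.ndarray, config: NsNMFConfig,
                    init: tuple[np.ndarray, np.ndarray] | None = None,
                    ) -> NsNMFFactorization:
    """Fit V ~ W S H by multiplicative KL updates.

    After each update pair, W columns are normalized to unit sum with the
    compensating rescale applied to H rows. Stops when the relative loss
    change drops below ``config.tol`` or at ``config.max_iter``.
    """
    V = np.asarray(V, dtype=float)
    if np.any(~np.isfinite(V)) or np.any(V < 0):
        raise ValueError("V must be finite and non-negative")
    if np.any(V.sum(axis=0) == 0):
        raise ValueError("V has all-zero columns")
    k = config.k
    if init is None:
        rng = np.random.default_rng(config.seed)
        W, H = _init_factors(V, k, rng)
    else:
        W, H = (np.array(init[0], dtype=float), np.array(init[1], dtype=float))
    S = smoothing_matrix(k, config.theta)
    ones = np.ones_like(V)
    trace = []
    converged = False
    for _ in range(config.max_iter):
        Ws = W @ S
        H *= (Ws.T @ (V / np.maximum(Ws @ H, EPS))) / np.maximum(Ws.T @ ones, EPS)
        Hs = S @ H
        W *= ((V / np.maximum(W @ Hs, EPS)) @ Hs.T) / np.maximum(ones @ Hs.T, EPS)
        col = np.maximum(W.sum(axis=0), EPS)
        W /= col
        H *= col[:, None]
        trace.append(kl_divergence(V, W @ S @ H))
        if len(trace) > 1:
            prev, cur = trace[-2], trace[-1]
            if abs(prev - cur) <= config.tol * max(abs(prev), EPS):
                converged = True
                break
    return NsNMFFactorization(W=W, H=H, theta=config.theta,
                              loss_trace=np.asarray(trace), converged=converged)


def assign_samples(fact: NsNMFFactorization) -> np.ndarray:
    """Hard sample labels 1..k: argmax basis component of each H column.

    Ties go to the lowest component index.
    """
    if np.any(fact.H.sum(axis=0) == 0):
        raise ValueError("H has all-zero columns; assignment undefined")
    return np.argmax(fact.H, axis=0) + 1


def _run_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(master_seed).spawn(n)


def consensus_cluster(V: np.ndarray, config: NsNMFConfig,
                      k_range: list[int]) -> ConsensusResult:
    """Rank scan: consensus clustering over random nsNMF restarts.

    For each k, ``config.n_runs`` factorizations from distinct seeded
    initializations produce connectivity matrices (1 where two samples
    share the same argmax component); the consensus is their mean. The
    cophenetic correlation between the consensus-derived distances
    (1 - consensus) and the dendrogram distances of their average-linkage
    clustering scores cluster stability; the chosen rank maximizes it
    (ties: smallest k).
    """
    V = np.asarray(V, dtype=float)
    n = V.shape[1]
    for k in k_range:
        if not 2 <= k <= n - 1:
            raise ValueError(f"k={k} outside valid range [2, {n - 1}]")
    consensus: dict[int, np.ndarray] = {}
    cophenetic: dict[int, float] = {}
    silhouette: dict[int, float] = {}
    seeds = _run_seeds(config.seed, len(k_range) * config.n_runs)
    si = 0
    for k in k_range:
        cfg_k = NsNMFConfig(k=k, theta=config.theta, n_runs=config.n_runs,
                            max_iter=config.max_iter, tol=config.tol,
                            seed=config.seed)
        C = np.zeros((n, n))
        for _ in range(config.n_runs):
            rng = np.random.default_rng(seeds[si])
            si += 1
            fact = nsnmf_factorize(V, cfg_k, init=_init_factors(V, k, rng))
            labels = assign_samples(fact)
            C += (labels[:, None] == labels[None, :]).astype(float)
        C /= config.n_runs
        np.fill_diagonal(C, 1.0)
        consensus[k] = C
        dist = squareform(1.0 - C, checks=False)
        Z = average(dist)
        if np.allclose(dist, dist[0]):
            # constant distances: cophenetic correlation undefined
            cophenetic[k] = 0.0
        else:
            cophenetic[k] = float(cophenet(Z, dist)[0])
        part = fcluster(Z, t=k, criterion="maxclust")
        silhouette[k] = _consensus_silhouette(1.0 - C, part)
    chosen = min(k_range, key=lambda k: (-round(cophenetic[k], 12), k))
    return ConsensusResult(k_values=list(k_range), consensus=consensus,
                           cophenetic=cophenetic, silhouette=silhouette,
                           chosen_k=chosen)


def _consensus_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import silhouette_score
    if len(np.unique(labels)) < 2:
        return 0.0
    return float(silhouette_score(dist, labels, metric="precomputed"))


def feature_scores(W: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Entropy-based per-gene scores from the basis matrix.

    Posterior p[g, j] = W[g, j] / sum_j W[g, j]; score
    f_g = 1 + (1 / log2 k) * sum_j p log2 p, with 0 log 0 := 0. One-hot
    rows score 1 (fully cluster-specific), uniform rows 0. All-zero W rows
    are flagged and excluded rather than normalized.
    """
    k = W.shape[1]
    rowsum = W.sum(axis=1)
    zero_rows = np.flatnonzero(rowsum == 0)
    p = np.zeros_like(W)
    ok = rowsum > 0
    p[ok] = W[ok] / rowsum[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    f = np.full(W.shape[0], np.nan)
    if k > 1:
        f[ok] = 1.0 + plogp[ok].sum(axis=1) / np.log2(k)
    else:
        f[ok] = 1.0
    return p, f, zero_rows


MAD_CONSISTENCY = 1.4826  # scales MAD to the SD of a normal sample


def extract_informative_genes(fact: NsNMFFactorization,
                              mad_multiplier: float = 3.0,
                              mad_scale: float = MAD_CONSISTENCY,
                              ) -> ClusterModel:
    """Cluster signatures by the Kim-Park feature-extraction convention.

    A gene is informative iff (a) its feature score exceeds
    median + ``mad_multiplier`` * MAD of the score distribution, with the
    MAD scaled by the usual normal-consistency constant 1.4826, and
    (b) its maximum basis contribution exceeds the median of all basis
    entries, which screens out low-expression genes whose scores are high
    only through row normalization. Each informative gene is uniquely
    assigned to its argmax basis component, so signatures are disjoint by
    construction.
    """
    p, f, zero_rows = feature_scores(fact.W)
    ok = ~np.isnan(f)
    cutoff = np.median(f[ok]) + mad_multiplier * mad_scale * mad(f[ok])
    basis_ok = fact.W.max(axis=1) > np.median(fact.W)
    informative = np.flatnonzero(ok & (f > cutoff) & basis_ok)
    assigned = np.argmax(fact.W, axis=1)
    k = fact.W.shape[1]
    sets: dict[int, list[int]] = {j: [] for j in range(1, k + 1)}
    for g in informative:
        sets[int(assigned[g]) + 1].append(int(g))
    return ClusterModel(sample_labels=assign_samples(fact),
                        gene_posteriors=p,
                        informative_genes=sets,
                        feature_scores=f,
                        zero_rows=zero_rows)


def fit_cluster_model(V: np.ndarray, config: NsNMFConfig) -> tuple[
        NsNMFFactorization, ClusterModel]:
    """Best-of-``n_runs`` nsNMF fit at fixed k plus signature extraction.

    Runs ``config.n_runs`` seeded restarts and keeps the factorization
    with the lowest final KL loss.
    """
    best = None
    for ss in _run_seeds(config.seed, config.n_runs):
        rng = np.random.default_rng(ss)
        fact = nsnmf_factorize(V, config,
                               init=_init_factors(V, config.k, rng))
        if best is None or fact.loss_trace[-1] < best.loss_trace[-1]:
            best = fact
    return best, extract_informative_genes(best)
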