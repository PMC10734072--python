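"""Cross-validated validation of cluster gene signatures.

A cluster signature is considered discriminative if a regularized
logistic-regression classifier supplied with the signature genes can
separate two sample groups (e.g. cases vs controls, or motor cortex vs
another brain region) under stratified 10-fold cross-validation. Because
signature genes are co-expressed and therefore collinear, three feature
scenarios are compared:

1. ``all_genes`` — every signature gene present in the dataset;
2. ``decollinear_per_fold`` — within each training fold, features are
   ranked by ANOVA F-value against the labels and accepted greedily only
   if their absolute Pearson correlation with every already-accepted
   feature stays below a threshold (default 0.4);
3. ``fold_stable_subset`` — the decollinear sets of all folds are
   intersected and the cross-validation is rerun on that fixed subset.

Per fold, standardization, minority oversampling (SMOTE), and feature
selection are fit on the training portion only, so the held-out estimates
carry no information leakage. A baseline repeats the analysis on random
gene draws of the same size; on data where the signal lives only in the
signature, it must stay at chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (f1_score, precision_score, recall_score,
                             roc_auc_score)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler

SCENARIOS = ("all_genes", "decollinear_per_fold", "fold_stable_subset")


@dataclass
class ScenarioSpec:
    scenario: str = "all_genes"
    correlation_threshold: float = 0.4
    n_folds: int = 10
    shuffle: bool = True
    seed: int = 0
    c_grid: tuple = (0.01, 0.1, 1.0, 10.0)
    inner_folds: int = 10
    smote_k_neighbors: int = 5

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not 0 < self.correlation_threshold < 1:
            raise ValueError("correlation_threshold must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class CVResult:
    roc_auc: tuple[float, float]     # (mean, sd) over folds
    precision: tuple[float, float]
    recall: tuple[float, float]
    f1: tuple[float, float]
    per_fold: dict[str, np.ndarray] = field(default_factory=dict)
    fold_features: list[list[int]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {m: {"mean": getattr(self, m)[0], "sd": getattr(self, m)[1]}
                for m in ("roc_auc", "precision", "recall", "f1")}


def stratified_folds(labels: np.ndarray, n_folds: int = 10,
                     seed: int = 0) -> list[np.ndarray]:
    """Test-index sets of a shuffled stratified k-fold partition."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if np.any(counts < n_folds):
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than "
            f"{n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def smote_oversample(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling.

    New minority points are ``x_i + u * (x_nn - x_i)`` with
    u ~ Uniform(0, 1) and ``x_nn`` one of the k nearest minority
    neighbors of ``x_i``. Returns equal-sized classes; balanced input is
    returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE here is binary-only")
    if counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("minority class of 1 sample cannot be oversampled")
    k = k_neighbors
    if n_min <= k:
        k = n_min - 1
        warnings.warn(f"minority class of {n_min}: k_neighbors reduced to {k}")
    Xm = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, neigh = nn.kneighbors(Xm)
    rng = np.random.default_rng(seed)
    n_new = n_maj - n_min
    base = rng.integers(n_min, size=n_new)
    pick = neigh[base, rng.integers(1, k + 1, size=n_new)]
    u = rng.uniform(size=(n_new, 1))
    X_new = Xm[base] + u * (Xm[pick] - Xm[base])
    return (np.vstack([X, X_new]),
            np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)]))


def select_noncollinear(X: np.ndarray, y: np.ndarray,
                        threshold: float = 0.4) -> list[int]:
    """Greedy decollinearization: F-ranked accept-if-compatible.

    Features are ranked by ANOVA F-value against ``y`` (descending); a
    feature is accepted iff its absolute Pearson correlation with every
    already-accepted feature is below ``threshold``. Returns column
    indices in acceptance order; at worst the single top-F feature.
    """
    X = np.asarray(X, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, _ = f_classif(X, y)
    F = np.where(np.isfinite(F), F, -np.inf)
    order = np.argsort(-F, kind="stable")
    sd = X.std(axis=0)
    accepted: list[int] = []
    for j in order:
        ok = True
        for a in accepted:
            if sd[j] == 0 or sd[a] == 0:
                r = 1.0  # constant features are degenerate duplicates
            else:
                r = np.corrcoef(X[:, j], X[:, a])[0, 1]
            if abs(r) >= threshold:
                ok = False
                break
        if ok:
            accepted.append(int(j))
    if not accepted:
        accepted = [int(order[0])]
    return accepted


def _fit_and_score(X_tr, y_tr, X_te, y_te, spec: ScenarioSpec, seed: int):
    inner = StratifiedKFold(n_splits=min(spec.inner_folds,
                                         int(np.bincount(y_tr).min())),
                            shuffle=True, random_state=seed)
    grid = GridSearchCV(
        LogisticRegression(max_iter=2000),
        {"C": list(spec.c_grid)}, scoring="roc_auc", cv=inner)
    grid.fit(X_tr, y_tr)
    prob = grid.predict_proba(X_te)[:, 1]
    pred = grid.predict(X_te)
    return {
        "roc_auc": roc_auc_score(y_te, prob),
        "precision": precision_score(y_te, pred, zero_division=0),
        "recall": recall_score(y_te, pred, zero_division=0),
        "f1": f1_score(y_te, pred, zero_division=0),
    }


def run_scenario(X: np.ndarray, labels: np.ndarray,
                 spec: ScenarioSpec,
                 fixed_features: list[int] | None = None) -> CVResult:
    """Cross-validated signature classifier under one scenario.

    ``X`` is samples x genes (the matrix already restricted to the
    signature), ``labels`` binary. Per fold: standardize (training fit),
    SMOTE the training portion, select features per scenario, grid-search
    an L2 logistic model by inner-CV ROC AUC, and score the held-out fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must be binary")
    y01 = (y == classes[1]).astype(int)
    folds = stratified_folds(y01, spec.n_folds, spec.seed)
    metrics = {m: [] for m in ("roc_auc", "precision", "recall", "f1")}
    fold_features: list[list[int]] = []
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y01)), test_idx)
        scaler = StandardScaler().fit(X[train_idx])
        X_tr = scaler.transform(X[train_idx])
        X_te = scaler.transform(X[test_idx])
        y_tr, y_te = y01[train_idx], y01[test_idx]
        X_tr, y_tr = smote_oversample(X_tr, y_tr, spec.smote_k_neighbors,
                                      seed=spec.seed + 7919 * fi)
        if fixed_features is not None:
            feats = list(fixed_features)
        elif spec.scenario == "decollinear_per_fold":
            feats = select_noncollinear(X_tr, y_tr,
                                        spec.correlation_threshold)
        else:
            feats = list(range(X.shape[1]))
        fold_features.append(feats)
        scores = _fit_and_score(X_tr[:, feats], y_tr, X_te[:, feats], y_te,
                                spec, seed=spec.seed + fi)
        for m, v in scores.items():
            metrics[m].append(v)
    per_fold = {m: np.asarray(v) for m, v in metrics.items()}
    result = CVResult(
        roc_auc=(per_fold["roc_auc"].mean(), per_fold["roc_auc"].std(ddof=1)),
        precision=(per_fold["precision"].mean(),
                   per_fold["precision"].std(ddof=1)),
        recall=(per_fold["recall"].mean(), per_fold["recall"].std(ddof=1)),
        f1=(per_fold["f1"].mean(), per_fold["f1"].std(ddof=1)),
        per_fold=per_fold, fold_features=fold_features,
    )
    return result


def run_scenario_3(X: np.ndarray, labels: np.ndarray,
                   spec: ScenarioSpec) -> CVResult:
    """Fold-stable subset: intersect per-fold decollinear sets, rerun CV."""
    spec2 = ScenarioSpec(scenario="decollinear_per_fold",
                         correlation_threshold=spec.correlation_threshold,
                         n_folds=spec.n_folds, shuffle=spec.shuffle,
                         seed=spec.seed, c_grid=spec.c_grid,
                         inner_folds=spec.inner_folds,
                         smote_k_neighbors=spec.smote_k_neighbors)
    first = run_scenario(X, labels, spec2)
    stable = set(first.fold_features[0])
    for feats in first.fold_features[1:]:
        stable &= set(feats)
    if not stable:
        sizes = [len(f) for f in first.fold_features]
        raise ValueError(
            f"no feature is decollinear in every fold (per-fold set sizes "
            f"{sizes})"
        )
    return run_scenario(X, labels, spec, fixed_features=sorted(stable))


def validate_signature(X: np.ndarray, labels: np.ndarray,
                       spec: ScenarioSpec) -> CVResult:
    """Dispatch on ``spec.scenario``."""
    if spec.scenario == "fold_stable_subset":
        return run_scenario_3(X, labels, spec)
    return run_scenario(X, labels, spec)


def random_gene_baseline(X_full: np.ndarray, labels: np.ndarray,
                         n_genes_per_draw: int, spec: ScenarioSpec,
                         n_classifiers: int = 10, seed: int = 0,
                         exclude: list[int] | None = None) -> tuple[CVResult, list[np.ndarray]]:
    """Chance baseline: repeat the scenario on random gene draws.

    Draws ``n_genes_per_draw`` columns without replacement (optionally
    excluding e.g. the signature genes) ``n_classifiers`` times, runs the
    scenario on each draw, and averages the metrics across classifiers.
    """
    X_full = np.asarray(X_full, dtype=float)
    pool = np.arange(X_full.shape[1])
    if exclude is not None:
        pool = np.setdiff1d(pool, np.asarray(exclude))
    if len(pool) < n_genes_per_draw:
        raise ValueError(
            f"pool of {len(pool)} genes is smaller than draw size "
            f"{n_genes_per_draw}"
        )
    rng = np.random.default_rng(seed)
    draws, results = [], []
    for _ in range(n_classifiers):
        draw = rng.choice(pool, size=n_genes_per_draw, replace=False)
        draws.append(np.sort(draw))
        results.append(validate_signature(X_full[:, draws[-1]], labels, spec))
    def agg(metric):
        means = np.array([getattr(r, metric)[0] for r in results])
        return (float(means.mean()), float(means.std(ddof=1)))
    averaged = CVResult(roc_auc=agg("roc_auc"), precision=agg("precision"),
                        recall=agg("recall"), f1=agg("f1"))
    return averaged, draws
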