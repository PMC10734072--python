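"""Cluster-phenotype association statistics.

Categorical phenotypes (sex, C9orf72 carrier status, site of onset) are
tested against cluster membership with Pearson's chi-square test of
independence on contingency tables, without continuity correction.
Continuous phenotypes (ages, disease duration, omics-derived measures)
are compared across clusters with a one-way ANCOVA adjusted for
covariates (typically sex assigned at birth), followed by Tukey's HSD
post-hoc on the covariate-adjusted cluster means. Each continuous
variable first passes a Shapiro-Wilk normality gate: if normality is
rejected at alpha the variable is natural-log transformed (values must be
positive; no silent shifting).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ContingencyTable:
    observed: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        if self.observed.ndim != 2:
            raise ValueError("observed must be 2-D")
        if np.any(self.observed < 0):
            raise ValueError("negative counts")
        if self.observed.shape[0] < 2 or self.observed.shape[1] < 2:
            raise ValueError("need at least 2 rows and 2 columns")


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray


@dataclass
class AncovaResult:
    f_statistic: float
    p_value: float
    df_num: int
    df_den: int
    adjusted_means: dict
    tukey_p: dict
    transform_applied: str = "none"


def build_binary_table(positives, totals, category: str = "positive",
                       col_labels: list[str] | None = None) -> ContingencyTable:
    """2 x k table of a binary category against clusters.

    Row 1 holds the per-cluster counts of the category, row 2 the
    complements against the cluster totals.
    """
    positives = np.asarray(positives, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if positives.shape != totals.shape:
        raise ValueError("positives and totals must align")
    if np.any(positives > totals):
        raise ValueError("positives exceed cluster totals")
    observed = np.vstack([positives, totals - positives])
    cols = col_labels or [f"cluster_{i + 1}" for i in range(len(totals))]
    return ContingencyTable(observed=observed,
                            row_labels=[category, f"not_{category}"],
                            col_labels=cols)


def chi_square_independence(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of independence (no continuity correction)."""
    obs = table.observed
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero row or column marginal: test undefined")
    statistic, p, df, expected = stats.chi2_contingency(obs, correction=False)
    return ChiSquareResult(statistic=float(statistic), df=int(df),
                           p_value=float(p), expected=expected)


def _design(clusters: np.ndarray, covariates: pd.DataFrame | None) -> tuple:
    """Full and reduced design matrices (dummy-coded cluster factor)."""
    levels = np.unique(clusters)
    n = len(clusters)
    dummies = np.column_stack([(clusters == lv).astype(float)
                               for lv in levels[1:]])
    cov = (covariates.to_numpy(dtype=float)
           if covariates is not None and covariates.shape[1] else
           np.empty((n, 0)))
    intercept = np.ones((n, 1))
    X_full = np.hstack([intercept, dummies, cov])
    X_red = np.hstack([intercept, cov])
    return X_full, X_red, levels


def ancova_oneway(outcome, clusters, covariates: pd.DataFrame | None = None,
                  normality_alpha: float | None = None) -> AncovaResult:
    """One-way ANCOVA for the cluster factor adjusted for covariates.

    The F statistic compares the full linear model (intercept + cluster
    dummies + covariates) against the reduced model omitting the cluster
    dummies. Categorical covariates must be pre-encoded as numeric
    columns. Rows with missing values are dropped listwise. If
    ``normality_alpha`` is given, the outcome first passes
    :func:`normality_gate` at that alpha.
    """
    outcome = np.asarray(outcome, dtype=float)
    clusters = np.asarray(clusters)
    if covariates is not None:
        covariates = pd.DataFrame(covariates).reset_index(drop=True)
        keep = np.isfinite(outcome) & ~covariates.isna().any(axis=1).to_numpy()
    else:
        keep = np.isfinite(outcome)
    outcome, clusters = outcome[keep], clusters[keep]
    if covariates is not None:
        covariates = covariates.loc[keep].reset_index(drop=True)
    transform = "none"
    if normality_alpha is not None:
        outcome, decision = normality_gate(outcome, alpha=normality_alpha)
        transform = decision
    levels, counts = np.unique(clusters, return_counts=True)
    if len(levels) < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 clusters each with >= 2 observations")
    X_full, X_red, levels = _design(clusters, covariates)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design: aliased columns")
    beta_full, rss_full = _ols(X_full, outcome)
    _, rss_red = _ols(X_red, outcome)
    n, p_full = X_full.shape
    df_num = len(levels) - 1
    df_den = n - p_full
    f_stat = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    p = float(stats.f.sf(f_stat, df_num, df_den))
    # covariate-adjusted cluster means: prediction at the covariate mean
    cov_mean = (covariates.to_numpy(dtype=float).mean(axis=0)
                if covariates is not None and covariates.shape[1] else
                np.empty(0))
    adj = {}
    for i, lv in enumerate(levels):
        dummy = np.zeros(len(levels) - 1)
        if i > 0:
            dummy[i - 1] = 1.0
        x = np.concatenate([[1.0], dummy, cov_mean])
        adj[lv] = float(x @ beta_full)
    s2 = rss_full / df_den
    sizes = {lv: int(c) for lv, c in zip(levels, counts)}
    tukey = tukey_hsd(adj, sizes, s2, df_den)
    return AncovaResult(f_statistic=float(f_stat), p_value=p,
                        df_num=df_num, df_den=df_den, adjusted_means=adj,
                        tukey_p=tukey, transform_applied=transform)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def tukey_hsd(adjusted_means: dict, group_sizes: dict, residual_variance: float,
              df_resid: int) -> dict:
    """Tukey HSD p-values on (adjusted) group means.

    The studentized-range statistic for groups i, j is
    ``q = |m_i - m_j| / sqrt(s^2 / 2 * (1/n_i + 1/n_j))`` with the model's
    residual variance ``s^2``; p-values come from the studentized range
    distribution with k groups and ``df_resid`` degrees of freedom.
    """
    groups = sorted(adjusted_means)
    k = len(groups)
    if k < 2:
        raise ValueError("Tukey HSD needs >= 2 groups")
    out = {}
    for a, b in itertools.combinations(groups, 2):
        se = np.sqrt(residual_variance / 2.0 *
                     (1.0 / group_sizes[a] + 1.0 / group_sizes[b]))
        q = abs(adjusted_means[a] - adjusted_means[b]) / se
        out[(a, b)] = float(stats.studentized_range.sf(q, k, df_resid))
    return out


def normality_gate(values: np.ndarray, alpha: float = 0.05,
                   ) -> tuple[np.ndarray, str]:
    """Shapiro-Wilk gate: log-transform non-normal variables.

    Returns the (possibly natural-log transformed) values and the decision
    ("keep" or "log"). A required log transform on non-positive values
    raises instead of shifting silently.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(values) == 0:
        raise ValueError("constant values: normality test undefined")
    _, p = stats.shapiro(values)
    if p >= alpha:
        return values, "keep"
    if np.any(values <= 0):
        raise ValueError(
            "log transform required by the normality gate but values are "
            "not all positive; transform or rescale the variable upstream"
        )
    return np.log(values), "log"


def categorical_association_tests(pheno: pd.DataFrame,
                                  labels: np.ndarray) -> pd.DataFrame:
    """Chi-square tests of the standard categorical phenotypes.

    Builds 2 x k binary tables (category vs complement across clusters)
    for sex (male), C9orf72 positivity, and each onset-site level present,
    skipping any category with a zero marginal.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    totals = np.array([np.sum(labels == c) for c in clusters], dtype=float)
    rows = []

    def add(category, mask):
        positives = np.array([np.sum(mask & (labels == c)) for c in clusters],
                             dtype=float)
        if positives.sum() == 0 or positives.sum() == totals.sum():
            return
        table = build_binary_table(positives, totals, category=category)
        res = chi_square_independence(table)
        rows.append({"category": category, "statistic": res.statistic,
                     "df": res.df, "p_value": res.p_value})

    if "sex" in pheno:
        add("male", pheno["sex"].to_numpy() == "M")
    if "c9_status" in pheno:
        add("c9_positive", pheno["c9_status"].to_numpy() == "positive")
    if "onset_site" in pheno:
        for level in pd.unique(pheno["onset_site"]):
            add(f"{level}_onset", pheno["onset_site"].to_numpy() == level)
    return pd.DataFrame(rows)
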