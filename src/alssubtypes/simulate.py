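"""Synthetic bulk-expression data with planted molecular subtypes.

The generator emulates the structure the subtyping pipeline assumes: a
discovery cohort of cases whose samples fall into ``k`` latent clusters,
each marked by a disjoint block of up-regulated signature genes on top of
shared per-gene baselines; negative-binomial counting noise with
library-size variation; an independent validation cohort observed on a
restricted gene panel (emulating a different platform or annotation); a
signature-free control cohort; and per-sample demographic/clinical tables
whose distributions are cluster-conditional.

Counts are negative binomial with mean ``mu`` and dispersion ``alpha``
(variance ``mu + alpha * mu**2``), the noise model underlying
median-of-ratios normalization of bulk RNA-seq.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionDataset

# Cluster-conditional phenotype distributions. The defaults mirror the
# demographic profile of a three-subtype sporadic-ALS motor-cortex cohort:
# a dominant cluster (~54%) holding nearly all C9orf72 carriers and with
# earlier onset, a small later-onset cluster, and an intermediate cluster.
DEFAULT_PHENOTYPE_MODEL: dict = {
    "sex": {  # P(male) per cluster
        1: 35 / 60, 2: 15 / 28, 3: 15 / 24,
    },
    "c9_status": {  # P(C9orf72 expansion carrier) per cluster
        1: 7 / 60, 2: 1 / 28, 3: 0.0,
    },
    "onset_site": {  # P(limb), P(bulbar), P(limb_and_bulbar) per cluster
        1: (36 / 52, 15 / 52, 1 / 52),
        2: (10 / 18, 7 / 18, 1 / 18),
        3: (17 / 22, 5 / 22, 0.0),
    },
    "age_onset": {  # Normal(mean, sd), years
        1: (58.8, 11.6), 2: (65.7, 12.3), 3: (61.7, 15.7),
    },
    "duration": {  # log-normal(meanlog, sdlog), years from onset to death
        1: (1.15, 0.55), 2: (0.83, 0.55), 3: (0.87, 0.55),
    },
}

ONSET_LEVELS = ("limb", "bulbar", "limb_and_bulbar")


@dataclass
class SyntheticConfig:
    """Parameters of the planted-subtype generative model.

    Defaults describe a discovery cohort of 120 cases, 2000 genes, three
    clusters each marked by 50 signature genes up-regulated by
    ``log2_fold_change`` = 2 (a four-fold mean shift) in their own cluster.
    """

    n_genes: int = 2000
    n_samples: int = 120
    k_clusters: int = 3
    signature_size: int = 50
    log2_fold_change: float = 2.0
    nb_dispersion: float = 0.2
    libsize_log_sd: float = 0.2
    baseline_log_mean: float = 3.5
    baseline_log_sd: float = 1.0
    cluster_proportions: tuple | None = None
    nonautosomal_fraction: float = 0.05
    phenotype_model: dict = field(default_factory=lambda: DEFAULT_PHENOTYPE_MODEL)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_proportions is None:
            self.cluster_proportions = tuple(
                [1.0 / self.k_clusters] * self.k_clusters
            )
        props = np.asarray(self.cluster_proportions, dtype=float)
        if len(props) != self.k_clusters:
            raise ValueError("cluster_proportions length must equal k_clusters")
        if abs(props.sum() - 1.0) > 1e-12:
            raise ValueError("cluster_proportions must sum to 1")
        if np.any(props < 0):
            raise ValueError("cluster_proportions must be non-negative")
        if self.signature_size * self.k_clusters > self.n_genes:
            raise ValueError(
                "signature_size * k_clusters exceeds n_genes: disjoint "
                "signature blocks do not fit"
            )
        for name in ("nb_dispersion", "libsize_log_sd", "baseline_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.log2_fold_change < 0:
            raise ValueError("log2_fold_change must be >= 0")
        if not 0 <= self.nonautosomal_fraction < 1:
            raise ValueError("nonautosomal_fraction must be in [0, 1)")


def gene_baselines(config: SyntheticConfig) -> np.ndarray:
    """Per-gene baseline mean counts, log-normal across genes.

    Derived from a dedicated substream of ``config.seed`` so that discovery
    and control datasets built from the same config share gene baselines.
    """
    rng = np.random.default_rng([config.seed, 101])
    return rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                         size=config.n_genes)


def signature_blocks(config: SyntheticConfig) -> dict[int, np.ndarray]:
    """Disjoint signature gene indices per cluster (1..k), seed-determined."""
    rng = np.random.default_rng([config.seed, 102])
    order = rng.permutation(config.n_genes)
    return {
        j + 1: np.sort(order[j * config.signature_size:(j + 1) * config.signature_size])
        for j in range(config.k_clusters)
    }


def _chromosomes(config: SyntheticConfig) -> list[str]:
    # Round-robin over autosomes; a trailing fraction goes to X/Y/MT so the
    # autosome filter always has something to remove.
    n_nonauto = int(round(config.nonautosomal_fraction * config.n_genes))
    n_auto = config.n_genes - n_nonauto
    labels = [str(1 + i % 22) for i in range(n_auto)]
    labels += [("X", "Y", "MT")[i % 3] for i in range(n_nonauto)]
    return labels


def _sample_counts(mean: np.ndarray, alpha: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw NB(mean, dispersion alpha) counts; Poisson in the alpha -> 0 limit."""
    if alpha == 0:
        return rng.poisson(mean).astype(float)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p).astype(float)


def _draw_labels(config: SyntheticConfig, n_samples: int,
                 rng: np.random.Generator) -> np.ndarray:
    labels = rng.choice(np.arange(1, config.k_clusters + 1), size=n_samples,
                        p=np.asarray(config.cluster_proportions, dtype=float))
    # guarantee every cluster is represented when feasible
    if n_samples >= config.k_clusters:
        for j in range(1, config.k_clusters + 1):
            if not np.any(labels == j):
                labels[rng.integers(n_samples)] = j
    return labels


def _expression_matrix(config: SyntheticConfig, labels: np.ndarray,
                       gene_subset: np.ndarray | None,
                       rng: np.random.Generator,
                       platform_shift_sd: float = 0.0) -> np.ndarray:
    base = gene_baselines(config)
    sigs = signature_blocks(config)
    n = len(labels)
    libsize = rng.lognormal(0.0, config.libsize_log_sd, size=n)
    fold = 2.0 ** config.log2_fold_change
    shift = (rng.lognormal(0.0, platform_shift_sd, size=config.n_genes)
             if platform_shift_sd > 0 else np.ones(config.n_genes))
    mean = np.outer(base * shift, libsize)
    for j, idx in sigs.items():
        in_cluster = labels == j
        if np.any(in_cluster):
            mean[np.ix_(idx, in_cluster)] *= fold
    if gene_subset is not None:
        mean = mean[gene_subset]
    counts = _sample_counts(mean, config.nb_dispersion, rng)
    return counts, libsize


def generate_phenotypes(labels: np.ndarray, sample_ids: list[str],
                        model: dict, seed: int) -> pd.DataFrame:
    """Cluster-conditional demographic/clinical table.

    Columns match the phenotype tests downstream: sex, C9orf72 carrier
    status, site of onset, age at onset/death (years), disease duration.
    """
    rng = np.random.default_rng([seed, 103])
    rows = []
    for s, lab in zip(sample_ids, labels):
        lab = int(lab)
        sex = "M" if rng.random() < model["sex"][lab] else "F"
        c9 = "positive" if rng.random() < model["c9_status"][lab] else "negative"
        onset_site = ONSET_LEVELS[
            rng.choice(3, p=np.asarray(model["onset_site"][lab]) /
                       np.sum(model["onset_site"][lab]))
        ]
        mu, sd = model["age_onset"][lab]
        age_onset = rng.normal(mu, sd)
        mlog, slog = model["duration"][lab]
        duration = rng.lognormal(mlog, slog)
        rows.append({
            "sample_id": s, "cluster": lab, "sex": sex, "c9_status": c9,
            "onset_site": onset_site, "age_onset": round(age_onset, 1),
            "age_death": round(age_onset + duration, 1),
            "disease_duration": round(duration, 2),
        })
    return pd.DataFrame(rows)


def generate_discovery(config: SyntheticConfig) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Discovery cohort: planted clusters, signatures, and phenotypes.

    Returns the counts dataset (with ground truth attached) and the
    matching phenotype table.
    """
    rng = np.random.default_rng([config.seed, 104])
    labels = _draw_labels(config, config.n_samples, rng)
    counts, libsize = _expression_matrix(config, labels, None, rng)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    sigs = signature_blocks(config)
    truth = {
        "labels": labels,
        "signatures": {j: [gene_ids[i] for i in idx] for j, idx in sigs.items()},
        "libsize": libsize,
        "config": config,
    }
    ds = ExpressionDataset(values=counts, gene_ids=gene_ids,
                           sample_ids=sample_ids,
                           chromosome=_chromosomes(config),
                           data_kind="counts", truth=truth)
    pheno = generate_phenotypes(labels, sample_ids, config.phenotype_model,
                                config.seed)
    return ds, pheno


def generate_validation(discovery: ExpressionDataset, gene_keep_fraction: float,
                        platform_shift_sd: float, n_samples: int,
                        seed: int) -> ExpressionDataset:
    """Independent cohort from the same cluster model on a restricted panel.

    New samples are drawn from the discovery generative model; only a random
    fraction of genes is observed, with an optional per-gene multiplicative
    platform shift (log-normal, sd on the log scale).
    """
    if discovery.truth is None or "config" not in discovery.truth:
        raise ValueError("discovery dataset carries no generative truth")
    if not 0 < gene_keep_fraction <= 1:
        raise ValueError("gene_keep_fraction must be in (0, 1]")
    if platform_shift_sd < 0:
        raise ValueError("platform_shift_sd must be >= 0")
    config: SyntheticConfig = discovery.truth["config"]
    rng = np.random.default_rng([seed, 105])
    n_keep = int(round(gene_keep_fraction * config.n_genes))
    if gene_keep_fraction == 1.0:
        keep = np.arange(config.n_genes)
    else:
        keep = np.sort(rng.choice(config.n_genes, size=n_keep, replace=False))
    sigs = signature_blocks(config)
    keep_set = set(keep.tolist())
    for j, idx in sigs.items():
        retained = sum(1 for i in idx if i in keep_set)
        if retained < 2:
            raise ValueError(
                f"gene_keep_fraction={gene_keep_fraction} leaves only "
                f"{retained} genes of the cluster-{j} signature"
            )
    labels = _draw_labels(config, n_samples, rng)
    counts, libsize = _expression_matrix(config, labels, keep, rng,
                                         platform_shift_sd=platform_shift_sd)
    gene_ids = [f"G{i:05d}" for i in keep]
    sample_ids = [f"V{i:04d}" for i in range(n_samples)]
    chrom_all = _chromosomes(config)
    truth = {
        "labels": labels,
        "signatures": {j: [f"G{i:05d}" for i in idx if i in keep_set]
                       for j, idx in sigs.items()},
        "libsize": libsize,
        "config": config,
    }
    return ExpressionDataset(values=counts, gene_ids=gene_ids,
                             sample_ids=sample_ids,
                             chromosome=[chrom_all[i] for i in keep],
                             data_kind="counts", truth=truth)


def generate_control(config: SyntheticConfig, n_samples: int,
                     seed: int) -> ExpressionDataset:
    """Signature-free cohort: all samples exchangeable draws of the baseline."""
    rng = np.random.default_rng([seed, 106])
    base = gene_baselines(config)
    libsize = rng.lognormal(0.0, config.libsize_log_sd, size=n_samples)
    mean = np.outer(base, libsize)
    counts = _sample_counts(mean, config.nb_dispersion, rng)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    sample_ids = [f"C{i:04d}" for i in range(n_samples)]
    return ExpressionDataset(values=counts, gene_ids=gene_ids,
                             sample_ids=sample_ids,
                             chromosome=_chromosomes(config),
                             data_kind="counts", truth=None)
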