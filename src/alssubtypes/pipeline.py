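"""End-to-end pipeline driver and YAML configuration.

The demo pipeline exercises every stage on synthetic data: simulate a
discovery cohort with planted subtypes, preprocess and cluster it with
nsNMF, transfer the clusters to a simulated validation cohort via LDA
with bootstrap stability, validate the first cluster's signature with the
case-control classifier framework against simulated controls, and run the
cluster-phenotype association tests. Every artifact is reproducible from
(config, master seed); the manifest records parameters and SHA-256 hashes
of each output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as asio
from .nsnmf import NsNMFConfig, consensus_cluster, fit_cluster_model
from .phenotype import ancova_oneway, categorical_association_tests
from .preprocess import preprocess_counts
from .signature import ScenarioSpec, validate_signature
from .simulate import SyntheticConfig, generate_control, generate_discovery, \
    generate_validation
from .transfer import assign, bootstrap_stability, fit_lda, intersect_genes, \
    reverse_validate

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed", "out_dir", "synthetic", "preprocess", "nsnmf", "k_scan",
    "transfer", "signature", "phenotype", "log_level",
}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "pipeline_out"
    synthetic: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=lambda: {
        "min_total_count": 10, "n_top": 1000})
    nsnmf: dict = field(default_factory=lambda: {
        "k": 3, "theta": 0.5, "n_runs": 20, "max_iter": 1000, "tol": 1e-5})
    k_scan: list = field(default_factory=lambda: [2, 3, 4])
    transfer: dict = field(default_factory=lambda: {
        "gene_keep_fraction": 0.6, "platform_shift_sd": 0.0,
        "n_samples": 60, "bootstrap_iterations": 200})
    signature: dict = field(default_factory=lambda: {
        "n_controls": 60, "scenarios": ["all_genes"], "baseline_draws": 0})
    phenotype: dict = field(default_factory=lambda: {
        "continuous": ["age_onset", "age_death"], "covariates": ["sex"]})
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _seed(master: int, stream: int) -> int:
    return int(np.random.SeedSequence([master, stream]).generate_state(1)[0]
               % (2 ** 31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return the manifest (also written to disk)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "parameters": asdict(config),
                      "stages": {}, "hashes": {}}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["hashes"][name] = _sha256(path)

    # --- simulate ---------------------------------------------------------
    syn = SyntheticConfig(**{**config.synthetic,
                             "seed": _seed(config.seed, 1)})
    discovery, pheno = generate_discovery(syn)
    emit("discovery_counts.tsv", lambda p: asio.write_expression(discovery, p))
    emit("discovery_annotation.tsv",
         lambda p: asio.write_annotation(discovery, p))
    emit("discovery_truth.json", lambda p: asio.write_truth(discovery, p))
    emit("phenotypes.csv", lambda p: pheno.to_csv(p, index=False))
    manifest["stages"]["simulate"] = {"n_genes": syn.n_genes,
                                      "n_samples": syn.n_samples}

    # --- preprocess -------------------------------------------------------
    norm, top_genes = preprocess_counts(discovery, **config.preprocess)
    emit("vst_matrix.tsv", lambda p: norm.to_frame().to_csv(p, sep="\t"))
    manifest["stages"]["preprocess"] = {
        "n_genes_kept": len(norm.gene_ids),
        "n_top": len(top_genes),
        "removed": {k: len(v) for k, v in norm.genes_removed.items()},
    }

    # --- cluster ----------------------------------------------------------
    V = norm.to_frame().loc[top_genes].to_numpy()
    nscfg = NsNMFConfig(**{**config.nsnmf, "seed": _seed(config.seed, 2)})
    scan = consensus_cluster(V, nscfg, list(config.k_scan))
    fact, cmodel = fit_cluster_model(V, nscfg)
    labels = cmodel.sample_labels
    signatures = {j: [top_genes[i] for i in idx]
                  for j, idx in cmodel.informative_genes.items()}
    emit("cluster_labels.tsv", lambda p: _write_labels(
        p, discovery.sample_ids, labels))
    emit("informative_genes.tsv", lambda p: _write_signatures(
        p, cmodel, top_genes))
    emit("rank_scan.json", lambda p: asio.write_json(
        {"cophenetic": scan.cophenetic, "silhouette": scan.silhouette,
         "chosen_k": scan.chosen_k}, p))
    manifest["stages"]["cluster"] = {
        "chosen_k": scan.chosen_k,
        "n_informative": int(sum(len(v) for v in signatures.values())),
    }

    # --- transfer ---------------------------------------------------------
    tcfg = dict(config.transfer)
    n_boot = tcfg.pop("bootstrap_iterations", 200)
    validation = generate_validation(discovery, seed=_seed(config.seed, 3),
                                     **tcfg)
    vnorm, _ = preprocess_counts(validation, n_top=len(validation.gene_ids),
                                 min_total_count=0)
    shared, per_cluster = intersect_genes(signatures, vnorm.gene_ids)
    disc_frame = norm.to_frame()
    model = fit_lda(disc_frame.loc[shared].to_numpy().T, labels,
                    shared_genes=shared)
    target_X = vnorm.to_frame().loc[shared].to_numpy().T
    result = assign(model, target_X)
    stability = bootstrap_stability(model, target_X, n_iterations=n_boot,
                                    seed=_seed(config.seed, 4))
    emit("assignments.tsv", lambda p: _write_assignments(
        p, validation.sample_ids, result))
    emit("avg_posterior.tsv", lambda p: np.savetxt(
        p, result.avg_posterior, delimiter="\t", fmt="%.6f"))
    emit("stability.json", lambda p: asio.write_json(
        {"median_accuracy": stability.median_accuracy,
         "accuracy_ci": stability.accuracy_ci,
         "median_silhouette": stability.median_silhouette,
         "silhouette_ci": stability.silhouette_ci,
         "n_iterations": stability.n_iterations}, p))
    overlaps = reverse_validate(validation, nscfg, result.labels,
                                n_top=config.preprocess.get("n_top", 1000),
                                min_total_count=0)
    emit("reverse_validation.json", lambda p: asio.write_json(overlaps, p))
    manifest["stages"]["transfer"] = {
        "shared_genes": len(shared), "per_cluster": per_cluster,
        "median_accuracy": stability.median_accuracy,
    }

    # --- signature validation --------------------------------------------
    sig_cfg = config.signature
    control = generate_control(syn, sig_cfg.get("n_controls", 60),
                               seed=_seed(config.seed, 5))
    cnorm, _ = preprocess_counts(control, n_top=len(control.gene_ids),
                                 min_total_count=0)
    sig1 = [g for g in signatures.get(1, []) if g in set(cnorm.gene_ids)]
    cv_report = {}
    if len(sig1) >= 2:
        cases = disc_frame.loc[sig1].to_numpy().T[labels == 1]
        controls = cnorm.to_frame().loc[sig1].to_numpy().T
        X = np.vstack([cases, controls])
        y = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])
        for scen in sig_cfg.get("scenarios", ["all_genes"]):
            spec = ScenarioSpec(scenario=scen, seed=_seed(config.seed, 6))
            cv_report[scen] = validate_signature(X, y, spec).as_dict()
    emit("signature_cv.json", lambda p: asio.write_json(cv_report, p))
    manifest["stages"]["signature"] = {
        "signature_size": len(sig1),
        "scenarios": list(cv_report),
    }

    # --- phenotype --------------------------------------------------------
    chi = categorical_association_tests(pheno, labels)
    emit("phenotype_chi2.tsv", lambda p: chi.to_csv(p, sep="\t", index=False))
    ancova_rows = {}
    covs = (pheno[config.phenotype.get("covariates", [])]
            .apply(lambda c: (c == "M").astype(float) if c.dtype == object
                   else c.astype(float)))
    for var in config.phenotype.get("continuous", []):
        if var not in pheno:
            continue
        res = ancova_oneway(pheno[var].to_numpy(), labels, covariates=covs,
                            normality_alpha=0.05)
        ancova_rows[var] = {
            "F": res.f_statistic, "p": res.p_value,
            "transform": res.transform_applied,
            "tukey": {f"{a}-{b}": p for (a, b), p in res.tukey_p.items()},
        }
    emit("phenotype_ancova.json", lambda p: asio.write_json(ancova_rows, p))
    manifest["stages"]["phenotype"] = {"n_chi2": len(chi),
                                       "n_ancova": len(ancova_rows)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return manifest


def _write_labels(path, sample_ids, labels):
    with open(path, "w") as fh:
        fh.write("sample_id\tcluster\n")
        for s, l in zip(sample_ids, labels):
            fh.write(f"{s}\t{int(l)}\n")


def _write_signatures(path, cmodel, gene_ids):
    with open(path, "w") as fh:
        fh.write("gene_id\tcluster\tposterior\tfeature_score\n")
        for j, idx in cmodel.informative_genes.items():
            for i in idx:
                fh.write(f"{gene_ids[i]}\t{j}\t"
                         f"{cmodel.gene_posteriors[i, j - 1]:.6f}\t"
                         f"{cmodel.feature_scores[i]:.6f}\n")


def _write_assignments(path, sample_ids, result):
    k = result.posteriors.shape[1]
    with open(path, "w") as fh:
        fh.write("sample_id\tcluster\t" +
                 "\t".join(f"posterior_{j + 1}" for j in range(k)) + "\n")
        for s, l, row in zip(sample_ids, result.labels, result.posteriors):
            fh.write(f"{s}\t{int(l)}\t" +
                     "\t".join(f"{v:.6f}" for v in row) + "\n")
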