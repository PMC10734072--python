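"""LDA cluster transfer, bootstrap stability, and reverse validation."""

import numpy as np
import pytest

from alssubtypes import (NsNMFConfig, generate_validation)
from alssubtypes.preprocess import preprocess_counts
from alssubtypes.transfer import (assign, bootstrap_stability, fit_lda,
                                  intersect_genes, match_clusters,
                                  reverse_validate)


@pytest.fixture(scope="module")
def transfer_setup(small_fit):
    """Discovery model + matched validation cohort at keep fraction 0.6."""
    disc, norm, top, cm = (small_fit["disc"], small_fit["norm"],
                           small_fit["top"], small_fit["cmodel"])
    signatures = {j: [top[i] for i in idx]
                  for j, idx in cm.informative_genes.items()}
    val = generate_validation(disc, gene_keep_fraction=0.6,
                              platform_shift_sd=0.0, n_samples=60, seed=17)
    vnorm, _ = preprocess_counts(val, n_top=val.n_genes, min_total_count=0)
    shared, counts = intersect_genes(signatures, vnorm.gene_ids)
    model = fit_lda(norm.to_frame().loc[shared].to_numpy().T,
                    cm.sample_labels, shared_genes=shared)
    X = vnorm.to_frame().loc[shared].to_numpy().T
    return {"model": model, "X": X, "val": val, "shared": shared,
            "counts": counts, "signatures": signatures, "vnorm": vnorm}


class TestIntersect:
    def test_superset_retains_everything(self):
        sigs = {1: ["a", "b"], 2: ["c"]}
        shared, counts = intersect_genes(sigs, ["a", "b", "c", "d"])
        assert shared == ["a", "b", "c"]
        assert counts == {1: 2, 2: 1}

    def test_disjoint_sets_error(self):
        with pytest.raises(ValueError):
            intersect_genes({1: ["a"]}, ["b", "c"])

    def test_keep_fraction_reflected_in_overlap(self, transfer_setup):
        n_sig = sum(len(v) for v in transfer_setup["signatures"].values())
        n_shared = len(transfer_setup["shared"])
        # binomial(n_sig, 0.6): allow 4 sd either way
        sd = np.sqrt(n_sig * 0.6 * 0.4)
        assert abs(n_shared - 0.6 * n_sig) <= 4 * sd


class TestFitLDA:
    def test_separable_classes_fit_perfectly(self, rng):
        X = np.concatenate([rng.normal(0, 1, 50),
                            rng.normal(10, 1, 50)])[:, None]
        y = np.repeat([1, 2], 50)
        model = fit_lda(X, y)
        res = assign(model, X)
        assert np.array_equal(res.labels, y)
        # the 0.5 posterior crossing sits near the midpoint of the means
        grid = np.linspace(0, 10, 1001)[:, None]
        post = assign(model, grid).posteriors[:, 0]
        crossing = grid[np.argmin(np.abs(post - 0.5)), 0]
        assert 4.0 < crossing < 6.0

    def test_identical_classes_posterior_near_priors(self, rng):
        X = rng.normal(size=(300, 3))
        y = np.repeat([1, 2], 150)
        model = fit_lda(X, y)
        res = assign(model, X)
        assert np.allclose(res.posteriors.mean(axis=0), model.priors,
                           atol=0.1)

    def test_perfect_collinearity_tolerated(self, rng):
        base = rng.normal(size=(40, 1))
        X = np.hstack([base, base, base + rng.normal(0, 1, size=(40, 1))])
        y = np.repeat([1, 2], 20)
        model = fit_lda(X, y)  # must not raise
        assert np.all(np.linalg.eigvalsh(model.pooled_covariance) > 0)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(np.zeros((3, 2)), np.array([1, 1, 2]))

    def test_matches_sklearn_on_well_conditioned_data(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        X = np.vstack([rng.normal(0, 1, size=(80, 4)),
                       rng.normal(1.5, 1, size=(80, 4))])
        y = np.repeat([0, 1], 80)
        ours = assign(fit_lda(X, y, ridge=1e-9), X).posteriors
        ref = LinearDiscriminantAnalysis(solver="svd").fit(X, y)
        assert np.allclose(ours, ref.predict_proba(X), atol=1e-3)


class TestAssign:
    def test_posterior_rows_sum_to_one(self, transfer_setup):
        res = assign(transfer_setup["model"], transfer_setup["X"])
        assert np.allclose(res.posteriors.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(
            res.labels,
            transfer_setup["model"].classes[np.argmax(res.posteriors, axis=1)])

    def test_one_hot_posteriors_give_identity_average(self, rng):
        X = np.concatenate([rng.normal(0, 0.01, 30),
                            rng.normal(100, 0.01, 30)])[:, None]
        y = np.repeat([1, 2], 30)
        model = fit_lda(X, y)
        res = assign(model, X)
        assert np.allclose(res.avg_posterior, np.eye(2), atol=1e-6)

    def test_missing_shared_gene_named_in_error(self, transfer_setup):
        model = transfer_setup["model"]
        X = transfer_setup["X"][:, :-1]
        genes = model.shared_genes[:-1]
        with pytest.raises(KeyError, match=model.shared_genes[-1]):
            assign(model, X, gene_ids=genes)

    def test_gene_order_permutation_invariant(self, transfer_setup, rng):
        model, X = transfer_setup["model"], transfer_setup["X"]
        ref = assign(model, X, gene_ids=model.shared_genes)
        perm = rng.permutation(X.shape[1])
        permuted = assign(model, X[:, perm],
                          gene_ids=[model.shared_genes[i] for i in perm])
        assert np.array_equal(ref.labels, permuted.labels)
        assert np.allclose(ref.posteriors, permuted.posteriors)

    def test_planted_labels_recovered_with_high_certainty(self, transfer_setup):
        res = assign(transfer_setup["model"], transfer_setup["X"])
        truth = transfer_setup["val"].truth["labels"]
        mapping = match_clusters(truth, res.labels)
        acc = np.mean([mapping.get(int(l)) == t
                       for l, t in zip(res.labels, truth)])
        assert acc >= 0.95
        assert np.nanmin(np.diag(res.avg_posterior)) >= 0.8


class TestBootstrap:
    def test_reproducible_and_well_separated(self, transfer_setup):
        a = bootstrap_stability(transfer_setup["model"], transfer_setup["X"],
                                n_iterations=50, seed=4)
        b = bootstrap_stability(transfer_setup["model"], transfer_setup["X"],
                                n_iterations=50, seed=4)
        assert a.median_accuracy == b.median_accuracy
        assert a.median_silhouette == b.median_silhouette
        assert a.median_accuracy == 1.0
        assert -1.0 <= a.median_silhouette <= 1.0
        assert a.accuracy_ci[0] <= a.median_accuracy <= a.accuracy_ci[1]

    def test_overlapping_classes_destabilize(self, rng):
        X = rng.normal(size=(80, 5))
        y = np.repeat([1, 2], 40)
        model = fit_lda(X, y)
        stab = bootstrap_stability(model, X, n_iterations=100, seed=9)
        assert stab.median_accuracy < 1.0
        assert stab.accuracy_ci[1] > stab.accuracy_ci[0]


class TestReverseValidation:
    def test_self_consistency_is_perfect(self, small_fit):
        cfg = NsNMFConfig(k=3, theta=0.5, n_runs=3, max_iter=500, tol=1e-6,
                          seed=5)
        overlaps = reverse_validate(small_fit["disc"], cfg,
                                    small_fit["cmodel"].sample_labels,
                                    n_top=200)
        assert all(v == 1.0 for v in overlaps.values())

    def test_match_is_label_permutation_invariant(self, rng):
        ref = rng.integers(1, 4, size=60)
        denovo = ref.copy()
        permuted = np.array([{1: 3, 2: 1, 3: 2}[x] for x in denovo])
        m1 = match_clusters(ref, denovo)
        m2 = match_clusters(ref, permuted)
        agree1 = np.mean([m1[x] for x in denovo] == ref)
        agree2 = np.mean([m2[x] for x in permuted] == ref)
        assert agree1 == agree2 == 1.0


def test_transfer_accuracy_monotone_in_effect_size(small_config):
    from alssubtypes import SyntheticConfig, generate_discovery
    from alssubtypes.nsnmf import fit_cluster_model
    accs = []
    for lfc in (0.25, 1.0, 2.0):
        cfg = SyntheticConfig(**{**small_config.__dict__,
                                 "log2_fold_change": lfc, "seed": 23})
        disc, _ = generate_discovery(cfg)
        norm, top = preprocess_counts(disc, n_top=200)
        V = norm.to_frame().loc[top].to_numpy()
        fact, cm = fit_cluster_model(V, NsNMFConfig(k=3, n_runs=2,
                                                    max_iter=300, tol=1e-5,
                                                    seed=3))
        # score transfer against the generator's truth, mapped optimally
        val = generate_validation(disc, 0.8, 0.0, 60, seed=29)
        vnorm, _ = preprocess_counts(val, n_top=val.n_genes,
                                     min_total_count=0)
        sigs = {j: [top[i] for i in idx]
                for j, idx in cm.informative_genes.items()}
        try:
            shared, _ = intersect_genes(sigs, vnorm.gene_ids)
        except ValueError:
            accs.append(0.0)
            continue
        model = fit_lda(norm.to_frame().loc[shared].to_numpy().T,
                        cm.sample_labels, shared_genes=shared)
        res = assign(model, vnorm.to_frame().loc[shared].to_numpy().T)
        truth = val.truth["labels"]
        mapping = match_clusters(truth, res.labels)
        accs.append(np.mean([mapping.get(int(l)) == t
                             for l, t in zip(res.labels, truth)]))
    assert accs[0] <= accs[1] + 0.05 and accs[1] <= accs[2] + 0.05
    assert accs[2] >= 0.95
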