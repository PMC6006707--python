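import numpy as np
import pytest

import pyracipe as pr
from pyracipe.analysis import (
    DISSIMILARITY_CAP,
    apply_normalization,
    bhattacharyya,
    expression_histogram,
    hierarchical_clusters,
    histogram_support,
    kl_divergence,
    minimal_setting_scan,
    normalize_expressions,
    parameter_differentiation,
    pca_project,
    project_onto,
    replicate_dissimilarity,
    state_count_distribution,
    zero_expression_z,
)


def two_blobs(n_per=100, sep=8.0, dim=10, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n_per, dim))
    b = rng.normal(sep / np.sqrt(dim), 1.0, (n_per, dim))
    X = np.vstack([a, b])
    truth = np.array([0] * n_per + [1] * n_per)
    return X, truth


class TestNormalization:
    def test_zscore_definition(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 3, (200, 4))
        Z, mean, sd = normalize_expressions(X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-12)
        assert np.allclose((X - mean) / sd, Z)

    def test_zero_variance_gene_named(self):
        X = np.ones((10, 3))
        X[:, [0, 2]] = np.random.default_rng(1).normal(size=(10, 2))
        with pytest.raises(ValueError, match="geneB"):
            normalize_expressions(X, gene_names=["geneA", "geneB", "geneC"])

    def test_reference_normalization_of_constant_column(self):
        # a knocked-out gene normalized with reference stats lands at one
        # fixed negative z-coordinate
        rng = np.random.default_rng(2)
        wt = rng.normal(4, 2, (300, 2))
        _, mean, sd = normalize_expressions(wt)
        ko = np.column_stack([np.full(50, np.log2(1e-10)), rng.normal(4, 2, 50)])
        z = apply_normalization(ko, mean, sd)
        assert np.all(z[:, 0] == z[0, 0])
        assert z[0, 0] < 0
        assert z[0, 0] == pytest.approx(zero_expression_z(mean, sd)[0])


class TestClustering:
    def test_two_blobs_two_major_clusters(self):
        X, truth = two_blobs()
        rep = hierarchical_clusters(X)
        assert rep.n_major == 2
        # labels match ground truth up to permutation
        for t in (0, 1):
            labs = rep.labels[truth == t]
            assert len(set(labs)) == 1
        assert set(rep.labels[truth == 0]) != set(rep.labels[truth == 1])

    def test_duplicate_rows_cluster_together(self):
        X = np.vstack([np.zeros((5, 3)), np.ones((5, 3)) * 10])
        rep = hierarchical_clusters(X)
        assert rep.n_major == 2
        assert len(set(rep.labels[:5])) == 1

    def test_n_target_forces_cut(self):
        X, _ = two_blobs()
        rep = hierarchical_clusters(X, n_target=4)
        assert len(rep.fractions) == 4

    def test_fractions_sum_to_one(self):
        X, _ = two_blobs(seed=5)
        rep = hierarchical_clusters(X)
        assert rep.fractions.sum() == pytest.approx(1.0)
        assert np.all(rep.fractions[: rep.n_major] >= rep.cutoff)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            hierarchical_clusters(np.zeros((1, 3)))


class TestPCA:
    def test_separated_clusters_and_sign_convention(self):
        X, truth = two_blobs()
        Z, _, _ = normalize_expressions(X)
        res = pca_project(Z)
        side = res.coords[:, 0] > 0
        assert (side == truth.astype(bool)).mean() in (0.0, 1.0)
        for c in res.components:
            assert c[np.argmax(np.abs(c))] > 0

    def test_full_reconstruction(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 6))
        res = pca_project(X, n_components=6)
        recon = res.coords @ res.components + res.mean
        assert np.allclose(recon, X, atol=1e-10)

    def test_knockout_displacement_is_along_ko_loadings(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 5))
        res = pca_project(X, n_components=2)
        state = X[0].copy()
        ko_state = state.copy()
        ko_state[2] = -7.5  # pinned zero-expression coordinate
        d = project_onto(res, ko_state[None, :]) - project_onto(res, state[None, :])
        expected = (ko_state[2] - state[2]) * res.components[:, 2]
        assert np.allclose(d[0], expected)


class TestDistributions:
    def test_state_count_distribution_basics(self):
        d = state_count_distribution([1, 1, 1, 1])
        assert np.allclose(d, [0, 1])
        d = state_count_distribution([0, 1, 2, 2, 3])
        assert d.sum() == pytest.approx(1.0)
        # mean * n_models equals total states
        counts = np.array([1, 2, 3, 2, 1, 1])
        d = state_count_distribution(counts)
        mean = np.sum(np.arange(len(d)) * d)
        assert mean * len(counts) == pytest.approx(counts.sum())

    @pytest.mark.parametrize(
        "p, q, expected",
        [
            ([0.3, 0.7], [0.3, 0.7], 0.0),
            ([1.0, 0.0], [0.5, 0.5], -np.log(np.sqrt(0.5))),
        ],
    )
    def test_bhattacharyya_values(self, p, q, expected):
        assert bhattacharyya(p, q) == pytest.approx(expected, abs=1e-12)

    def test_bhattacharyya_symmetric_and_capped(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(6))
        q = rng.dirichlet(np.ones(6))
        assert bhattacharyya(p, q) == pytest.approx(bhattacharyya(q, p))
        assert bhattacharyya([1.0, 0.0], [0.0, 1.0]) == DISSIMILARITY_CAP

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            bhattacharyya([0.5, 0.2], [0.5, 0.5])
        with pytest.raises(ValueError):
            kl_divergence([0.5, 0.5], [0.9, 0.2])

    def test_kl_properties(self):
        p = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)
        q = np.array([0.5, 0.3, 0.2])
        assert kl_divergence(p, q) > 0
        assert kl_divergence([1.0, 0.0], [0.0, 1.0]) == DISSIMILARITY_CAP

    def test_support_padding(self):
        assert bhattacharyya([1.0], [1.0, 0.0]) == pytest.approx(0.0)


class TestReplicateDissimilarity:
    def test_identical_replicates_give_zero(self):
        p = [np.array([0.4, 0.6])] * 3
        assert replicate_dissimilarity(p, p) == pytest.approx(0.0)

    def test_matches_brute_force_pairwise_average(self):
        rng = np.random.default_rng(1)
        reps = [rng.dirichlet(np.ones(4)) for _ in range(3)]
        refs = [rng.dirichlet(np.ones(4)) for _ in range(3)]
        # independent brute force with its own Bhattacharyya formula
        total = 0.0
        for p in reps:
            for q in refs:
                total += -np.log(np.sum(np.sqrt(p * q)))
        assert replicate_dissimilarity(reps, refs) == pytest.approx(total / 9.0)

    def test_kl_metric_nonnegative(self):
        rng = np.random.default_rng(2)
        reps = [rng.dirichlet(np.ones(4)) for _ in range(3)]
        refs = [rng.dirichlet(np.ones(4)) for _ in range(3)]
        assert replicate_dissimilarity(reps, refs, metric="kl") >= 0.0
        assert replicate_dissimilarity(reps, reps[:1] * 2, metric="kl") >= 0.0

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            replicate_dissimilarity([np.array([1.0])], [np.array([1.0])] * 2)

    def test_histograms_share_support(self):
        rng = np.random.default_rng(3)
        ref = [rng.normal(0, 1, 500) for _ in range(3)]
        lo, hi = histogram_support(ref)
        h1 = expression_histogram(ref[0], lo, hi)
        h2 = expression_histogram(rng.normal(5, 1, 500), lo, hi)  # clipped in
        assert len(h1) == len(h2) == 50
        assert h1.sum() == pytest.approx(1.0)
        assert h2.sum() == pytest.approx(1.0)


class TestMinimalSettingScan:
    def test_flat_sequence_returns_first_point(self):
        assert minimal_setting_scan([10, 50, 100], [0.3, 0.3, 0.3]) == 10

    def test_single_subthreshold_step(self):
        settings = [10, 50, 100, 500]
        D = [0.5, 0.3, 0.2999, 0.1]
        assert minimal_setting_scan(settings, D, threshold=5e-4) == 50

    def test_never_converging(self):
        assert minimal_setting_scan([1, 2, 3], [0.9, 0.5, 0.1]) is None

    def test_validation(self):
        with pytest.raises(ValueError):
            minimal_setting_scan([1], [0.1])
        with pytest.raises(ValueError):
            minimal_setting_scan([2, 1], [0.1, 0.2])


class TestParameterDifferentiation:
    def test_null_has_few_discoveries(self):
        rng = np.random.default_rng(0)
        params = rng.normal(size=(400, 12))
        state_models = np.arange(400)
        labels = np.where(rng.random(400) < 0.5, 1, 2)  # random split
        res = parameter_differentiation(params, state_models, labels, 1, 2)
        assert np.mean(res.qvalue < 0.05) <= 0.10
        assert not res.small_sample

    def test_identical_clusters_zero_effect(self):
        rng = np.random.default_rng(1)
        params = rng.normal(size=(50, 5))
        state_models = np.repeat(np.arange(50), 2)
        labels = np.tile([1, 2], 50)  # every model in both clusters
        res = parameter_differentiation(params, state_models, labels, 1, 2)
        assert np.allclose(res.effect, 0.0)
        assert np.all(res.qvalue == 1.0)

    def test_small_cluster_flagged(self):
        rng = np.random.default_rng(2)
        params = rng.normal(size=(30, 3))
        state_models = np.arange(30)
        labels = np.array([1] * 3 + [2] * 27)
        res = parameter_differentiation(params, state_models, labels, 1, 2)
        assert res.small_sample

    def test_toggle_switch_inhibition_strength_direction(self, toggle):
        # monostable A-high models must show weaker inhibition of A by B
        # (fold change closer to 1) than monostable B-high models
        ranges = pr.build_parameter_ranges(
            toggle, pr.SimulationConfig(mc_samples=2000),
            rng=np.random.default_rng(0),
        )
        res = pr.run_ensemble(toggle, 500, 20, master_seed=21, ranges=ranges)
        owners, states = res.state_matrix()
        counts = res.state_counts
        mono = counts[owners] == 1
        a_high = states[:, 0] > states[:, 1]
        labels = np.where(a_high, 1, 2)
        keep = mono
        diff = parameter_differentiation(
            res.params, owners[keep], labels[keep], 1, 2, names=res.ranges.names
        )
        j = res.ranges.names.index("Fld_of_BToA")
        assert diff.effect[j] > 0
        assert diff.qvalue[j] < 0.05
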