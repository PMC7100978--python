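import numpy as np
import pytest

import mosaiq as mq
from mosaiq.annotation import CellGraph, _mean_community_extent
from mosaiq.errors import (
    AttenuationError,
    InsufficientComponentsError,
    PrecondError,
    ZeroVarianceError,
)
from conftest import three_group_sample


def block_positions(n, offset, seed=0, spread=1.0):
    rng = np.random.default_rng(seed)
    return rng.uniform(0, spread, (n, 2)) + np.asarray(offset)


class TestSpatialCorrelation:
    def test_iid_field_has_no_structure(self, rng):
        pos = rng.uniform(0, 100, (300, 2))
        X = rng.normal(0, 1, 300)
        corr = mq.spatial_correlation(pos, X, seed=1)
        # each bin averages ~m unit-variance products; 3 sigma = 3/sqrt(m)
        m = (300 * 299 / 2) / len(corr.psi)
        assert np.all(np.abs(corr.psi[1:]) < 3 / np.sqrt(m) + 0.05)

    def test_two_clone_field_decays(self, rng):
        left = np.column_stack([rng.uniform(0, 50, 200), rng.uniform(0, 100, 200)])
        right = np.column_stack([rng.uniform(50, 100, 200), rng.uniform(0, 100, 200)])
        pos = np.vstack([left, right])
        X = np.concatenate([np.full(200, -1.0), np.full(200, 1.0)])
        X += rng.normal(0, 0.05, 400)
        corr = mq.spatial_correlation(pos, X, seed=2)
        assert corr.psi[0] > 0.8
        assert corr.psi[-1] < corr.psi[0] - 0.5
        assert 0 < corr.decay_length < 150

    def test_coincident_duplicates_normalize_to_one(self, rng):
        # 20 distinct sites, 3 coincident cells each, X = +-1 balanced:
        # the 60 zero-distance pairs overfill the first equal-count bin and
        # every such pair contributes (X - mu)^2 / sigma^2 = 1 exactly.
        base = rng.uniform(0, 100, (20, 2))
        X20 = np.repeat([-1.0, 1.0], 10)
        pos = np.vstack([base, base, base])
        X = np.concatenate([X20, X20, X20])
        corr = mq.spatial_correlation(pos, X, seed=3)
        assert corr.bin_centers[0] == pytest.approx(0.0, abs=1e-9)
        assert corr.psi[0] == pytest.approx(1.0, abs=1e-9)

    def test_constant_field_raises(self, rng):
        with pytest.raises(ZeroVarianceError):
            mq.spatial_correlation(rng.uniform(0, 1, (60, 2)), np.ones(60))

    def test_too_few_cells_raises(self, rng):
        with pytest.raises(PrecondError):
            mq.spatial_correlation(rng.uniform(0, 1, (10, 2)), rng.normal(size=10))


class TestSampleContext:
    def test_mean_of_neighbors_excludes_self(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        X = np.array([5.0, 0.0, 2.0])
        Y = mq.sample_context(pos, X, radius=1.5)
        assert Y[0] == pytest.approx(1.0)  # mean of {0, 2}

    def test_constant_field_fixed_point(self, rng):
        pos = rng.uniform(0, 10, (30, 2))
        Y = mq.sample_context(pos, np.full(30, 3.3), radius=5.0)
        assert np.allclose(Y, 3.3)

    def test_isolated_cells_fall_back_to_own_level(self, rng):
        pos = rng.uniform(0, 100, (20, 2))
        X = rng.normal(size=20)
        Y = mq.sample_context(pos, X, radius=1e-6)
        assert np.allclose(Y, X)


class TestFitMixture:
    def test_bic_formula(self):
        assert mq.bic_score(100, 5, -50.0) == pytest.approx(123.0259, abs=1e-3)

    def test_selects_three_components_and_recovers_means(self):
        X, Y, _ = three_group_sample(150, sigma=0.1, seed=0)
        model = mq.fit_mixture(X, Y, k_range=range(3, 6), seed=0)
        assert model.K == 3
        means = np.sort(np.exp(model.means[:, 0]))
        assert np.allclose(means, [0.5, 1.0, 2.0], rtol=0.10)

    def test_em_loglik_nondecreasing(self):
        X, Y, _ = three_group_sample(100, sigma=0.3, seed=1)
        model = mq.fit_mixture(X, Y, k_range=range(3, 5), seed=1)
        trace = np.array(model.trace)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_agrees_with_reference_em(self):
        """Cross-check against sklearn's diagonal GMM on the same data."""
        from sklearn.mixture import GaussianMixture

        X, Y, _ = three_group_sample(200, sigma=0.15, seed=2)
        model = mq.fit_mixture(X, Y, k_range=[3], seed=2)
        Z = np.column_stack([X, Y])
        ref = GaussianMixture(3, covariance_type="diag", n_init=5,
                              random_state=0).fit(Z)
        ours = np.sort(model.means[:, 0])
        theirs = np.sort(ref.means_[:, 0])
        assert np.allclose(ours, theirs, atol=0.05)
        assert model.loglik / len(Z) == pytest.approx(ref.score(Z), abs=1e-3)

    def test_small_sample_precondition(self):
        with pytest.raises(PrecondError):
            mq.fit_mixture(np.zeros(5), np.zeros(5), k_range=[3])


class TestMapComponents:
    def make_model(self, mus):
        K = len(mus)
        return mq.MixtureModel(
            weights=np.full(K, 1 / K),
            means=np.column_stack([np.log(mus), np.zeros(K)]),
            variances=np.full((K, 2), 0.01),
            loglik=0.0, bic=0.0, n_obs=100,
        )

    def test_identity_on_three_sorted(self):
        model = self.make_model([0.5, 1.0, 2.0])
        f = mq.map_components(model)
        assert f.tolist() == [0, 1, 2]

    def test_five_component_grouping(self):
        model = self.make_model([0.4, 0.55, 1.0, 1.9, 2.1])
        f = mq.map_components(model)
        assert f.tolist() == [0, 0, 1, 2, 2]

    def test_permuting_components_leaves_cell_labels_unchanged(self, rng):
        mus = [0.4, 0.55, 1.0, 1.9, 2.1]
        model = self.make_model(mus)
        f = mq.map_components(model)
        X = rng.normal(0, 1, 50)
        labels = f[np.argmax(model.marginal_posterior(X), axis=1)]
        perm = rng.permutation(5)
        permuted = self.make_model(list(np.array(mus)[perm]))
        fp = mq.map_components(permuted)
        labels_p = fp[np.argmax(permuted.marginal_posterior(X), axis=1)]
        assert np.array_equal(labels, labels_p)

    def test_too_few_components(self):
        with pytest.raises(InsufficientComponentsError):
            mq.map_components(self.make_model([0.5, 2.0]))

    def test_binary_labeling(self):
        model = self.make_model([0.5, 0.6, 2.0])
        f = mq.map_components(model, n_labels=2)
        assert f.tolist() == [0, 0, 1]


class TestCellGraph:
    def test_weight_formula(self, rng):
        pos = rng.uniform(0, 10, (30, 2))
        X = rng.normal(0, 1, 30)
        g = mq.build_cell_graph(pos, X)
        E = np.abs(X[g.edges[:, 0]] - X[g.edges[:, 1]])
        assert np.allclose(g.weights, np.exp(-E / E.mean()))

    def test_identical_levels_give_unit_weight(self, rng):
        pos = rng.uniform(0, 10, (20, 2))
        X = np.zeros(20)
        X[:10] = 1.0
        g = mq.build_cell_graph(pos, X)
        same = X[g.edges[:, 0]] == X[g.edges[:, 1]]
        assert np.allclose(g.weights[same], 1.0)

    def test_mean_fold_change_maps_to_inverse_e(self):
        E = np.array([0.5, 1.0, 1.5, 1.0])  # mean exactly 1.0
        w = mq.edge_weights(E)
        assert w[1] == pytest.approx(np.exp(-1), abs=1e-12)
        assert w[1] == pytest.approx(0.3679, abs=5e-5)

    def test_outlier_isolated_by_length_filter(self, rng):
        # dense unit-square cloud + one far outlier: every edge reaching the
        # outlier sits above the 95th length percentile and is dropped
        pos = np.vstack([rng.uniform(0, 1, (60, 2)), [[100.0, 50.0]]])
        g = mq.build_cell_graph(pos, np.zeros(61), max_edge_quantile=0.95)
        assert not np.any(g.edges == 60)

    def test_collinear_points_raise(self):
        pos = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(Exception):
            mq.build_cell_graph(pos, np.zeros(5))


def two_block_graph(w_cross=0.05, n=5, sep=50.0):
    """Two spatial blocks, strong internal edges, weak bridges."""
    pos = np.vstack([block_positions(n, (0, 0), 1), block_positions(n, (sep, 0), 2)])
    edges, weights = [], []
    for block in (range(n), range(n, 2 * n)):
        block = list(block)
        for a in range(len(block)):
            for b in range(a + 1, len(block)):
                edges.append((block[a], block[b]))
                weights.append(1.0)
    edges.append((0, n))
    weights.append(w_cross)
    X = np.concatenate([np.zeros(n), np.ones(n)])
    return CellGraph(
        positions=pos, X=X, edges=np.array(edges), weights=np.array(weights)
    )


class TestCommunities:
    def test_two_blocks_detected(self):
        g = two_block_graph()
        membership = mq.detect_communities(g, decay_length=10.0, seed=0)
        assert len(np.unique(membership)) == 2
        assert len(set(membership[:5])) == 1
        assert len(set(membership[5:])) == 1

    def test_uniform_complete_graph_single_community(self):
        n = 6
        pos = block_positions(n, (0, 0), 3)
        edges = np.array([(a, b) for a in range(n) for b in range(a + 1, n)])
        g = CellGraph(positions=pos, X=np.zeros(n), edges=edges,
                      weights=np.ones(len(edges)))
        membership = mq.detect_communities(g, decay_length=100.0, seed=0)
        assert len(np.unique(membership)) == 1

    def test_membership_is_partition(self):
        g = two_block_graph()
        membership = mq.detect_communities(g, decay_length=10.0, seed=1)
        assert len(membership) == g.n
        assert np.all(membership >= 0)

    def test_cut_respects_decay_length(self):
        g = two_block_graph()
        # tiny decay length: even the block level is too coarse -> finest kept
        fine = mq.detect_communities(g, decay_length=1e-3, seed=0)
        coarse = mq.detect_communities(g, decay_length=1000.0, seed=0)
        assert len(np.unique(fine)) >= len(np.unique(coarse))

    def test_community_context(self):
        X = np.array([1.0, 3.0, 5.0])
        Y = mq.community_context(X, np.array([0, 0, 1]))
        assert np.allclose(Y, [2.0, 2.0, 5.0])
        assert np.allclose(mq.community_context(X, np.arange(3)), X)

    def test_mean_extent_zero_for_singletons(self, rng):
        pos = rng.uniform(0, 10, (5, 2))
        assert _mean_community_extent(pos, np.arange(5)) == 0.0


class TestDiffusion:
    def test_alpha_zero_is_identity(self):
        g = two_block_graph()
        p = np.random.default_rng(0).dirichlet(np.ones(3), g.n)
        assert np.allclose(mq.diffuse_posteriors(g, p, 0.0), p)

    def test_two_node_solve(self):
        g = CellGraph(
            positions=np.array([[0.0, 0], [1, 0]]),
            X=np.zeros(2),
            edges=np.array([[0, 1]]),
            weights=np.array([1.0]),
        )
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        p_hat = mq.diffuse_posteriors(g, p, alpha=0.5)
        assert np.allclose(p_hat, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]])

    def test_rows_renormalized(self):
        g = two_block_graph()
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(4), g.n)
        p_hat = mq.diffuse_posteriors(g, p, alpha=0.5 / g.spectral_radius())
        assert np.allclose(p_hat.sum(axis=1), 1.0, atol=1e-10)

    def test_attenuation_too_large(self):
        g = two_block_graph()
        with pytest.raises(AttenuationError):
            mq.diffuse_posteriors(g, np.ones((g.n, 2)) / 2, alpha=2.0)

    def test_alpha_increases_neighbor_agreement(self):
        g = two_block_graph(w_cross=0.2, n=12)
        rng = np.random.default_rng(2)
        # mostly-noise posteriors with a weak block-aligned signal, so some
        # cells start mislabeled and diffusion corrects them progressively
        p = np.column_stack([1 - g.X, g.X]) * 0.15 + rng.dirichlet([1, 1], g.n) * 0.85
        p /= p.sum(axis=1, keepdims=True)
        rho = g.spectral_radius()

        def agreement(alpha):
            lab = np.argmax(mq.diffuse_posteriors(g, p, alpha), axis=1)
            return np.mean(lab[g.edges[:, 0]] == lab[g.edges[:, 1]])

        scores = [agreement(a) for a in (0.0, 0.5 / rho, 0.95 / rho)]
        assert scores[0] <= scores[1] <= scores[2]
        assert scores[2] > scores[0]


class TestClassifyMarginal:
    def test_sample_at_component_mean(self):
        model = TestMapComponents().make_model([0.5, 1.0, 2.0])
        mq.map_components(model)
        labels = mq.classify_marginal(np.log([0.5, 1.0, 2.0]), model)
        assert labels.tolist() == [0, 1, 2]

    def test_tie_breaks_to_lower_component(self):
        model = mq.MixtureModel(
            weights=np.array([0.5, 0.5]),
            means=np.array([[-1.0, 0.0], [1.0, 0.0]]),
            variances=np.full((2, 2), 1.0),
            loglik=0.0, bic=0.0, n_obs=10,
        )
        model.dosage_map = np.array([0, 2])
        assert mq.classify_marginal(np.array([0.0]), model)[0] == 0

    def test_frequencies_match_truth_on_clean_data(self):
        X, Y, dosages = three_group_sample(200, sigma=0.1, seed=4)
        model = mq.fit_mixture(X, Y, k_range=range(3, 5), seed=4)
        mq.map_components(model)
        labels = mq.classify_marginal(X, model)
        for m in (0, 1, 2):
            assert abs(np.mean(labels == m) - np.mean(dosages == m)) <= 0.02


class TestAnnotate:
    def test_strong_regime_accuracy(self, small_table, annotated_small):
        labeled, result = annotated_small
        scores = mq.score_labels(labeled)
        assert scores["accuracy"] >= 0.95
        assert scores["mae"] <= 0.05

    def test_confidence_is_winning_posterior_mass(self, annotated_small):
        labeled, result = annotated_small
        conf = labeled.data["confidence"].to_numpy()
        assert np.all((conf >= 0) & (conf <= 1))
        f = result.model.dosage_map
        direct = np.array(
            [result.diffused[i, f == m].sum()
             for i, m in enumerate(result.dosages)]
        )
        keep = ~result.fallback
        # non-fallback cells carry the diffused posterior mass exactly
        assert np.allclose(conf[keep], np.clip(direct, 0, 1)[keep], atol=1e-10)

    def test_posterior_normalization(self, annotated_small):
        _, result = annotated_small
        assert np.allclose(result.posteriors.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(result.diffused.sum(axis=1), 1.0, atol=1e-10)

    def test_labels_within_range(self, annotated_small):
        labeled, result = annotated_small
        assert set(labeled.data["dosage"].unique()) <= {0, 1, 2}
        assert set(result.model.dosage_map) == {0, 1, 2}  # f onto when K >= 3

    def test_degenerate_separation_interior_cells_exact(self, small_culture):
        # zero fluorescence ambiguity: levels exactly 2^(n-1)
        culture = small_culture
        levels = 2.0 ** (culture.alive_dosages - 1.0)
        import pandas as pd

        table = mq.MeasurementTable(
            pd.DataFrame(
                {
                    "cell_id": np.arange(culture.n_alive),
                    "x": culture.alive_positions[:, 0],
                    "y": culture.alive_positions[:, 1],
                    "ch1": levels,
                    "true_dosage": culture.alive_dosages,
                }
            )
        )
        labeled = mq.annotate(table, mq.AnnotationConfig(marker_channel=1, seed=0))
        border = mq.flag_borders(table.positions, culture.alive_dosages)
        pred = labeled.data["dosage"].to_numpy(dtype=float)
        truth = culture.alive_dosages
        assert np.all(pred[~border] == truth[~border])

    def test_too_few_cells_rejected(self, rng):
        import pandas as pd

        table = mq.MeasurementTable(
            pd.DataFrame(
                {
                    "cell_id": np.arange(10),
                    "x": rng.uniform(0, 1, 10),
                    "y": rng.uniform(0, 1, 10),
                    "ch1": rng.uniform(1, 2, 10),
                }
            )
        )
        with pytest.raises(PrecondError):
            mq.annotate(table)


def test_log_expression_floors_nonpositive_values():
    levels = np.array([-5.0, 0.0, 1.0, 10.0])
    X = mq.log_expression(levels, floor_frac=0.01)
    assert np.all(np.isfinite(X))
    eps = 0.01 * np.median([1.0, 10.0])
    assert X[0] == pytest.approx(np.log(eps))
    assert X[2] == pytest.approx(0.0)
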