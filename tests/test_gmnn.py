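"""Loss terms, score fusion and the variational-EM trainer."""

import numpy as np
import pytest

from circlink import (
    TrainConfig,
    loss_cotrain,
    loss_kl,
    loss_label,
    loss_manifold,
    loss_reconstruction,
    predict_scores,
    total_loss_p,
    total_loss_q,
    train_em,
)
from circlink.similarity import SimilarityGraph, sparsify_and_normalize


def _graph(weights):
    weights = np.asarray(weights, float)
    return sparsify_and_normalize(weights, k_neighbors=weights.shape[0] - 1)


class TestLossReconstruction:
    def test_identity_is_zero(self, rng):
        x = rng.standard_normal((3, 4))
        assert loss_reconstruction(x, x) == 0.0

    def test_half_squared_error(self):
        assert loss_reconstruction(np.array([[1.0, 0.0]]), np.zeros((1, 2))) == 0.5

    def test_matches_scalar_loop(self, rng):
        x, xp = rng.standard_normal((3, 3)), rng.standard_normal((3, 3))
        brute = 0.5 * sum(
            (x[i, j] - xp[i, j]) ** 2 for i in range(3) for j in range(3)
        )
        assert loss_reconstruction(x, xp) == pytest.approx(brute, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            loss_reconstruction(np.zeros((2, 2)), np.zeros((2, 3)))


class TestLossKl:
    def test_standard_normal_is_zero(self):
        assert loss_kl(np.zeros((3, 2)), np.ones((3, 2))) == pytest.approx(0, abs=1e-12)

    def test_unit_mean_single_element(self):
        assert loss_kl(np.array([[1.0]]), np.array([[1.0]])) == pytest.approx(0.5)

    def test_monte_carlo_oracle(self, rng):
        # KL(N(0.5, 2^2) || N(0,1)) estimated by sampling
        mu, sigma = 0.5, 2.0
        z = rng.normal(mu, sigma, size=1_000_000)
        log_q = -0.5 * np.log(2 * np.pi * sigma**2) - (z - mu) ** 2 / (2 * sigma**2)
        log_p = -0.5 * np.log(2 * np.pi) - z**2 / 2
        mc = (log_q - log_p).mean()
        assert loss_kl(np.array([[mu]]), np.array([[sigma]])) == pytest.approx(
            mc, abs=1e-2
        )

    def test_nonnegative_and_positive_sigma_required(self, rng):
        mu = rng.standard_normal((4, 4))
        sigma = np.abs(rng.standard_normal((4, 4))) + 0.1
        assert loss_kl(mu, sigma) >= -1e-12
        with pytest.raises(ValueError):
            loss_kl(mu, np.zeros_like(sigma))


class TestLossLabel:
    def test_no_positives(self):
        assert loss_label(np.zeros((3, 3)), np.full((3, 3), 0.5)) == 0.0

    def test_single_cell(self):
        assert loss_label(np.array([[1.0]]), np.array([[np.exp(-1.0)]])) == pytest.approx(1.0)

    def test_matches_scalar_loop(self, rng):
        Y = rng.integers(0, 2, size=(4, 4)).astype(float)
        F = rng.uniform(0.1, 0.9, size=(4, 4))
        brute = -sum(
            Y[i, j] * np.log(F[i, j]) for i in range(4) for j in range(4)
        )
        assert loss_label(Y, F) == pytest.approx(brute, abs=1e-12)

    def test_zero_prediction_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="circlink"):
            val = loss_label(np.array([[1.0]]), np.array([[0.0]]))
        assert np.isfinite(val)
        assert any("clamping" in r.message for r in caplog.records)


class TestLossManifold:
    def test_constant_rows_on_connected_graph(self):
        g = _graph([[1.0, 0.8, 0.8], [0.8, 1.0, 0.8], [0.8, 0.8, 1.0]])
        F = np.ones((3, 2)) * 0.7
        assert loss_manifold(F, g) == pytest.approx(0.0, abs=1e-12)

    def test_two_node_hand_value(self):
        g = _graph([[1.0, 1.0], [1.0, 1.0]])
        F = np.array([[1.0], [0.0]])
        # Laplacian quadratic form = w*(1-0)^2 = 1; one edge
        assert loss_manifold(F, g) == pytest.approx(1.0)

    def test_nonnegative(self, rng):
        raw = rng.random((6, 6))
        g = _graph(0.5 * (raw + raw.T) + np.eye(6))
        assert loss_manifold(rng.standard_normal((6, 3)), g) >= 0


class TestLossCotrain:
    def test_agreement_is_zero(self, rng):
        Sc = rng.random((3, 4))
        assert loss_cotrain(Sc, Sc.T) == 0.0

    def test_single_cell(self):
        assert loss_cotrain(np.array([[0.9]]), np.array([[0.5]])) == pytest.approx(0.16)

    def test_symmetric_up_to_transpose(self, rng):
        Sc, Sd = rng.random((3, 4)), rng.random((4, 3))
        assert loss_cotrain(Sc, Sd) == pytest.approx(loss_cotrain(Sd, Sc))


class TestTotalLosses:
    def test_q_affine_combination(self):
        assert total_loss_q(1.0, 2.0, 3.0, alpha=0.5, beta=1.0) == pytest.approx(4.5)

    def test_p_affine_combination(self):
        assert total_loss_p(2.0, 4.0, alpha=0.25) == pytest.approx(3.5)

    def test_alpha_boundary_clipped(self):
        assert total_loss_p(2.0, 4.0, alpha=1.0) == pytest.approx(2.0, abs=1e-6)

    def test_invalid_alpha_beta(self):
        with pytest.raises(ValueError):
            total_loss_q(1, 1, 1, alpha=1.5, beta=0)
        with pytest.raises(ValueError):
            total_loss_q(1, 1, 1, alpha=0.5, beta=-1)


class TestPredictScores:
    def test_boundaries(self, rng):
        Fc, Fd = rng.random((3, 4)), rng.random((4, 3))
        np.testing.assert_allclose(predict_scores(Fc, Fd, 1.0), Fc)
        np.testing.assert_allclose(predict_scores(Fc, Fd, 0.0), Fd.T)

    def test_default_weighting(self):
        F = predict_scores(np.array([[1.0]]), np.array([[0.5]]), alpha=0.8)
        assert F[0, 0] == pytest.approx(0.9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            predict_scores(np.zeros((2, 3)), np.zeros((2, 3)), 0.8)


@pytest.fixture(scope="module")
def trained(tiny_bundle, fast_cfg):
    from circlink import train_and_score

    return train_and_score(tiny_bundle.A_train, tiny_bundle.side_nets, fast_cfg)


class TestTrainEm:
    def test_losses_finite_and_decreasing(self, trained):
        assert np.isfinite(trained.loss_trace_q).all()
        assert np.isfinite(trained.loss_trace_p).all()
        assert trained.loss_trace_q[-1] < trained.loss_trace_q[0]
        assert trained.loss_trace_p[-1] < trained.loss_trace_p[0]

    def test_deterministic_given_seed(self, tiny_bundle, fast_cfg, trained):
        from circlink import train_and_score

        again = train_and_score(tiny_bundle.A_train, tiny_bundle.side_nets, fast_cfg)
        np.testing.assert_array_equal(trained.scores, again.scores)

    def test_rank_inequality_of_fusion(self, trained):
        Fc, Fd = trained.pstate.Fc, trained.pstate.Fd
        fused = predict_scores(Fc, Fd, 0.8)
        r = np.linalg.matrix_rank(fused, tol=1e-8)
        assert r <= np.linalg.matrix_rank(Fc, tol=1e-8) + np.linalg.matrix_rank(
            Fd, tol=1e-8
        )

    def test_propagated_labels_in_unit_interval(self, trained):
        for F in (trained.pstate.Fc, trained.pstate.Fd):
            assert F.min() > 0.0 and F.max() < 1.0

    def test_recovers_masked_positives_above_chance(self, tiny_bundle, trained):
        from circlink.evaluation import masked_recovery_metrics

        roc, _ = masked_recovery_metrics(
            trained.scores,
            np.asarray(tiny_bundle.A_full.values, float),
            np.asarray(tiny_bundle.A_train.values, float),
        )
        assert roc > 0.7

    def test_graph_size_mismatch_rejected(self, tiny_bundle, fast_cfg):
        from circlink import build_side_graphs, conv_feature_map, matrix_factorize

        emb = matrix_factorize(tiny_bundle.A_train, k=5, reg=0.01)
        feats = conv_feature_map(emb)
        g_c, g_d = build_side_graphs(tiny_bundle.A_train, tiny_bundle.side_nets)
        with pytest.raises(ValueError, match="graph sizes"):
            train_em(tiny_bundle.A_train, (g_d, g_c), feats, fast_cfg)
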