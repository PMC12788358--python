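import numpy as np
import pytest

from gcirnet.model import (
    ArchitectureConfig,
    LatentStats,
    LossWeights,
    TrainConfig,
    _train_step,
    build_model,
    load_model,
    loss_cla,
    loss_rec,
    loss_reg,
    predict,
    reparameterize,
    save_model,
    search_loss_weights,
    simplex_lattice,
    total_loss,
    train,
)

TINY = ArchitectureConfig(
    input_shape=(8, 8, 2), conv_filters=(2, 3, 4), latent_dim=5,
    classifier_hidden=6, n_classes=2,
)


def _separable_images(rng, n_per_class=16, shape=(8, 8, 2), gap=0.6):
    """Class 0 bright on the left half, class 1 on the right."""
    h, w, b = shape
    Y = rng.uniform(0, 0.25, (2 * n_per_class, h, w, b))
    Y[:n_per_class, :, : w // 2, :] += gap
    Y[n_per_class:, :, w // 2 :, :] += gap
    Y = np.clip(Y, 0, 1)
    P = np.zeros((2 * n_per_class, 2))
    P[:n_per_class, 0] = 1
    P[n_per_class:, 1] = 1
    return Y, P


class TestArchitecture:
    def test_flattened_feature_length_is_12000(self):
        cfg = ArchitectureConfig()
        assert cfg.flat_features == 12000

    def test_encoder_shape_sequence(self):
        model = build_model(ArchitectureConfig(), seed=0)
        shapes = model.encoder_shapes()
        # post-activation / post-pool shapes along the encoder
        assert shapes[1] == (40, 40, 6)
        assert shapes[2] == (20, 20, 6)
        assert shapes[4] == (20, 20, 16)
        assert shapes[5] == (10, 10, 16)
        assert shapes[7] == (10, 10, 120)
        assert shapes[8] == (12000,)
        assert shapes[10] == (128,)

    def test_parameter_count_matches_layer_arithmetic(self):
        model = build_model(ArchitectureConfig(), seed=0)

        def conv(ci, co):
            return 9 * ci * co + co

        def dense(i, o):
            return i * o + o

        expected = (
            conv(4, 6) + conv(6, 16) + conv(16, 120) + dense(12000, 128)
            + dense(128, 128) + dense(128, 128)            # mu, logvar heads
            + dense(128, 128) + dense(128, 12000)          # decoder dense
            + conv(120, 16) + conv(16, 6) + conv(6, 4)     # decoder convs
            + dense(128, 128) + dense(128, 2)              # classifier
        )
        assert sum(p.size for p in model.params) == expected

    def test_same_seed_bit_identical_init(self):
        m1 = build_model(TINY, seed=42)
        m2 = build_model(TINY, seed=42)
        for p1, p2 in zip(m1.params, m2.params):
            np.testing.assert_array_equal(p1, p2)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ArchitectureConfig(input_shape=(42, 42, 4))


class TestReparameterize:
    def test_zero_variance_returns_mean(self):
        ls = LatentStats(mu=np.ones((1, 4)), logvar=np.full((1, 4), -1e9))
        z = reparameterize(ls, np.ones((1, 4)))
        np.testing.assert_allclose(z, 1.0, atol=1e-6)

    def test_standard_prior_returns_epsilon(self, rng):
        eps = rng.standard_normal((3, 5))
        ls = LatentStats(mu=np.zeros((3, 5)), logvar=np.zeros((3, 5)))
        np.testing.assert_array_equal(reparameterize(ls, eps), eps)

    def test_monte_carlo_mean(self, rng):
        mu = np.array([[0.7, -1.2]])
        logvar = np.array([[0.3, -0.5]])
        n = 100_000
        eps = rng.standard_normal((n, 2))
        z = reparameterize(LatentStats(np.tile(mu, (n, 1)), np.tile(logvar, (n, 1))), eps)
        sd = np.exp(0.5 * logvar[0])
        assert np.all(np.abs(z.mean(axis=0) - mu[0]) <= 3 * sd / np.sqrt(n))


class TestLosses:
    def test_perfect_reconstruction_is_zero(self, rng):
        Y = rng.uniform(0, 1, (4, 6, 6, 2))
        assert loss_rec(Y, Y.copy(), Y.mean(axis=0)) == 0.0

    def test_mean_image_predictor_is_one(self, rng):
        Y = rng.uniform(0, 1, (4, 6, 6, 2))
        Ybar = Y.mean(axis=0)
        Yhat = np.broadcast_to(Ybar, Y.shape)
        np.testing.assert_allclose(loss_rec(Y, Yhat, Ybar), 1.0, atol=1e-9)

    def test_rec_matches_elementwise_oracle(self, rng):
        Y = rng.uniform(0, 1, (3, 5, 5, 2))
        Yhat = rng.uniform(0, 1, (3, 5, 5, 2))
        Ybar = rng.uniform(0, 1, (5, 5, 2))
        num = sum(
            (Y[i, a, b, c] - Yhat[i, a, b, c]) ** 2
            for i in range(3) for a in range(5) for b in range(5) for c in range(2)
        )
        den = sum(
            (Y[i, a, b, c] - Ybar[a, b, c]) ** 2
            for i in range(3) for a in range(5) for b in range(5) for c in range(2)
        )
        np.testing.assert_allclose(loss_rec(Y, Yhat, Ybar), num / den, atol=1e-12)

    def test_all_equal_to_mean_rejected(self):
        Y = np.full((3, 2, 2, 1), 0.5)
        with pytest.raises(ValueError):
            loss_rec(Y, Y, Y[0])

    def test_uniform_prediction_scores_one(self):
        P = np.array([[1.0, 0], [0, 1.0], [1.0, 0]])
        Phat = np.full((3, 2), 0.5)
        np.testing.assert_allclose(loss_cla(P, Phat), 1.0, atol=1e-9)

    def test_uniform_prediction_scores_one_multiclass(self):
        P = np.eye(5)
        Phat = np.full((5, 5), 0.2)
        np.testing.assert_allclose(loss_cla(P, Phat), 1.0, atol=1e-9)

    def test_perfect_onehot_prediction_near_zero(self):
        P = np.array([[1.0, 0], [0, 1.0]])
        assert loss_cla(P, P.copy()) < 1e-5

    def test_hand_computed_binary_ratio(self):
        # p=(1,0), phat=(0.8,0.2): CCE = -ln 0.8; uniform normalizer
        # = -(ln 0.8 + ln 0.2)/2; ratio = 0.243529...
        P = np.array([[1.0, 0.0]])
        Phat = np.array([[0.8, 0.2]])
        expected = -np.log(0.8) / (-(np.log(0.8) + np.log(0.2)) / 2)
        np.testing.assert_allclose(loss_cla(P, Phat), expected, atol=1e-12)
        np.testing.assert_allclose(expected, 0.2435, atol=5e-5)

    def test_non_simplex_prediction_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            loss_cla(np.array([[1.0, 0]]), np.array([[0.9, 0.3]]))

    def test_prior_matching_posterior_is_zero(self):
        ls = LatentStats(np.zeros((4, 8)), np.zeros((4, 8)))
        assert loss_reg(ls) == 0.0

    def test_hand_computed_kl_value(self):
        # N=2, 1-D latent, mu=1, logvar=0: KL per sample = 1/2; total
        # normalized by N ln N = 2 ln 2
        ls = LatentStats(np.ones((2, 1)), np.zeros((2, 1)))
        np.testing.assert_allclose(loss_reg(ls), 1.0 / (2 * np.log(2)), atol=1e-12)

    def test_kl_nonnegative(self, rng):
        ls = LatentStats(rng.standard_normal((6, 4)), rng.standard_normal((6, 4)))
        assert loss_reg(ls) >= 0

    def test_single_sample_guard_warns(self):
        ls = LatentStats(np.ones((1, 2)), np.zeros((1, 2)))
        with pytest.warns(UserWarning, match="single-sample"):
            val = loss_reg(ls)
        assert np.isfinite(val) and val > 0

    def test_total_loss_is_convex_combination(self, rng):
        assert total_loss(LossWeights(1, 0, 0), 0.3, 9.0, 9.0) == 0.3
        assert total_loss(LossWeights(1 / 3, 1 / 3, 1 / 3), 1, 1, 1) == pytest.approx(1.0)
        r, c, k = rng.uniform(0, 2, 3)
        w = LossWeights(0.2, 0.5, 0.3)
        np.testing.assert_allclose(total_loss(w, r, c, k), 0.2 * r + 0.5 * c + 0.3 * k)

    def test_weights_must_live_on_simplex(self):
        with pytest.raises(ValueError):
            LossWeights(0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            LossWeights(-0.2, 0.6, 0.6)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Central-difference check of the composite loss gradient."""
        model = build_model(TINY, seed=3)
        n = 3
        Y = rng.uniform(0.1, 0.9, (n,) + TINY.input_shape)
        P = np.zeros((n, 2))
        P[np.arange(n), rng.integers(0, 2, n)] = 1
        Ybar = rng.uniform(0.3, 0.7, TINY.input_shape)
        w = LossWeights(0.3, 0.4, 0.3)
        eps = rng.standard_normal((n, TINY.latent_dim))

        _train_step(model, Y, P, Ybar, w, eps)
        analytic = [gr.copy() for gr in model.grads]

        def f():
            return _train_step(model, Y, P, Ybar, w, eps)["total"]

        h = 1e-6
        checked = 0
        idx_rng = np.random.default_rng(0)
        for pi, param in enumerate(model.params):
            for _ in range(3):
                flat = idx_rng.integers(0, param.size)
                orig = param.flat[flat]
                param.flat[flat] = orig + h
                fp = f()
                param.flat[flat] = orig - h
                fm = f()
                param.flat[flat] = orig
                numeric = (fp - fm) / (2 * h)
                a = analytic[pi].flat[flat]
                denom = max(abs(a), abs(numeric), 1e-8)
                assert abs(a - numeric) / denom < 1e-4, (
                    f"param {pi} entry {flat}: analytic {a} vs numeric {numeric}"
                )
                checked += 1
        assert checked >= 30


class TestTraining:
    def test_loss_decreases_on_separable_data(self, rng):
        Y, P = _separable_images(rng)
        model = build_model(TINY, seed=0)
        train(model, Y, P, Y[:6], P[:6], LossWeights(0.2, 0.6, 0.2),
              cfg=TrainConfig(epochs=6, batch_size=8), seed=0)
        tot = model.history["total"]
        assert tot[-1] < tot[0]

    def test_early_stopping_fires_within_patience(self, rng):
        Y, P = _separable_images(rng, n_per_class=8)
        model = build_model(TINY, seed=1)
        cfg = TrainConfig(epochs=200, batch_size=8, patience=4)
        train(model, Y, P, Y[:4], P[:4], LossWeights(0.3, 0.4, 0.3), cfg=cfg, seed=1)
        n_epochs = len(model.history["total"])
        best = int(model.history["best_epoch"][0])
        assert n_epochs <= best + cfg.patience + 1

    def test_fixed_seed_reproducible_history(self, rng):
        Y, P = _separable_images(rng, n_per_class=8)
        hists = []
        for _ in range(2):
            model = build_model(TINY, seed=5)
            train(model, Y, P, Y[:4], P[:4], LossWeights(0.3, 0.4, 0.3),
                  cfg=TrainConfig(epochs=4, batch_size=8), seed=5)
            hists.append(model.history)
        np.testing.assert_array_equal(hists[0]["total"], hists[1]["total"])
        np.testing.assert_array_equal(hists[0]["val_total"], hists[1]["val_total"])

    def test_empty_split_rejected(self, rng):
        Y, P = _separable_images(rng, n_per_class=4)
        model = build_model(TINY, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(model, Y, P, Y[:0], P[:0], LossWeights(1 / 3, 1 / 3, 1 / 3))


class TestPredict:
    def test_output_contracts(self, rng):
        model = build_model(TINY, seed=2)
        Y = rng.uniform(0, 1, (5,) + TINY.input_shape)
        out = predict(model, Y)
        np.testing.assert_allclose(out["probs"].sum(axis=1), 1.0, atol=1e-6)
        assert out["reconstruction"].min() >= 0 and out["reconstruction"].max() <= 1
        assert out["mu"].shape == (5, TINY.latent_dim)
        out2 = predict(model, Y)
        np.testing.assert_array_equal(out["probs"], out2["probs"])

    def test_shape_mismatch_rejected(self, rng):
        model = build_model(TINY, seed=2)
        with pytest.raises(ValueError, match="shape"):
            predict(model, rng.uniform(0, 1, (2, 12, 12, 2)))

    def test_checkpoint_round_trip(self, rng, tmp_path):
        model = build_model(TINY, seed=9)
        Y = rng.uniform(0, 1, (3,) + TINY.input_shape)
        path = tmp_path / "model.ckpt"
        save_model(model, str(path))
        back = load_model(str(path))
        np.testing.assert_array_equal(
            predict(model, Y)["probs"], predict(back, Y)["probs"]
        )


class TestWeightSearch:
    def test_single_candidate_returned_unchanged(self, rng):
        Y, P = _separable_images(rng, n_per_class=4)
        only = LossWeights(0.5, 0.25, 0.25)
        got = search_loss_weights(Y, P, Y[:4], P[:4], TINY, candidates=[only])
        assert got == only

    def test_lattice_candidates_on_simplex(self):
        lattice = simplex_lattice(0.1)
        assert len(lattice) == 66
        for w in lattice:
            arr = w.as_array()
            assert abs(arr.sum() - 1) < 1e-9 and np.all(arr >= 0)

    def test_uninformative_labels_deprioritize_classification(self):
        """With label structure destroyed, the searched weights should
        not favor the classification term (its validation loss cannot
        drop below the uniform baseline)."""
        candidates = [
            LossWeights(0.8, 0.1, 0.1),
            LossWeights(0.1, 0.8, 0.1),
            LossWeights(0.1, 0.1, 0.8),
            LossWeights(1 / 3, 1 / 3, 1 / 3),
        ]
        median_cla = np.median([w.lam_cla for w in candidates])
        selected = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            Y, _ = _separable_images(rng, n_per_class=8)
            P = np.zeros((16, 2))
            P[np.arange(16), rng.integers(0, 2, 16)] = 1  # labels shuffled away
            w = search_loss_weights(
                Y[:12], P[:12], Y[12:], P[12:], TINY,
                candidates=candidates, cfg=TrainConfig(epochs=3, batch_size=8),
                seed=seed,
            )
            selected.append(w.lam_cla)
        assert np.mean(selected) <= median_cla
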