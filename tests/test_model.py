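"""Adversarial model: network forwards, minimax value, gradients, training
determinism, scoring and checkpointing."""

import numpy as np
import pytest
from sklearn.base import clone

from biganlda import (
    BiGANAssociationScorer,
    BiGANModel,
    NetworkConfig,
    TrainConfig,
    rank_candidates,
    score_pairs,
    train,
)
from biganlda.bigan import (
    association_scores,
    bigan_value,
    bigan_value_disc_grads,
    discriminator_forward,
    encoder_forward,
    generator_forward,
    load_checkpoint,
    save_checkpoint,
)
from biganlda.datatypes import PairFeature
from biganlda.nn import MLP, sigmoid


def tiny_model(input_dim=2, latent_dim=1, hidden=(3,), seed=0):
    cfg = NetworkConfig(
        input_dim=input_dim,
        latent_dim=latent_dim,
        hidden_dims_encoder=hidden,
        hidden_dims_generator=hidden,
        hidden_dims_discriminator=hidden,
    )
    return BiGANModel(cfg, seed=seed)


def make_features(X, labels=None):
    labels = labels if labels is not None else np.ones(len(X), dtype=int)
    return [
        PairFeature(f"d{i}", f"l{i}", x, label=int(y))
        for i, (x, y) in enumerate(zip(X, labels))
    ]


class TestForwardPasses:
    def test_relu_zeroes_negatives_with_identity_weights(self):
        rng = np.random.default_rng(0)
        net = MLP([2, 2, 2], rng)
        net.weights[0] = np.eye(2)
        net.biases[0] = np.zeros(2)
        net.weights[1] = np.eye(2)
        net.biases[1] = np.zeros(2)
        out = net.forward(np.array([1.0, -2.0]))
        np.testing.assert_array_equal(out[0], [1.0, 0.0])

    def test_zero_input_zero_bias_gives_zero(self):
        model = tiny_model()
        for net in (model.encoder, model.generator):
            for k in range(net.n_layers):
                net.biases[k][:] = 0.0
        assert np.all(encoder_forward(model, np.zeros(2)) == 0.0)
        assert np.all(generator_forward(model, np.zeros(1)) == 0.0)

    def test_forward_is_deterministic(self):
        model = tiny_model(seed=3)
        x = np.array([0.3, -0.7])
        np.testing.assert_array_equal(
            encoder_forward(model, x), encoder_forward(model, x)
        )

    def test_generator_output_dimension(self):
        model = tiny_model(input_dim=5, latent_dim=2)
        assert generator_forward(model, np.zeros(2)).shape == (5,)

    def test_shape_errors(self):
        model = tiny_model()
        with pytest.raises(ValueError, match="features"):
            encoder_forward(model, np.zeros(7))


class TestDiscriminator:
    def test_zero_logit_gives_half(self):
        model = tiny_model()
        disc = model.discriminator
        for k in range(disc.n_layers):
            disc.weights[k][:] = 0.0
            disc.biases[k][:] = 0.0
        assert discriminator_forward(model, np.zeros(2), np.zeros(1)) == 0.5

    def test_sigmoid_monotone_and_bounded(self):
        x = np.linspace(-50, 50, 101)
        s = sigmoid(x)
        assert np.all(np.diff(s) >= 0)
        assert s.min() >= 0.0 and s.max() <= 1.0
        assert sigmoid(np.array([-1e3]))[0] == 0.0  # saturates, never negative
        assert sigmoid(np.array([1e3]))[0] == 1.0

    def test_deterministic(self):
        model = tiny_model(seed=9)
        x, z = np.array([0.1, 0.2]), np.array([0.5])
        assert discriminator_forward(model, x, z) == discriminator_forward(
            model, x, z
        )


class TestMinimaxValue:
    def test_equilibrium_value_with_half_discriminator(self):
        model = tiny_model()
        disc = model.discriminator
        for k in range(disc.n_layers):
            disc.weights[k][:] = 0.0
            disc.biases[k][:] = 0.0
        rng = np.random.default_rng(1)
        v = bigan_value(model, rng.normal(size=(8, 2)), rng.normal(size=(8, 1)))
        assert v == pytest.approx(-2.0 * np.log(2.0), abs=1e-15)

    def test_matches_direct_probability_computation(self):
        model = tiny_model(seed=4)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 2))
        Z = rng.normal(size=(5, 1))
        e = model.encoder.forward(X)
        g = model.generator.forward(Z)
        p_real = np.array(
            [discriminator_forward(model, x, ze) for x, ze in zip(X, e)]
        )
        p_fake = np.array(
            [discriminator_forward(model, gx, z) for gx, z in zip(g, Z)]
        )
        expected = np.log(p_real).mean() + np.log1p(-p_fake).mean()
        assert bigan_value(model, X, Z) == pytest.approx(expected, rel=1e-12)

    def test_empty_batch_rejected(self):
        model = tiny_model()
        with pytest.raises(ValueError, match="non-empty"):
            bigan_value(model, np.empty((0, 2)), np.ones((1, 1)))

    def test_discriminator_gradient_matches_finite_differences(self):
        """Backprop gradient of the minimax value vs central differences."""
        model = tiny_model(seed=7)
        rng = np.random.default_rng(11)
        X = rng.normal(size=(4, 2))
        Z = rng.normal(size=(4, 1))
        grads = bigan_value_disc_grads(model, X, Z)
        params = model.discriminator.params()
        h = 1e-6
        for p, g in zip(params, grads):
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = p[idx]
                p[idx] = orig + h
                up = bigan_value(model, X, Z)
                p[idx] = orig - h
                down = bigan_value(model, X, Z)
                p[idx] = orig
                num = (up - down) / (2 * h)
                denom = max(abs(num), abs(g[idx]), 1e-8)
                assert abs(num - g[idx]) / denom < 1e-4


class TestTraining:
    def _data(self, n=80, dim=6, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(0, 1, size=(n, dim))

    def _cfgs(self, dim=6, **kw):
        net = NetworkConfig(
            input_dim=dim, latent_dim=2,
            hidden_dims_encoder=(8,), hidden_dims_generator=(8,),
            hidden_dims_discriminator=(8,),
        )
        return net, TrainConfig(batch_size=16, **kw)

    def test_same_seed_identical_parameters(self):
        X = self._data()
        net, tc = self._cfgs(epochs=2, seed=5)
        m1 = train(X, net, tc)
        m2 = train(X, net, tc)
        for a, b in zip(m1.encoder.params() + m1.generator.params()
                        + m1.discriminator.params(),
                        m2.encoder.params() + m2.generator.params()
                        + m2.discriminator.params()):
            np.testing.assert_array_equal(a, b)

    def test_zero_epochs_returns_initialised_model(self):
        X = self._data()
        net, tc = self._cfgs(epochs=0, seed=5)
        trained = train(X, net, tc)
        fresh = BiGANModel(net, seed=5)
        for a, b in zip(trained.encoder.params(), fresh.encoder.params()):
            np.testing.assert_array_equal(a, b)

    def test_training_improves_bidirectional_consistency(self):
        X = self._data()
        net, tc = self._cfgs(epochs=10, seed=5)
        trained = train(X, net, tc)
        untrained = train(X, net, TrainConfig(batch_size=16, epochs=0, seed=5))
        assert trained.recon_scale_ < untrained.recon_scale_

    def test_too_few_positives_raises(self):
        X = self._data(n=10)
        net, tc = self._cfgs(epochs=1)
        with pytest.raises(ValueError, match="batch_size"):
            train(X, net, tc)

    def test_parameters_stay_finite(self):
        X = self._data()
        net, tc = self._cfgs(epochs=5, seed=2)
        m = train(X, net, tc)
        for p in (m.encoder.params() + m.generator.params()
                  + m.discriminator.params()):
            assert np.isfinite(p).all()


class TestScoring:
    def _trained(self, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, size=(60, 6))
        net = NetworkConfig(
            input_dim=6, latent_dim=2, hidden_dims_encoder=(8,),
            hidden_dims_generator=(8,), hidden_dims_discriminator=(8,),
        )
        model = train(X, net, TrainConfig(epochs=3, batch_size=16, seed=seed))
        return model

    def test_scores_in_unit_interval(self):
        model = self._trained()
        feats = make_features(np.random.default_rng(1).uniform(0, 1, (10, 6)))
        table = score_pairs(model, feats)
        assert ((table["score"] > 0) & (table["score"] < 1)).all()

    def test_identical_vectors_identical_scores(self):
        model = self._trained()
        v = np.full(6, 0.4)
        feats = make_features(np.stack([v, v]))
        table = score_pairs(model, feats)
        assert table["score"].iloc[0] == table["score"].iloc[1]

    def test_scores_invariant_to_submission_order(self):
        model = self._trained()
        X = np.random.default_rng(3).uniform(0, 1, (8, 6))
        fwd = score_pairs(model, make_features(X))
        rev = score_pairs(model, make_features(X[::-1]))
        np.testing.assert_allclose(
            fwd["score"].to_numpy(), rev["score"].to_numpy()[::-1]
        )

    def test_rank_candidates_contracts(self):
        import pandas as pd
        table = pd.DataFrame({
            "disease_id": ["d"] * 4,
            "lncrna_id": ["l3", "l1", "l2", "l0"],
            "score": [0.1, 0.9, 0.1, 0.1],
            "known_flag": [0, 0, 0, 1],
        })
        assert rank_candidates(table, "d", 2) == ["l1", "l2"]
        # k larger than candidate count: no padding
        assert rank_candidates(table, "d", 10) == ["l1", "l2", "l3"]
        # all-equal scores fall back to lexicographic order
        table["score"] = 0.5
        assert rank_candidates(table, "d", 3) == ["l1", "l2", "l3"]
        with pytest.raises(KeyError):
            rank_candidates(table, "unknown", 2)


class TestCheckpoint:
    def test_round_trip_scores_exactly(self, tmp_path):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(40, 6))
        net = NetworkConfig(
            input_dim=6, latent_dim=2, hidden_dims_encoder=(8,),
            hidden_dims_generator=(8,), hidden_dims_discriminator=(8,),
        )
        model = train(X, net, TrainConfig(epochs=2, batch_size=16, seed=1))
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        Xq = rng.uniform(0, 1, size=(7, 6))
        np.testing.assert_array_equal(
            association_scores(model, Xq), association_scores(loaded, Xq)
        )
        assert loaded.recon_scale_ == model.recon_scale_


class TestEstimatorInterface:
    def test_sklearn_clone_and_params(self):
        est = BiGANAssociationScorer(latent_dim=4, epochs=2)
        cloned = clone(est)
        assert cloned.get_params()["latent_dim"] == 4
        est.set_params(epochs=3)
        assert est.epochs == 3

    def test_fit_and_score(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(64, 6))
        est = BiGANAssociationScorer(
            latent_dim=2, hidden_dims_encoder=(8,), hidden_dims_generator=(8,),
            hidden_dims_discriminator=(8,), epochs=2, batch_size=16,
        )
        est.fit(X)
        s = est.decision_function(X[:5])
        assert s.shape == (5,)
        assert ((s > 0) & (s < 1)).all()
        assert est.n_features_in_ == 6
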