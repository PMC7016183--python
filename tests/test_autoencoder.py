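import numpy as np
import pytest

from modlight.autoencoder import (
    AEArchitecture,
    TrainConfig,
    corrupt,
    encode,
    fit_metrics,
    forward,
    init_model,
    load_model,
    save_model,
    train,
)
from modlight.expression import ExpressionMatrix
from modlight.synthetic import SyntheticConfig, generate

from conftest import random_model


def brute_force_forward(model, X):
    """Independent layer-by-layer recursion used as the oracle."""
    def sigmoid(z):
        return 1.0 / (1.0 + np.exp(-z))
    acts = [np.asarray(X, dtype=float)]
    for k in range(2, model.n_layers + 1):
        W, b = model.weights[k - 2], model.biases[k - 2]
        z = W @ acts[-1] + b[:, None]
        acts.append(sigmoid(z))
    return acts


class TestArchitecture:
    def test_layer_widths_include_gene_count(self):
        arch = AEArchitecture(n_features=100, hidden_widths=(8, 8, 8))
        assert arch.layer_widths == (100, 8, 8, 8, 100)
        assert arch.n_layers == 5

    @pytest.mark.parametrize("bad", [(), (0,), (8, -1)])
    def test_invalid_widths(self, bad):
        with pytest.raises(ValueError):
            AEArchitecture(n_features=10, hidden_widths=bad)


class TestInitModel:
    def test_deep_shapes(self):
        # three hidden layers -> encoder two weight sets, decoder two
        model = init_model(AEArchitecture(n_features=100, hidden_widths=(8, 8, 8)), 0)
        shapes = [W.shape for W in model.weights]
        assert shapes == [(8, 100), (8, 8), (8, 8), (100, 8)]
        assert [b.shape for b in model.biases] == [(8,), (8,), (8,), (100,)]

    def test_shallow_has_two_weight_matrices(self):
        model = init_model(AEArchitecture(n_features=20, hidden_widths=(4,)), 0)
        assert len(model.weights) == 2

    def test_seed_reproducible_bitwise(self):
        arch = AEArchitecture(n_features=30, hidden_widths=(5, 5, 5))
        a, b = init_model(arch, 42), init_model(arch, 42)
        for Wa, Wb in zip(a.weights, b.weights):
            assert np.array_equal(Wa, Wb)


class TestForward:
    def test_zero_weights_give_half(self):
        model = init_model(AEArchitecture(n_features=6, hidden_widths=(3,)), 0)
        for W in model.weights:
            W[:] = 0
        acts = forward(model, np.zeros((6, 2)))
        for x in acts[1:]:
            np.testing.assert_allclose(x, 0.5)

    def test_sigmoid_saturation(self):
        model = init_model(AEArchitecture(n_features=1, hidden_widths=(1,)), 0)
        for W in model.weights:
            W[:] = 0
        model.biases[-1][:] = 50.0
        out = forward(model, np.array([[0.3]]))[-1]
        assert out[0, 0] > 1 - 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(7, (4, 3, 4), seed)
        X = rng.uniform(size=(7, 5))
        got = forward(model, X)
        want = brute_force_forward(model, X)
        for g, w in zip(got, want):
            np.testing.assert_allclose(g, w, atol=1e-12)

    def test_shape_mismatch(self):
        model = init_model(AEArchitecture(n_features=6, hidden_widths=(3,)), 0)
        with pytest.raises(ValueError, match="rows"):
            forward(model, np.zeros((5, 2)))


class TestEncode:
    def test_encode_equals_forward_layer(self, rng):
        model = random_model(6, (3, 3, 3), 1)
        X = rng.uniform(size=(6, 4))
        for layer in (2, 3, 4):
            np.testing.assert_array_equal(encode(model, X, layer),
                                          forward(model, X)[layer - 1])

    @pytest.mark.parametrize("layer", [1, 5, 0])
    def test_layer_out_of_range(self, layer):
        model = init_model(AEArchitecture(n_features=6, hidden_widths=(3, 3, 3)), 0)
        with pytest.raises(ValueError, match="layer"):
            encode(model, np.zeros((6, 1)), layer)


class TestTrain:
    def test_zero_epochs_leaves_model_unchanged(self, rng):
        model = init_model(AEArchitecture(n_features=5, hidden_widths=(2,)), 3)
        before = [W.copy() for W in model.weights]
        train(model, rng.uniform(size=(5, 10)), config=TrainConfig(epochs=0))
        for W, Wb in zip(model.weights, before):
            assert np.array_equal(W, Wb)

    def test_values_outside_unit_interval_rejected(self):
        model = init_model(AEArchitecture(n_features=2, hidden_widths=(2,)), 0)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            train(model, np.array([[2.0], [0.0]]), config=TrainConfig(epochs=1))

    def test_rank2_data_reconstructed(self):
        # 2 planted modules, low noise: a deep 8-wide AE explains >= 90 % of
        # the variance after 200 epochs
        comp = generate(SyntheticConfig(
            n_genes=100, n_samples=300, n_modules=2, genes_per_module=50,
            n_cell_types=2, n_diseases=1, noise_sd=0.02, seed=0,
        ))
        model = init_model(AEArchitecture(n_features=100, hidden_widths=(8, 8, 8)), 0)
        model, history = train(
            model, comp.expression,
            config=TrainConfig(learning_rate=1e-2, epochs=200, shuffle_seed=0),
        )
        assert fit_metrics(model, comp.expression).r2_global >= 0.9
        # loss decreases on average
        h = history["train_loss"]
        assert np.mean(h[-20:]) < np.mean(h[:20])

    def test_training_deterministic_given_seeds(self, rng):
        X = rng.uniform(size=(10, 30))
        runs = []
        for _ in range(2):
            model = init_model(AEArchitecture(n_features=10, hidden_widths=(3,)), 5)
            model, _ = train(model, X, config=TrainConfig(
                learning_rate=1e-3, epochs=5, shuffle_seed=9))
            runs.append([W.copy() for W in model.weights])
        for Wa, Wb in zip(*runs):
            assert np.array_equal(Wa, Wb)

    def test_sparse_l1_shrinks_weights(self, rng):
        X = rng.uniform(size=(20, 60))
        configs = {}
        for l1 in (0.0, 1e-2):
            model = init_model(
                AEArchitecture(n_features=20, hidden_widths=(4,), sparse_l1=l1), 2
            )
            model, _ = train(model, X, config=TrainConfig(
                learning_rate=1e-2, epochs=60, shuffle_seed=2))
            configs[l1] = np.mean([np.abs(W).mean() for W in model.weights])
        assert configs[1e-2] < configs[0.0]

    def test_early_stopping_restores_best(self, rng):
        X = rng.uniform(size=(8, 20))
        model = init_model(AEArchitecture(n_features=8, hidden_widths=(3,)), 1)
        model, history = train(model, X, X, config=TrainConfig(
            learning_rate=1e-2, epochs=200, patience=5, shuffle_seed=1))
        assert len(history["valid_mse"]) <= 200


class TestCorruption:
    def test_clipped_noise_stays_in_unit_interval_with_reduced_sd(self, rng):
        # clipping a N(0, 0.5) perturbation of 0.5 at [0, 1] shrinks its spread
        batch = np.full((200, 200), 0.5)
        noisy = corrupt(batch, 0.5, rng)
        assert noisy.min() >= 0.0 and noisy.max() <= 1.0
        assert noisy.std() < 0.5
        assert noisy.std() > 0.3  # still plenty of corruption

    def test_denoising_training_runs(self, rng):
        X = rng.uniform(size=(10, 30))
        model = init_model(
            AEArchitecture(n_features=10, hidden_widths=(3,), denoising_sd=0.5), 0
        )
        _, history = train(model, X, config=TrainConfig(epochs=2))
        assert np.isfinite(history["train_loss"]).all()


class TestFitMetrics:
    def test_perfect_reconstruction(self):
        # identity behaviour cannot be realized by a sigmoid net, so compare
        # a model against its own output
        model = random_model(5, (3,), 0)
        X = np.random.default_rng(0).uniform(size=(5, 7))
        recon = forward(model, X)[-1]
        m = fit_metrics(model, X)
        # recompute with an independent two-pass oracle
        sse = float(((recon - X) ** 2).sum())
        sst = float(((X - X.mean()) ** 2).sum())
        np.testing.assert_allclose(m.r2_global, 1 - sse / sst, atol=1e-12)

    def test_mean_predictor_scores_zero(self):
        # zero weights emit 0.5 everywhere; on data with global mean 0.5 and
        # symmetric gene means that is exactly the mean predictor
        model = init_model(AEArchitecture(n_features=2, hidden_widths=(2,)), 0)
        for W in model.weights:
            W[:] = 0
        X = np.array([[0.2, 0.8], [0.6, 0.4]])
        m = fit_metrics(model, X)
        np.testing.assert_allclose(m.r2_global, 0.0, atol=1e-12)

    def test_genewise_oracle_and_constant_gene_nan(self, rng):
        model = random_model(4, (2,), 3)
        X = rng.uniform(size=(4, 6))
        X[2, :] = 0.5  # constant gene
        m = fit_metrics(model, X)
        recon = forward(model, X)[-1]
        for i in (0, 1, 3):
            sse = ((recon[i] - X[i]) ** 2).sum()
            sst = ((X[i] - X[i].mean()) ** 2).sum()
            np.testing.assert_allclose(m.r2_genewise[i], 1 - sse / sst, atol=1e-12)
        assert np.isnan(m.r2_genewise[2])
        assert m.r2_global <= 1
        np.testing.assert_allclose(m.error_global, 1 - m.r2_global)


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path):
        model = random_model(12, (4, 4, 4), 8)
        model.architecture.denoising_sd = 0.5
        path = tmp_path / "model.zip"
        save_model(model, path)
        back = load_model(path)
        assert back.architecture == model.architecture
        assert back.init_seed == model.init_seed
        for Wa, Wb in zip(model.weights, back.weights):
            assert np.array_equal(Wa, Wb)
        for ba, bb in zip(model.biases, back.biases):
            assert np.array_equal(ba, bb)
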