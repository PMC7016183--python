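import numpy as np
import pytest

from modlight.autoencoder import AEArchitecture, TrainConfig, encode, init_model
from modlight.disease import (
    DiseaseScore,
    PhenotypeDesign,
    StackedNet,
    SupervisedNet,
    build_phenotype_matrix,
    naive_baseline,
    predict_disease_genes,
    score_disease,
    stack,
    train_reverse,
)
from modlight.disease import _moment_match
from modlight.expression import ExpressionMatrix, SampleAnnotation

from conftest import random_model


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def make_sup(P, H, seed, hidden=None):
    rng = np.random.default_rng(seed)
    hidden = H if hidden is None else hidden
    return SupervisedNet(
        rng.normal(size=(hidden, P)), rng.normal(size=hidden),
        rng.normal(size=(H, hidden)), rng.normal(size=H), train_seed=seed,
    )


class TestPhenotypeMatrix:
    def test_indicator_layout(self):
        anns = [SampleAnnotation(s, p, "disease")
                for s, p in [("s1", "A"), ("s2", "B"), ("s3", "A")]]
        design = build_phenotype_matrix(anns, ["A", "B"])
        np.testing.assert_array_equal(design.matrix, [[1, 0, 1], [0, 1, 0]])

    def test_unannotated_sample_gets_zero_column(self):
        anns = [SampleAnnotation("s1", "A", "disease")]
        design = build_phenotype_matrix(anns, ["A"], samples=["s1", "s2"])
        np.testing.assert_array_equal(design.matrix, [[1, 0]])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_phenotype_matrix([], ["A", "A"])

    def test_conflicting_labels_rejected(self):
        anns = [SampleAnnotation("s1", "A", "disease"),
                SampleAnnotation("s1", "B", "disease")]
        with pytest.raises(ValueError, match="two labels"):
            build_phenotype_matrix(anns, ["A", "B"])

    def test_multi_column_design_rejected(self):
        with pytest.raises(ValueError, match="more than one"):
            PhenotypeDesign(["A", "B"], ["s1"], np.array([[1.0], [1.0]]))


class TestTrainReverse:
    def test_single_phenotype_converges_to_mean(self, rng):
        target = rng.uniform(size=(4, 20))
        anns = [SampleAnnotation(f"s{j}", "A", "disease") for j in range(20)]
        design = build_phenotype_matrix(anns, ["A"])
        net = train_reverse(target, design,
                            config=TrainConfig(learning_rate=1e-2, epochs=400), seed=0)
        pred = net.forward(design.indicator("A")[:, None])[:, 0]
        np.testing.assert_allclose(pred, target.mean(axis=1), atol=0.05)

    def test_loss_decreases_from_init(self, rng):
        target = rng.uniform(size=(3, 30))
        labels = ["A", "B", "C"]
        anns = [SampleAnnotation(f"s{j}", labels[j % 3], "disease")
                for j in range(30)]
        design = build_phenotype_matrix(anns, labels)
        init = make_sup(3, 3, 1)
        init_loss = float(np.mean((init.forward(design.matrix) - target) ** 2))
        net = train_reverse(target, design,
                            config=TrainConfig(learning_rate=1e-2, epochs=200), seed=1)
        final_loss = float(np.mean((net.forward(design.matrix) - target) ** 2))
        assert final_loss < init_loss

    def test_separated_phenotypes_predict_centroids(self, rng):
        # two well-separated groups in a 5-dimensional code
        c1, c2 = np.full(5, 0.2), np.full(5, 0.8)
        Z = np.column_stack([c1 + rng.normal(0, 0.01, 5) for _ in range(15)]
                            + [c2 + rng.normal(0, 0.01, 5) for _ in range(15)])
        anns = [SampleAnnotation(f"s{j}", "A" if j < 15 else "B", "disease")
                for j in range(30)]
        design = build_phenotype_matrix(anns, ["A", "B"])
        net = train_reverse(Z, design,
                            config=TrainConfig(learning_rate=1e-2, epochs=500), seed=2)
        for label, idx in (("A", slice(0, 15)), ("B", slice(15, 30))):
            pred = net.forward(design.indicator(label)[:, None])[:, 0]
            centroid = Z[:, idx].mean(axis=1)
            assert np.mean((pred - centroid) ** 2) < 0.01

    def test_width_mismatch_rejected(self, rng):
        design = build_phenotype_matrix(
            [SampleAnnotation("s0", "A", "disease")], ["A"])
        with pytest.raises(ValueError, match="samples"):
            train_reverse(rng.uniform(size=(4, 5)), design)


class TestStack:
    def test_rescale_off_composes_exactly(self):
        ae = random_model(8, (3, 3, 3), 0)
        sup = make_sup(2, 3, 1)
        stacked = stack(sup, ae, 4, [f"g{i}" for i in range(8)], ["A", "B"],
                        rescale=False)
        r = np.array([1.0, 0.0])
        x = sup.forward(r[:, None])[:, 0]
        want = ae.weights[-1] @ x
        got = score_disease(stacked, "A").scores
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_moment_match_identity_on_self(self, rng):
        W = rng.normal(size=(4, 4))
        out, scale, shift = _moment_match(W, W)
        np.testing.assert_allclose(out, W, atol=1e-12)
        assert abs(scale - 1) < 1e-12 and abs(shift) < 1e-12

    def test_rescaled_moments_match_target(self, rng):
        source, target = rng.normal(2, 3, size=(5, 6)), rng.normal(-1, 0.5, (7, 2))
        out, _, _ = _moment_match(source, target)
        assert abs(out.mean() - target.mean()) < 1e-12
        assert abs(out.std() - target.std()) < 1e-12

    def test_width_mismatch_rejected(self):
        ae = random_model(8, (3, 3, 3), 0)
        sup = make_sup(2, 4, 1)  # wrong output width
        with pytest.raises(ValueError, match="width"):
            stack(sup, ae, 4, [f"g{i}" for i in range(8)], ["A", "B"])


class TestScoreDisease:
    def test_zero_final_weights_give_zero_scores(self):
        genes = [f"g{i}" for i in range(6)]
        sup = make_sup(2, 3, 0)
        stacked = StackedNet(["A", "B"], genes,
                             [(sup.W_hidden, sup.b_hidden, "sigmoid"),
                              (sup.W_out, sup.b_out, "linear")],
                             np.zeros((6, 3)))
        res = score_disease(stacked, "A")
        np.testing.assert_array_equal(res.scores, np.zeros(6))
        assert res.ranked_genes == genes

    def test_single_layer_stack_selects_column(self, rng):
        W = rng.normal(size=(5, 3))
        stacked = StackedNet(["a", "b", "c"], [f"g{i}" for i in range(5)], [], W)
        res = score_disease(stacked, "b")
        np.testing.assert_allclose(res.scores, W[:, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_recursion(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(7)]
        sup = make_sup(3, 4, seed)
        ae = random_model(7, (4, 4, 4), seed + 50)
        stacked = stack(sup, ae, 3, genes, ["p0", "p1", "p2"], rescale=False)
        res = score_disease(stacked, "p1")
        # oracle: explicit recursion
        x = np.array([0.0, 1.0, 0.0])
        x = sigmoid(sup.W_hidden @ x + sup.b_hidden)
        x = sup.W_out @ x + sup.b_out
        x = sigmoid(ae.weights[2] @ x + ae.biases[2])   # layer 3 -> 4
        want = ae.weights[3] @ x                        # final, no bias
        np.testing.assert_allclose(res.scores, want, atol=1e-10)

    def test_unknown_phenotype(self):
        stacked = StackedNet(["A"], ["g0"], [], np.zeros((1, 1)))
        with pytest.raises(KeyError):
            score_disease(stacked, "B")

    def test_ranking_uses_absolute_value(self):
        res = DiseaseScore("p", np.array([0.1, -5.0, 2.0]), ["g0", "g1", "g2"])
        assert res.ranked_genes == ["g1", "g2", "g0"]


@pytest.fixture(scope="module")
def tiny_pipeline_inputs():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(12)]
    samples = [f"s{j}" for j in range(24)]
    E = ExpressionMatrix(genes, samples, rng.uniform(size=(12, 24)))
    anns = []
    for j, s in enumerate(samples):
        anns.append(SampleAnnotation(s, "A" if j % 2 else "B", "disease"))
    ae = random_model(12, (4, 4, 4), 3)
    return E, anns, ae


class TestPredictDiseaseGenes:
    def test_single_repeat_equals_aggregate(self, tiny_pipeline_inputs):
        E, anns, ae = tiny_pipeline_inputs
        cfg = TrainConfig(learning_rate=1e-2, epochs=20)
        preds = predict_disease_genes(E, anns, ae, 4, ["A", "B"], config=cfg,
                                      repeats=1, seeds=[4])
        np.testing.assert_allclose(preds["A"].mean_abs_score,
                                   np.abs(preds["A"].per_repeat[0]))

    def test_same_seeds_identical_and_repeat_order_invariant(self, tiny_pipeline_inputs):
        E, anns, ae = tiny_pipeline_inputs
        cfg = TrainConfig(learning_rate=1e-2, epochs=20)
        a = predict_disease_genes(E, anns, ae, 4, ["A", "B"], config=cfg,
                                  repeats=2, seeds=[1, 2])
        b = predict_disease_genes(E, anns, ae, 4, ["A", "B"], config=cfg,
                                  repeats=2, seeds=[2, 1])
        np.testing.assert_allclose(a["A"].mean_abs_score, b["A"].mean_abs_score,
                                   atol=1e-12)

    def test_empty_phenotype_skipped_with_warning(self, tiny_pipeline_inputs):
        E, anns, ae = tiny_pipeline_inputs
        cfg = TrainConfig(learning_rate=1e-2, epochs=5)
        with pytest.warns(UserWarning, match="ghost"):
            preds = predict_disease_genes(E, anns, ae, 4, ["A", "ghost"],
                                          config=cfg, repeats=1, seeds=[0])
        assert "ghost" not in preds and "A" in preds


class TestNaiveBaseline:
    def test_deterministic_and_full_length(self, tiny_pipeline_inputs):
        E, anns, _ = tiny_pipeline_inputs
        design = build_phenotype_matrix(anns, ["A", "B"], samples=E.sample_ids)
        cfg = TrainConfig(learning_rate=1e-2, epochs=20)
        a = naive_baseline(E, design, hidden=6, config=cfg, seed=9)
        b = naive_baseline(E, design, hidden=6, config=cfg, seed=9)
        assert set(a) == {"A", "B"}
        for p in a:
            assert len(a[p].scores) == E.n_genes
            np.testing.assert_array_equal(a[p].scores, b[p].scores)
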