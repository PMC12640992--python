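import numpy as np
import pytest

from panfuse.classifier import (
    ClassifierConfig,
    ClassifierResults,
    CrossFusionClassifier,
    _Network,
    cross_fusion,
)
from panfuse.io import ExpressionMatrix


def brute_cross_fusion(Fc, Fg, scale="sqrt_d"):
    """Scalar-loop evaluation of the fusion equation, kept deliberately dumb."""
    L, d = Fc.shape
    denom = d**0.5 if scale == "sqrt_d" else float(d)
    scores = [[sum(Fc[i][m] * Fg[j][m] for m in range(d)) / denom for j in range(L)] for i in range(L)]
    att = []
    for row in scores:
        mx = max(row)
        exps = [np.exp(v - mx) for v in row]
        s = sum(exps)
        att.append([e / s for e in exps])
    S = [[Fc[i][m] + Fg[i][m] for m in range(d)] for i in range(L)]
    Fcg = [[sum(att[i][j] * S[j][m] for j in range(L)) for m in range(d)] for i in range(L)]
    return np.array(att), np.array(Fcg)


class TestCrossFusion:
    def test_matches_scalar_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            L = int(rng.integers(1, 6))
            d = int(rng.integers(1, 5))
            Fc = rng.standard_normal((L, d))
            Fg = rng.standard_normal((L, d))
            ft = cross_fusion(Fc, Fg)
            att, Fcg = brute_cross_fusion(Fc, Fg)
            np.testing.assert_allclose(ft.attention, att, atol=1e-6)
            np.testing.assert_allclose(ft.Fcg, Fcg, atol=1e-6)

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        ft = cross_fusion(rng.standard_normal((4, 3)), rng.standard_normal((4, 3)))
        np.testing.assert_allclose(ft.attention.sum(axis=1), 1.0, atol=1e-6)
        assert (ft.attention >= 0).all()

    def test_single_token_collapses_to_sum(self):
        Fc = np.array([[1.0, -2.0, 0.5]])
        Fg = np.array([[0.25, 4.0, -1.0]])
        ft = cross_fusion(Fc, Fg)
        np.testing.assert_array_equal(ft.Fcg, Fc + Fg)

    def test_zero_spatial_features_give_uniform_attention(self):
        rng = np.random.default_rng(2)
        Fg = rng.standard_normal((5, 3))
        ft = cross_fusion(np.zeros((5, 3)), Fg)
        np.testing.assert_allclose(ft.attention, 1.0 / 5, atol=1e-12)
        np.testing.assert_allclose(ft.Fcg, np.tile(Fg.mean(axis=0), (5, 1)), atol=1e-12)

    def test_literal_d_scaling_option(self):
        rng = np.random.default_rng(3)
        Fc, Fg = rng.standard_normal((3, 4)), rng.standard_normal((3, 4))
        att, Fcg = brute_cross_fusion(Fc, Fg, scale="d")
        ft = cross_fusion(Fc, Fg, scale="d")
        np.testing.assert_allclose(ft.Fcg, Fcg, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_fusion(np.zeros((2, 3)), np.zeros((3, 2)))


def _toy_matrix(n_samples=24, n_genes=64, k=3, seed=0, effect=6.0):
    rng = np.random.default_rng(seed)
    y = np.arange(n_samples) % k
    values = rng.standard_normal((n_genes, n_samples))
    for c in range(k):
        values[c * 5 : (c + 1) * 5, y == c] += effect
    X = ExpressionMatrix(
        [f"g{i}" for i in range(n_genes)], [f"s{i}" for i in range(n_samples)], values
    )
    return X, y


class TestNetworkShapes:
    def test_branch_token_grid_shapes(self):
        # 64 genes, window 4 -> L = 16 tokens, projected to d = 8
        cfg = ClassifierConfig(d=8, lstm_hidden=4, conv_channels=(4, 8, 8))
        net = _Network(n_genes=64, k=3, cfg=cfg, rng=np.random.default_rng(0))
        assert net.L == 16
        ft = net.fusion_tensors(np.random.default_rng(1).standard_normal(64))
        assert ft.Fc.shape == (16, 8)
        assert ft.Fg.shape == (16, 8)
        assert ft.Fcg.shape == (16, 8)

    def test_zero_input_zero_bias_conv_is_zero(self):
        cfg = ClassifierConfig(d=8, lstm_hidden=4, conv_channels=(4, 8, 8))
        net = _Network(n_genes=64, k=2, cfg=cfg, rng=np.random.default_rng(0))
        ft = net.fusion_tensors(np.zeros(64))
        np.testing.assert_allclose(ft.Fc, 0.0, atol=1e-12)  # relu(conv(0)+0) proj with zero bias

    def test_zeroed_final_layer_gives_uniform_distribution(self):
        X, y = _toy_matrix()
        model = CrossFusionClassifier(X, y, config=ClassifierConfig(d=8, lstm_hidden=4))
        net = _Network(len(model.gene_order), model.k, model.config, np.random.default_rng(0))
        net.params["fc_w"].data[:] = 0.0
        net.params["fc_b"].data[:] = 0.0
        from panfuse.classifier import _row_softmax

        logits = net.forward(model._design(X))
        probs = _row_softmax(logits.data)
        np.testing.assert_allclose(probs, 1.0 / 3, atol=1e-12)

    def test_length_mismatch_is_error(self):
        X, y = _toy_matrix()
        model = CrossFusionClassifier(X, y, config=ClassifierConfig(d=8, lstm_hidden=4))
        bad = ExpressionMatrix(["g0", "g1"], ["a"], np.zeros((2, 1)))
        fitted = ClassifierResults(
            model=model,
            network=_Network(64, 3, model.config, np.random.default_rng(0)),
            history=None, best_epoch=0, classes=3,
        )
        with pytest.raises(KeyError):
            fitted.predict_proba(bad)


@pytest.fixture(scope="module")
def trained_toy():
    X, y = _toy_matrix(n_samples=30, n_genes=64, seed=4)
    cfg = ClassifierConfig(
        d=16, lstm_hidden=8, conv_channels=(8, 16, 16),
        max_epochs=40, patience=10, batch_size=8, seed=0,
    )
    res = CrossFusionClassifier(X, y, config=cfg).fit()
    return X, y, res, cfg


class TestTraining:
    def test_probabilities_normalised(self, trained_toy):
        X, y, res, _ = trained_toy
        probs = res.predict_proba(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_training_loss_trends_down(self, trained_toy):
        _, _, res, _ = trained_toy
        loss = res.history["train_loss"].to_numpy()
        # monotone trend over the opening of training: mean of first 3 epochs
        # exceeds mean of epochs 5-8 on a separable fixture
        assert loss[:3].mean() > loss[4:8].mean()

    def test_fit_accuracy_on_separable_fixture(self, trained_toy):
        X, y, res, _ = trained_toy
        assert (res.predict(X) == y).mean() >= 0.9

    def test_seed_determinism(self, trained_toy):
        X, y, _, cfg = trained_toy
        r1 = CrossFusionClassifier(X, y, config=cfg).fit()
        r2 = CrossFusionClassifier(X, y, config=cfg).fit()
        for name in r1.network.params:
            np.testing.assert_array_equal(
                r1.network.params[name].data, r2.network.params[name].data
            )
        assert r1.history.equals(r2.history)

    def test_missing_class_rejected(self):
        X, y = _toy_matrix()
        y = y.copy()
        y[y == 2] = 1  # class 2 absent but max label says k=3
        y[0] = 2
        with pytest.raises(ValueError):
            CrossFusionClassifier(X, np.where(y == 2, 3, y))

    def test_save_load_round_trip(self, trained_toy, tmp_path):
        X, y, res, _ = trained_toy
        res.save(tmp_path / "model")
        back = ClassifierResults.load(tmp_path / "model")
        np.testing.assert_allclose(back.predict_proba(X), res.predict_proba(X), atol=1e-12)


class TestEvaluate:
    def test_perfect_probabilities_score_one(self, trained_toy):
        X, y, res, _ = trained_toy
        # hand-crafted: probabilities equal to one-hot truth
        from panfuse.classifier import _row_softmax  # noqa: F401
        from sklearn.metrics import roc_auc_score

        probs = np.eye(3)[y]
        for c in range(3):
            assert roc_auc_score((y == c).astype(int), probs[:, c]) == 1.0

    def test_auc_matches_brute_force_pair_counting(self, trained_toy):
        X, y, res, _ = trained_toy
        probs = res.predict_proba(X)
        metrics = res.evaluate(X, y)
        for c in range(3):
            pos = probs[y == c, c]
            neg = probs[y != c, c]
            pairs = concord = 0
            for a in pos:
                for b in neg:
                    pairs += 1
                    concord += 1.0 if a > b else (0.5 if a == b else 0.0)
            np.testing.assert_allclose(metrics["auc_per_class"][c], concord / pairs, atol=1e-12)

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(7)
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, 4000)
        scores = rng.random(4000)
        assert abs(roc_auc_score(y, scores) - 0.5) <= 0.05

    def test_single_class_test_set_rejected(self, trained_toy):
        X, y, res, _ = trained_toy
        with pytest.raises(ValueError):
            res.evaluate(X, np.zeros_like(y))
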