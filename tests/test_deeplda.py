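"""Fisher ratio, Deep-LDA training and CV evaluation contracts."""

import numpy as np
import pandas as pd
import pytest

from translocv.deeplda import DeepLDAConfig, DeepLDACV, fisher_ratio, train_deep_lda
from translocv.errors import InputError, SchemaError
from translocv.tables import DescriptorTable


class TestFisherRatio:
    def test_identical_class_distributions_give_zero(self):
        z = np.random.default_rng(0).normal(size=200)
        labels = np.array(["A"] * 100 + ["B"] * 100)
        both = np.concatenate([z[:100], z[:100]])
        assert fisher_ratio(both, labels) == pytest.approx(0.0, abs=1e-12)

    def test_unit_variance_classes_at_plus_minus_two_give_four(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 50000)
        a = (a - a.mean()) / a.std()  # exact moments
        z = np.concatenate([a + 2.0, a - 2.0])
        labels = np.array(["A"] * len(a) + ["B"] * len(a))
        assert fisher_ratio(z, labels) == pytest.approx(4.0, rel=1e-10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        z = np.concatenate([rng.normal(1, 1, 300), rng.normal(-1, 2, 300)])
        labels = np.array(["A"] * 300 + ["B"] * 300)
        assert fisher_ratio(10 * z, labels) == pytest.approx(fisher_ratio(z, labels))

    def test_degenerate_label_sets_rejected(self):
        with pytest.raises(InputError):
            fisher_ratio([1.0, 2.0], ["A", "A"])
        with pytest.raises(InputError):
            fisher_ratio([1.0, 2.0, 3.0], ["A", "B", "C"])


def _gaussian_two_class_table(n=400, d=6, seed=0):
    rng = np.random.default_rng(seed)
    cov = np.diag(rng.uniform(0.5, 2.0, d))
    mu = rng.normal(0, 2.0, d)
    Xa = rng.multivariate_normal(mu, cov, n)
    Xb = rng.multivariate_normal(-mu, cov, n)
    df = pd.DataFrame(np.vstack([Xa, Xb]), columns=[f"f{i}" for i in range(d)])
    labels = np.array(["PRE"] * n + ["POST"] * n)
    return DescriptorTable(df, labels=labels), mu, cov


class TestTraining:
    def test_linear_network_recovers_the_closed_form_discriminant(self):
        table, mu, cov = _gaussian_two_class_table(n=2000, seed=3)
        cfg = DeepLDAConfig(
            layer_widths=(6, 3), epochs=800, learning_rate=5e-3, seed=0
        )
        model = train_deep_lda(table, cfg)
        # overall linear map: x -> (x W + b) . w, direction = W w (in
        # standardized coordinates); compare with Sw^-1 (mu1 - mu2)
        W = model.net.W[0]
        learned = W @ model.direction / model.standardizer.std
        Xa = table.values()[:2000]
        Xb = table.values()[2000:]
        Sw = 0.5 * (np.cov(Xa.T) + np.cov(Xb.T))
        closed = np.linalg.solve(Sw, Xa.mean(axis=0) - Xb.mean(axis=0))
        cos = learned @ closed / np.linalg.norm(learned) / np.linalg.norm(closed)
        assert abs(cos) > 0.99

    def test_shuffled_labels_destroy_separation(self):
        table, _, _ = _gaussian_two_class_table(n=300, seed=4)
        rng = np.random.default_rng(0)
        table.labels = rng.permutation(table.labels)
        cfg = DeepLDAConfig(layer_widths=(6, 4, 3), epochs=150, seed=0)
        model = train_deep_lda(table, cfg)
        z = model.raw_projection(table.values())
        assert fisher_ratio(z, table.labels) < 0.1

    def test_training_loss_decreases_epoch_smoothed(self, labeled_two_state):
        cfg = DeepLDAConfig(layer_widths=(69, 30, 20, 15, 10, 5), epochs=120, seed=0)
        model = train_deep_lda(labeled_two_state, cfg)
        h = model.loss_history
        k = 20
        assert h[-k:].mean() < h[:k].mean()

    def test_same_seed_same_parameters(self, labeled_two_state):
        cfg = DeepLDAConfig(layer_widths=(69, 30, 20, 15, 10, 5), epochs=30, seed=5)
        m1 = train_deep_lda(labeled_two_state, cfg)
        m2 = train_deep_lda(labeled_two_state, cfg)
        for a, b in zip(m1.net.parameters(), m2.net.parameters()):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(m1.direction, m2.direction)

    def test_too_few_frames_rejected(self):
        table, _, _ = _gaussian_two_class_table(n=50)
        with pytest.raises(InputError):
            train_deep_lda(table, DeepLDAConfig(layer_widths=(6, 3)))


@pytest.fixture(scope="module")
def small_trained_cv(labeled_two_state):
    cfg = DeepLDAConfig(layer_widths=(69, 30, 20, 15, 10, 5), epochs=150, seed=2)
    return train_deep_lda(labeled_two_state, cfg)


class TestEvaluation:
    def test_evaluation_is_deterministic_and_batch_consistent(
        self, small_trained_cv, labeled_two_state
    ):
        X = labeled_two_state.values()[:16]
        batch = small_trained_cv.evaluate(X)
        singles = np.array([small_trained_cv.evaluate(x[None, :])[0] for x in X])
        np.testing.assert_allclose(batch, singles)
        np.testing.assert_array_equal(batch, small_trained_cv.evaluate(X))

    def test_training_mean_vector_maps_like_the_zero_input(self, small_trained_cv):
        cv_at_mean = small_trained_cv.raw_projection(
            small_trained_cv.standardizer.mean[None, :]
        )
        h0 = small_trained_cv.net.forward(np.zeros((1, 69)))
        assert cv_at_mean[0] == pytest.approx((h0 @ small_trained_cv.direction).item())

    def test_output_is_bounded_on_arbitrary_probes(self, small_trained_cv):
        rng = np.random.default_rng(0)
        probes = rng.uniform(-1e4, 1e4, size=(200, 69))
        cv = small_trained_cv.evaluate(probes)
        bound = (small_trained_cv.lorentzian_scale + abs(small_trained_cv.offset)) / abs(
            small_trained_cv.halfspan
        )
        assert np.all(np.abs(cv) <= bound)

    def test_state_sign_convention_and_separation(self, small_trained_cv, labeled_two_state):
        cv = small_trained_cv.evaluate(labeled_two_state.values())
        pre = cv[labeled_two_state.labels == "PRE"]
        post = cv[labeled_two_state.labels == "POST"]
        assert pre.mean() > 0 > post.mean()
        # histogram overlap coefficient below 5%
        lo, hi = min(cv), max(cv)
        bins = np.linspace(lo, hi, 60)
        hp, _ = np.histogram(pre, bins=bins, density=True)
        hq, _ = np.histogram(post, bins=bins, density=True)
        overlap = np.minimum(hp, hq).sum() * (bins[1] - bins[0])
        assert overlap < 0.05

    def test_input_gradient_matches_finite_differences(self, small_trained_cv):
        x = small_trained_cv.standardizer.mean + 0.3
        g = small_trained_cv.gradient(x[None, :])[0]
        eps = 1e-5
        num = np.empty_like(x)
        for j in range(len(x)):
            dx = np.zeros_like(x)
            dx[j] = eps
            num[j] = (
                small_trained_cv.evaluate((x + dx)[None, :])[0]
                - small_trained_cv.evaluate((x - dx)[None, :])[0]
            ) / (2 * eps)
        np.testing.assert_allclose(g, num, rtol=1e-3, atol=1e-8)

    def test_dimension_mismatch_raises_schema_error(self, small_trained_cv):
        with pytest.raises(SchemaError):
            small_trained_cv.evaluate(np.zeros((3, 12)))

    def test_model_file_round_trip(self, small_trained_cv, labeled_two_state, tmp_path):
        path = tmp_path / "cv.json"
        small_trained_cv.save(path)
        loaded = DeepLDACV.load(path)
        X = labeled_two_state.values()[:8]
        np.testing.assert_allclose(loaded.evaluate(X), small_trained_cv.evaluate(X))
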