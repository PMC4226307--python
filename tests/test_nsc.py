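import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_matrix
from wntstrat.io import ExpressionMatrix
from wntstrat.nsc import (
    classify,
    cross_validate,
    soft_threshold,
    to_wnt_calls,
    train_nsc,
    transfer_classify,
)
from wntstrat.simulate import SimulationConfig, simulate_perturbation_training


def two_class_matrix(rng, n_genes=20, n_per_class=10, shift=3.0):
    vals = rng.standard_normal((n_genes, 2 * n_per_class))
    vals[0, :n_per_class] += shift  # gene 0 separates the classes
    X = ExpressionMatrix(pd.DataFrame(
        vals, index=[f"G{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(2 * n_per_class)]))
    labels = ["pos"] * n_per_class + ["neg"] * n_per_class
    return X, labels


class TestSoftThreshold:
    @pytest.mark.parametrize("d,delta,expected", [
        (2.5, 1.0, 1.5),
        (-0.3, 1.0, 0.0),
        (-2.5, 1.0, -1.5),
        (0.0, 5.0, 0.0),
    ])
    def test_examples(self, d, delta, expected):
        assert soft_threshold(d, delta) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-1e6, 1e6), st.floats(0, 1e6))
    def test_shrinks_toward_zero_never_past(self, d, delta):
        out = float(soft_threshold(d, delta))
        assert abs(out) <= abs(d) + 1e-9
        assert out == 0 or np.sign(out) == np.sign(d)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestTrain:
    def test_delta_zero_keeps_raw_centroids(self, rng):
        X, labels = two_class_matrix(rng)
        model = train_nsc(X, labels)
        shrunk = model.shrunken_centroids(0.0)
        pd.testing.assert_frame_equal(shrunk, model.centroids,
                                      check_exact=False, atol=1e-10)

    def test_full_shrinkage_collapses_to_overall(self, rng):
        X, labels = two_class_matrix(rng)
        model = train_nsc(X, labels)
        big = float(np.abs(model.dik.to_numpy()).max())
        shrunk = model.shrunken_centroids(big + 1e-9)
        for cls in model.classes:
            np.testing.assert_allclose(shrunk.loc[cls].to_numpy(),
                                       model.overall_centroid.to_numpy(),
                                       atol=1e-10)

    def test_surviving_offsets_have_correct_sign(self, rng):
        """Well-separated one-informative-gene classes: after moderate
        shrinkage only gene 0 survives and d' signs match the class means.
        Checked against a by-hand computation of d_ik."""
        X, labels = two_class_matrix(rng, n_genes=10, n_per_class=20, shift=5.0)
        model = train_nsc(X, labels)
        vals = X.values
        overall = vals.mean(axis=1)
        pos = vals[:, :20]
        n, n_k = 40, 20
        m_k = np.sqrt(1 / n_k - 1 / n)
        ss = ((pos - pos.mean(1, keepdims=True)) ** 2).sum(1) + \
            ((vals[:, 20:] - vals[:, 20:].mean(1, keepdims=True)) ** 2).sum(1)
        s = np.sqrt(ss / (n - 2))
        d_pos_hand = (pos.mean(1) - overall) / (m_k * (s + np.median(s)))
        np.testing.assert_allclose(model.dik.loc["pos"].to_numpy(), d_pos_hand,
                                   rtol=1e-10)
        dp = model.shrunken_offsets(0.5 * abs(d_pos_hand[0]))
        assert dp.loc["pos", "G0"] > 0 and dp.loc["neg", "G0"] < 0

    def test_monotone_shrinkage_path(self, rng):
        X, labels = two_class_matrix(rng, n_genes=100)
        model = train_nsc(X, labels)
        counts = [model.nonzero_gene_count(d) for d in model.delta_grid]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[0] == 100 and counts[-1] == 0

    def test_singleton_class_errors(self, rng):
        X, _ = two_class_matrix(rng, n_per_class=2)
        with pytest.raises(ValueError, match="< 2 samples"):
            train_nsc(X, ["a", "a", "a", "b"])


class TestClassify:
    def test_sample_at_centroid_gets_maximal_posterior(self, rng):
        X, labels = two_class_matrix(rng)
        model = train_nsc(X, labels)
        at_centroid = ExpressionMatrix(pd.DataFrame(
            {"q": model.shrunken_centroids(0.0).loc["pos"].to_numpy()},
            index=model.genes))
        out = classify(model, at_centroid, delta=0.0)
        assert out.loc["q", "call"] == "pos"
        assert out.loc["q", "pos"] > out.loc["q", "neg"]

    def test_full_shrinkage_gives_uniform_posteriors(self, rng):
        X, labels = two_class_matrix(rng)
        model = train_nsc(X, labels)
        big = float(np.abs(model.dik.to_numpy()).max()) + 1.0
        out = classify(model, X, delta=big)
        np.testing.assert_allclose(out[["pos", "neg"]].to_numpy(), 0.5, atol=1e-12)

    def test_posteriors_sum_to_one(self, rng):
        X, labels = two_class_matrix(rng)
        model = train_nsc(X, labels)
        out = classify(model, X, delta=0.3)
        np.testing.assert_allclose(out[["pos", "neg"]].sum(axis=1), 1.0, atol=1e-12)

    def test_matches_brute_force_discriminant(self, rng):
        """<=5 genes, 3 classes: classify equals an explicit discriminant."""
        vals = rng.standard_normal((5, 12))
        X = ExpressionMatrix(pd.DataFrame(
            vals, index=[f"G{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(12)]))
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        model = train_nsc(X, labels)
        delta = 0.4
        out = classify(model, X, delta=delta)
        cent = model.shrunken_centroids(delta)
        denom = (model.s + model.s0).to_numpy()
        for j, sid in enumerate(X.sample_ids):
            disc = {}
            for cls in model.classes:
                resid = (vals[:, j] - cent.loc[cls].to_numpy()) / denom
                disc[cls] = (resid ** 2).sum() - 2 * np.log(model.priors[cls])
            best = min(disc, key=disc.get)
            assert out.loc[sid, "call"] == best

    def test_no_shared_genes_errors(self, rng):
        X, labels = two_class_matrix(rng)
        model = train_nsc(X, labels)
        other = ExpressionMatrix(pd.DataFrame({"q": [1.0]}, index=["ZZZ"]))
        with pytest.raises(ValueError, match="shared"):
            classify(model, other)


class TestCrossValidate:
    def test_separable_data_zero_error_at_delta_zero(self, rng):
        X, labels = two_class_matrix(rng, shift=8.0)
        chosen, curve = cross_validate(X, labels, folds=4, seed=0)
        assert curve["cv_error"].iloc[0] == 0.0
        assert curve.loc[np.isclose(curve["delta"], chosen), "cv_error"].iloc[0] \
            == curve["cv_error"].min()

    def test_null_labels_give_chance_error(self, rng):
        vals = rng.standard_normal((30, 100))
        X = ExpressionMatrix(pd.DataFrame(
            vals, index=[f"G{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(100)]))
        labels = list(rng.permutation(["a"] * 50 + ["b"] * 50))
        _, curve = cross_validate(X, labels, folds=5, seed=1)
        assert abs(curve["cv_error"].min() - 0.5) < 0.15

    def test_same_seed_reproducible(self, rng):
        X, labels = two_class_matrix(rng)
        c1, curve1 = cross_validate(X, labels, folds=3, seed=7)
        c2, curve2 = cross_validate(X, labels, folds=3, seed=7)
        assert c1 == c2
        pd.testing.assert_frame_equal(curve1, curve2)


class TestTransfer:
    def make_model(self, seed=0, effect=1.5):
        cfg = SimulationConfig(seed=seed, n_genes=400, pathway_effect=effect)
        X, labels, _ = simulate_perturbation_training(cfg)
        binary = labels.map(lambda c: "Wnt" if c == "beta-catenin" else "other")
        model = train_nsc(X, binary)
        model.delta = float(model.delta_grid[len(model.delta_grid) // 2])
        return model, X

    def test_affine_distorted_cohort_gets_identical_calls(self, rng):
        """Per-gene affine distortion is removed by z-scoring: same calls."""
        model, X = self.make_model()
        slope = rng.uniform(0.8, 1.2, X.n_genes)[:, None]
        offset = rng.uniform(-0.5, 0.5, X.n_genes)[:, None]
        distorted = X.with_data(
            pd.DataFrame(slope * X.values + offset, index=X.gene_ids,
                         columns=X.sample_ids))
        calls_raw = transfer_classify(model, X)["call"]
        calls_dist = transfer_classify(model, distorted)["call"]
        pd.testing.assert_series_equal(calls_raw, calls_dist)

    def test_transfer_on_training_cohort_self_consistent(self):
        """Transferring onto the training matrix reproduces the calls of the
        z-space model on the z-scored training data."""
        from wntstrat.preprocess import zscore_genes
        model, X = self.make_model()
        transferred = transfer_classify(model, X)
        Xz = zscore_genes(X)
        refit = train_nsc(Xz, model.training_classes,
                          delta_grid=model.delta_grid, priors="uniform")
        direct = classify(refit, Xz, delta=model.delta)
        pd.testing.assert_series_equal(transferred["call"], direct["call"])

    def test_too_few_shared_genes_refused(self):
        model, X = self.make_model()
        small = ExpressionMatrix(X.data.iloc[:10], cohort_id="thin")
        with pytest.raises(ValueError, match="refusing"):
            transfer_classify(model, small)

    def test_wnt_call_view(self):
        model, X = self.make_model()
        out = transfer_classify(model, X)
        calls = to_wnt_calls(out, "Wnt")
        assert len(calls) == X.n_samples
        for c in calls:
            assert c.call in ("Wnt+", "Wnt-")
            assert 0.0 <= c.posterior <= 1.0
        n_pos = sum(c.call == "Wnt+" for c in calls)
        assert n_pos == (out["call"] == "Wnt").sum()
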