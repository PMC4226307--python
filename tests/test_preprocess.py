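import numpy as np
import pandas as pd
import pytest

from conftest import random_matrix
from wntstrat.io import ExpressionMatrix
from wntstrat.preprocess import (
    combine_replicates,
    harmonize_cohorts,
    hierarchical_cluster,
    quantile_normalize,
    scale_to_target_intensity,
    zscore_genes,
)


def em(data: dict, index, cohort_id="c", scale="log2"):
    return ExpressionMatrix(pd.DataFrame(data, index=index), cohort_id=cohort_id,
                            scale=scale)


class TestQuantileNormalize:
    def test_two_column_example(self):
        X = em({"a": [1.0, 2, 3], "b": [4.0, 5, 6]}, ["G1", "G2", "G3"])
        out = quantile_normalize(X)
        np.testing.assert_allclose(out.data["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out.data["b"], [2.5, 3.5, 4.5])

    def test_identical_distributions_fixed_point(self, rng):
        col = rng.standard_normal(30)
        X = em({"a": col, "b": rng.permutation(col)}, [f"G{i}" for i in range(30)])
        out = quantile_normalize(X)
        np.testing.assert_allclose(np.sort(out.data["a"]), np.sort(col), atol=1e-12)
        np.testing.assert_allclose(out.data["a"], X.data["a"], atol=1e-12)

    def test_columns_share_sorted_vector_and_idempotent(self, rng):
        X = random_matrix(rng, 50, 6)
        out = quantile_normalize(X)
        ref = np.sort(out.data.iloc[:, 0].to_numpy())
        for j in range(6):
            np.testing.assert_allclose(np.sort(out.data.iloc[:, j]), ref, atol=1e-12)
        again = quantile_normalize(out)
        pd.testing.assert_frame_equal(again.data, out.data)

    def test_tied_values_get_mean_of_tied_rank_references(self):
        # column a has a 3-way tie occupying ranks 1..3
        X = em({"a": [5.0, 5.0, 5.0, 9.0], "b": [1.0, 2.0, 3.0, 4.0]},
               ["G1", "G2", "G3", "G4"])
        out = quantile_normalize(X)
        ref = np.sort(X.values, axis=0).mean(axis=1)
        np.testing.assert_allclose(out.data["a"][:3], np.repeat(ref[:3].mean(), 3))

    def test_column_exchangeability(self, rng):
        X = random_matrix(rng, 40, 5)
        out = quantile_normalize(X)
        perm = ["s3", "s0", "s4", "s1", "s2"]
        Xp = X.with_data(X.data[perm])
        outp = quantile_normalize(Xp)
        pd.testing.assert_frame_equal(outp.data, out.data[perm])

    def test_single_column_warns_and_passes_through(self, caplog):
        X = em({"a": [1.0, 2.0]}, ["G1", "G2"])
        with caplog.at_level("WARNING"):
            out = quantile_normalize(X)
        pd.testing.assert_frame_equal(out.data, X.data)


class TestCombineReplicates:
    def test_identical_replicates_unchanged(self):
        X = em({"s1_r1": [1.0, 2], "s1_r2": [1.0, 2], "s2": [5.0, 6]}, ["G1", "G2"])
        out = combine_replicates(X, {"s1_r1": "s1", "s1_r2": "s1"})
        assert out.sample_ids == ["s1", "s2"]
        np.testing.assert_allclose(out.data["s1"], [1.0, 2.0])

    def test_arithmetic_mean(self):
        X = em({"a_r1": [1.0], "a_r2": [3.0]}, ["G1"])
        out = combine_replicates(X, {"a_r1": "a", "a_r2": "a"})
        assert out.data.loc["G1", "a"] == 2.0

    def test_mean_reduces_standard_error(self, rng):
        """Mean of 3 replicates is within 3*sigma/sqrt(3) of mu in >=99% of draws."""
        mu, sigma, hits, n = 5.0, 1.0, 0, 1000
        for _ in range(n):
            vals = rng.normal(mu, sigma, 3)
            hits += abs(vals.mean() - mu) < 3 * sigma / np.sqrt(3)
        assert hits / n >= 0.99

    def test_unknown_sample_in_map_errors(self, tiny_matrix):
        with pytest.raises(KeyError, match="ghost"):
            combine_replicates(tiny_matrix, {"ghost": "s1"})


class TestScaleToTarget:
    def test_column_at_half_target_doubles(self, rng):
        from scipy.stats import trim_mean
        vals = rng.uniform(10, 1000, 200)
        vals = vals * (300 / trim_mean(vals, 0.02))  # trimmed mean exactly 300
        X = em({"a": vals}, [f"G{i}" for i in range(200)], scale="linear")
        out = scale_to_target_intensity(X, target=600)
        np.testing.assert_allclose(out.data["a"], 2 * vals, rtol=1e-9)

    def test_postcondition_trimmed_mean_equals_target(self, rng):
        from scipy.stats import trim_mean
        vals = rng.uniform(1, 2000, 500)
        X = em({"a": vals}, [f"G{i}" for i in range(500)], scale="linear")
        out = scale_to_target_intensity(X, target=600)
        assert abs(trim_mean(out.data["a"], 0.02) - 600) < 1e-9

    def test_fixed_point_when_already_at_target(self, rng):
        from scipy.stats import trim_mean
        vals = rng.uniform(1, 2000, 500)
        vals = vals * (600 / trim_mean(vals, 0.02))
        X = em({"a": vals}, [f"G{i}" for i in range(500)], scale="linear")
        out = scale_to_target_intensity(X, target=600)
        np.testing.assert_allclose(out.data["a"], vals, rtol=1e-12)

    def test_all_zero_column_errors(self):
        X = em({"a": [0.0, 0.0, 0.0]}, ["G1", "G2", "G3"], scale="linear")
        with pytest.raises(ValueError, match="zero"):
            scale_to_target_intensity(X)

    def test_log_scale_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="linear"):
            scale_to_target_intensity(tiny_matrix)


class TestZscore:
    def test_closed_form_row(self):
        X = em({"a": [1.0], "b": [2.0], "c": [3.0]}, ["G1"])
        out = zscore_genes(X)
        np.testing.assert_allclose(out.data.loc["G1"],
                                   [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_constant_row_zeroed_with_warning(self, caplog):
        X = em({"a": [5.0, 1.0], "b": [5.0, 2.0], "c": [5.0, 3.0]}, ["G1", "G2"])
        with caplog.at_level("WARNING"):
            out = zscore_genes(X)
        assert (out.data.loc["G1"] == 0).all()
        assert "constant" in caplog.text

    def test_postconditions_and_rank_preservation(self, rng):
        X = random_matrix(rng, 30, 8)
        out = zscore_genes(X)
        means = out.data.mean(axis=1).to_numpy()
        sds = out.data.std(axis=1, ddof=0).to_numpy()
        assert np.abs(means).max() < 1e-12
        assert np.all((np.abs(sds - 1) < 1e-12) | (sds == 0))
        for gene in X.gene_ids:  # per-gene sample ordering preserved
            assert (X.data.loc[gene].rank() == out.data.loc[gene].rank()).all()


class TestHarmonize:
    def test_duplicate_sample_kept_in_first_cohort(self, rng):
        X1 = random_matrix(rng, 10, 3, "c1")
        X2 = random_matrix(rng, 10, 3, "c2")
        X2.data.columns = ["s7", "x", "y"]
        X1.data.columns = ["s7", "a", "b"]
        out = harmonize_cohorts([X1, X2])
        assert "s7" in out[0].sample_ids and "s7" not in out[1].sample_ids

    def test_disjoint_cohorts_unchanged(self, rng):
        X1 = random_matrix(rng, 10, 3, "c1")
        X2 = random_matrix(rng, 10, 3, "c2")
        X2.data.columns = ["t0", "t1", "t2"]
        out = harmonize_cohorts([X1, X2])
        pd.testing.assert_frame_equal(out[0].data, X1.data)
        pd.testing.assert_frame_equal(out[1].data, X2.data)

    def test_gene_intersection_restriction(self, rng):
        genes = [f"G{i:03d}" for i in range(100)]
        X1 = ExpressionMatrix(pd.DataFrame(
            rng.standard_normal((100, 2)), index=genes, columns=["a", "b"]), "c1")
        X2 = ExpressionMatrix(pd.DataFrame(
            rng.standard_normal((80, 2)), index=genes[20:], columns=["c", "d"]), "c2")
        out = harmonize_cohorts([X1, X2])
        assert out[0].gene_ids == out[1].gene_ids == genes[20:]

    def test_idempotent(self, rng):
        X1 = random_matrix(rng, 10, 3, "c1")
        X2 = random_matrix(rng, 12, 3, "c2")
        X2.data.columns = ["t0", "t1", "t2"]
        once = harmonize_cohorts([X1, X2])
        twice = harmonize_cohorts(once)
        for a, b in zip(once, twice):
            pd.testing.assert_frame_equal(a.data, b.data)

    def test_empty_intersection_errors(self, rng):
        X1 = random_matrix(rng, 5, 2, "c1")
        X2 = random_matrix(rng, 5, 2, "c2")
        X2.data.index = [f"H{i}" for i in range(5)]
        X2.data.columns = ["x", "y"]
        with pytest.raises(ValueError, match="intersection"):
            harmonize_cohorts([X1, X2])


class TestHierarchicalCluster:
    def test_identical_pair_merges_first(self):
        X = em({"s1": [0.0, 0], "s2": [0.0, 0], "s3": [10.0, 10]}, ["G1", "G2"])
        res = hierarchical_cluster(X, axis="samples")
        first = res.linkage_matrix[0, :2].astype(int)
        assert {res.ids[i] for i in first} == {"s1", "s2"}

    def test_determinism_across_runs_and_column_order(self, rng):
        X = random_matrix(rng, 20, 6)
        r1 = hierarchical_cluster(X, axis="samples")
        shuffled = X.with_data(X.data[["s4", "s1", "s0", "s5", "s2", "s3"]])
        r2 = hierarchical_cluster(shuffled, axis="samples")
        np.testing.assert_allclose(r1.linkage_matrix, r2.linkage_matrix)
        assert r1.order == r2.order

    def test_two_tight_triplets_recovered_at_k2(self, rng):
        """Brute-force nearest-pair agglomeration: two separated triplets
        must come out as the two flat clusters."""
        a = rng.normal(0, 0.05, (3, 4))
        b = rng.normal(10, 0.05, (3, 4))
        df = pd.DataFrame(np.vstack([a, b]).T,
                          index=[f"G{i}" for i in range(4)],
                          columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        res = hierarchical_cluster(ExpressionMatrix(df), axis="samples")
        cut = res.cut(2)
        assert cut["a1"] == cut["a2"] == cut["a3"]
        assert cut["b1"] == cut["b2"] == cut["b3"]
        assert cut["a1"] != cut["b1"]

    def test_missing_values_error(self):
        X = em({"a": [1.0, np.nan], "b": [2.0, 3.0], "c": [1.5, 2.0]}, ["G1", "G2"])
        with pytest.raises(ValueError, match="issing"):
            hierarchical_cluster(X, axis="samples")

    def test_newick_contains_all_leaves(self, rng):
        X = random_matrix(rng, 10, 5)
        res = hierarchical_cluster(X, axis="samples")
        nwk = res.to_newick()
        assert nwk.endswith(";")
        for s in X.sample_ids:
            assert s in nwk
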