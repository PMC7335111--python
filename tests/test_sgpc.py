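"""Surrogate-subtype classifier: delta-Z arithmetic, permutation
p-values, cell calls, quantile merging and the bulk classifier."""

import numpy as np
import pandas as pd
import pytest

from glioproteo.containers import SignatureSet
from glioproteo.sgpc import (
    build_signature,
    classify_cells,
    delta_z,
    permutation_pvalue,
    quantile_merge,
    single_cell_gene_filter,
    surrogate_bulk_classify,
    zscore_genes,
)
from glioproteo.synthetic import generate_single_cells

SIG4 = SignatureSet(gpc1_high=["a1", "a2"], gpc2_high=["b1", "b2"])


class TestDeltaZ:
    def test_zero_vector_and_hand_value(self):
        z0 = pd.Series(0.0, index=SIG4.genes)
        assert delta_z(z0, SIG4) == 0.0
        z = pd.Series({"a1": 1.0, "a2": 1.0, "b1": -1.0, "b2": -1.0})
        assert delta_z(z, SIG4) == pytest.approx(2.0)

    def test_antisymmetry_under_side_swap(self):
        rng = np.random.default_rng(0)
        z = pd.Series(rng.normal(size=4), index=SIG4.genes)
        swapped = SignatureSet(gpc1_high=SIG4.gpc2_high, gpc2_high=SIG4.gpc1_high)
        assert delta_z(z, swapped) == pytest.approx(-delta_z(z, SIG4))

    def test_global_shift_invariance(self):
        rng = np.random.default_rng(1)
        z = pd.Series(rng.normal(size=4), index=SIG4.genes)
        assert delta_z(z + 3.7, SIG4) == pytest.approx(delta_z(z, SIG4))

    def test_missing_gene_listed_in_error(self):
        z = pd.Series({"a1": 1.0, "a2": 1.0, "b1": 0.0})
        with pytest.raises(ValueError, match="b2"):
            delta_z(z, SIG4)


class TestPermutationPvalue:
    def test_constant_vector_p_one(self):
        z = pd.Series(1.3, index=SIG4.genes)
        assert permutation_pvalue(z, SIG4, n_perm=200, seed=0) == 1.0

    def test_strong_signal_hits_lower_bound(self):
        sig = SignatureSet(
            gpc1_high=[f"a{i}" for i in range(50)],
            gpc2_high=[f"b{i}" for i in range(50)],
        )
        z = pd.Series(
            np.concatenate([np.full(50, 10.0), np.full(50, -10.0)]), index=sig.genes
        )
        p = permutation_pvalue(z, sig, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_lower_bound_and_determinism(self):
        rng = np.random.default_rng(2)
        z = pd.Series(rng.normal(size=4), index=SIG4.genes)
        p1 = permutation_pvalue(z, SIG4, n_perm=99, seed=5)
        p2 = permutation_pvalue(z, SIG4, n_perm=99, seed=5)
        assert p1 == p2
        assert p1 >= 1 / 100

    def test_invalid_n_perm_errors(self):
        z = pd.Series(0.0, index=SIG4.genes)
        with pytest.raises(ValueError):
            permutation_pvalue(z, SIG4, n_perm=0)


class TestClassifyCells:
    def test_planted_cells_called_with_high_sensitivity(self, signature_100):
        cells, truth = generate_single_cells(200, signature_100, signal=1.5, seed=11)
        out = classify_cells(cells, signature_100, n_perm=500, seed=11)
        for side in ("GPC1", "GPC2"):
            mask = truth == side
            assert (out.loc[mask.to_numpy(), "call"] == side).mean() >= 0.9

    def test_null_cells_rarely_called(self, signature_100):
        cells, _ = generate_single_cells(300, signature_100, signal=0.0, seed=3)
        out = classify_cells(cells, signature_100, n_perm=500, seed=3)
        assert (out["call"] != "unassigned").mean() < 0.12

    def test_determinism_and_call_sign_consistency(self, signature_100):
        cells, _ = generate_single_cells(50, signature_100, signal=1.0, seed=4)
        a = classify_cells(cells, signature_100, seed=4, n_perm=200)
        b = classify_cells(cells, signature_100, seed=4, n_perm=200)
        pd.testing.assert_frame_equal(a, b)
        called = a[a["call"] != "unassigned"]
        assert ((called["call"] == "GPC1") == (called["delta_z"] > 0)).all()


class TestZscoreAndFilters:
    def test_per_gene_axis_standardizes_columns(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(2, 3, size=(50, 4)), columns=list("wxyz"))
        z = zscore_genes(m)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_single_cell_prefilter_drops_sparse_genes(self):
        bulk = pd.DataFrame(
            {"s1": [10.0, 5.0, 1.0], "s2": [9.0, 6.0, 1.0]},
            index=["high_dense", "high_sparse", "low"],
        )
        cells = pd.DataFrame(
            {"high_dense": [1.0, 2.0, 3.0, 4.0],
             "high_sparse": [0.0, 0.0, 0.0, 5.0],
             "low": [1.0, 1.0, 1.0, 1.0]},
            index=[f"c{i}" for i in range(4)],
        )
        kept = single_cell_gene_filter(bulk, cells, top_n=2, min_cell_fraction=0.5)
        assert kept == ["high_dense"]


class TestBuildSignature:
    def _training(self, seed=0, n_inf=40, n_genes=200):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(30)]
        labels = pd.Series(["GPC1"] * 15 + ["GPC2"] * 15, index=samples)
        X = rng.normal(size=(n_genes, 30))
        genes = [f"g{i:03d}" for i in range(n_genes)]
        X[: n_inf // 2, :15] += 3.0   # GPC1-high block
        X[n_inf // 2: n_inf, 15:] += 3.0  # GPC2-high block
        return pd.DataFrame(X, index=genes, columns=samples), labels, genes

    def test_planted_genes_dominate_signature(self):
        expr, labels, genes = self._training()
        sig = build_signature(expr, labels, mode="top_n", n=20)
        assert len(set(sig.gpc1_high) & set(genes[:20])) == 20
        assert len(set(sig.gpc2_high) & set(genes[20:40])) == 20

    def test_fdr_mode_on_null_errors(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(100, 20)),
                            index=[f"g{i}" for i in range(100)],
                            columns=[f"s{i}" for i in range(20)])
        labels = pd.Series(["GPC1"] * 10 + ["GPC2"] * 10, index=expr.columns)
        with pytest.raises(ValueError):
            build_signature(expr, labels, mode="fdr", fdr=0.10)

    def test_shortfall_reported(self):
        expr, labels, _ = self._training(n_genes=30)
        with pytest.raises(ValueError, match="side"):
            build_signature(expr, labels, mode="top_n", n=100)


class TestQuantileMerge:
    def test_sorted_columns_identical_after_merge(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(40)]
        a = pd.DataFrame(rng.normal(size=(40, 5)), index=genes,
                         columns=[f"a{i}" for i in range(5)])
        b = pd.DataFrame(rng.normal(3, 2, size=(40, 4)), index=genes,
                         columns=[f"b{i}" for i in range(4)])
        merged = quantile_merge(a, b)
        ref = np.sort(merged.iloc[:, 0].to_numpy())
        for col in merged.columns:
            np.testing.assert_allclose(np.sort(merged[col].to_numpy()), ref)

    def test_three_sample_hand_example(self):
        a = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [4.0, 6.0, 8.0]},
                         index=["g1", "g2", "g3"])
        b = pd.DataFrame({"z": [2.0, 3.0, 10.0]}, index=["g1", "g2", "g3"])
        merged = quantile_merge(a, b)
        ref = [7 / 3, 11 / 3, 7.0]  # means of order statistics
        np.testing.assert_allclose(merged["x"], ref)
        np.testing.assert_allclose(merged["z"], ref)

    def test_disjoint_gene_sets_error(self):
        a = pd.DataFrame({"x": [1.0]}, index=["g1"])
        b = pd.DataFrame({"y": [1.0]}, index=["g2"])
        with pytest.raises(ValueError):
            quantile_merge(a, b)


class TestBulkClassifier:
    def _cohorts(self, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:03d}" for i in range(150)]
        train_samples = [f"tr{i}" for i in range(24)]
        labels = pd.Series(["GPC1"] * 12 + ["GPC2"] * 12, index=train_samples)
        X = rng.normal(size=(150, 24))
        X[:30, :12] += 3.0
        X[30:60, 12:] += 3.0
        train = pd.DataFrame(X, index=genes, columns=train_samples)
        return train, labels, genes

    def test_duplicated_training_samples_recovered(self):
        train, labels, _ = self._cohorts()
        test = train[["tr0", "tr13"]].copy()
        test.columns = ["te_gpc1", "te_gpc2"]
        out = surrogate_bulk_classify(train, labels, test, seed=0, cv=3)
        assert out.loc["te_gpc1", "call"] == "GPC1"
        assert out.loc["te_gpc2", "call"] == "GPC2"
        assert out.loc["te_gpc1", "prob_GPC1"] >= 0.6

    def test_threshold_zero_calls_everything(self):
        train, labels, genes = self._cohorts()
        rng = np.random.default_rng(9)
        test = pd.DataFrame(rng.normal(size=(150, 3)), index=genes,
                            columns=["t1", "t2", "t3"])
        out = surrogate_bulk_classify(train, labels, test, prob_threshold=0.0,
                                      seed=0, cv=3)
        assert (out["call"] != "unassigned").all()

    def test_single_class_training_errors(self):
        train, labels, _ = self._cohorts()
        labels[:] = "GPC1"
        with pytest.raises(ValueError):
            surrogate_bulk_classify(train, labels, train, seed=0)
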