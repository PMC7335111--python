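"""Quantification-layer behavior: GIS ratios, centering, imputation,
coverage filtering and phospho-site aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glioproteo.containers import IntensityMatrix
from glioproteo.quant import (
    aggregate_phospho_sites,
    collapse_isoforms,
    filter_gis_coverage,
    gis_normalize,
    impute_second_smallest,
    median_center,
    phospho_site_intensity,
)


def _raw(values, tmt_sets):
    samples = pd.DataFrame(
        {"tmt_set": tmt_sets, "gis_batch": tmt_sets}, index=values.columns
    )
    return IntensityMatrix(values, log2=False, samples=samples)


class TestGisNormalize:
    def test_ratio_one_gives_zero_and_simple_ratio(self):
        values = pd.DataFrame(
            {"s1": [2.0, 8.0], "s2": [2.0, np.nan]}, index=["f1", "f2"]
        )
        gis = pd.DataFrame({"set1": [2.0, 2.0]}, index=["f1", "f2"])
        out = gis_normalize(_raw(values, ["set1", "set1"]), gis)
        assert out.log2
        assert out.values.loc["f1", "s1"] == 0.0
        assert out.values.loc["f2", "s1"] == pytest.approx(2.0)  # log2(8/2)
        assert np.isnan(out.values.loc["f2", "s2"])  # missing propagates

    def test_scaling_a_sample_shifts_by_log2_c(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.uniform(1, 100, size=(5, 2)), index=list("abcde"), columns=["s1", "s2"]
        )
        gis = pd.DataFrame({"set1": rng.uniform(1, 10, 5)}, index=list("abcde"))
        base = gis_normalize(_raw(values, ["set1"] * 2), gis)
        scaled = gis_normalize(_raw(values.assign(s1=values["s1"] * 8), ["set1"] * 2), gis)
        np.testing.assert_allclose(
            scaled.values["s1"] - base.values["s1"], np.log2(8), rtol=1e-12
        )

    def test_nonpositive_gis_names_feature(self):
        values = pd.DataFrame({"s1": [2.0]}, index=["f1"])
        gis = pd.DataFrame({"set1": [0.0]}, index=["f1"])
        with pytest.raises(ValueError, match="f1"):
            gis_normalize(_raw(values, ["set1"]), gis)


class TestMedianCenter:
    def test_worked_2x3_example(self, toy_matrix):
        # sample medians (2,4,4); then feature medians (-1, 1)
        out = median_center(toy_matrix)
        expected = pd.DataFrame(
            [[0.0, -1.0, 0.0], [0.0, 1.0, 0.0]],
            index=["f1", "f2"], columns=["s1", "s2", "s3"],
        )
        pd.testing.assert_frame_equal(out.values, expected)

    def test_constant_matrix_maps_to_zero(self):
        values = pd.DataFrame(3.7, index=["f1", "f2"], columns=["s1", "s2"])
        out = median_center(IntensityMatrix(values, log2=True), pd.Series("b1", index=values.columns))
        assert (out.values == 0).all().all()

    def test_within_batch_feature_medians_are_exactly_zero(self, default_cohort):
        matrix, _, batches = default_cohort
        out = median_center(matrix)
        for _, cols in out.values.columns.to_series().groupby(batches):
            med = out.values[cols.index].median(axis=1, skipna=True)
            np.testing.assert_allclose(med.dropna(), 0.0, atol=1e-12)

    def test_batch_centering_step_is_a_fixed_point(self, default_cohort):
        # the final (feature-within-batch) step is idempotent: centering
        # a matrix whose batch medians are already zero changes nothing
        matrix, _, batches = default_cohort
        out = median_center(matrix)
        v = out.values
        recentered = v.copy()
        for _, cols in v.columns.to_series().groupby(batches, sort=False):
            block = recentered[cols.index]
            recentered[cols.index] = block.sub(block.median(axis=1, skipna=True), axis=0)
        np.testing.assert_allclose(
            recentered.to_numpy(), v.to_numpy(), atol=1e-12
        )

    def test_unassigned_sample_errors(self, toy_matrix):
        with pytest.raises(ValueError):
            median_center(toy_matrix, pd.Series({"s1": "b1", "s2": "b1"}))


class TestImputation:
    def test_second_smallest_per_row(self):
        values = pd.DataFrame(
            [[np.nan, 2.0, 3.0, 4.0], [1.0, 1.0, 1.0, 1.0]],
            index=["f1", "f2"], columns=list("abcd"),
        )
        out = impute_second_smallest(IntensityMatrix(values, log2=True))
        assert out.values.loc["f1", "a"] == 3.0
        pd.testing.assert_series_equal(out.values.loc["f2"], values.loc["f2"])

    def test_duplicate_second_order_statistic(self):
        values = pd.DataFrame([[np.nan, 5.0, 5.0]], index=["f1"], columns=list("abc"))
        out = impute_second_smallest(IntensityMatrix(values, log2=True))
        assert out.values.loc["f1", "a"] == 5.0

    def test_too_few_observed_errors(self):
        values = pd.DataFrame([[np.nan, 5.0, np.nan]], index=["f1"], columns=list("abc"))
        with pytest.raises(ValueError, match="f1"):
            impute_second_smallest(IntensityMatrix(values, log2=True))

    def test_global_scope(self):
        values = pd.DataFrame(
            [[np.nan, 9.0], [1.0, 2.0]], index=["f1", "f2"], columns=["a", "b"]
        )
        out = impute_second_smallest(IntensityMatrix(values, log2=True), scope="global")
        assert out.values.loc["f1", "a"] == 2.0


class TestGisCoverage:
    def _matrix(self):
        values = pd.DataFrame(
            {
                "s1": [1.0, np.nan, 1.0],
                "s2": [1.0, 1.0, np.nan],
                "s3": [1.0, np.nan, np.nan],
            },
            index=["full", "b2only", "b1only"],
        )
        samples = pd.DataFrame(
            {"tmt_set": ["t1", "t2", "t3"], "gis_batch": ["b1", "b2", "b3"]},
            index=["s1", "s2", "s3"],
        )
        return IntensityMatrix(values, log2=True, samples=samples)

    def test_zero_threshold_is_identity(self):
        m = self._matrix()
        assert filter_gis_coverage(m, 0).values.shape == m.values.shape

    def test_known_coverage_counts(self):
        m = self._matrix()
        assert list(filter_gis_coverage(m, 3).values.index) == ["full"]
        assert list(filter_gis_coverage(m, 1).values.index) == ["full", "b2only", "b1only"]

    def test_threshold_above_batches_errors(self):
        with pytest.raises(ValueError):
            filter_gis_coverage(self._matrix(), 4)


class TestPhosphoSiteAggregation:
    @pytest.mark.parametrize(
        "classes,expected",
        [
            ([4.0], 4.0),              # single class reduces to identity
            ([2.0, 2.0, 2.0], 2.0),    # equal classes are a fixed point
            ([3.0, 1.0], 2.5),         # (9+1)/4
            ([3.0, 0.0], 3.0),         # zero class treated as absent
            ([np.nan, 5.0], 5.0),
        ],
    )
    def test_self_weighted_mean(self, classes, expected):
        assert phospho_site_intensity(classes) == pytest.approx(expected)

    def test_all_absent_is_missing(self):
        assert np.isnan(phospho_site_intensity([0.0, np.nan]))

    @given(
        st.lists(st.floats(min_value=0.1, max_value=1e4), min_size=1, max_size=3),
        st.floats(min_value=0.01, max_value=100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_equivariance_and_bounds(self, classes, lam):
        base = phospho_site_intensity(classes)
        scaled = phospho_site_intensity([lam * c for c in classes])
        assert scaled == pytest.approx(lam * base, rel=1e-9)
        assert min(classes) - 1e-9 <= base <= max(classes) + 1e-9
        assert base >= np.mean(classes) - 1e-9  # self-weighted mean >= mean

    def test_table_aggregation_with_peptide_averaging(self):
        table = pd.DataFrame(
            {
                "site": ["s1"] * 3 + ["s2"],
                "phospho_class": [1, 1, 2, 1],
                "sample": ["A"] * 3 + ["A"],
                "intensity": [2.0, 4.0, 1.0, 8.0],
            }
        )
        out = aggregate_phospho_sites(table, log2=False)
        # class 1 average = 3, class 2 = 1 -> (9+1)/4
        assert out.values.loc["s1", "A"] == pytest.approx(2.5)
        assert out.values.loc["s2", "A"] == pytest.approx(8.0)

    def test_log2_default_and_missing_cells(self):
        table = pd.DataFrame(
            {"site": ["s1"], "phospho_class": [1], "sample": ["A"], "intensity": [4.0]}
        )
        out = aggregate_phospho_sites(table)
        assert out.values.loc["s1", "A"] == pytest.approx(2.0)

    def test_recovers_generator_ground_truth(self):
        from glioproteo.synthetic import generate_phosphopeptides

        table, truth = generate_phosphopeptides(30, 5, seed=3)
        out = aggregate_phospho_sites(table, log2=False)
        np.testing.assert_allclose(
            out.values.loc[truth.index, truth.columns].to_numpy(),
            truth.to_numpy(), rtol=1e-9,
        )


class TestCollapseIsoforms:
    def test_identical_rows_merge_differing_kept(self):
        values = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [1.0, 3.0]],
            index=["PKM_a", "PKM_b", "PKM2"], columns=["s1", "s2"],
        )
        gene = {"PKM_a": "PKM", "PKM_b": "PKM", "PKM2": "PKM"}
        out = collapse_isoforms(IntensityMatrix(values, log2=True), gene)
        assert list(out.values.index) == ["PKM2", "PKM_a"]

    def test_different_genes_never_merge(self):
        values = pd.DataFrame(
            [[1.0], [1.0]], index=["g1", "g2"], columns=["s1"]
        )
        out = collapse_isoforms(
            IntensityMatrix(values, log2=True), {"g1": "A", "g2": "B"}
        )
        assert out.values.shape[0] == 2
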