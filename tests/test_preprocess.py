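"""Metabolite preprocessing: normalization, imputation, filtering, design assembly."""

import numpy as np
import pandas as pd
import pytest

from crgmet.preprocess import (
    CovariateSchema,
    MetaboliteMatrix,
    assemble_design,
    compute_fold_change,
    encode_covariates,
    filter_low_detection,
    impute_below_lod,
    median_normalize,
    preprocess_matrix,
)


def make_matrix(values, mask=None, tissue="benign"):
    values = np.asarray(values, dtype=float)
    v = pd.DataFrame(values, index=[f"P{i}" for i in range(values.shape[0])],
                     columns=[f"M{j}" for j in range(values.shape[1])])
    m = pd.DataFrame(np.zeros_like(values, dtype=bool) if mask is None else np.asarray(mask, bool),
                     index=v.index, columns=v.columns)
    return MetaboliteMatrix(v, m, tissue)


class TestMedianNormalize:
    def test_divides_by_detected_median(self):
        out = median_normalize(make_matrix([[2.0], [4.0], [6.0]]))
        assert list(out.values["M0"]) == [0.5, 1.0, 1.5]

    def test_constant_column_becomes_ones(self):
        out = median_normalize(make_matrix([[5.0], [5.0], [5.0]]))
        assert list(out.values["M0"]) == [1.0, 1.0, 1.0]

    def test_median_over_detected_values_only(self):
        # detected entries (1, 3): median 2 -> (0.5, 1.5); the masked cell is irrelevant
        out = median_normalize(make_matrix([[1.0], [3.0], [0.0]], mask=[[False], [False], [True]]))
        detected = out.values["M0"][~out.below_lod["M0"]]
        assert list(detected) == [0.5, 1.5]

    def test_detected_median_is_one_and_idempotent(self, rng):
        values = rng.lognormal(size=(30, 8))
        mask = rng.random((30, 8)) < 0.2
        out = median_normalize(make_matrix(values, mask))
        med = out.values.where(~out.below_lod).median()
        assert np.allclose(med, 1.0, atol=1e-9)
        twice = median_normalize(out)
        assert np.allclose(twice.values.values, out.values.values, atol=1e-12)


class TestImputeBelowLod:
    def test_fills_with_minimum_detected(self):
        out = impute_below_lod(make_matrix(
            [[0.5], [1.0], [1.5], [0.0]], mask=[[False], [False], [False], [True]]))
        assert list(out.values["M0"]) == [0.5, 1.0, 1.5, 0.5]

    def test_no_bdl_is_identity(self, rng):
        m = make_matrix(rng.lognormal(size=(10, 4)))
        out = impute_below_lod(m)
        assert np.array_equal(out.values.values, m.values.values)

    def test_multiple_bdl_cells_share_the_minimum(self):
        out = impute_below_lod(make_matrix(
            [[1.0], [0.0], [0.0], [1.0]], mask=[[False], [True], [True], [False]]))
        assert list(out.values["M0"]) == [1.0, 1.0, 1.0, 1.0]

    def test_imputed_never_exceeds_any_detected_value(self, rng):
        values = rng.lognormal(size=(25, 10))
        mask = rng.random((25, 10)) < 0.3
        mask[0] = False  # keep at least one detected value per column
        m = median_normalize(make_matrix(values, mask))
        out = impute_below_lod(m)
        for col in out.values.columns:
            detected_min = m.values[col][~m.below_lod[col]].min()
            assert (out.values[col][m.below_lod[col]] <= detected_min + 1e-12).all()


class TestDetectionFilter:
    def test_eliminates_above_75_percent_bdl(self):
        mask = np.zeros((10, 2), dtype=bool)
        mask[:8, 0] = True  # 80% > 75% -> out
        mask[:7, 1] = True  # 70% <= 75% -> kept
        m = make_matrix(np.ones((10, 2)), mask)
        assert filter_low_detection(m) == ["M1"]

    def test_retention_monotone_in_threshold(self, rng):
        mask = rng.random((20, 30)) < rng.uniform(0, 1, 30)
        m = make_matrix(np.ones((20, 30)), mask)
        previous = 31
        for thr in (0.9, 0.75, 0.5, 0.25, 0.0):
            n = len(filter_low_detection(m, thr))
            assert n <= previous
            previous = n

    def test_empty_matrix_warns(self):
        m = make_matrix(np.empty((3, 0)))
        with pytest.warns(UserWarning):
            assert filter_low_detection(m) == []


class TestFoldChange:
    def test_elementwise_ratio(self):
        b = make_matrix([[2.0], [1.0], [0.5]])
        t = make_matrix([[1.0], [1.0], [2.0]], tissue="tumor")
        fc = compute_fold_change(b, t)
        assert list(fc.values["M0"]) == [2.0, 1.0, 0.25]
        assert fc.tissue == "fold_change"

    def test_self_fold_change_is_all_ones(self, rng):
        b = make_matrix(rng.lognormal(size=(10, 5)))
        t = MetaboliteMatrix(b.values.copy(), b.below_lod.copy(), "tumor")
        fc = compute_fold_change(b, t)
        assert np.allclose(fc.values.values, 1.0)

    def test_flag_propagates_from_either_tissue(self):
        b = make_matrix([[1.0], [1.0]], mask=[[True], [False]])
        t = make_matrix([[1.0], [1.0]], mask=[[False], [True]], tissue="tumor")
        fc = compute_fold_change(b, t)
        assert list(fc.below_lod["M0"]) == [True, True]


class TestEncodeCovariates:
    schema = CovariateSchema(continuous=("age",), categorical={"t_stage": "pT1a", "diabetes": "no"})

    def test_reference_level_gets_no_column(self):
        table = pd.DataFrame({
            "age": np.arange(14, dtype=float),
            "t_stage": ["pT1a", "pT1b", "pT2a", "pT2b", "pT3a", "pT3b", "pT4"] * 2,
            "diabetes": ["no", "yes"] * 7,
        })
        out = encode_covariates(table, self.schema)
        dummies = [c for c in out.columns if c.startswith("t_stage=")]
        assert len(dummies) == 6 and "t_stage=pT1a" not in out.columns
        assert list(out["diabetes=yes"][:2]) == [0.0, 1.0]

    def test_constant_column_dropped_with_warning(self):
        table = pd.DataFrame({"age": [60.0, 61.0], "t_stage": ["pT1b", "pT1b"], "diabetes": ["no", "yes"]})
        with pytest.warns(UserWarning, match="t_stage=pT1b"):
            out = encode_covariates(table, self.schema)
        assert "t_stage=pT1b" not in out.columns

    def test_unseen_level_raises_by_name(self):
        table = pd.DataFrame({"age": [60.0, 61.0, 62.0], "t_stage": ["pT1b", "pT9", "pT2a"], "diabetes": ["no", "yes", "no"]})
        with pytest.raises(ValueError, match="pT9"):
            encode_covariates(table, self.schema, levels={"t_stage": ["pT1b", "pT2a"]})

    def test_missing_continuous_fails_loudly(self):
        table = pd.DataFrame({"age": [60.0, np.nan], "t_stage": ["pT1b", "pT2a"], "diabetes": ["no", "yes"]})
        with pytest.raises(ValueError, match="age"):
            encode_covariates(table, self.schema)


class TestAssembleDesign:
    def test_columns_are_centered_and_named_by_tissue(self, rng):
        m = make_matrix(rng.lognormal(size=(9, 4)))
        cov = pd.DataFrame({"x": np.arange(9, dtype=float)}, index=m.values.index)
        design = assemble_design(m, cov)
        assert np.allclose(design.X.mean(axis=0), 0.0, atol=1e-9)
        assert design.X.columns[0] == "M0_benign"
        assert list(design.X["x"]) == list(np.arange(9.0) - 4.0)
        assert (design.meta["source"] == "metabolite").sum() == 4

    def test_metabolites_only_design(self, rng):
        m = make_matrix(rng.lognormal(size=(5, 3)), tissue="fold_change")
        design = assemble_design(m, None)
        assert design.X.shape == (5, 3)
        assert design.X.columns[0].endswith("_benign_tumor_fc")

    def test_patient_mismatch_raises(self, rng):
        m = make_matrix(rng.lognormal(size=(5, 3)))
        cov = pd.DataFrame({"x": [1.0, 2.0]}, index=["Q1", "Q2"])
        with pytest.raises(ValueError, match="patient sets"):
            assemble_design(m, cov)

    def test_unit_variance_scaling_option(self, rng):
        m = make_matrix(rng.lognormal(size=(9, 4)))
        design = assemble_design(m, None, scale=True)
        assert np.allclose(design.X.std(axis=0, ddof=1), 1.0, atol=1e-9)


def test_pipeline_order_normalize_filter_impute(rng):
    values = rng.lognormal(size=(20, 6))
    mask = np.zeros_like(values, dtype=bool)
    mask[:16, 0] = True  # 80% BDL -> eliminated
    mask[:3, 1] = True   # 15% BDL -> imputed
    out = preprocess_matrix(make_matrix(values, mask))
    assert "M0" not in out.values.columns and "M1" in out.values.columns
    assert (out.values.values > 0).all()
    med = out.values.where(~out.below_lod).median()
    assert np.allclose(med, 1.0, atol=1e-9)
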