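"""Synthetic cohort generator: determinism, marginals, planted structure, file layout."""

import numpy as np
import pandas as pd
import pytest

from crgmet.io import load_s1_dir
from crgmet.preprocess import filter_low_detection, median_normalize
from crgmet.synthetic import (
    SyntheticTruth,
    _compound_ids,
    emulate_s1_layout,
    generate_cohort,
    generate_dataset,
    generate_metabolome,
    make_annotations,
)


class TestDeterminism:
    def test_identical_seed_identical_dataset(self):
        a, ta = generate_dataset(n_patients=12, n_metabolites=40, n_identified=30, truth=None, seed=5)
        b, tb = generate_dataset(n_patients=12, n_metabolites=40, n_identified=30, truth=None, seed=5)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)
        pd.testing.assert_frame_equal(a.volumes, b.volumes)
        pd.testing.assert_frame_equal(a.benign.values, b.benign.values)
        pd.testing.assert_frame_equal(a.tumor.below_lod, b.tumor.below_lod)

    def test_different_seeds_differ(self):
        a, _ = generate_dataset(n_patients=12, n_metabolites=40, n_identified=30, truth=None, seed=5)
        b, _ = generate_dataset(n_patients=12, n_metabolites=40, n_identified=30, truth=None, seed=6)
        assert not a.benign.values.equals(b.benign.values)


class TestCohortMarginals:
    def test_age_mean_near_study_population(self):
        cov, _ = generate_cohort(n_patients=2000, seed=0)
        assert cov["age"].mean() == pytest.approx(60.0, abs=1.0)
        assert cov["age"].between(37, 86).all()

    def test_binary_covariate_frequencies(self):
        cov, _ = generate_cohort(n_patients=2000, seed=1)
        assert (cov["hypertension"] == "yes").mean() == pytest.approx(0.633, abs=0.04)
        assert (cov["gender"] == "male").mean() == pytest.approx(0.796, abs=0.04)

    def test_volumes_encode_true_crg(self):
        crg = np.full(20, 1.3)
        _, vol = generate_cohort(n_patients=20, seed=2, crg_true=crg, observer_sigma=0.0)
        base = vol[vol["timepoint"] == "baseline"]
        np.testing.assert_allclose(base["vc_cc"] / base["vi_cc"], 1.3, rtol=1e-9)

    def test_zero_observer_noise_gives_zero_exclusions(self):
        from crgmet.volumetry import build_responses

        _, vol = generate_cohort(n_patients=40, seed=3, observer_sigma=0.0)
        responses = build_responses(vol)
        assert int(responses["qc_excluded"].sum()) == 0


class TestMetabolome:
    def test_no_censoring_when_lod_quantile_zero(self):
        benign, tumor, _, _, _ = generate_metabolome(15, 30, 20, seed=0, lod_quantile=0.0)
        assert not benign.below_lod.values.any()
        assert filter_low_detection(median_normalize(benign)) == benign.metabolite_ids

    def test_censoring_fraction_matches_lod_quantile(self):
        benign, _, _, _, _ = generate_metabolome(40, 25, 10, seed=1, lod_quantile=0.3)
        frac = benign.below_lod.mean(axis=0)
        np.testing.assert_allclose(frac, 0.3, atol=1.0 / 40 + 1e-12)

    def test_requested_population_r2_achieved_at_large_n(self):
        ids = _compound_ids(30)[:5]
        truth = SyntheticTruth(benign_effects={c: 0.4 for c in ids}, r2=0.6)
        _, _, _, crg, g = generate_metabolome(5000, 30, 10, truth, seed=2, lod_quantile=0.0)
        r2 = np.corrcoef(np.log(crg), g)[0, 1] ** 2
        assert r2 == pytest.approx(0.6, abs=0.05)

    def test_infeasible_r2_rejected(self):
        with pytest.raises(ValueError):
            generate_metabolome(10, 5, 2, SyntheticTruth(r2=1.5), seed=0)

    def test_planted_loading_shows_up_as_correlation(self):
        ids = _compound_ids(50)[:1]
        truth = SyntheticTruth(benign_effects={ids[0]: 0.8}, r2=1.0)
        benign, _, _, crg, _ = generate_metabolome(3000, 50, 10, truth, seed=3, lod_quantile=0.0)
        r = np.corrcoef(np.log(benign.values[ids[0]]), np.log(crg))[0, 1]
        assert r == pytest.approx(0.8, abs=0.05)

    def test_annotations_identified_iff_sub_pathway(self):
        ann = make_annotations(60, 35, 0)
        has_sub = ann["sub_pathway"].notna()
        assert (ann["identified"] == has_sub).all()
        assert int(ann["identified"].sum()) == 35


class TestDefaultTruth:
    def test_structure_of_planted_effects(self, default_dataset):
        _, truth = default_dataset
        strong_benign = [v for v in truth.benign_effects.values() if v >= 0.85]
        assert len(strong_benign) == 13  # 12 set members + the standout
        negs = [v for v in truth.tumor_effects.values() if v < 0]
        assert min(negs) == -0.80  # the sole strong negative
        assert truth.landmarks["fc_primary"] in truth.benign_effects
        assert truth.tumor_effects[truth.landmarks["fc_primary"]] < 0

    def test_truth_serialization_roundtrip(self, tmp_path, default_dataset):
        _, truth = default_dataset
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = SyntheticTruth.from_json(path)
        assert back.benign_effects == {str(k): v for k, v in truth.benign_effects.items()}
        assert back.r2 == truth.r2


class TestS1Layout:
    def test_roundtrip_preserves_detected_values_and_masks(self, tmp_path):
        data, truth = generate_dataset(n_patients=12, n_metabolites=25, n_identified=15, seed=4, truth=None)
        emulate_s1_layout(data, truth, tmp_path)
        back = load_s1_dir(tmp_path)
        for orig, rt in ((data.benign, back.benign), (data.tumor, back.tumor)):
            pd.testing.assert_frame_equal(
                orig.below_lod, rt.below_lod, check_names=False, check_column_type=False)
            det = ~orig.below_lod.values
            np.testing.assert_allclose(orig.values.values[det], rt.values.values[det], rtol=1e-9)

    def test_column_naming_convention(self, tmp_path):
        data, truth = generate_dataset(n_patients=10, n_metabolites=6, n_identified=4, seed=5, truth=None)
        paths = emulate_s1_layout(data, truth, tmp_path)
        header = pd.read_csv(paths["metabolites"], nrows=0).columns
        assert any(c.endswith("_benign") for c in header)
        assert any(c.endswith("_tumor") for c in header)
        assert any(c.endswith("_benign_tumor_fc") for c in header)

    def test_headers_survive_empty_cohort(self, tmp_path):
        from crgmet.io import CohortData, write_s1_layout
        from crgmet.preprocess import MetaboliteMatrix

        idx = pd.Index([], name="patient_id")
        empty = MetaboliteMatrix(
            pd.DataFrame(index=idx, columns=["10001"], dtype=float),
            pd.DataFrame(index=idx, columns=["10001"], dtype=bool),
        )
        tumor = MetaboliteMatrix(empty.values.copy(), empty.below_lod.copy(), "tumor")
        data = CohortData(
            volumes=pd.DataFrame(columns=["patient_id", "observer_id", "timepoint", "vc_cc", "vi_cc", "vtumor_cc"]),
            covariates=pd.DataFrame(index=idx),
            benign=empty, tumor=tumor,
            annotations=pd.DataFrame({"compound_id": ["10001"], "identified": [False], "sub_pathway": [None]}),
        )
        write_s1_layout(data, tmp_path)
        back = load_s1_dir(tmp_path)
        assert back.benign.values.shape[0] == 0
        assert list(back.benign.values.columns) == ["10001"]
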