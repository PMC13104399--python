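"""Flag removal, column normalization, validity filter and imputation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from duoprot.preprocess import (PreprocessParams, filter_min_valid,
                                impute_downshifted_normal, min_valid_counts,
                                normalize_and_log, preprocess_pipeline,
                                remove_flagged)
from duoprot.synthetic import SyntheticSpec, generate_dataset

from conftest import make_matrix


class TestRemoveFlagged:
    def test_flagged_rows_removed_with_counts(self, six_sample_design):
        m = make_matrix(np.ones((5, 6)), six_sample_design)
        m.flags.loc["P00001", "potential_contaminant"] = True
        m.flags.loc["P00002", "reverse"] = True
        out, counts = remove_flagged(m)
        assert out.n_proteins == 3
        assert counts["potential_contaminant"] == 1
        assert counts["reverse"] == 1
        assert counts["total_removed"] == 2

    def test_no_flags_is_identity(self, six_sample_design):
        m = make_matrix(np.arange(12.0).reshape(2, 6) + 1, six_sample_design)
        out, counts = remove_flagged(m)
        pd.testing.assert_frame_equal(out.values, m.values)
        assert counts["total_removed"] == 0

    def test_doubly_flagged_row_counted_once_in_total(self, six_sample_design):
        m = make_matrix(np.ones((3, 6)), six_sample_design)
        m.flags.loc["P00000", ["reverse", "potential_contaminant"]] = True
        out, counts = remove_flagged(m)
        assert out.n_proteins == 2
        assert counts["total_removed"] == 1
        assert counts["reverse"] + counts["potential_contaminant"] == 2


class TestNormalizeAndLog:
    def test_hand_arithmetic(self, six_sample_design):
        vals = np.full((2, 6), np.nan)
        vals[:, 0] = [1e10, 4e10]  # column sum 5e10 -> scale by 2
        vals[:, 1:] = 1.0
        m = make_matrix(vals, six_sample_design)
        out = normalize_and_log(m, scale_total=1e11)
        np.testing.assert_allclose(out.values.iloc[:, 0],
                                   np.log2([2e10, 8e10]))

    def test_column_sums_equal_scale_total(self, six_sample_design):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(20, 2, (50, 6))
        vals[rng.random((50, 6)) < 0.2] = np.nan
        out = normalize_and_log(make_matrix(vals, six_sample_design), 1e11)
        linear_sums = np.nansum(np.exp2(out.values.to_numpy()), axis=0)
        np.testing.assert_allclose(linear_sums, 1e11, rtol=1e-9)

    def test_scale_invariance_between_columns(self, six_sample_design):
        base = np.abs(np.random.default_rng(1).normal(5, 1, 20))
        vals = np.column_stack([base * k for k in (1, 2, 5, 10, 0.5, 100)])
        out = normalize_and_log(make_matrix(vals, six_sample_design))
        for j in range(1, 6):
            np.testing.assert_allclose(out.values.iloc[:, j],
                                       out.values.iloc[:, 0], rtol=1e-12)

    def test_missing_cells_stay_missing(self, six_sample_design):
        vals = np.ones((3, 6))
        vals[0, 0] = np.nan
        out = normalize_and_log(make_matrix(vals, six_sample_design))
        assert np.isnan(out.values.iloc[0, 0])
        assert out.values.iloc[1:, 0].notna().all()

    def test_all_missing_column_is_fatal(self, six_sample_design):
        vals = np.ones((3, 6))
        vals[:, 2] = np.nan
        with pytest.raises(ValueError, match="S3"):
            normalize_and_log(make_matrix(vals, six_sample_design))


class TestFilterMinValid:
    def test_ceiling_rule_on_study_groups(self, study_design):
        # thresholds for 90%: ceil(.9*11)=10, ceil(.9*6)=6, ceil(.9*9)=9
        assert min_valid_counts(study_design, 0.9) == {"N": 10, "P": 6, "D": 9}
        vals = np.full((2, 26), np.nan)
        vals[0, :10] = 1.0   # 10 valid in N, 0 in P, 0 in D -> retained
        vals[1, :9] = 1.0    # 9 in N
        vals[1, 11:16] = 1.0  # 5 in P
        vals[1, 17:25] = 1.0  # 8 in D -> all below threshold -> removed
        m = make_matrix(vals, study_design, log2_scale=True)
        out, n_kept = filter_min_valid(m, 0.9)
        assert n_kept == 1
        assert list(out.protein_ids) == ["P00000"]

    def test_fully_observed_protein_always_retained(self, study_design):
        m = make_matrix(np.ones((4, 26)), study_design, log2_scale=True)
        out, n = filter_min_valid(m, 1.0)
        assert n == 4

    def test_filter_is_idempotent_and_row_order_independent(self, study_design):
        rng = np.random.default_rng(2)
        vals = rng.normal(20, 2, (40, 26))
        vals[rng.random((40, 26)) < 0.3] = np.nan
        m = make_matrix(vals, study_design, log2_scale=True)
        once, _ = filter_min_valid(m, 0.9)
        twice, _ = filter_min_valid(once, 0.9)
        pd.testing.assert_frame_equal(once.values, twice.values)
        perm = rng.permutation(40)
        shuffled = make_matrix(vals[perm], study_design,
                               ids=[f"P{i:05d}" for i in perm], log2_scale=True)
        kept_shuffled, _ = filter_min_valid(shuffled, 0.9)
        assert set(kept_shuffled.protein_ids) == set(once.protein_ids)


class TestImputation:
    def test_complete_matrix_unchanged(self, six_sample_design):
        m = make_matrix(np.random.default_rng(0).normal(20, 2, (30, 6)),
                        six_sample_design, log2_scale=True)
        out, _ = impute_downshifted_normal(m, PreprocessParams(seed=1))
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_determinism_and_mask_restricted_change(self, six_sample_design):
        rng = np.random.default_rng(3)
        vals = rng.normal(20, 2, (100, 6))
        mask = rng.random((100, 6)) < 0.25
        vals[mask] = np.nan
        m = make_matrix(vals, six_sample_design, log2_scale=True)
        a, _ = impute_downshifted_normal(m, PreprocessParams(seed=5))
        b, _ = impute_downshifted_normal(m, PreprocessParams(seed=5))
        pd.testing.assert_frame_equal(a.values, b.values)
        # observed cells untouched
        np.testing.assert_array_equal(a.values.to_numpy()[~mask],
                                      m.values.to_numpy()[~mask])
        assert not np.isnan(a.values.to_numpy()).any()
        c, _ = impute_downshifted_normal(m, PreprocessParams(seed=6))
        assert not a.values.equals(c.values)

    def test_imputed_moments_match_downshifted_normal(self, six_sample_design):
        """1e5 draws in one sample: mean ~ m - 1.8 sd, sd ~ 0.3 sd, each
        within 1%."""
        n = 200_000
        rng = np.random.default_rng(4)
        vals = np.column_stack([
            np.r_[rng.normal(20, 2, n // 2), np.full(n // 2, np.nan)],
            *[rng.normal(20, 2, n) for _ in range(5)],
        ])
        m = make_matrix(vals, six_sample_design, log2_scale=True)
        out, used = impute_downshifted_normal(m, PreprocessParams(seed=8))
        obs = vals[: n // 2, 0]
        exp_mean = obs.mean() - 1.8 * obs.std(ddof=1)
        exp_sd = 0.3 * obs.std(ddof=1)
        imputed = out.values.to_numpy()[n // 2:, 0]
        assert imputed.mean() == pytest.approx(exp_mean, rel=0.01)
        assert imputed.std(ddof=1) == pytest.approx(exp_sd, rel=0.01)
        assert used["S1"]["n_imputed"] == n // 2

    def test_imputed_values_fit_the_stated_normal(self, six_sample_design):
        """Goodness of fit: KS test of imputed draws against the declared
        Normal(m - 1.8 sd, (0.3 sd)^2) does not reject at 1%."""
        rng = np.random.default_rng(9)
        vals = rng.normal(18, 3, (5000, 6))
        mask = rng.random((5000, 6)) < 0.3
        vals[mask] = np.nan
        m = make_matrix(vals, six_sample_design, log2_scale=True)
        out, used = impute_downshifted_normal(m, PreprocessParams(seed=11))
        for j, s in enumerate(m.design.samples):
            imputed = out.values.to_numpy()[mask[:, j], j]
            p = stats.kstest(imputed, "norm",
                             args=(used[s]["impute_mean"], used[s]["impute_sd"])).pvalue
            assert p > 0.01

    def test_too_few_valid_values_is_fatal(self, six_sample_design):
        vals = np.full((3, 6), np.nan)
        vals[:, 1:] = 1.0
        vals[0, 0] = 1.0
        m = make_matrix(vals, six_sample_design, log2_scale=True)
        with pytest.raises(ValueError, match="S1"):
            impute_downshifted_normal(m, PreprocessParams())


class TestPipeline:
    def test_stage_order_and_report(self):
        matrix, _ = generate_dataset(SyntheticSpec(n_proteins=600, seed=13))
        out, report = preprocess_pipeline(matrix, PreprocessParams(seed=13))
        assert report.n_input == 600
        assert report.n_input >= report.n_after_flag_removal >= report.n_after_filter
        assert report.n_after_filter < report.n_input  # generator attrition
        assert not out.values.isna().any().any()
        assert out.log2_scale

    def test_rerun_same_seed_identical(self):
        matrix, _ = generate_dataset(SyntheticSpec(n_proteins=300, seed=17))
        a, _ = preprocess_pipeline(matrix, PreprocessParams(seed=2))
        b, _ = preprocess_pipeline(matrix, PreprocessParams(seed=2))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PreprocessParams(min_valid_fraction=0.0)
        with pytest.raises(ValueError):
            PreprocessParams(min_valid_fraction=1.5)
        with pytest.raises(ValueError):
            PreprocessParams(impute_width=0.0)
        with pytest.raises(ValueError):
            PreprocessParams(scale_total=-1)
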