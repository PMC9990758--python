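"""Statistical layer: correlations, t-tests, outlier rule, analysis plan."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plrkit import simulate as sim
from plrkit import stats as ps


class TestAgeOutlierMask:
    def test_equal_ages_all_included(self):
        assert ps.age_outlier_mask([7.0] * 10).all()

    def test_isolated_old_adult_excluded(self):
        rng = np.random.default_rng(0)
        ages = np.concatenate([rng.uniform(19, 22, size=65), [46.0]])
        mask = ps.age_outlier_mask(ages)
        assert not mask[-1]
        assert mask[:-1].all()

    def test_exactly_three_sd_is_included(self):
        """'More than 3 SDs' is strict: a value exactly at mean + 3 SD stays."""
        base = np.array([-1.0, 1.0] * 20)

        def excess(v):
            ages = np.append(base, v)
            return v - (ages.mean() + 3.0 * np.std(ages, ddof=1))

        lo, hi = 1.0, 50.0
        for _ in range(200):  # bisect v so that v == mean + 3 SD exactly
            mid = 0.5 * (lo + hi)
            if excess(mid) > 0:
                hi = mid
            else:
                lo = mid
        v = 0.5 * (lo + hi)
        assert abs(excess(v)) < 1e-9
        assert ps.age_outlier_mask(np.append(base, v))[-1]
        assert not ps.age_outlier_mask(np.append(base, v + 1.0))[-1]


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert ps.pearson(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert ps.pearson(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        r_oracle = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        assert ps.pearson(x, y).statistic == pytest.approx(r_oracle, abs=1e-12)

    def test_symmetry_and_df(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert ps.pearson(x, y).statistic == pytest.approx(ps.pearson(y, x).statistic)
        assert ps.pearson(x, y).df == 28

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    def test_invariance_to_positive_affine_maps(self, a, b):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=25), rng.normal(size=25)
        r0 = ps.pearson(x, y).statistic
        assert ps.pearson(a * x + b, y).statistic == pytest.approx(r0, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ps.pearson(np.ones(10), np.arange(10.0))

    def test_pairwise_complete_n_recorded(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 3.0, np.nan, 5.0, 7.0])
        result = ps.pearson(x, y)
        assert result.n == 4
        assert result.df == 2


class TestPartialPearson:
    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=30)
        x = 0.5 * z + rng.normal(size=30)
        y = -0.3 * z + rng.normal(size=30)
        ours = ps.partial_pearson(x, y, z).statistic
        rx = x - np.polyval(np.polyfit(z, x, 1), z)
        ry = y - np.polyval(np.polyfit(z, y, 1), z)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=["x", "y", "z"])
        df["x"] += 0.4 * df["z"]
        expected = pingouin.partial_corr(df, x="x", y="y", covar="z")
        result = ps.partial_pearson(df["x"], df["y"], df["z"])
        assert result.statistic == pytest.approx(float(expected["r"].iloc[0]), abs=1e-9)
        assert result.p_value == pytest.approx(float(expected["p_val"].iloc[0]), abs=1e-9)

    def test_uncorrelated_covariate_collapses_to_bivariate(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=40), rng.normal(size=40)
        z = rng.normal(size=40)
        # Orthogonalize z against both x and y so r_xz = r_yz = 0 exactly.
        basis = np.column_stack([np.ones(40), x, y])
        z = z - basis @ np.linalg.lstsq(basis, z, rcond=None)[0]
        assert ps.partial_pearson(x, y, z).statistic == pytest.approx(
            ps.pearson(x, y).statistic, abs=1e-10)

    def test_collinear_covariate_rejected(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        with pytest.raises(ValueError, match="collinear"):
            ps.partial_pearson(x, rng.normal(size=20), x)

    def test_df_is_n_minus_3(self):
        rng = np.random.default_rng(7)
        result = ps.partial_pearson(rng.normal(size=55), rng.normal(size=55),
                                    rng.normal(size=55))
        assert result.df == 52


class TestBonferroni:
    def test_single_comparison_returns_alpha(self):
        assert ps.bonferroni_threshold(0.04, 1) == 0.04

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            ps.bonferroni_threshold(0.05, 0)


class TestIndependentT:
    def test_identical_groups_zero(self):
        result = ps.independent_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.statistic == pytest.approx(0.0)
        assert result.effect_size == pytest.approx(0.0)

    def test_matches_hand_computed_pooled_formulas(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        result = ps.independent_t(a, b)
        # pooled SD = 1, SE = sqrt(2/3), t = -3 / SE, d = -3
        assert result.statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-12)
        assert result.effect_size == pytest.approx(-3.0, abs=1e-12)
        assert result.df == 4

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        r1 = ps.independent_t(a, b)
        r2 = ps.independent_t(3.7 * a, 3.7 * b)
        assert r2.statistic == pytest.approx(r1.statistic, abs=1e-9)
        assert r2.effect_size == pytest.approx(r1.effect_size, abs=1e-9)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            ps.independent_t([2.0, 2.0], [2.0, 2.0])


def _cohort_tables(seed=0, n_child=40, n_adult=40):
    child = dataclasses.replace(sim.default_child_group(), n=n_child)
    adult = dataclasses.replace(sim.default_adult_group(), n=n_adult)
    cfg = sim.CohortSimConfig(child=child, adult=adult, rng_seed=seed)
    gt = sim.draw_cohort_table(cfg)
    metrics = pd.DataFrame({
        "participant_id": gt.participant_id,
        "group": gt.group,
        "n_valid_trials": 9,
        "included": True,
        "mean_baseline_mm": gt.gt_baseline_mm,
        "mean_relative_amplitude": gt.gt_rel_amp,
        "mean_absolute_amplitude_mm": gt.gt_abs_amp_mm,
        "median_latency_ms": gt.gt_latency_ms,
    })
    traits = gt[["participant_id", "group", "age_years",
                 *sim.TRAIT_SCALES]].copy()
    return metrics, traits


class TestRunAnalysisPlan:
    def test_df_bookkeeping_on_every_result(self):
        metrics, traits = _cohort_tables(seed=1)
        report = ps.run_analysis_plan(metrics, traits)
        for r in report.results:
            if r.effect_size_kind == "d":
                assert r.df == r.n - 2
            elif "partial" in r.test_name:
                assert r.df == r.n - 3
            else:
                assert r.df == r.n - 2

    def test_family_sizes_and_thresholds(self):
        metrics, traits = _cohort_tables(seed=2)
        frame = ps.run_analysis_plan(metrics, traits).to_frame()
        by_family = frame.groupby("family").size()
        assert by_family["pupil_pupil"] == 12       # 6 pairs x 2 groups
        assert by_family["trait_pupil"] == 24       # 3 scales x 4 metrics x 2 groups
        assert by_family["group_comparison"] == 4
        assert set(frame[frame.family == "pupil_pupil"].critical_p) == {0.05 / 6}
        assert set(frame[frame.family == "trait_pupil"].critical_p) == {0.05 / 4}

    def test_children_use_partial_adults_bivariate(self):
        metrics, traits = _cohort_tables(seed=3)
        frame = ps.run_analysis_plan(metrics, traits).to_frame()
        child = frame[frame.test_name.str.startswith("child:")]
        adult = frame[frame.test_name.str.startswith("adult:")]
        assert child.test_name.str.contains("partial").all()
        assert adult.test_name.str.contains("bivariate").all()

    def test_single_group_cohort_reports_only_that_group(self):
        metrics, traits = _cohort_tables(seed=4, n_child=0)
        report = ps.run_analysis_plan(metrics, traits)
        assert set(report.group_ns) == {"adult"}
        frame = report.to_frame()
        assert not frame.test_name.str.startswith("child:").any()
        assert "group_comparison" not in set(frame.family)

    def test_report_deterministic(self):
        metrics, traits = _cohort_tables(seed=5)
        a = ps.run_analysis_plan(metrics, traits).to_json()
        b = ps.run_analysis_plan(metrics, traits).to_json()
        assert a == b

    def test_injected_adult_effect_detected_in_majority_of_replicates(self):
        """Power check: r = -0.36 at n = 66 clears the 4-comparison
        threshold in most replicates."""
        adult = dataclasses.replace(sim.default_adult_group(), n=66)
        rng = np.random.default_rng(17)
        crit = ps.bonferroni_threshold(0.05, 4)
        hits = 0
        reps = 200
        for _ in range(reps):
            t = sim.draw_group_table(adult, rng)
            result = ps.pearson(t.SRS2_RRB_T, t.gt_rel_amp, critical_p=crit)
            hits += result.significant
        assert hits / reps > 0.5

    def test_age_outliers_removed_once(self):
        metrics, traits = _cohort_tables(seed=6)
        traits = traits.copy()
        traits.loc[traits.index[-1], "age_years"] = 80.0  # adult far outlier
        report = ps.run_analysis_plan(metrics, traits)
        outlier_id = traits.iloc[-1].participant_id
        assert outlier_id in report.age_outliers["adult"]
        assert report.group_ns["adult"] == (traits.group == "adult").sum() - 1
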