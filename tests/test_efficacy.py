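"""Unit and property tests for the spotlight-count kill statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baitsow.efficacy import (
    ReplicateResult,
    TransectCount,
    TrialEfficacy,
    combined_mean,
    counts_to_frame,
    logit_adjusted,
    percent_kill,
    replicate_index,
    survivor_model,
    treatment_summary,
    welch_t,
)

from conftest import exact_moment_group


def _block(counts_by_transect, period="pre", block="A", treatment="strip"):
    recs = []
    for t, vals in enumerate(counts_by_transect, start=1):
        for night, c in enumerate(vals, start=1):
            recs.append(TransectCount(block, treatment, t, night, period, c))
    return counts_to_frame(recs)


class TestReplicateIndex:
    @pytest.mark.parametrize(
        "transects, expected",
        [
            ([(10, 10)] * 4, 10.0),
            ([(0, 0)] * 4, 0.0),
            ([(10, 14), (20, 20), (5, 7), (30, 30)], 17.0),
        ],
    )
    def test_balanced_mean(self, transects, expected):
        assert replicate_index(_block(transects)) == pytest.approx(expected)

    def test_unbalanced_averages_within_transect_first(self):
        # transect 1 has both nights, transect 2 only one: per-transect means
        # (10+20)/2 = 15 and 30, index = 22.5 rather than the raw mean 20
        df = _block([(10, 20)])
        df = pd.concat(
            [df, counts_to_frame([TransectCount("A", "strip", 2, 1, "pre", 30)])],
            ignore_index=True,
        )
        assert replicate_index(df) == pytest.approx(22.5)

    def test_errors(self):
        with pytest.raises(ValueError, match="no counts"):
            replicate_index(pd.DataFrame(columns=["block_id", "transect_id", "period", "count"]))
        mixed = pd.concat(
            [_block([(1, 1)], period="pre"), _block([(1, 1)], period="post")],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="mixed periods"):
            replicate_index(mixed)


class TestPercentKill:
    @pytest.mark.parametrize(
        "pre, post, expected", [(100, 0, 100.0), (50, 50, 0.0), (100, 23, 77.0)]
    )
    def test_examples(self, pre, post, expected):
        assert percent_kill(pre, post) == pytest.approx(expected)

    def test_negative_when_population_grew(self):
        assert percent_kill(10, 15) == pytest.approx(-50.0)

    def test_zero_pre_is_undefined(self):
        with pytest.raises(ValueError, match="undefined kill"):
            percent_kill(0, 5)

    @settings(derandomize=True, max_examples=50)
    @given(
        pre=st.floats(0.5, 1e4),
        post=st.floats(0, 1e4),
        scale=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, pre, post, scale):
        assert percent_kill(pre * scale, post * scale) == pytest.approx(
            percent_kill(pre, post), rel=1e-9, abs=1e-9
        )


class TestTreatmentSummary:
    def test_zero_variance(self):
        s = treatment_summary([90.0, 90.0, 90.0])
        assert s.mean_kill == 90.0
        assert s.ci95 == (90.0, 90.0)

    def test_ci_matches_inverted_halfwidth(self):
        # SD chosen so that the t-based 95% half-width at n=9 is 2.75 points
        kills = exact_moment_group(92.7, 2.75 * 3 / 2.306004, 9)
        s = treatment_summary(kills)
        assert s.ci95[0] == pytest.approx(89.95, abs=0.01)
        assert s.ci95[1] == pytest.approx(95.45, abs=0.01)

    def test_mc_calibration_against_generating_beta(self):
        # mean of 9 beta(48.1, 3.79) kills falls in its own 95% CI's
        # neighbourhood of the generating mean 92.7 in most draws
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(200):
            kills = 100 * rng.beta(48.1, 3.79, size=9)
            s = treatment_summary(kills)
            hits += s.ci95[0] <= 92.7 <= s.ci95[1]
        assert hits / 200 >= 0.90

    def test_ci_width_shrinks_as_sqrt_n(self):
        widths = []
        for n in (5, 20, 80):
            kills = exact_moment_group(90.0, 4.0, n)
            s = treatment_summary(kills)
            widths.append(s.ci95[1] - s.ci95[0])
        assert widths[0] > widths[1] > widths[2]
        # width scales as t(0.975, n-1)/sqrt(n) for fixed SD
        from scipy import stats

        expected = (stats.t.ppf(0.975, 19) / np.sqrt(20)) / (stats.t.ppf(0.975, 79) / np.sqrt(80))
        assert widths[1] / widths[2] == pytest.approx(expected, rel=1e-6)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="cannot form CI"):
            treatment_summary([95.0])

    def test_filters_replicate_results_by_treatment(self):
        reps = [
            ReplicateResult("A", "strip", 100, 5, 95.0),
            ReplicateResult("B", "strip", 100, 10, 90.0),
            ReplicateResult("C", "broadcast", 100, 50, 50.0),
            ReplicateResult("D", "broadcast", 100, 40, 60.0),
        ]
        s = treatment_summary(reps, "strip")
        assert s.n == 2 and s.mean_kill == pytest.approx(92.5)


class TestCombinedMean:
    def test_published_group_summaries_pool_correctly(self):
        s1 = treatment_summary(exact_moment_group(92.7, 3.58, 9))
        s2 = treatment_summary(exact_moment_group(94.0, 6.22, 10))
        assert combined_mean([s1, s2]) == pytest.approx(93.4, abs=0.05)

    def test_identical_groups(self):
        s = treatment_summary([80.0, 90.0])
        assert combined_mean([s, s]) == pytest.approx(85.0)

    def test_bounded_by_group_means(self):
        s1 = treatment_summary(exact_moment_group(50.0, 1.0, 3))
        s2 = treatment_summary(exact_moment_group(90.0, 1.0, 7))
        m = combined_mean([s1, s2])
        assert 50.0 < m < 90.0
        assert m == pytest.approx((50 * 3 + 90 * 7) / 10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combined_mean([])


class TestWelch:
    def test_identical_groups(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res.t_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_zero_variance_equal_means(self):
        res = welch_t([5, 5], [5, 5])
        assert res.t_stat == 0.0 and res.p_value == 1.0

    def test_summary_realized_groups(self):
        # groups realizing (92.7, 3.58, 9) and (94.0, 6.22, 10) exactly
        a = exact_moment_group(92.7, 3.58, 9)
        b = exact_moment_group(94.0, 6.22, 10)
        res = welch_t(b, a)
        assert res.t_stat == pytest.approx(0.565, abs=0.005)
        assert res.df == pytest.approx(14.62, abs=0.05)
        assert res.p_value > 0.5

    def test_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        a, b = rng.normal(90, 4, 9), rng.normal(94, 6, 10)
        ours = welch_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert ours.t_stat == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 1000))
    def test_swap_flips_sign(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(90, 4, 9), rng.normal(94, 6, 10)
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.t_stat == pytest.approx(-r2.t_stat)
        assert r1.p_value == pytest.approx(r2.p_value)


class TestLogitAdjusted:
    def test_symmetry_point(self):
        assert logit_adjusted([0.5])[0] == pytest.approx(0.0)

    def test_quarter(self):
        assert logit_adjusted([0.25])[0] == pytest.approx(np.log(1 / 3))

    def test_boundary_adjustment_uses_min_nonzero_complement(self):
        out = logit_adjusted([0.9, 1.0])
        assert out[0] == pytest.approx(np.log(9))
        assert out[1] == pytest.approx(np.log(10))

    def test_errors(self):
        with pytest.raises(ValueError):
            logit_adjusted([0.0, 0.5])
        with pytest.raises(ValueError, match="adjustment undefined"):
            logit_adjusted([1.0, 1.0])


class TestSurvivorModel:
    @staticmethod
    def _reps_on_plane(b0, b_pre, b_treat, b_int, pres, treatments):
        reps = []
        for i, (pre, t) in enumerate(zip(pres, treatments)):
            is_strip = float(t == "strip")
            log_post = b0 + b_pre * np.log(pre) + b_treat * is_strip + b_int * np.log(pre) * is_strip
            post = float(np.exp(log_post))
            reps.append(ReplicateResult(f"R{i}", t, pre, post, percent_kill(pre, post)))
        return reps

    def test_exact_plane_recovery(self):
        reps = self._reps_on_plane(
            -2.0, 1.1, 0.5, -0.2,
            pres=[10, 40, 160, 20, 80, 120],
            treatments=["strip", "strip", "strip", "broadcast", "broadcast", "broadcast"],
        )
        fit = survivor_model(reps)
        assert fit.params["intercept"] == pytest.approx(-2.0, abs=1e-8)
        assert fit.params["log_pre"] == pytest.approx(1.1, abs=1e-8)
        assert fit.params["treatment"] == pytest.approx(0.5, abs=1e-8)
        assert fit.params["interaction"] == pytest.approx(-0.2, abs=1e-8)

    def test_null_interaction_recovered_within_2se(self):
        # post = c * pre (slope 1, no treatment effect): the fitted
        # interaction should be within 2 SE of zero in >= 90% of runs
        rng = np.random.default_rng(11)
        hits, runs = 0, 100
        for _ in range(runs):
            pres = np.exp(rng.uniform(np.log(10), np.log(155), 19))
            treatments = ["strip"] * 9 + ["broadcast"] * 10
            posts = 0.07 * pres * np.exp(rng.normal(0, 0.3, 19))
            reps = [
                ReplicateResult(f"R{i}", t, p, q, percent_kill(p, q))
                for i, (t, p, q) in enumerate(zip(treatments, pres, posts))
            ]
            fit = survivor_model(reps)
            hits += abs(fit.params["interaction"]) < 2 * fit.bse["interaction"]
            assert fit.params["log_pre"] > 0  # survivors increase with initial counts
        assert hits / runs >= 0.90

    def test_zero_post_handled_by_adjustment(self):
        reps = self._reps_on_plane(
            -2.0, 1.0, 0.0, 0.0, [10, 40, 160, 20, 80], ["strip"] * 3 + ["broadcast"] * 2
        )
        reps[0] = ReplicateResult("R0", "strip", 10.0, 0.0, 100.0)
        fit = survivor_model(reps)
        assert np.isfinite(fit.params["log_pre"])

    def test_single_treatment_rejected(self):
        reps = self._reps_on_plane(0, 1, 0, 0, [10, 20, 40, 80, 160], ["strip"] * 5)
        with pytest.raises(ValueError, match="both treatments"):
            survivor_model(reps)


class TestTrialEfficacyModel:
    def test_fit_on_synthetic_trial(self, default_trial):
        counts, truths = default_trial
        res = TrialEfficacy(counts).fit()
        assert len(res.replicates) == 19
        assert set(res.summaries) == {"strip", "broadcast"}
        assert res.welch is not None and res.survivor is not None
        # estimated kills track latent truths closely
        merged = res.replicates.merge(truths, on=["block_id", "treatment"])
        err = merged["percent_kill"] - 100 * merged["true_kill"]
        assert err.abs().mean() < 2.0
        assert "Overall mean kill" in res.summary()

    def test_duplicate_rows_rejected(self, default_trial):
        counts, _ = default_trial
        dup = pd.concat([counts, counts.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            TrialEfficacy(dup)

    def test_kill_moments_are_fractions(self, default_trial):
        counts, _ = default_trial
        res = TrialEfficacy(counts).fit()
        for m, v in res.kill_moments().values():
            assert 0 < m < 1 and 0 < v < m * (1 - m)

    def test_csv_round_trip(self, default_trial, tmp_path):
        counts, _ = default_trial
        p = tmp_path / "counts.csv"
        counts.to_csv(p, index=False)
        res = TrialEfficacy.from_csv(p).fit(ancova=False)
        ref = TrialEfficacy(counts).fit(ancova=False)
        pd.testing.assert_frame_equal(res.replicates, ref.replicates)
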