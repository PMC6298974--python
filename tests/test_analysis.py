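"""Behavioural statistics: exclusion, d', bootstrap, polynomial fit, rmANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from sfg.analysis import (
    DetectionModel,
    apply_latency_correction,
    bootstrap_ci,
    correct_rt_latency,
    dprime,
    exclude_fast_responses,
    exclusion_fraction,
    fit_poly2,
    mauchly_test,
    rates_by_coherence,
    response_variability,
    rm_anova,
)
from sfg.session import ObserverParams, TaskDesign, TrialRecord, SessionData, simulate_sessions
from sfg.stimgen import ParameterError

from conftest import make_fixture_session


def _session_with_responses(times):
    trials = [
        TrialRecord(i, "figure", 8, 0.5, t, "hit" if t and t >= 0.5 else "false_alarm", 0.0)
        for i, t in enumerate(times)
    ]
    return SessionData("s0", "x", trials)


class TestPreprocessing:
    def test_strictly_below_threshold_excluded(self):
        s = _session_with_responses([0.2, 0.39, 0.4, 1.0])
        out = exclude_fast_responses(s, 0.4)
        flags = [t.excluded for t in out.trials]
        assert flags == [True, True, False, False]
        assert exclusion_fraction(out) == pytest.approx(0.5)

    def test_zero_threshold_excludes_nothing(self):
        s = _session_with_responses([0.2, 0.39])
        assert exclusion_fraction(exclude_fast_responses(s, 0.0)) == 0.0

    def test_no_responses_nothing_excluded(self):
        trials = [TrialRecord(i, "catch", None, None, None, "correct_rejection", 1.0)
                  for i in range(5)]
        s = SessionData("s0", "x", trials)
        assert exclusion_fraction(exclude_fast_responses(s, 0.4)) == 0.0

    def test_latency_correction_arithmetic(self):
        assert correct_rt_latency(0.56, 0.0) == pytest.approx(0.56)
        assert correct_rt_latency(0.50, 0.05) == pytest.approx(0.45)
        with pytest.raises(ParameterError):
            correct_rt_latency(0.03, 0.05)

    def test_batch_latency_preserves_ordering(self):
        times = [0.9, 0.5, 1.4, 0.7]
        s = _session_with_responses(times)
        out = apply_latency_correction(s, 0.05)
        corrected = [t.response_time for t in out.trials]
        assert corrected == pytest.approx([t - 0.05 for t in times])
        assert np.argsort(corrected).tolist() == np.argsort(times).tolist()


class TestRates:
    def test_counting_oracle_on_fixture_log(self):
        s = make_fixture_session({12: (103, 17), 4: (40, 60)}, fa_catch=10, n_catch=100)
        rows = {r.coherence: r for r in rates_by_coherence(s)}
        assert rows[12].hit_rate == pytest.approx(103 / 120)
        assert rows[4].hit_rate == pytest.approx(40 / 100)
        assert rows[12].fa_rate == pytest.approx(0.1)
        assert rows[4].fa_rate == pytest.approx(0.1)  # one session value per row
        assert rows[12].n_trials == 120

    def test_all_catch_held_gives_zero_fa(self):
        s = make_fixture_session({8: (5, 5)}, fa_catch=0, n_catch=50)
        assert rates_by_coherence(s)[0].fa_rate == 0.0

    def test_perfect_hits(self):
        s = make_fixture_session({8: (10, 0)}, fa_catch=5, n_catch=50)
        assert rates_by_coherence(s)[0].hit_rate == 1.0

    def test_excluded_trials_drop_from_denominators(self):
        s = make_fixture_session({8: (10, 10)}, fa_catch=5, n_catch=50, mean_rt=0.5)
        # exclude everything responded: all hits go, misses stay
        out = exclude_fast_responses(s, 10.0)
        rows = rates_by_coherence(out)
        assert rows[0].hit_rate == 0.0
        assert rows[0].n_trials == 10


class TestDprime:
    def test_equal_rates_give_zero(self):
        assert dprime(0.3, 0.3, 100, 100) == pytest.approx(0.0)

    def test_quantile_oracle_values(self):
        # Z(0.84) = 0.994457883, Z(0.5) = 0
        assert dprime(0.84, 0.50, 100, 100) == pytest.approx(0.994457883209753, rel=1e-9)

    def test_edge_correction_with_1_over_2n(self):
        # perfect performance at n=100: rates become 0.995 / 0.005
        val = dprime(1.0, 0.0, 100, 100)
        assert val == pytest.approx(5.151658607097801, rel=1e-9)
        assert val == pytest.approx(2 * sps.norm.ppf(0.995), rel=1e-9)

    def test_edge_without_n_rejected(self):
        with pytest.raises(ParameterError):
            dprime(1.0, 0.1, 0, 100)
        with pytest.raises(ParameterError):
            dprime(1.2, 0.1, 10, 10)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        h=st.floats(0.01, 0.99),
        f=st.floats(0.01, 0.99),
        delta=st.floats(0.001, 0.2),
    )
    def test_antisymmetry_and_monotonicity(self, h, f, delta):
        assert dprime(h, f, 50, 50) == pytest.approx(-dprime(f, h, 50, 50), abs=1e-12)
        if h + delta <= 0.99:
            assert dprime(h + delta, f, 50, 50) > dprime(h, f, 50, 50)
            assert dprime(f, h + delta, 50, 50) < dprime(f, h, 50, 50)


class TestVariability:
    def test_identical_rts_have_zero_spread(self):
        assert response_variability([0.5, 0.5, 0.5]) == 0.0

    def test_closed_form_sample_sd(self):
        assert response_variability([0.4, 0.6]) == pytest.approx(0.1414213562, rel=1e-8)

    def test_homogeneity(self):
        rts = [0.4, 0.55, 0.7, 0.52]
        assert response_variability([2 * r for r in rts]) == pytest.approx(
            2 * response_variability(rts)
        )

    def test_single_value_undefined(self):
        with pytest.raises(ParameterError):
            response_variability([0.5])


class TestBootstrap:
    def test_constant_input_zero_width(self):
        lo, hi = bootstrap_ci([2.5] * 10, np.mean, 1000, 0.95, rng=0)
        assert lo == hi == 2.5

    def test_deterministic_given_seed(self):
        vals = np.random.default_rng(4).normal(size=40)
        a = bootstrap_ci(vals, np.mean, 2000, 0.95, rng=8)
        b = bootstrap_ci(vals, np.mean, 2000, 0.95, rng=8)
        assert a == b

    def test_generic_statistic_matches_fast_path(self):
        vals = np.random.default_rng(5).normal(size=30)
        fast = bootstrap_ci(vals, np.mean, 1000, 0.95, rng=3)
        slow = bootstrap_ci(vals, lambda v: float(np.mean(v)), 1000, 0.95, rng=3)
        assert fast == pytest.approx(slow)

    def test_coverage_of_the_mean(self):
        """95% interval covers the true mean in >= 94% of 200 replications."""
        rng = np.random.default_rng(1234)
        covered = 0
        for _ in range(200):
            vals = rng.normal(size=500)
            lo, hi = bootstrap_ci(vals, np.mean, 5000, 0.95, rng=rng)
            covered += lo <= 0.0 <= hi
        assert covered >= 0.94 * 200


class TestPoly2:
    def test_exact_quadratic_interpolated(self):
        x = np.array([4, 6, 8, 10, 12], float)
        coeffs, fitted = fit_poly2(x, x**2)
        assert coeffs == pytest.approx([1.0, 0.0, 0.0], abs=1e-8)
        assert fitted == pytest.approx(x**2)

    def test_constant_data(self):
        x = np.array([4, 6, 8, 10, 12], float)
        coeffs, _ = fit_poly2(x, np.full(5, 3.3))
        assert abs(coeffs[0]) < 1e-8 and abs(coeffs[1]) < 1e-8

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(2)
        x = np.array([4, 6, 8, 10, 12], float)
        y = rng.normal(size=5)
        coeffs, fitted = fit_poly2(x, y)
        resid = y - fitted
        for col in (np.ones_like(x), x, x**2):
            assert abs(resid @ col) < 1e-8

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            fit_poly2([1, 2], [1, 2])


class TestRmAnova:
    def _pingouin_f(self, data):
        import pingouin as pg

        df = pd.DataFrame(data).reset_index().melt("index", var_name="cond", value_name="y")
        aov = pg.rm_anova(data=df, dv="y", within="cond", subject="index")
        return float(aov["F"].iloc[0]), float(aov["p_unc"].iloc[0])

    def test_fixture_matches_reference_implementation(self):
        data = np.random.default_rng(3).normal(size=(6, 3)) + [0.0, 0.5, 1.0]
        res = rm_anova(data, correction="none")
        f_ref, p_ref = self._pingouin_f(data)
        assert res.F == pytest.approx(f_ref, abs=1e-8)
        assert res.p == pytest.approx(p_ref, abs=1e-8)
        assert (res.df_num, res.df_den) == (2, 10)

    def test_mauchly_matches_reference(self):
        import pingouin as pg

        data = np.random.default_rng(6).normal(size=(12, 4)) * [1.0, 1.0, 2.0, 4.0]
        w, p = mauchly_test(data)
        df = pd.DataFrame(data).reset_index().melt("index", var_name="cond", value_name="y")
        ref = pg.sphericity(data=df, dv="y", within="cond", subject="index")
        assert w == pytest.approx(ref.W, abs=1e-10)
        assert p == pytest.approx(ref.pval, abs=1e-10)

    def test_lower_bound_correction_degrees_of_freedom(self):
        """k=5 conditions, n=51 sessions, strong sphericity violation -> F(1, 50)."""
        rng = np.random.default_rng(9)
        base = rng.normal(size=(51, 1))
        # correlated columns with wildly different difference variances
        data = np.hstack([base + rng.normal(scale=s, size=(51, 1))
                          for s in (0.05, 0.1, 1.0, 3.0, 6.0)])
        res = rm_anova(data)
        assert res.sphericity_violated
        assert res.epsilon == pytest.approx(0.25)
        assert (res.df_num, res.df_den) == (1, 50)
        assert res.correction == "lower-bound"
        # uncorrected df when sphericity holds
        iid = rng.normal(size=(51, 5))
        res2 = rm_anova(iid)
        if not res2.sphericity_violated:
            assert (res2.df_num, res2.df_den) == (4, 200)

    def test_null_data_not_significant(self):
        rng = np.random.default_rng(14)
        data = rng.normal(size=(20, 5)) + rng.normal(size=(20, 1))
        res = rm_anova(data)
        assert res.p > 0.05

    def test_greenhouse_geisser_option(self):
        rng = np.random.default_rng(10)
        data = np.hstack([rng.normal(scale=s, size=(30, 1)) for s in (0.1, 0.1, 5.0)])
        res = rm_anova(data, correction="greenhouse-geisser")
        if res.sphericity_violated:
            assert 1 / 2 <= res.epsilon <= 1.0
            assert res.correction == "greenhouse-geisser"

    def test_missing_cells_rejected(self):
        data = np.ones((5, 3))
        data[0, 0] = np.nan
        with pytest.raises(ParameterError):
            rm_anova(data)

    def test_ks_normality_reported_per_condition(self):
        data = np.random.default_rng(8).normal(size=(25, 4))
        res = rm_anova(data)
        assert len(res.ks_normal_p) == 4
        assert all(0 <= p <= 1 for p in res.ks_normal_p)


@pytest.fixture(scope="module")
def results():
    sessions = simulate_sessions(8, TaskDesign(n_trials=600), ObserverParams(), rng=17)
    return DetectionModel(sessions).fit(n_boot=500, rng=0)


class TestDetectionModel:

    def test_per_coherence_table(self, results):
        tab = results.by_coherence("hit_rate")
        assert list(tab["coherence"]) == [4, 6, 8, 10, 12]
        assert np.all(tab["ci_low"] <= tab["mean"]) and np.all(tab["mean"] <= tab["ci_high"])

    def test_hit_rate_increases_with_coherence(self, results):
        hits = results.mean_curve("hit_rate")
        assert hits[-1] > hits[0]

    def test_summary_and_report(self, results):
        text = results.summary()
        assert "rmANOVA d_prime" in text and "false-alarm rate" in text
        report = results.anova_report()
        assert set(report) == {"d_prime", "mean_rt", "rt_variability"}
        assert all("mauchly_p" in v for v in report.values())

    def test_from_dataframe_groups_sessions(self):
        sessions = simulate_sessions(3, TaskDesign(n_trials=300), ObserverParams(), rng=2)
        df = pd.concat([s.to_dataframe() for s in sessions], ignore_index=True)
        model = DetectionModel.from_dataframe(df)
        assert len(model.sessions) == 3
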