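"""Model fitting: Gompertz AFT likelihood, Cox-on-age, GrimAge-type clock."""

import numpy as np
import pytest

from accelerage import (
    CoxAge,
    GompertzAFT,
    GrimAgeModel,
    SimConfig,
    SurvivalData,
    build_from_parametric,
    draw_cohort,
)
from accelerage.models import GompertzAFTResults


def _duplicate(d: SurvivalData) -> SurvivalData:
    return SurvivalData(
        entry_age=np.concatenate([d.entry_age] * 2),
        exit_age=np.concatenate([d.exit_age] * 2),
        status=np.concatenate([d.status] * 2),
        markers=np.concatenate([d.markers] * 2),
    )


def _permute(d: SurvivalData, rng) -> SurvivalData:
    idx = rng.permutation(len(d))
    return d.subset(idx)


@pytest.fixture(scope="module")
def fit(aft_cohort):
    return GompertzAFT(aft_cohort.data).fit()


@pytest.fixture(scope="module")
def grim_fit(ph_cohort):
    return GrimAgeModel(ph_cohort.data).fit()


@pytest.fixture(scope="module")
def true_fit(gompertz):
    from types import SimpleNamespace

    # the exact generating model, wrapped as a fitted-results object
    params = np.array([np.log(gompertz.a), np.log(gompertz.b), 0.05, 0.05])
    return GompertzAFTResults(
        model=SimpleNamespace(data=SimpleNamespace(marker_names=["x1", "x2"])),
        params_internal=params, vcov_internal=np.eye(4), llf=0.0,
        converged=True, niter=0,
    )


class TestGompertzAFT:

    def test_recovers_generating_coefficients(self):
        cohort = draw_cohort(SimConfig(mechanism="gompertz_aft", n_obs=10_000, seed=7))
        res = GompertzAFT(cohort.data).fit()
        se = res.bse[2:]
        assert np.all(np.abs(res.beta_hat - 0.05) < 3 * se)
        assert res.a_hat > 0 and res.b_hat > 0
        assert res.converged

    def test_duplication_doubles_loglik_keeps_estimates(self, aft_cohort, fit):
        res2 = GompertzAFT(_duplicate(aft_cohort.data)).fit()
        np.testing.assert_allclose(res2.params_internal, fit.params_internal,
                                   rtol=1e-7, atol=1e-9)
        assert res2.llf == pytest.approx(2 * fit.llf, rel=1e-9)

    def test_score_vanishes_at_optimum(self, aft_cohort, fit):
        # finite-difference gradient of the log-likelihood, independent of
        # the analytic score used during optimization
        m = GompertzAFT(aft_cohort.data)
        p = fit.params_internal
        g = np.empty_like(p)
        for j in range(p.size):
            h = 1e-6 * (1 + abs(p[j]))
            pp, pm = p.copy(), p.copy()
            pp[j] += h
            pm[j] -= h
            g[j] = (m.loglike(pp) - m.loglike(pm)) / (2 * h)
        assert np.linalg.norm(g) < 1e-4

    def test_analytic_score_matches_finite_differences(self, aft_cohort):
        m = GompertzAFT(aft_cohort.data)
        p = np.array([-8.5, np.log(0.07), 0.02, -0.03])
        g = m.score(p)
        for j in range(p.size):
            h = 1e-6
            pp, pm = p.copy(), p.copy()
            pp[j] += h
            pm[j] -= h
            num = (m.loglike(pp) - m.loglike(pm)) / (2 * h)
            assert g[j] == pytest.approx(num, rel=1e-5, abs=1e-4)

    def test_permutation_invariance(self, aft_cohort, fit):
        rng = np.random.default_rng(3)
        res2 = GompertzAFT(_permute(aft_cohort.data, rng)).fit()
        np.testing.assert_allclose(res2.params_internal, fit.params_internal, atol=1e-10)

    def test_summary_has_all_parameters(self, fit):
        s = fit.summary()
        assert list(s.index) == ["log_a", "log_b", "x1", "x2"]
        assert np.all(s["se"] > 0)

    def test_requires_events_and_full_rank(self):
        d = SurvivalData(entry_age=[20, 30], exit_age=[25, 35], status=[1, 0],
                         markers=np.ones((2, 1)))
        with pytest.raises(ValueError, match="events"):
            GompertzAFT(d)
        cohort = draw_cohort(SimConfig(n_obs=100, seed=1))
        dd = cohort.data
        degenerate = SurvivalData(entry_age=dd.entry_age, exit_age=dd.exit_age,
                                  status=dd.status,
                                  markers=np.column_stack([dd.markers[:, 0]] * 2))
        with pytest.raises(ValueError, match="rank"):
            GompertzAFT(degenerate)


class TestCoxAge:
    def test_partial_likelihood_matches_brute_force(self):
        cohort = draw_cohort(SimConfig(mechanism="gompertz_ph", n_obs=20, seed=5))
        m = CoxAge(cohort.data)
        res = m.fit()
        assert res.llf == pytest.approx(m.partial_loglike(res.beta_hat), abs=1e-9)

    def test_recovers_generating_coefficients(self):
        cohort = draw_cohort(SimConfig(mechanism="gompertz_ph", n_obs=10_000, seed=8))
        res = CoxAge(cohort.data).fit()
        assert np.all(np.abs(res.beta_hat - 0.3) < 3 * res.bse)

    def test_breslow_is_nondecreasing_and_zero_below_first_event(self, ph_cohort):
        res = CoxAge(ph_cohort.data).fit()
        assert np.all(np.diff(res.breslow_cumhaz) > 0)
        first_event = ph_cohort.data.exit_age[ph_cohort.data.status == 1].min()
        assert res.cumhaz_at(first_event - 1e-6) == 0.0

    def test_breslow_matches_direct_risk_set_enumeration(self):
        cohort = draw_cohort(SimConfig(mechanism="gompertz_ph", n_obs=50, seed=9))
        d = cohort.data
        res = CoxAge(d).fit()
        lp = d.markers @ res.beta_hat
        H = 0.0
        for t in np.sort(d.exit_age[d.status == 1]):
            at_risk = (d.entry_age < t) & (t <= d.exit_age)
            H += 1.0 / np.exp(lp[at_risk]).sum()
        assert res.breslow_cumhaz[-1] == pytest.approx(H, rel=1e-12)


class TestGrimAge:
    def test_training_set_prediction_moments_match_age(self, ph_cohort, grim_fit):
        d = ph_cohort.data
        b = grim_fit.predict_bioage_values(d.entry_age, d.markers)
        assert b.mean() == pytest.approx(d.entry_age.mean(), abs=1e-10)
        assert b.std(ddof=1) == pytest.approx(d.entry_age.std(ddof=1), abs=1e-10)

    def test_cox_stage_matches_generic_time_on_study_fit(self, ph_cohort, grim_fit):
        # independent route: scikit-survival's Cox fit on the same design
        from sksurv.linear_model import CoxPHSurvivalAnalysis
        from sksurv.util import Surv

        d = ph_cohort.data
        X = np.column_stack([d.entry_age, d.markers])
        y = Surv.from_arrays(event=d.status.astype(bool), time=d.time_on_study)
        ref = CoxPHSurvivalAnalysis(tol=1e-12).fit(X, y)
        np.testing.assert_allclose(grim_fit.beta_hat, ref.coef_, rtol=1e-5)

    def test_null_markers_track_entry_age(self):
        # markers unrelated to survival: prediction is driven by the age
        # coefficient, so it correlates with entry age with the same sign
        rng = np.random.default_rng(11)
        cohort = draw_cohort(SimConfig(mechanism="gompertz_ph", n_obs=2000, seed=12,
                                       beta=(0.0, 0.0)))
        d = cohort.data
        noise = SurvivalData(entry_age=d.entry_age, exit_age=d.exit_age, status=d.status,
                             markers=rng.normal(size=(len(d), 2)))
        res = GrimAgeModel(noise).fit()
        b = res.predict_bioage_values(noise.entry_age, noise.markers)
        r = np.corrcoef(b, noise.entry_age)[0, 1]
        assert np.sign(r) == np.sign(res.beta_hat[0])
        assert abs(r) > 0.9


class TestConditionalResidualLife:
    def test_null_markers_equal_baseline_residual_life(self, true_fit, gompertz):
        table = build_from_parametric(gompertz)
        for c in (30.0, 50.0, 70.0):
            got = true_fit.predict_residual_life([c], np.zeros((1, 2)), kind="median")[0]
            assert got == pytest.approx(table.residual_life(c, "median"), abs=0.01)

    def test_closed_form_median_matches_grid_machinery(self, true_fit, gompertz):
        from accelerage.distributions import conditional_params

        x = np.array([[1.0, 0.7]])
        theta = float(np.exp(true_fit.linear_predictor(x))[0])
        cond = build_from_parametric(conditional_params(gompertz, theta), grid=(0, 140, 0.01))
        for c in (40.0, 60.0):
            got = true_fit.predict_residual_life([c], x, kind="median")[0]
            assert got == pytest.approx(cond.residual_life(c, "median"), abs=0.02)

    def test_monotone_decreasing_in_acceleration(self, true_fit):
        xs = np.linspace(-2, 2, 9)
        rl = true_fit.predict_residual_life(np.full(9, 50.0), np.column_stack([xs, xs]))
        assert np.all(np.diff(rl) < 0)

    def test_mean_median_gap_small_at_60(self, true_fit):
        med = true_fit.predict_residual_life([60.0], np.zeros((1, 2)), kind="median")[0]
        mean = true_fit.predict_residual_life([60.0], np.zeros((1, 2)), kind="mean")[0]
        assert abs(mean - med) / mean < 0.15

    def test_cox_insufficient_tail_support(self):
        cohort = draw_cohort(SimConfig(mechanism="gompertz_ph", n_obs=500, seed=14,
                                       c_min=20, c_max=40, followup_years=5))
        res = CoxAge(cohort.data).fit()
        from accelerage.lifetable import InsufficientTailSupportError

        with pytest.raises(InsufficientTailSupportError):
            res.predict_residual_life([30.0], np.zeros((1, 2)), kind="median")
        out = res.predict_residual_life([30.0], np.zeros((1, 2)), kind="median",
                                        missing="nan")
        assert np.isnan(out[0])
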