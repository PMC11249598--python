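"""Life-table construction, residual life and its inversion."""

import numpy as np
import pandas as pd
import pytest

from accelerage import (
    CovariateEffect,
    GompertzParams,
    LifeTable,
    NotInvertibleError,
    SurvivalData,
    build_from_data,
    build_from_parametric,
    read_lifetable,
    write_lifetable,
)
from accelerage.lifetable import InsufficientTailSupportError, extend_tail_gompertz


def exponential_table(rate=0.1, t_max=200.0, step=0.05):
    ages = np.arange(0, t_max + step / 2, step)
    return LifeTable(ages=ages, survival=np.exp(-rate * ages))


@pytest.fixture(scope="module")
def gompertz_table(gompertz):
    return build_from_parametric(gompertz)


class TestResidualLife:
    def test_exponential_closed_forms(self):
        # memoryless: mrl = 1/rate, medrl = log(2)/rate at every age
        t = exponential_table(rate=0.1)
        for age in (0.0, 10.0, 30.0, 50.0):
            assert t.residual_life(age, "mean") == pytest.approx(10.0, rel=1e-3)
            assert t.residual_life(age, "median") == pytest.approx(10 * np.log(2), rel=1e-3)

    def test_gompertz_median_at_birth_matches_hazard_root(self, gompertz, gompertz_table):
        root = gompertz.inverse_cumulative_hazard(np.log(2))
        assert gompertz_table.residual_life(0.0, "median") == pytest.approx(root, abs=0.05)

    def test_mrl_strictly_decreasing_for_increasing_hazard(self, gompertz_table):
        ages = np.arange(20.0, 100.0, 1.0)
        mrl = gompertz_table.residual_life(ages, "mean")
        assert np.all(np.diff(mrl) < 0)

    def test_uniform_death_law_mean(self):
        # S(t) = 1 - t/tmax has mrl(t) = (tmax - t)/2
        ages = np.arange(0, 100.0001, 0.05)
        t = LifeTable(ages=ages, survival=1 - ages / 100.0 + 1e-12)
        assert t.residual_life(40.0, "mean") == pytest.approx(30.0, rel=1e-4)

    def test_grid_refinement_consistency(self, gompertz):
        coarse = build_from_parametric(gompertz, grid=(0, 120, 0.05))
        fine = build_from_parametric(gompertz, grid=(0, 120, 0.01))
        d = abs(coarse.residual_life(50.0, "median") - fine.residual_life(50.0, "median"))
        assert d < 0.02

    def test_mean_requires_tail_support(self):
        ages = np.arange(0, 50.0001, 0.05)
        t = LifeTable(ages=ages, survival=np.exp(-0.01 * ages))
        with pytest.raises(InsufficientTailSupportError):
            t.residual_life(20.0, "mean")


class TestMarginalTable:
    def test_null_effect_equals_baseline(self, gompertz):
        eff = CovariateEffect(beta=np.zeros(2), assumption="AFT")
        marg = build_from_parametric(gompertz, effect=eff, marker_sd_linear_predictor=0.0,
                                     mode="marginal")
        base = build_from_parametric(gompertz, mode="baseline")
        np.testing.assert_allclose(marg.survival, base.survival, atol=1e-15)

    def test_marginal_requires_effect(self, gompertz):
        with pytest.raises(ValueError):
            build_from_parametric(gompertz, mode="marginal")

    def test_quadrature_matches_monte_carlo(self, gompertz):
        eff = CovariateEffect(beta=np.array([0.05, 0.05]), assumption="AFT")
        sigma = eff.lp_sd_std_normal
        marg = build_from_parametric(gompertz, effect=eff, marker_sd_linear_predictor=sigma,
                                     mode="marginal")
        rng = np.random.default_rng(42)
        lp = rng.normal(0.0, sigma, 1_000_000)
        theta = np.exp(lp)
        for t in (40.0, 60.0, 80.0):
            s = np.exp(-gompertz.cumulative_hazard(theta * t))
            mc, se = s.mean(), s.std(ddof=1) / 1000.0
            assert abs(marg.survival_at(t) - mc) < 3 * se


class TestEmpiricalTable:
    def test_matches_hand_computed_km(self):
        # n = 6, entry at 0, no censoring: S drops by 1/6 at each death
        times = np.array([55.0, 60.0, 65.0, 70.0, 80.0, 90.0])
        data = SurvivalData(entry_age=np.zeros(6) + 1e-9, exit_age=times,
                            status=np.ones(6), markers=np.zeros((6, 1)))
        t = build_from_data(data, grid=(0, 95, 0.5))
        for k, age in enumerate(times):
            assert t.survival_at(age + 0.25) == pytest.approx((5 - k) / 6, abs=1e-12)
        assert t.survival_at(50.0) == 1.0

    def test_all_censored_rejected(self):
        data = SurvivalData(entry_age=np.zeros(3), exit_age=np.array([10.0, 20.0, 30.0]),
                            status=np.zeros(3), markers=np.zeros((3, 1)))
        with pytest.raises(ValueError, match="no events"):
            build_from_data(data)

    def test_invariant_under_record_duplication(self, aft_cohort):
        d = aft_cohort.data
        doubled = SurvivalData(
            entry_age=np.concatenate([d.entry_age] * 2),
            exit_age=np.concatenate([d.exit_age] * 2),
            status=np.concatenate([d.status] * 2),
            markers=np.concatenate([d.markers] * 2),
        )
        t1 = build_from_data(d)
        t2 = build_from_data(doubled)
        np.testing.assert_allclose(t1.survival, t2.survival, atol=1e-12)

    def test_warns_when_median_support_missing(self):
        # short follow-up: the estimated curve never reaches half its value
        rng = np.random.default_rng(0)
        entry = rng.uniform(20, 40, 300)
        exit_age = entry + rng.uniform(0.1, 5.0, 300)
        status = np.zeros(300, dtype=int)
        status[:10] = 1  # a handful of deaths: the curve stays near 1
        data = SurvivalData(entry_age=entry, exit_age=exit_age, status=status,
                            markers=np.zeros((300, 1)))
        with pytest.warns(UserWarning, match="half"):
            build_from_data(data, grid=(0, 50, 0.1))

    def test_gompertz_tail_extension(self, gompertz):
        # empirical-style table truncated at 95 y gains a decreasing tail
        full = build_from_parametric(gompertz, grid=(0, 120, 0.1))
        surv = np.where(full.ages <= 95, full.survival, full.survival_at(95.0))
        trunc = LifeTable(ages=full.ages, survival=surv)
        ext = extend_tail_gompertz(trunc)
        assert ext.survival[-1] < trunc.survival[-1]
        np.testing.assert_allclose(ext.survival_at(110.0), full.survival_at(110.0), rtol=0.3)


class TestFileDialects:
    def test_lx_normalization(self, tmp_path):
        p = tmp_path / "lx.csv"
        pd.DataFrame({"age": [0, 1, 2, 3], "lx": [100000, 99000, 97000, 90000]}).to_csv(
            p, index=False
        )
        t = read_lifetable(p, dialect="lx")
        np.testing.assert_allclose(t.survival_at([0, 1, 2, 3]), [1.0, 0.99, 0.97, 0.90])

    def test_constant_qx_is_geometric(self, tmp_path):
        q = 0.02
        p = tmp_path / "qx.csv"
        pd.DataFrame({"age": np.arange(50), "qx": np.full(50, q)}).to_csv(p, index=False)
        t = read_lifetable(p, dialect="qx")
        ages = np.arange(0, 50)
        np.testing.assert_allclose(t.survival_at(ages), (1 - q) ** ages, rtol=1e-12)

    def test_write_read_round_trip(self, tmp_path, gompertz_table):
        p = tmp_path / "rt.csv"
        write_lifetable(gompertz_table, p)
        back = read_lifetable(p, dialect="survival")
        np.testing.assert_allclose(back.survival, gompertz_table.survival, atol=1e-12)
        np.testing.assert_allclose(back.ages, gompertz_table.ages, atol=1e-12)

    def test_stratified_file_equals_individual_tables(self, tmp_path, gompertz):
        male = build_from_parametric(gompertz, grid=(0, 110, 1.0))
        female = build_from_parametric(GompertzParams(a=gompertz.a / 2, b=gompertz.b),
                                       grid=(0, 110, 1.0))
        p = tmp_path / "strat.csv"
        write_lifetable({"male": male, "female": female}, p)
        tables = read_lifetable(p, dialect="survival", stratum_col="stratum")
        assert set(tables) == {"male", "female"}
        np.testing.assert_allclose(tables["male"].survival, male.survival, atol=1e-12)
        np.testing.assert_allclose(tables["female"].survival, female.survival, atol=1e-12)

    def test_errors_name_the_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"age": [0, 2, 1], "survival": [1.0, 0.9, 0.8]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="line 3"):
            read_lifetable(p, dialect="survival")
        p2 = tmp_path / "bad2.csv"
        pd.DataFrame({"age": [0, 1, 2], "survival": [1.0, 0.8, 0.9]}).to_csv(p2, index=False)
        with pytest.raises(ValueError, match="increases"):
            read_lifetable(p2, dialect="survival")
        p3 = tmp_path / "bad3.csv"
        pd.DataFrame({"age": [0, 1], "foo": [1, 2]}).to_csv(p3, index=False)
        with pytest.raises(ValueError, match="missing required"):
            read_lifetable(p3, dialect="survival")


class TestInversion:
    @pytest.mark.parametrize("c", [30.0, 50.0, 70.0])
    @pytest.mark.parametrize("kind", ["mean", "median"])
    def test_round_trip_within_one_grid_step(self, gompertz_table, c, kind):
        rl = gompertz_table.residual_life(c, kind)
        back = gompertz_table.invert_residual_life(rl, kind)
        assert abs(back - c) <= gompertz_table.step

    def test_reference_example_twenty_years_maps_to_57(self):
        # uniform-death law: mrl(t) = (tmax - t)/2, so tmax = 97 puts
        # a 20-year mean residual life exactly at age 57
        ages = np.arange(0, 97.0001, 0.05)
        t = LifeTable(ages=ages, survival=1 - ages / 97.0 + 1e-12)
        assert t.invert_residual_life(20.0, "mean") == pytest.approx(57.0, abs=0.1)

    def test_exponential_not_invertible(self):
        t = exponential_table(rate=0.1)
        with pytest.raises(NotInvertibleError):
            t.invert_residual_life(5.0, "median")

    def test_out_of_range_raises_or_flags(self, gompertz_table):
        big = gompertz_table.residual_life(0.0, "median") + 10.0
        with pytest.raises(ValueError, match="outside"):
            gompertz_table.invert_residual_life(big, "median")
        out = gompertz_table.invert_residual_life(np.array([big, 20.0]), "median",
                                                  out_of_range="nan")
        assert np.isnan(out[0]) and np.isfinite(out[1])
        clipped = gompertz_table.invert_residual_life(big, "median", out_of_range="clip")
        assert clipped == pytest.approx(0.0, abs=1e-9)
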