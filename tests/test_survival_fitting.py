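"""Parametric MLE, mixture cure model, AIC selection, background mortality
and the proportional-hazards diagnostic."""

import numpy as np
import pandas as pd
import pytest

from psmcure import (
    ArmSpec,
    BackgroundSurvival,
    FitResult,
    LifeTable,
    apply_background_mortality,
    build_default_lifetable,
    default_calibration,
    fit_all_families,
    fit_mixture_cure,
    fit_parametric,
    generate_ipd,
    get_family,
    select_model,
    survival_non_mixture_cure,
    test_ph,
)
from psmcure.families import FAMILY_NAMES
from psmcure.survival_fitting import CureFitResult, cure_loglikelihood, loglikelihood


class TestParametricMLE:
    def test_exponential_uncensored_closed_form(self):
        # MLE rate = events / total time = 3/6
        fit = fit_parametric((np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1])), "exponential")
        assert fit.params["rate"] == pytest.approx(0.5, rel=1e-5)

    def test_exponential_censored_closed_form(self):
        # last observation censored: rate = 2/6
        fit = fit_parametric((np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0])), "exponential")
        assert fit.params["rate"] == pytest.approx(2 / 6, rel=1e-5)

    def test_aic_definition(self):
        fit = fit_parametric((np.arange(1.0, 30.0), np.ones(29, int)), "weibull")
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * 2)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            fit_parametric((np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0])), "exponential")

    @pytest.mark.parametrize("family", FAMILY_NAMES)
    def test_fitted_survival_is_valid(self, family, trial_2k):
        ds, _ = trial_2k
        fit = fit_parametric(ds, family, "os", "C")
        t = np.linspace(0, 120, 10_000)
        s = fit.survival(t)
        assert s[0] == pytest.approx(1.0)
        assert (np.diff(s) <= 1e-12).all()
        assert s[-1] >= 0.0

    @pytest.mark.parametrize(
        "family,params",
        [
            ("exponential", {"rate": 0.08}),
            ("weibull", {"shape": 1.4, "scale": 12.0}),
            ("gompertz", {"shape": 0.12, "rate": 0.03}),
            ("loglogistic", {"shape": 2.0, "scale": 9.0}),
            ("lognormal", {"mu": 2.2, "sigma": 0.8}),
        ],
    )
    def test_parameter_recovery_at_n2000(self, family, params):
        rng = np.random.default_rng(7)
        fam = get_family(family)
        t = fam.rvs(params, 2000, rng)
        fit = fit_parametric((t, np.ones(2000, int)), family)
        for name, true in params.items():
            assert fit.params[name] == pytest.approx(true, rel=0.05), (family, name)

    def test_optimum_beats_random_admissible_vectors(self, trial_2k):
        ds, _ = trial_2k
        times, events = ds.endpoint("os", "C")
        fit = fit_parametric(ds, "weibull", "os", "C")
        rng = np.random.default_rng(0)
        for _ in range(50):
            cand = {"shape": rng.uniform(0.2, 4.0), "scale": rng.uniform(1.0, 40.0)}
            assert loglikelihood("weibull", cand, times, events) <= fit.loglik + 1e-6

    def test_dual_route_against_lifelines(self, trial_2k):
        from lifelines import LogNormalFitter, WeibullFitter

        ds, _ = trial_2k
        times, events = ds.endpoint("os", "C")
        ours = fit_parametric(ds, "weibull", "os", "C")
        ll = WeibullFitter().fit(times, events)
        assert ours.loglik == pytest.approx(ll.log_likelihood_, rel=1e-6)
        assert ours.params["scale"] == pytest.approx(ll.lambda_, rel=1e-3)
        assert ours.params["shape"] == pytest.approx(ll.rho_, rel=1e-3)
        ours_ln = fit_parametric(ds, "lognormal", "os", "C")
        ln = LogNormalFitter().fit(times, events)
        assert ours_ln.loglik == pytest.approx(ln.log_likelihood_, rel=1e-6)


class TestSelectModel:
    @staticmethod
    def _dummy(family, aic, k=2, converged=True):
        return FitResult(family, {f"p{i}": 1.0 for i in range(k)}, -aic / 2 + k,
                         aic, None, converged, 100, 90)

    def test_lowest_aic_wins(self):
        fits = [self._dummy("a", 100), self._dummy("b", 90), self._dummy("c", 95)]
        best, table = select_model(fits)
        assert best.family == "b"
        assert list(table["family"]) == ["b", "c", "a"]

    def test_tie_prefers_fewer_parameters(self):
        fits = [self._dummy("two", 90, k=2), self._dummy("one", 90, k=1)]
        best, _ = select_model(fits)
        assert best.family == "one"

    def test_non_converged_excluded(self):
        fits = [self._dummy("bad", 10, converged=False), self._dummy("ok", 99)]
        best, _ = select_model(fits)
        assert best.family == "ok"
        with pytest.raises(ValueError):
            select_model([self._dummy("bad", 10, converged=False)])

    def test_true_family_ranked_first_on_large_gompertz_sample(self):
        fam = get_family("gompertz")
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = fam.rvs({"shape": 0.14, "rate": 0.03}, 3000, rng)
            fits = fit_all_families((t, np.ones(3000, int)))
            best, _ = select_model(fits)
            wins += best.family == "gompertz"
        assert wins >= 8


class TestMixtureCure:
    def test_limit_p_zero_reduces_to_background_times_uncured(self):
        lt = build_default_lifetable()
        bg = BackgroundSurvival(lt, 64.0)
        res = CureFitResult(0.0, "weibull", {"shape": 1.2, "scale": 10.0}, bg,
                            0.0, 0.0, True, True, 10, 10)
        t = np.array([0.0, 6.0, 18.0])
        expected = bg.sf(t) * get_family("weibull").sf(t, res.uncured_params)
        assert np.allclose(res.survival(t), expected)

    def test_limit_p_one_reduces_to_background(self):
        lt = build_default_lifetable()
        bg = BackgroundSurvival(lt, 64.0)
        res = CureFitResult(1.0, "weibull", {"shape": 1.2, "scale": 10.0}, bg,
                            0.0, 0.0, True, True, 10, 10)
        t = np.array([0.0, 12.0, 60.0])
        assert np.allclose(res.survival(t), bg.sf(t))

    def test_cure_fraction_recovery_over_ten_seeds(self):
        # data generated with a 15% cured fraction and Gompertz uncured kernel
        lt = build_default_lifetable()
        bg = BackgroundSurvival(lt, 64.0)
        estimates = []
        for seed in range(10):
            spec = ArmSpec(
                name="X", n=2000, cure_fraction=0.15,
                uncured_os_family="gompertz",
                uncured_os_params={"shape": 0.12, "rate": 0.027},
                pfs_family="lognormal", pfs_params={"mu": 2.4, "sigma": 0.95},
            )
            ds = generate_ipd([spec], lt, seed=seed)
            fit = fit_mixture_cure(ds, "gompertz", bg, "os", "X")
            estimates.append(fit.p_cured)
        assert abs(np.mean(estimates) - 0.15) <= 0.05

    def test_population_survival_ratio_converges_to_cure_fraction(self, trial_2k):
        ds, lt = trial_2k
        bg = BackgroundSurvival(lt, 64.0)
        fit = fit_mixture_cure(ds, "gompertz", bg, "os", "A+C")
        t_far = 300.0  # 10× the 30-month model horizon
        ratio = fit.survival(t_far) / bg.sf(t_far)
        assert ratio == pytest.approx(fit.p_cured, abs=1e-3)

    def test_reported_loglik_matches_public_likelihood(self, trial_2k):
        ds, lt = trial_2k
        bg = BackgroundSurvival(lt, 64.0)
        fit = fit_mixture_cure(ds, "gompertz", bg, "os", "A+C")
        ll = cure_loglikelihood(fit.p_cured, "gompertz", fit.uncured_params, bg,
                                *ds.endpoint("os", "A+C"))
        assert ll == pytest.approx(fit.loglik, abs=1e-6)
        assert fit.aic == pytest.approx(-2 * ll + 2 * fit.n_params)


class TestNonMixtureCure:
    def test_time_zero_is_one(self):
        assert survival_non_mixture_cure(0.3, 1.0) == pytest.approx(1.0)

    def test_asymptote_is_cure_fraction(self):
        assert survival_non_mixture_cure(0.3, 0.0) == pytest.approx(0.3)
        assert survival_non_mixture_cure(0.3, 0.0, s_gen=0.9) == pytest.approx(0.27)

    def test_hand_value(self):
        # exp(ln 0.5 · 0.5) = 1/√2
        assert survival_non_mixture_cure(0.5, 0.5) == pytest.approx(0.70710678, abs=1e-6)

    def test_p_zero_rejected(self):
        with pytest.raises(ValueError):
            survival_non_mixture_cure(0.0, 0.5)


class TestBackgroundMortality:
    def test_zero_background_leaves_model_unchanged(self):
        lt = LifeTable(np.arange(0, 111, dtype=float), np.zeros(111))
        adj = apply_background_mortality(lambda t: np.exp(-0.05 * np.asarray(t)), lt, 64.0)
        t = np.linspace(0, 30, 50)
        assert np.allclose(adj(t), np.exp(-0.05 * t))

    def test_constant_qx_closed_form(self):
        # qx = 0.01/year with flat model survival: S_adj(12 months) = 0.99
        lt = LifeTable(np.arange(0, 111, dtype=float), np.full(111, 0.01))
        adj = apply_background_mortality(lambda t: np.ones_like(np.asarray(t, float)), lt, 64.0)
        assert float(adj(12.0)) == pytest.approx(0.99, abs=1e-9)

    def test_adjusted_below_both_factors(self, trial_2k):
        ds, lt = trial_2k
        fit = fit_parametric(ds, "gompertz", "os", "C")
        adj = apply_background_mortality(fit.survival, lt, 64.0)
        bg = BackgroundSurvival(lt, 64.0)
        t = np.linspace(0.0, 60.0, 200)
        assert (adj(t) <= np.minimum(fit.survival(t), bg.sf(t)) + 1e-12).all()

    def test_horizon_beyond_coverage_rejected(self):
        lt = LifeTable(np.arange(60, 70, dtype=float), np.full(10, 0.01))
        with pytest.raises(ValueError):
            apply_background_mortality(lambda t: t, lt, 64.0, horizon_months=200.0)


def _two_arm_exponential(n, rate_a, rate_b, seed, admin=1e6):
    lt = build_default_lifetable()
    mk = lambda nm, r: ArmSpec(nm, n, 0.0, "exponential", {"rate": r},
                               "lognormal", {"mu": 1.0, "sigma": 0.5},
                               0.0, admin, 0.0)
    return generate_ipd([mk("a", rate_a), mk("b", rate_b)], lt, seed=seed)


class TestProportionalHazardsDiagnostic:
    def test_identical_arms_not_significant(self):
        ds = _two_arm_exponential(150, 0.08, 0.08, seed=11)
        res = test_ph(ds, "os")
        assert res.p_value > 0.05
        assert not res.rejects_ph

    def test_type_one_error_near_nominal_under_exact_ph(self):
        # two exponential arms (HR 0.7) satisfy PH exactly
        rejections = 0
        n_sims = 200
        for seed in range(n_sims):
            ds = _two_arm_exponential(80, 0.07, 0.10, seed=seed, admin=60.0)
            rejections += test_ph(ds, "os").rejects_ph
        assert 0.01 <= rejections / n_sims <= 0.12

    def test_power_against_cure_induced_crossing_hazards(self):
        lt = build_default_lifetable()
        rejections = 0
        n_sims = 40
        for seed in range(n_sims):
            cured = ArmSpec("a", 150, 0.35, "gompertz", {"shape": 0.25, "rate": 0.02},
                            "lognormal", {"mu": 1.0, "sigma": 0.5}, 0.0, 60.0, 0.0)
            plain = ArmSpec("b", 150, 0.0, "exponential", {"rate": 0.06},
                            "lognormal", {"mu": 1.0, "sigma": 0.5}, 0.0, 60.0, 0.0)
            ds = generate_ipd([cured, plain], lt, seed=seed)
            rejections += test_ph(ds, "os").rejects_ph
        assert rejections / n_sims > 0.5

    def test_loglog_curves_exported(self, trial_2k):
        ds, _ = trial_2k
        res = test_ph(ds, "os")
        assert set(res.loglog_curves["arm"]) == {"A+C", "C"}
        assert len(res.loglog_curves) > 50
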