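"""Tests of the 4PL machinery: evaluation, fitting, nested F test, power law."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nervedose import (DoseResponseSimConfig, FourPLParams, fit_fourpl,
                       fit_grouped_fourpl, fit_power_law, fourpl,
                       simulate_displacement, simulate_dose_response,
                       treatment_F)
from nervedose.dose_response import FitError, _fourpl_jac

SPLS = np.arange(20.0, 111.0, 10.0)
TRUTH = FourPLParams(b=-0.15, c=1.0, d=8.0, e=75.0)


def _curve_table(params_by_group, n_per_group=6, noise_sd=0.0, seed=0):
    cfg = DoseResponseSimConfig(
        truth_per_group=params_by_group, n_animals_per_group=n_per_group,
        animal_intercept_sd=0.0, residual_sd=noise_sd, seed=seed)
    return simulate_dose_response(cfg)


class TestFourPL:
    def test_midpoint_identity(self):
        p = FourPLParams(b=-0.2, c=1.0, d=10.0, e=70.0)
        assert fourpl(70.0, p) == pytest.approx((1.0 + 10.0) / 2)

    def test_upper_asymptote_limit(self):
        p = FourPLParams(b=-0.2, c=1.0, d=10.0, e=70.0)
        assert fourpl(70.0 + 1000.0, p) == pytest.approx(10.0, abs=1e-8)
        assert fourpl(70.0 - 1000.0, p) == pytest.approx(1.0, abs=1e-8)

    def test_matches_one_line_formula_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            b, c, d, e = rng.normal(0, 0.5), rng.normal(0, 5), rng.normal(0, 5), \
                rng.uniform(0, 120)
            x = rng.uniform(-50, 170)
            got = float(fourpl(x, FourPLParams(b, c, d, e)))
            want = c + (d - c) / (1.0 + np.exp(b * (x - e)))  # printed equation
            assert got == pytest.approx(want, abs=1e-12)

    def test_no_overflow_at_extreme_arguments(self):
        p = FourPLParams(b=-5.0, c=0.0, d=1.0, e=0.0)
        assert fourpl(1e6, p) == pytest.approx(1.0)
        assert fourpl(-1e6, p) == pytest.approx(0.0)

    @given(b=st.floats(-0.5, -0.01), x1=st.floats(0, 120), x2=st.floats(0, 120))
    @settings(max_examples=50, deadline=None)
    def test_monotone_for_fixed_sign_b(self, b, x1, x2):
        p = FourPLParams(b=b, c=1.0, d=8.0, e=70.0)
        lo, hi = sorted([x1, x2])
        assert fourpl(lo, p) <= fourpl(hi, p) + 1e-12

    def test_analytic_jacobian_matches_finite_differences(self):
        theta = np.array([-0.15, 1.0, 8.0, 75.0])
        x = np.linspace(20, 110, 10)
        J = _fourpl_jac(x, theta)
        for i in range(4):
            h = 1e-6 * max(abs(theta[i]), 1.0)
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd = (fourpl(x, FourPLParams.from_array(tp))
                  - fourpl(x, FourPLParams.from_array(tm))) / (2 * h)
            assert np.allclose(J[:, i], fd, rtol=1e-5, atol=1e-8)


class TestFitFourPL:
    def test_exact_data_recovered(self):
        y = fourpl(SPLS, TRUTH)
        fit = fit_fourpl(SPLS, y)
        assert fit.rss < 1e-12
        assert np.allclose(fit.params.as_array(), TRUTH.as_array(), atol=1e-6)
        assert fit.df_residual == len(SPLS) - 4
        assert fit.converged

    def test_residuals_orthogonal_to_jacobian(self):
        rng = np.random.default_rng(0)
        y = fourpl(SPLS, TRUTH) + rng.normal(0, 0.3, SPLS.size)
        fit = fit_fourpl(SPLS, y)
        r = y - fourpl(SPLS, fit.params)
        J = _fourpl_jac(SPLS, fit.params.as_array())
        # normal equations at the optimum
        assert np.all(np.abs(J.T @ r) < 1e-5 * max(np.abs(r).sum(), 1.0))

    def test_too_few_or_degenerate_points_refused(self):
        with pytest.raises(FitError):
            fit_fourpl([60, 70, 80, 90], [1, 2, 3, 4])
        with pytest.raises(FitError):
            fit_fourpl([60] * 6, [1, 2, 3, 4, 5, 6])
        with pytest.raises(FitError):
            fit_fourpl(SPLS, np.full(SPLS.size, 2.0))

    def test_e_bias_small_under_noise(self):
        # 30 animals, sd 0.3: mean absolute bias of the inflection < 1 dB
        errs = []
        for seed in range(50):
            tab = _curve_table({"control": TRUTH, "noise": TRUTH},
                               n_per_group=15, noise_sd=0.3, seed=seed)
            fit = fit_fourpl(tab.spl_db, tab.sigma)
            errs.append(fit.params.e - TRUTH.e)
        assert abs(np.mean(errs)) < 1.0

    def test_never_beaten_by_random_search(self):
        rng = np.random.default_rng(21)
        for trial in range(10):
            y = fourpl(SPLS, TRUTH) + rng.normal(0, 0.4, SPLS.size)
            fit = fit_fourpl(SPLS, y)
            cand = np.column_stack([
                rng.uniform(-0.6, -0.01, 1000),
                rng.uniform(0.0, 3.0, 1000),
                rng.uniform(4.0, 12.0, 1000),
                rng.uniform(40.0, 110.0, 1000),
            ])
            rss_cand = min(
                float(np.sum((fourpl(SPLS, FourPLParams.from_array(t)) - y) ** 2))
                for t in cand)
            assert fit.rss <= rss_cand + 1e-9


class TestGroupedFit:
    def test_identical_noiseless_groups(self):
        tab = _curve_table({"control": TRUTH, "noise": TRUTH})
        grouped = fit_grouped_fourpl(tab)
        assert grouped.rss_full < 1e-10
        assert grouped.rss_reduced < 1e-10

    def test_constructed_d_difference_recovered(self):
        truth = {"control": FourPLParams(-0.15, 1, 8, 75),
                 "noise": FourPLParams(-0.15, 1, 5, 75)}
        tab = _curve_table(truth, n_per_group=10, noise_sd=0.2, seed=4)
        grouped = fit_grouped_fourpl(tab)
        assert grouped.rss_full < 0.5 * grouped.rss_reduced
        d_ctrl = grouped.group_fits["control"].params.d
        d_noise = grouped.group_fits["noise"].params.d
        assert d_ctrl - d_noise == pytest.approx(3.0, abs=0.4)

    def test_nesting_inequality(self):
        for seed in range(5):
            tab = _curve_table({"control": TRUTH,
                                "noise": FourPLParams(-0.15, 1, 6, 80)},
                               n_per_group=6, noise_sd=0.5, seed=seed)
            grouped = fit_grouped_fourpl(tab)
            assert grouped.rss_full <= grouped.rss_reduced + 1e-9

    def test_small_group_refused(self):
        tab = _curve_table({"control": TRUTH, "noise": TRUTH}, n_per_group=2)
        tab = tab[(tab.treatment == "control") | (tab.spl_db < 50)]
        with pytest.raises(FitError):
            fit_grouped_fourpl(tab)


class TestTreatmentF:
    def test_duplicated_identical_noiseless_groups_give_zero_F(self):
        tab = _curve_table({"control": TRUTH, "noise": TRUTH})
        comp = treatment_F(fit_grouped_fourpl(tab))
        assert comp.F == 0.0

    def test_hand_fixture_matches_brute_force_oracle(self):
        """F from an independent refit (random search + Nelder-Mead polish)."""
        from scipy.optimize import minimize
        rng = np.random.default_rng(8)
        x = np.array([20, 30, 40, 50, 60, 70, 80, 90, 100, 110], float)
        ya = fourpl(x, FourPLParams(-0.2, 1, 7, 70)) + rng.normal(0, 0.3, 10)
        yb = fourpl(x, FourPLParams(-0.2, 1, 5, 80)) + rng.normal(0, 0.3, 10)
        tab = pd.DataFrame({
            "spl_db": np.concatenate([x, x]),
            "sigma": np.concatenate([ya, yb]),
            "treatment": ["control"] * 10 + ["noise"] * 10,
        })
        comp = treatment_F(fit_grouped_fourpl(tab))

        def best_rss(xs, ys):
            def rss(t):
                return float(np.sum((fourpl(xs, FourPLParams.from_array(t)) - ys) ** 2))
            best = None
            for _ in range(400):
                t0 = np.array([rng.uniform(-0.6, -0.02), rng.uniform(-1, 3),
                               rng.uniform(3, 10), rng.uniform(40, 110)])
                res = minimize(rss, t0, method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-12,
                                        "maxiter": 4000})
                if best is None or res.fun < best:
                    best = res.fun
            return best

        rss_full = best_rss(x, ya) + best_rss(x, yb)
        rss_red = best_rss(np.concatenate([x, x]), np.concatenate([ya, yb]))
        f_oracle = ((rss_red - rss_full) / 4) / (rss_full / (20 - 8))
        assert comp.F == pytest.approx(f_oracle, rel=1e-3)
        assert comp.F_df == (4, 12)

    def test_relabeling_and_affine_invariance(self):
        truth = {"control": TRUTH, "noise": FourPLParams(-0.15, 1, 5, 85)}
        tab = _curve_table(truth, n_per_group=6, noise_sd=0.3, seed=7)
        comp = treatment_F(fit_grouped_fourpl(tab))
        swapped = tab.copy()
        swapped["treatment"] = swapped["treatment"].map(
            {"control": "noise", "noise": "control"})
        comp_sw = treatment_F(fit_grouped_fourpl(swapped))
        assert comp_sw.F == pytest.approx(comp.F, rel=1e-6)
        assert comp_sw.param_diff["d"] == pytest.approx(-comp.param_diff["d"],
                                                        rel=1e-4)
        scaled = tab.copy()
        scaled["sigma"] = 2.5 * scaled["sigma"] + 3.0
        comp_sc = treatment_F(fit_grouped_fourpl(scaled))
        assert comp_sc.F == pytest.approx(comp.F, rel=1e-5)

    def test_per_parameter_t_detects_d_shift(self):
        truth = {"control": TRUTH, "noise": FourPLParams(-0.15, 1, 5, 75)}
        tab = _curve_table(truth, n_per_group=10, noise_sd=0.2, seed=3)
        comp = treatment_F(fit_grouped_fourpl(tab))
        assert comp.param_p["d"] < 0.001
        assert comp.param_diff["d"] < 0  # noise minus control


class TestPowerLaw:
    def test_exact_law_recovered(self):
        tab = simulate_displacement(power_exponent=1.2, scale=1e-3,
                                    noise_floor=0.0, noise_cv=0.0,
                                    n_animals=1, seed=0)
        fit = fit_power_law(tab, floor_spl=0.0)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.pressure_exponent == pytest.approx(1.2, abs=1e-10)

    def test_two_points_give_exact_line(self):
        tab = pd.DataFrame({"animal_id": ["a", "a"], "spl_db": [70.0, 90.0],
                            "displacement_nm": [2.0, 8.0]})
        fit = fit_power_law(tab, floor_spl=0.0)
        assert fit.slope_per_db == pytest.approx(np.log10(4.0) / 20.0)
        assert fit.n_used == 2

    def test_floor_exclusion_removes_bias(self):
        exps_good, exps_bad = [], []
        for seed in range(200):
            tab = simulate_displacement(power_exponent=1.0, scale=1e-3,
                                        noise_floor=1.0, noise_cv=0.05,
                                        n_animals=2, seed=seed)
            exps_good.append(fit_power_law(tab, floor_spl=60.0).pressure_exponent)
            exps_bad.append(fit_power_law(tab, floor_spl=0.0).pressure_exponent)
        good = np.mean(exps_good)
        bad = np.mean(exps_bad)
        assert abs(good - 1.0) < 0.05          # within 5% with floor excluded
        assert abs(bad - 1.0) > abs(good - 1.0)  # floor contamination biases

    def test_nonpositive_displacement_refused(self):
        tab = pd.DataFrame({"animal_id": ["a"] * 3, "spl_db": [70.0, 80, 90],
                            "displacement_nm": [2.0, -1.0, 8.0]})
        with pytest.raises(FitError):
            fit_power_law(tab, floor_spl=0.0)
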