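"""Tests of OLS, crossed-intercept REML, Satterthwaite df and Cohen's d."""

import numpy as np
import pandas as pd
import pytest

from nervedose import (ModelSpec, cohens_d, fit_lm, fit_lmem, satterthwaite_df)
from nervedose.linear_mixed import ModelError, _profiled_criterion, build_design


def _one_way_table(n_groups, n_per, mu, sd_u, sd_e, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, sd_u)
        for _ in range(n_per):
            rows.append({"animal_id": f"a{g:02d}",
                         "y": mu + u + rng.normal(0, sd_e)})
    return pd.DataFrame(rows)


def _crossed_table(n_animals, spls, beta_treat, sd_a, sd_s, sd_e, seed):
    rng = np.random.default_rng(seed)
    ua = rng.normal(0, sd_a, n_animals)
    us = rng.normal(0, sd_s, len(spls))
    rows = []
    for i in range(n_animals):
        group = "noise" if i >= n_animals // 2 else "control"
        for j, spl in enumerate(spls):
            y = (1.0 + beta_treat * (group == "noise") + 0.03 * spl
                 + ua[i] + us[j] + rng.normal(0, sd_e))
            rows.append({"animal_id": f"a{i:02d}", "treatment": group,
                         "spl_db": float(spl), "y": y})
    return pd.DataFrame(rows)


class TestFitLM:
    def test_intercept_only_is_sample_mean(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"y": rng.normal(3.0, 2.0, 40)})
        fit = fit_lm(ModelSpec(response="y"), df)
        assert fit.beta[0] == pytest.approx(df["y"].mean())
        assert fit.se[0] == pytest.approx(df["y"].std(ddof=1) / np.sqrt(40))
        assert fit.df[0] == 39

    def test_exact_linear_data(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2.0 + 0.5 * df["x"]
        fit = fit_lm(ModelSpec(response="y", fixed=("x",)), df)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)
        assert fit.beta == pytest.approx([2.0, 0.5])

    def test_six_row_fixture_matches_normal_equation_oracle(self):
        df = pd.DataFrame({
            "x": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0],
            "g": ["a", "a", "b", "b", "a", "b"],
            "y": [1.2, 1.9, 3.4, 4.1, 3.3, 6.0],
        })
        fit = fit_lm(ModelSpec(response="y", fixed=("x", "g")), df)
        # hand-coded matrix algebra oracle
        X = np.column_stack([np.ones(6), df["x"],
                             (df["g"] == "b").astype(float)])
        y = df["y"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        s2 = (r @ r) / (6 - 3)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        assert np.allclose(fit.beta, beta, atol=1e-10)
        assert np.allclose(fit.se, se, atol=1e-10)
        assert np.allclose(fit.t, beta / se, atol=1e-10)

    def test_rank_deficient_design_names_columns(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "z": [2.0, 4, 6, 8],
                           "y": [1.0, 2, 3, 4]})
        with pytest.raises(ModelError, match="z"):
            fit_lm(ModelSpec(response="y", fixed=("x", "z")), df)


class TestFitLMEM:
    def test_boundary_limit_equals_ols(self):
        # no true animal variance; seed chosen where REML hits the boundary
        df = _one_way_table(8, 5, 2.0, 0.0, 1.0, seed=3)
        spec = ModelSpec(response="y", random=("animal_id",))
        fit = fit_lmem(spec, df)
        ols = fit_lm(ModelSpec(response="y"), df)
        assert fit.vc["animal_id"] < 1e-6 * fit.sigma2
        assert fit.boundary
        assert np.allclose(fit.beta, ols.beta, atol=1e-6)
        assert fit.df[0] == pytest.approx(fit.n_obs - 1)

    def test_balanced_one_way_matches_closed_form_reml(self):
        # balanced design: sigma_u^2 = (MSB - MSW)/m, sigma_e^2 = MSW
        g, m = 10, 6
        df = _one_way_table(g, m, 5.0, 1.5, 0.8, seed=7)
        spec = ModelSpec(response="y", random=("animal_id",))
        fit = fit_lmem(spec, df)
        means = df.groupby("animal_id")["y"].mean()
        grand = df["y"].mean()
        msb = m * ((means - grand) ** 2).sum() / (g - 1)
        msw = sum(((df[df.animal_id == a]["y"] - means[a]) ** 2).sum()
                  for a in means.index) / (g * (m - 1))
        assert fit.sigma2 == pytest.approx(msw, abs=1e-8)
        assert fit.vc["animal_id"] == pytest.approx((msb - msw) / m, abs=1e-8)
        assert fit.beta[0] == pytest.approx(grand, abs=1e-10)

    def test_crossed_fixture_matches_statsmodels_and_random_search(self):
        import statsmodels.regression.mixed_linear_model as smm
        df = _crossed_table(10, (50.0, 70.0, 90.0, 110.0, 130.0),
                            beta_treat=1.0, sd_a=0.7, sd_s=0.5, sd_e=0.4,
                            seed=11)
        assert len(df) == 50
        spec = ModelSpec(response="y", fixed=("treatment", "spl_db"),
                         random=("animal_id", "spl_db"))
        fit = fit_lmem(spec, df)

        # reference mixed-model implementation (crossed intercepts via
        # variance components within a single super-group)
        df2 = df.assign(one=1)
        md = smm.MixedLM.from_formula(
            "y ~ treatment + spl_db", groups="one",
            vc_formula={"animal_id": "0 + C(animal_id)",
                        "spl": "0 + C(spl_db)"},
            re_formula="0", data=df2)
        ref = md.fit(reml=True, method="lbfgs", maxiter=500)
        assert np.allclose(fit.beta, ref.fe_params.to_numpy(), atol=1e-4)

        # REML criterion at the optimum beats 500 random candidates
        y, X, _, Z_named = build_design(spec, df)
        ZZ = [Z @ Z.T for _, Z in Z_named]
        lam_hat = np.array([fit.vc["animal_id"], fit.vc["spl_db"]]) / fit.sigma2
        best, _ = _profiled_criterion(lam_hat, y, X, ZZ, reml=True)
        rng = np.random.default_rng(0)
        for _ in range(500):
            cand = rng.uniform(0.0, 20.0, 2)
            val, _ = _profiled_criterion(cand, y, X, ZZ, reml=True)
            assert best <= val + 1e-6

    def test_single_level_grouping_refused(self):
        df = pd.DataFrame({"y": [1.0, 2, 3], "g": ["a", "a", "a"]})
        with pytest.raises(ModelError):
            fit_lmem(ModelSpec(response="y", random=("g",)), df)

    def test_mean_shift_invariance(self):
        df = _crossed_table(8, (60.0, 80.0, 100.0), 0.5, 0.5, 0.3, 0.4, seed=2)
        spec = ModelSpec(response="y", fixed=("treatment",),
                         random=("animal_id",))
        fit0 = fit_lmem(spec, df)
        df2 = df.assign(y=df["y"] + 100.0)
        fit1 = fit_lmem(spec, df2)
        assert fit1.beta[0] == pytest.approx(fit0.beta[0] + 100.0, abs=1e-5)
        assert fit1.beta[1] == pytest.approx(fit0.beta[1], abs=1e-6)
        assert fit1.sigma2 == pytest.approx(fit0.sigma2, rel=1e-5)
        assert fit1.vc["animal_id"] == pytest.approx(fit0.vc["animal_id"],
                                                     rel=1e-4, abs=1e-8)

    def test_reml_criterion_dominates_ml_solution(self):
        df = _crossed_table(8, (60.0, 80.0, 100.0), 0.5, 0.6, 0.3, 0.4, seed=5)
        spec_reml = ModelSpec(response="y", fixed=("treatment",),
                              random=("animal_id",), method="REML")
        spec_ml = ModelSpec(response="y", fixed=("treatment",),
                            random=("animal_id",), method="ML")
        fit_r = fit_lmem(spec_reml, df)
        fit_m = fit_lmem(spec_ml, df)
        y, X, _, Z_named = build_design(spec_reml, df)
        ZZ = [Z @ Z.T for _, Z in Z_named]
        lam_m = np.array([fit_m.vc["animal_id"]]) / fit_m.sigma2
        lam_r = np.array([fit_r.vc["animal_id"]]) / fit_r.sigma2
        crit_at_ml, _ = _profiled_criterion(lam_m, y, X, ZZ, reml=True)
        crit_at_r, _ = _profiled_criterion(lam_r, y, X, ZZ, reml=True)
        assert crit_at_r <= crit_at_ml + 1e-9

    def test_duplicated_rows_keep_fixed_effects(self):
        df = _crossed_table(6, (60.0, 90.0), 0.8, 0.5, 0.2, 0.4, seed=9)
        spec = ModelSpec(response="y", fixed=("treatment",),
                         random=("animal_id",))
        fit0 = fit_lmem(spec, df)
        fit2 = fit_lmem(spec, pd.concat([df, df], ignore_index=True))
        assert np.allclose(fit0.beta, fit2.beta, atol=1e-4)


class TestSatterthwaite:
    def test_ols_limit_df(self):
        df = _one_way_table(8, 5, 2.0, 0.0, 1.0, seed=3)
        fit = fit_lmem(ModelSpec(response="y", random=("animal_id",)), df)
        dfv, _, _ = satterthwaite_df(fit, 0)
        assert dfv == pytest.approx(fit.n_obs - 1)

    def test_balanced_between_animal_contrast_df(self):
        # between-group contrast in a balanced design: df ~ 2g - 2
        g = 6  # animals per group
        rng = np.random.default_rng(13)
        rows = []
        for i in range(2 * g):
            grp = "noise" if i >= g else "control"
            u = rng.normal(0, 1.0)   # animal variance dominates
            for _ in range(5):
                rows.append({"animal_id": f"a{i:02d}", "treatment": grp,
                             "y": (grp == "noise") * 0.5 + u
                             + rng.normal(0, 0.1)})
        df = pd.DataFrame(rows)
        fit = fit_lmem(ModelSpec(response="y", fixed=("treatment",),
                                 random=("animal_id",)), df)
        dfv, _, _ = satterthwaite_df(fit, "treatment")
        assert dfv == pytest.approx(2 * g - 2, abs=0.5)

    def test_df_bounded_by_ols_df(self):
        for seed in range(30):
            df = _crossed_table(6, (60.0, 80.0, 100.0), 0.5,
                                sd_a=abs(np.sin(seed)) + 0.05, sd_s=0.2,
                                sd_e=0.3, seed=seed)
            fit = fit_lmem(ModelSpec(response="y", fixed=("treatment",),
                                     random=("animal_id", "spl_db")), df)
            for j in range(fit.p_fixed):
                dfv, _, p = satterthwaite_df(fit, j)
                assert 0 < dfv <= fit.n_obs - fit.p_fixed
                assert 0 <= p <= 1


class TestCohensD:
    def test_identical_groups_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert cohens_d(a, a) == 0.0

    def test_sign_convention_a_minus_b(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 100000)
        b = rng.normal(1.0, 1.0, 100000)
        assert cohens_d(a, b) == pytest.approx(-1.0, abs=0.02)

    def test_zero_pooled_sd_refused(self):
        with pytest.raises(ModelError):
            cohens_d([2.0, 2.0, 2.0], [2.0, 2.0])

    def test_sampling_distribution_at_true_effect(self):
        # truth d = 1.45, n = 12/group: estimate within 3 SE(d) in >= 95% of sims
        rng = np.random.default_rng(99)
        d_true, n = 1.45, 12
        se_d = np.sqrt((n + n) / (n * n) + d_true ** 2 / (2 * (2 * n - 2)))
        hits = 0
        n_sims = 500
        for _ in range(n_sims):
            a = rng.normal(d_true, 1.0, n)
            b = rng.normal(0.0, 1.0, n)
            if abs(cohens_d(a, b) - d_true) <= 3 * se_d:
                hits += 1
        assert hits / n_sims >= 0.95
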