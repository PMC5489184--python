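"""Model assembly, two-step estimation, scores and lattice selection."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

import smilespline as sp
from smilespline.design import DOMAINS
from smilespline.kernels import cubic_gram
from smilespline.model import (
    MixedSSANOVA,
    ModelSpec,
    enumerate_smile_models,
    estimate_random_intercept,
    information_criteria,
    select_model,
    _whiten,
    _group_indices,
)

from conftest import single_term_model, small_config


class TestLattice:
    def test_nine_hierarchical_specs(self):
        specs = enumerate_smile_models()
        assert len(specs) == 9
        # additive model last; exactly one spec carries the three-way
        assert specs[-1].stimulus_terms == ("angle", "extent", "dental")
        assert sum("angle:extent:dental" in s.interactions for s in specs) == 1
        assert specs[0].interactions[-1] == "angle:extent:dental"
        # every spec contains all three spatial mains
        for s in specs:
            assert set(("angle", "extent", "dental")) <= set(s.stimulus_terms)

    def test_hierarchy_enforced(self):
        with pytest.raises(ValueError):
            ModelSpec("effective", "symmetric",
                      ("angle:extent", "angle:extent:dental"))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec("sentiment")
        with pytest.raises(ValueError):
            ModelSpec("effective", "asymmetric", ("angle:extent",))


class TestREML:
    def test_balanced_oneway_matches_anova_closed_form(self):
        # method-of-moments oracle: theta2 = (MSB - MSW)/k, sigma2 = MSW
        rng = np.random.default_rng(5)
        m, k = 40, 6
        b = rng.normal(0, 0.12, m)
        y = (b[:, None] + rng.normal(0, 0.2, (m, k))).ravel()
        df = pd.DataFrame({
            "participant_id": np.repeat([f"P{i}" for i in range(m)], k),
            "smile_index": 1, "age": 40, "drinks": 0, "gender": "F",
            "effective": y,
        })
        ybar_i = y.reshape(m, k).mean(axis=1)
        msb = k * np.sum((ybar_i - y.mean()) ** 2) / (m - 1)
        msw = np.sum((y.reshape(m, k) - ybar_i[:, None]) ** 2) / (m * (k - 1))
        th, s2 = estimate_random_intercept(df, ModelSpec("effective"))
        assert th == pytest.approx((msb - msw) / k, abs=1e-6)
        assert s2 == pytest.approx(msw, abs=1e-6)

    def test_matches_mixedlm_reference(self):
        # independent route: statsmodels MixedLM REML on the same proxy design
        import statsmodels.formula.api as smf

        cfg = small_config(100, theta2=0.012, sigma2=0.04)
        truth = sp.default_truth(cfg)
        data = sp.generate_ratings(cfg, truth, seed=14)
        sym = data[data.stimulus_kind == "symmetric"]
        th, s2 = estimate_random_intercept(sym, ModelSpec("pleasant"))
        df = sym.rename(columns={"pleasant": "_y"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = smf.mixedlm(
                "_y ~ C(smile_index) + age + drinks + C(gender)",
                df, groups=df["participant_id"]).fit(reml=True)
        assert ref.converged
        assert th == pytest.approx(float(ref.cov_re.values[0, 0]), rel=1e-3,
                                   abs=1e-6)
        assert s2 == pytest.approx(float(ref.scale), rel=1e-3)

    def test_zero_between_variance(self):
        cfg = small_config(120, theta2=0.0, sigma2=0.04)
        truth = sp.default_truth(cfg)
        data = sp.generate_ratings(cfg, truth, seed=2)
        sym = data[data.stimulus_kind == "symmetric"]
        th, _ = estimate_random_intercept(sym, ModelSpec("genuine"))
        assert th <= 1e-3

    def test_degenerate_grouping_warns(self):
        df = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(30)],
            "smile_index": 1, "age": 40, "drinks": 0, "gender": "F",
            "effective": np.random.default_rng(0).normal(0.5, 0.2, 30),
        })
        with pytest.warns(UserWarning, match="unidentifiable"):
            th, s2 = estimate_random_intercept(df, ModelSpec("effective"))
        assert th == 0.0 and s2 > 0

    def test_recovers_study_scale_variances(self):
        """Single-seed spot check of the spec's recovery bands at full size
        (the 20-seed version runs in the acceptance suite)."""
        cfg = sp.StudyConfig(theta2=0.0124, sigma2=0.0413)
        truth = sp.default_truth(cfg)
        data = sp.generate_ratings(cfg, truth, seed=100)
        sym = data[data.stimulus_kind == "symmetric"]
        th, s2 = estimate_random_intercept(sym, ModelSpec("effective"))
        assert 0.009 <= th <= 0.016
        assert 0.037 <= s2 <= 0.046


class TestSolver:
    def test_gcv_matches_grid_search(self):
        m = single_term_model()
        grid = np.arange(-12.0, 12.0001, 0.01)
        vals = [m.gcv_score([g], 0.0) for g in grid]
        gstar = grid[int(np.argmin(vals))]
        fit = m.fit(theta2=0.0, sigma2=1.0)
        assert abs(np.log(fit.lambdas["age"]) - gstar) <= 0.011

    def test_gcv_bracket(self):
        # the optimizer's criterion value is no worse than a coarse grid's
        m = single_term_model(seed=7)
        fit = m.fit(theta2=0.0, sigma2=1.0)
        grid_best = min(m.gcv_score([g], 0.0) for g in np.arange(-12, 12.1, 0.5))
        assert fit.gcv <= grid_best + 1e-12

    def test_representer_equals_full_kernel_system(self):
        # independent linear-algebra route: the classical representer system
        # [[K + n*lam*I, T], [T', 0]] at every observation
        m = single_term_model()
        n = m.n
        lam = 1e-2
        x = DOMAINS["age"].rescale(m.data["age"].to_numpy(float))
        K = cubic_gram(x, x)
        T = np.column_stack([np.ones(n), x - 0.5])
        A = np.block([[K + n * lam * np.eye(n), T], [T.T, np.zeros((2, 2))]])
        sol = np.linalg.solve(A, np.concatenate([m.y, np.zeros(2)]))
        fitted_oracle = K @ sol[:n] + T @ sol[n:]
        fit = m.fit(theta2=0.0, sigma2=1.0, lambdas=np.array([lam]))
        assert np.abs(fit.fitted_fixed - fitted_oracle).max() < 1e-8

    def test_infinite_smoothing_is_gls_line(self):
        m = single_term_model()
        x = DOMAINS["age"].rescale(m.data["age"].to_numpy(float))
        X = np.column_stack([np.ones(m.n), x - 0.5])
        gamma = 0.3
        Bt, yt = _whiten(X, m.y, m.groups, gamma)
        beta = np.linalg.lstsq(Bt, yt, rcond=None)[0]
        fit = m.fit(theta2=gamma * 0.04, sigma2=0.04,
                    lambdas=np.array([1e15]))
        assert np.abs(fit.fitted_fixed - X @ beta).max() < 1e-6

    def test_noiseless_additive_interpolation(self):
        cfg = small_config(60, theta2=0.0, sigma2=1e-8)
        truth = sp.synthetic.additive_truth(cfg)
        data = sp.generate_ratings(cfg, truth, seed=4)
        sym = data[data.stimulus_kind == "symmetric"].reset_index(drop=True)
        spec = enumerate_smile_models("genuine")[-1]
        fit = MixedSSANOVA(sym, spec).fit(theta2=0.0, sigma2=1e-8)
        surf = truth.smile_surface.set_index("smile_index")["genuine"]
        mu = surf.loc[sym["smile_index"]].to_numpy() \
            + truth.age_effect(sym["age"].to_numpy())
        assert np.abs(fit.fitted_fixed - mu).max() < 1e-4

    def test_whitened_residuals_orthogonal_to_null_space(self, sym_fit):
        m = sym_fit.model
        gamma = sym_fit.theta2 / (sym_fit.sigma2 + 1e-300)
        Bt, yt = _whiten(m.design.matrix, m.y, m.groups, gamma)
        resid = yt - Bt @ sym_fit.params
        null_cols = [0] + [i for t in m.design._layout for i in t[1]]
        cols = Bt[:, null_cols]
        cosines = (cols.T @ resid) / (
            np.linalg.norm(cols, axis=0) * np.linalg.norm(resid))
        assert np.abs(cosines).max() < 1e-6

    def test_participant_relabelling_invariance(self):
        m1 = single_term_model(seed=9)
        df2 = m1.data.copy()
        df2["participant_id"] = df2["participant_id"].map(
            lambda s: f"Z{hash(s) % 1000}_{s}")
        m2 = MixedSSANOVA(df2, m1.spec, terms=("age",))
        lam = np.array([0.05])
        f1 = m1.fit(theta2=0.01, sigma2=0.05, lambdas=lam)
        f2 = m2.fit(theta2=0.01, sigma2=0.05, lambdas=lam)
        assert np.abs(f1.params - f2.params).max() < 1e-8


class TestScores:
    def test_df_penalties(self, sym_fit):
        # AIC/BIC are -2 loglik + penalty * (edf + 2); BIC penalty exceeds
        # AIC's whenever log n > 2
        df = sym_fit.edf + 2
        assert sym_fit.aic == pytest.approx(-2 * sym_fit.loglik + 2 * df)
        assert sym_fit.bic == pytest.approx(
            -2 * sym_fit.loglik + np.log(sym_fit.n) * df)
        assert sym_fit.bic > sym_fit.aic
        a_off, b_off = information_criteria(sym_fit, offset=900.0)
        assert a_off == pytest.approx(sym_fit.aic + 900.0)
        assert b_off == pytest.approx(sym_fit.bic + 900.0)

    def test_equal_loglik_prefers_fewer_df(self, sym_fit):
        bigger = dataclasses.replace(sym_fit)
        bigger.edf = sym_fit.edf + 3.0
        bigger.aic = -2 * bigger.loglik + 2 * (bigger.edf + 2)
        bigger.bic = -2 * bigger.loglik + np.log(bigger.n) * (bigger.edf + 2)
        assert bigger.aic > sym_fit.aic and bigger.bic > sym_fit.bic

    def test_select_single_and_tiebreak(self, sym_fit):
        assert select_model([sym_fit]) is sym_fit
        # exact AIC tie: parsimony wins
        smaller_spec = enumerate_smile_models("effective")[-1]
        twin = dataclasses.replace(sym_fit, spec=smaller_spec)
        winner = select_model([sym_fit, twin])
        assert winner.spec == smaller_spec
        with pytest.raises(ValueError):
            select_model([])


class TestResults:
    def test_fit_result_invariants(self, sym_fit):
        f = sym_fit
        assert f.theta2 >= 0 and f.sigma2 > 0
        assert 0 <= f.rho < 1
        assert 0 <= f.r2 <= f.r2_star <= 1
        assert 1 <= f.edf <= f.n
        assert len(f.blups) == f.model.data["participant_id"].nunique()

    def test_summary_mentions_key_quantities(self, sym_fit):
        s = sym_fit.summary()
        for token in ("edf", "sigma2", "theta2", "AIC", "R2",
                      "angle:extent:dental"):
            assert token in s
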