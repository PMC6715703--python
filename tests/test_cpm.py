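"""Cumulative probability model fitting, inference, and subset selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit
from scipy.stats import mannwhitneyu

from thermolimits import (
    best_subset_bic,
    fit_cpm,
    hierarchical_models,
    model_inference,
    null_cpm,
)
from thermolimits.cpm import ConvergenceError


def simulate_cpm(rng, n, beta, binary=False):
    p = len(beta)
    X = rng.standard_normal((n, p))
    lin = X @ beta
    if binary:
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(float)
    else:
        y = lin + rng.logistic(size=n)
    return y, X


class TestFitCPM:
    def test_binary_outcome_matches_logistic_regression(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        for _ in range(3):
            y, X = simulate_cpm(rng, 250, [0.8, -0.5], binary=True)
            fit = fit_cpm(y, X)
            oracle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
            assert fit.betas == pytest.approx(oracle.params[1:], abs=1e-6)
            assert fit.loglik == pytest.approx(oracle.llf, abs=1e-8)

    def test_intercept_only_reproduces_exceedance_logits(self, rng):
        y = rng.choice([1.0, 2.5, 2.5, 4.0, 7.0], size=60)
        fit = null_cpm(y)
        vals, counts = np.unique(y, return_counts=True)
        tail = np.cumsum(counts[::-1])[::-1]
        assert fit.intercepts == pytest.approx(
            logit(tail[1:] / y.size), abs=1e-12
        )
        assert np.all(np.diff(fit.intercepts) < 0)

    def test_monotone_outcome_transform_leaves_beta(self, rng):
        y, X = simulate_cpm(rng, 200, [1.0, -0.6])
        f0 = fit_cpm(y, X)
        for transform in (np.exp, lambda v: rankdata_like(v)):
            f1 = fit_cpm(transform(y), X)
            assert f1.betas == pytest.approx(f0.betas, abs=1e-6)

    def test_reversing_outcome_negates_beta(self, rng):
        y, X = simulate_cpm(rng, 150, [0.7])
        f0 = fit_cpm(y, X)
        f1 = fit_cpm(-y, X)
        assert f1.betas == pytest.approx(-f0.betas, abs=1e-6)

    def test_agreement_with_statsmodels_ordered_model(self, rng):
        om = pytest.importorskip("statsmodels.miscmodels.ordinal_model")
        y = rng.integers(0, 5, size=300).astype(float)
        X = rng.standard_normal((300, 2))
        y += (X[:, 0] > 0.5)  # induce an effect
        fit = fit_cpm(y, X)
        oracle = om.OrderedModel(y, X, distr="logit").fit(
            method="bfgs", disp=0
        )
        # OrderedModel parameterizes P(Y <= j) = F(theta_j - x beta)
        assert fit.betas == pytest.approx(oracle.params[:2], abs=1e-4)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-5)

    def test_wald_ci_covers_true_beta(self, rng):
        hits = 0
        for _ in range(200):
            y, X = simulate_cpm(rng, 150, [1.0])
            fit = fit_cpm(y, X)
            se = fit.se_beta()[0]
            hits += abs(fit.betas[0] - 1.0) < 1.96 * se
        assert hits / 200 == pytest.approx(0.95, abs=0.045)

    def test_wmw_agreement_binary_predictor(self, rng):
        # score/LR test of a single binary predictor tracks Wilcoxon-MW
        group = np.repeat([0.0, 1.0], 50)
        y = rng.lognormal(size=100) + 0.4 * group
        fit = fit_cpm(y, group[:, None])
        stats = model_inference(fit)
        wmw_p = mannwhitneyu(y[group == 1], y[group == 0]).pvalue
        assert np.sign(np.log(stats.p / wmw_p)) in (-1, 0, 1)  # both defined
        assert abs(np.log10(stats.p) - np.log10(wmw_p)) < 0.5

    def test_separation_raises(self):
        y = np.arange(20.0)
        x = (y > 9.5).astype(float)
        with pytest.raises(ConvergenceError):
            fit_cpm(y, x[:, None])

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_cpm(np.ones(10), np.random.default_rng(0).normal(size=(10, 1)))
        with pytest.raises(ValueError):
            x = np.random.default_rng(0).normal(size=10)
            fit_cpm(x, np.column_stack([x, x]))  # rank deficient


def rankdata_like(v):
    from scipy.stats import rankdata

    return rankdata(v)


class TestModelInference:
    def test_null_against_itself(self, rng):
        y, X = simulate_cpm(rng, 120, [0.8])
        fit = fit_cpm(y, X)
        self_stats = model_inference(fit, fit)
        assert self_stats.lr_chi2 == pytest.approx(0.0, abs=1e-9)
        assert model_inference(null_cpm(y)).nagelkerke_r2 == pytest.approx(0.0)

    def test_wald_tracks_lr_for_strong_predictor(self, rng):
        y, X = simulate_cpm(rng, 800, [0.6])
        fit = fit_cpm(y, X)
        stats = model_inference(fit)
        wald = stats.coef_table["wald_chi2"].iloc[0]
        assert wald == pytest.approx(stats.lr_chi2, rel=0.10)

    def test_aor_ci_duality_with_wald_p(self, rng):
        for _ in range(10):
            y, X = simulate_cpm(rng, 80, [0.3, 0.0])
            stats = model_inference(fit_cpm(y, X))
            for _, row in stats.coef_table.iterrows():
                excludes_one = row["aOR_low"] > 1 or row["aOR_high"] < 1
                assert excludes_one == (row["p"] < 0.05)

    def test_lr_additive_across_nested_chain(self, rng):
        y, X = simulate_cpm(rng, 200, [0.8, -0.4])
        f1 = fit_cpm(y, X[:, :1])
        f2 = fit_cpm(y, X)
        lr_1 = model_inference(f1).lr_chi2
        lr_21 = model_inference(f2, f1).lr_chi2
        lr_2 = model_inference(f2).lr_chi2
        assert lr_1 + lr_21 == pytest.approx(lr_2, abs=1e-6)
        assert lr_21 >= 0


class TestBestSubset:
    def test_weights_sum_to_one(self, rng):
        y, X = simulate_cpm(rng, 120, [0.5, 0.0, 0.0])
        base = pd.DataFrame({"b": X[:, 0]})
        cand = pd.DataFrame({"c1": X[:, 1], "c2": X[:, 2]})
        sel = best_subset_bic(y, base, cand)
        assert sel.table["bic_weight"].sum() == pytest.approx(1.0)
        assert sel.table.loc[sel.best_id, "evidence_ratio"] == 1.0
        assert len(sel.table) == 4  # 2^2 subsets

    def test_selects_true_strong_effect(self, rng):
        n = 1000
        X = rng.standard_normal((n, 3))
        y = 1.5 * X[:, 1] + rng.logistic(size=n)
        base = pd.DataFrame({"b": X[:, 0]})
        cand = pd.DataFrame({"signal": X[:, 1], "noise": X[:, 2]})
        sel = best_subset_bic(y, base, cand)
        assert sel.inclusion_probs["signal"] > 0.95
        assert "signal" in sel.table.loc[sel.best_id, "subset"]


class TestHierarchical:
    def _toy_data(self, rng, n=150, gmd_driver=False):
        df = pd.DataFrame(
            {
                "dx": rng.integers(0, 2, n).astype(float),
                "age": rng.uniform(7, 50, n),
                "male": rng.integers(0, 2, n).astype(float),
                "order": rng.integers(0, 2, n).astype(float),
                "piq": rng.normal(105, 14, n),
                "viq": rng.normal(105, 13, n),
            }
        )
        if gmd_driver:
            df["gmd"] = 0.3 + 0.25 * df["dx"] + 0.1 * rng.random(n)
            y = 2.0 * df["gmd"] + 0.3 * rng.logistic(size=n)
        else:
            df["gmd"] = rng.uniform(0.2, 1.0, n)
            y = -0.03 * df["piq"] + rng.logistic(size=n)
        return y.to_numpy() if hasattr(y, "to_numpy") else y, df

    def test_constant_gmd_adds_nothing(self, rng):
        y, df = self._toy_data(rng)
        df["gmd"] = 0.5
        res = hierarchical_models(
            y, df, ["dx", "age", "male", "order"], ["piq", "viq"], "gmd"
        )
        assert abs(res.stats["delta_r2_step3"]) < 1e-6

    def test_gmd_driven_outcome_attenuates_diagnosis(self, rng):
        y, df = self._toy_data(rng, n=400, gmd_driver=True)
        res = hierarchical_models(
            y, df, ["dx", "age", "male", "order"], ["piq", "viq"], "gmd"
        )
        beta2 = dict(zip(res.step2.beta_names, res.step2.betas))["dx"]
        beta3 = dict(zip(res.step3.beta_names, res.step3.betas))["dx"]
        assert abs(beta3) < abs(beta2)
        assert res.stats["delta_r2_step3"] > res.stats["delta_r2_step2"]

    def test_deterministic(self, rng):
        y, df = self._toy_data(rng)
        args = (y, df, ["dx", "age", "male", "order"], ["piq", "viq"], "gmd")
        r1 = hierarchical_models(*args)
        r2 = hierarchical_models(*args)
        assert np.array_equal(r1.step3.betas, r2.step3.betas)

    def test_missing_column_raises(self, rng):
        y, df = self._toy_data(rng)
        with pytest.raises(KeyError):
            hierarchical_models(y, df, ["dx"], ["nope"], "gmd")
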