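"""Power fit, SMR/net cost, and the random-intercept mixed model.

The mixed-model implementation (REML via statsmodels, with our own
Satterthwaite df, R² decomposition and ML likelihood-ratio test) is
cross-checked against lme4 + lmerTest through Rscript on one frozen
dataset — a fully independent route to the same estimates.
"""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from videba.calibration import (
    LMMFit,
    fit_lmm,
    fit_power,
    lrt_random_effect,
    net_cost,
    predict_mo2,
    smr,
)
from videba.errors import FitError


def make_table(rng, n_ind=5, n_obs=12, beta0=150.0, beta1=700.0, s_id=30.0, s_eps=20.0):
    rows = []
    for i in range(n_ind):
        u = rng.normal(0, s_id)
        for _ in range(n_obs):
            x = rng.uniform(0.02, 0.6)
            rows.append(
                {
                    "individual": f"F{i}",
                    "mean_vedba": x,
                    "mo2": beta0 + u + beta1 * x + rng.normal(0, s_eps),
                }
            )
    return pd.DataFrame(rows)


class TestPowerFit:
    U = np.repeat([5.0, 10, 15, 20, 25, 30], 2)

    def test_exact_recovery_of_published_curve_parameters(self):
        y = 152.15 + 0.47 * self.U**1.76
        fit = fit_power(self.U, y)
        assert fit.a == pytest.approx(152.15, rel=1e-6)
        assert fit.b == pytest.approx(0.47, rel=1e-6)
        assert fit.c == pytest.approx(1.76, rel=1e-6)

    def test_nests_the_linear_model(self):
        y = 10.0 + 2.0 * self.U
        fit = fit_power(self.U, y)
        lin_sse = 0.0  # a perfect line
        assert fit.sse <= lin_sse + 1e-8

    def test_sse_never_worse_than_best_fixed_exponent_start(self, rng):
        y = 152.15 + 0.47 * self.U**1.76 + rng.normal(0, 15, len(self.U))
        fit = fit_power(self.U, y)
        for c0 in (0.5, 1.0, 1.5, 2.0, 3.0):
            X = np.column_stack([np.ones_like(self.U), self.U**c0])
            ab, *_ = np.linalg.lstsq(X, y, rcond=None)
            ab[1] = max(ab[1], 0.0)
            assert fit.sse <= np.sum((y - X @ ab) ** 2) + 1e-8

    def test_too_few_speeds_rejected(self):
        with pytest.raises(FitError):
            fit_power(np.array([5.0, 5, 10, 10]), np.array([1.0, 2, 3, 4]))

    def test_smr_is_the_intercept_and_net_cost_subtracts_it(self):
        fit = fit_power(self.U, 150 + 0.5 * self.U**1.8)
        assert smr(fit) == pytest.approx(150.0, rel=1e-6)
        table = pd.DataFrame({"individual": ["A", "A"], "mo2": [200.0, 150.0]})
        out = net_cost(table, {"A": 150.0})
        assert list(out["net_cost"]) == [50.0, 0.0]

    def test_net_cost_requires_every_individual(self):
        table = pd.DataFrame({"individual": ["A", "B"], "mo2": [200.0, 150.0]})
        with pytest.raises(FitError):
            net_cost(table, {"A": 150.0})


class TestLMM:
    def test_recovers_generator_slope(self, rng):
        table = make_table(rng)
        fit = fit_lmm(table)
        assert abs(fit.beta1 - 700.0) <= 2.5 * fit.se_beta1
        assert fit.r2_conditional >= fit.r2_marginal

    def test_profiled_at_zero_variance_reproduces_ols(self, rng):
        from statsmodels.api import OLS, add_constant

        from videba.calibration import _group_blocks, _reml_quantities

        table = make_table(rng, s_id=0.0)
        x = table["mean_vedba"].to_numpy()
        y = table["mo2"].to_numpy()
        blocks = _group_blocks(x, y, table["individual"].to_numpy())
        _, beta, _ = _reml_quantities(np.array([0.0, 25.0]), blocks)
        ols = OLS(y, add_constant(x)).fit()
        assert beta[0] == pytest.approx(ols.params[0], rel=1e-8)
        assert beta[1] == pytest.approx(ols.params[1], rel=1e-8)

    def test_zero_variance_generator_keeps_r2s_close(self, rng):
        fit = fit_lmm(make_table(rng, s_id=0.0))
        # σ̂²_id is near zero, so the conditional R² gains almost nothing
        assert fit.r2_conditional - fit.r2_marginal < 0.05

    def test_r2_decomposition_sums(self, rng):
        table = make_table(rng, s_id=50.0)
        fit = fit_lmm(table)
        var_fixed = np.var(fit.beta1 * table["mean_vedba"], ddof=1)
        total = var_fixed + fit.sigma2_id + fit.sigma2_eps
        assert 0.0 <= fit.r2_marginal <= fit.r2_conditional <= 1.0
        assert fit.r2_marginal == pytest.approx(var_fixed / total, rel=1e-9)
        assert fit.r2_conditional - fit.r2_marginal == pytest.approx(
            fit.sigma2_id / total, rel=1e-9
        )

    def test_kenward_roger_is_explicitly_unavailable(self, rng):
        with pytest.raises(NotImplementedError):
            fit_lmm(make_table(rng), ddf_method="kenward-roger")

    def test_agrees_with_lme4_and_lmertest(self, tmp_path, rng):
        table = make_table(rng)
        csv = tmp_path / "table.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            """
            suppressMessages({library(lme4); library(lmerTest); library(jsonlite)})
            d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
            m <- lmerTest::lmer(mo2 ~ mean_vedba + (1|individual), data=d, REML=TRUE)
            s <- summary(m, ddf="Satterthwaite")$coefficients
            vc <- as.data.frame(VarCorr(m))
            m_ml <- lme4::lmer(mo2 ~ mean_vedba + (1|individual), data=d, REML=FALSE)
            m0 <- lm(mo2 ~ mean_vedba, data=d)
            cat(toJSON(list(beta=unname(s[,1]), se=unname(s[,2]), ddf=unname(s[,3]),
                            sig2=unname(vc$vcov), chi2=2*(logLik(m_ml)[1]-logLik(m0)[1])),
                       digits=12))
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(csv)], capture_output=True, text=True, check=True
        )
        ref = json.loads(out.stdout)
        fit = fit_lmm(table)
        chi2, _ = lrt_random_effect(table)
        assert fit.beta0 == pytest.approx(ref["beta"][0], rel=1e-5)
        assert fit.beta1 == pytest.approx(ref["beta"][1], rel=1e-5)
        assert fit.se_beta1 == pytest.approx(ref["se"][1], rel=1e-4)
        assert fit.sigma2_id == pytest.approx(ref["sig2"][0], rel=1e-3)
        assert fit.sigma2_eps == pytest.approx(ref["sig2"][1], rel=1e-3)
        assert fit.ddf == pytest.approx(ref["ddf"][1], rel=0.02)
        assert chi2 == pytest.approx(ref["chi2"][0], abs=1e-3)

    def test_lrt_detects_strong_clustering(self, rng):
        table = make_table(rng, s_id=100.0, s_eps=20.0)
        chi2, p = lrt_random_effect(table)
        assert p < 0.01

    def test_lrt_nesting_never_negative(self, rng):
        for _ in range(10):
            chi2, _ = lrt_random_effect(make_table(rng, s_id=0.0))
            assert chi2 >= 0.0


class TestPredict:
    def test_zero_vedba_returns_intercepts(self, rng):
        table = make_table(rng)
        fit = fit_lmm(table)
        pop = predict_mo2(fit, 0.0)
        ind = predict_mo2(fit, 0.0, individual="F0")
        assert pop["predicted"].iloc[0] == pytest.approx(fit.beta0)
        assert ind["predicted"].iloc[0] == pytest.approx(fit.beta0 + fit.ranef["F0"])

    def test_fitted_value_at_observed_design_point(self, rng):
        table = make_table(rng)
        fit = fit_lmm(table)
        row = table.iloc[0]
        pred = predict_mo2(fit, row["mean_vedba"], individual=row["individual"])
        fitted = fit.beta0 + fit.ranef[row["individual"]] + fit.beta1 * row["mean_vedba"]
        assert pred["predicted"].iloc[0] == pytest.approx(fitted)

    def test_unknown_individual_falls_back_with_warning(self, rng):
        fit = fit_lmm(make_table(rng))
        with pytest.warns(UserWarning, match="population"):
            pred = predict_mo2(fit, 0.1, individual="nobody")
        assert (pred["level"] == "population").all()

    def test_prediction_interval_wider_than_confidence(self, rng):
        fit = fit_lmm(make_table(rng))
        ci = predict_mo2(fit, 0.3, individual="F0", interval="confidence")
        pi = predict_mo2(fit, 0.3, individual="F0", interval="prediction")
        assert pi["hi"].iloc[0] - pi["lo"].iloc[0] > ci["hi"].iloc[0] - ci["lo"].iloc[0]

    def test_roundtrip_through_json(self, rng, tmp_path):
        fit = fit_lmm(make_table(rng))
        d = json.loads(json.dumps(fit.to_dict()))
        back = LMMFit.from_dict(d)
        assert back.beta1 == fit.beta1 and back.sigma2_id == fit.sigma2_id
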