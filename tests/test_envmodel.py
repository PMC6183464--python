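"""Hierarchical logistic models, AICc comparison and averaging."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from hatchtrace.envmodel import (CandidateModel, compare_and_average,
                                 fit_candidate_models, fit_logistic_mixed,
                                 prepare_covariates, screen_model_covariates)


def _simulate(seed, n_sites=30, n_fish=50, b_temp=0.5, b_ph=-0.5,
              site_sd=0.5, intercept=-1.0, extra_cols=()):
    rng = np.random.default_rng(seed)
    cols = ["temperature", "pH", *extra_cols]
    cov = pd.DataFrame(
        rng.normal(size=(n_sites, len(cols))), columns=cols,
        index=pd.Index([f"s{j}" for j in range(n_sites)], name="site"),
    )
    cov = (cov - cov.mean()) / cov.std(ddof=1)
    u = rng.normal(0, site_sd, n_sites)
    rows = []
    for j, s in enumerate(cov.index):
        eta = (intercept + b_temp * cov.loc[s, "temperature"]
               + b_ph * cov.loc[s, "pH"] + u[j])
        y = rng.random(n_fish) < 1 / (1 + np.exp(-eta))
        rows += [{"site": s, "introgressed": int(v)} for v in y]
    return pd.DataFrame(rows), cov


class TestPrepareCovariates:
    def test_zscore_uses_sample_sd(self):
        raw = pd.DataFrame({"site": ["a", "b", "c"], "x": [1.0, 2.0, 3.0]})
        z, _ = prepare_covariates(raw)
        assert list(z["x"]) == pytest.approx([-1.0, 0.0, 1.0], abs=1e-12)

    def test_zscore_invariants(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(rng.normal(2, 7, size=(20, 3)), columns=list("abc"))
        z, _ = prepare_covariates(raw)
        assert np.allclose(z.mean(), 0, atol=1e-9)
        assert np.allclose(z.std(ddof=1), 1, atol=1e-9)

    def test_duplicated_column_flagged_and_dropped(self):
        raw = pd.DataFrame({"x": [1.0, 2.0, 5.0, 3.0], "y": [1.0, 2.0, 5.0, 3.0],
                            "z": [4.0, 1.0, 2.0, 7.0]})
        _, flagged = prepare_covariates(raw)
        assert ("x", "y") in flagged
        kept, dropped = screen_model_covariates(["x", "y", "z"], flagged)
        assert kept == ["x", "z"] and dropped == ["y"]

    def test_independent_columns_unflagged(self):
        rng = np.random.default_rng(1)
        raw = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        _, flagged = prepare_covariates(raw)
        assert flagged == []

    def test_constant_column_rejected(self):
        raw = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            prepare_covariates(raw)


class TestMixedFit:
    def test_sign_recovery(self):
        data, cov = _simulate(2)
        model = fit_candidate_models(
            data, cov.reset_index(), model_sets={"m": ["temperature", "pH"]}
        )[0]
        assert model.beta["temperature"] > 0
        assert model.beta["pH"] < 0
        assert model.converged

    def test_zero_variance_boundary_matches_plain_logistic(self):
        sm = pytest.importorskip("statsmodels.api")
        data, cov = _simulate(3, site_sd=0.0, b_ph=0.0, n_sites=40,
                              n_fish=150)
        model = fit_candidate_models(
            data, cov.reset_index(), model_sets={"m": ["temperature"]}
        )[0]
        z, _ = prepare_covariates(cov.reset_index())
        X = sm.add_constant(
            z.loc[data["site"], ["temperature"]].reset_index(drop=True)
        )
        plain = sm.Logit(data["introgressed"], X).fit(disp=0)
        assert model.sigma_site < 0.1
        # with the variance component near its boundary the mixed fit
        # collapses onto the plain logistic fit
        assert model.beta["intercept"] == pytest.approx(
            plain.params["const"], abs=5e-3
        )
        assert model.beta["temperature"] == pytest.approx(
            plain.params["temperature"], abs=5e-3
        )

    def test_matches_lme4_glmer_oracle(self, tmp_path):
        data, cov = _simulate(4, n_sites=15, n_fish=30)
        model = fit_candidate_models(
            data, cov.reset_index(), model_sets={"m": ["temperature", "pH"]}
        )[0]
        z, _ = prepare_covariates(cov.reset_index())
        merged = data.join(z.loc[data["site"]].reset_index(drop=True))
        csv = tmp_path / "d.csv"
        merged.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- glmer(introgressed ~ temperature + pH + (1|site), data=d,\n"
            "           family=binomial, nAGQ=9)\n"
            "cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep='\\n')\n"
        )
        try:
            out = subprocess.run(
                ["Rscript", str(script)], capture_output=True, text=True,
                timeout=240, check=True,
            )
        except (FileNotFoundError, subprocess.SubprocessError) as exc:
            pytest.skip(f"lme4 oracle unavailable: {exc}")
        vals = [float(v) for v in out.stdout.split()]
        b0, bt, bp, sigma, ll = vals
        assert model.beta["intercept"] == pytest.approx(b0, abs=0.02)
        assert model.beta["temperature"] == pytest.approx(bt, abs=0.02)
        assert model.beta["pH"] == pytest.approx(bp, abs=0.02)
        assert model.sigma_site == pytest.approx(sigma, abs=0.05)
        assert model.log_likelihood == pytest.approx(ll, abs=0.1)

    def test_aicc_undefined_when_n_too_small(self):
        data, cov = _simulate(5, n_sites=3, n_fish=1)
        with pytest.raises(ValueError, match="AICc undefined"):
            fit_candidate_models(
                data, cov.reset_index(), model_sets={"m": ["temperature"]}
            )

    def test_separation_falls_back_to_penalized(self):
        # one covariate perfectly separates the responses
        cov = pd.DataFrame({
            "site": [f"s{j}" for j in range(10)],
            "temperature": np.linspace(-2, 2, 10),
        })
        rows = []
        for j in range(10):
            for _ in range(12):
                rows.append({"site": f"s{j}", "introgressed": int(j >= 5)})
        model = fit_candidate_models(
            pd.DataFrame(rows), cov, model_sets={"m": ["temperature"]}
        )[0]
        assert model.penalized
        assert np.isfinite(model.aicc)


def _mock_model(name, ll, k, n, coefs):
    aic = -2 * ll + 2 * k
    aicc = aic + 2 * k * (k + 1) / (n - k - 1)
    frame = pd.DataFrame({
        "estimate": pd.Series(coefs),
        "se": pd.Series({c: 0.1 for c in coefs}),
    })
    frame["ci_low"] = frame["estimate"] - 1.96 * frame["se"]
    frame["ci_high"] = frame["estimate"] + 1.96 * frame["se"]
    return CandidateModel(
        name=name, covariates=[c for c in coefs if c != "intercept"],
        dropped=[], coefficients=frame, sigma_site=0.3, log_likelihood=ll,
        k=k, n=n, aic=aic, aicc=aicc, marginal_r2=0.02,
    )


class TestCompareAndAverage:
    def test_equal_aicc_gives_equal_weights(self):
        models = [
            _mock_model("a", -100.0, 3, 500, {"intercept": -1.0, "x": 0.2}),
            _mock_model("b", -100.0, 3, 500, {"intercept": -1.0, "y": 0.1}),
        ]
        mc = compare_and_average(models)
        assert mc.table["weight"].to_numpy() == pytest.approx([0.5, 0.5])

    def test_weight_ratio_is_exact_exponential(self):
        models = [
            _mock_model("a", -100.0, 3, 500, {"intercept": -1.0}),
            _mock_model("b", -100.175, 3, 500, {"intercept": -1.0}),
            _mock_model("c", -110.0, 3, 500, {"intercept": -1.0}),
        ]
        mc = compare_and_average(models)
        w = mc.table["weight"]
        assert w.loc["a"] / w.loc["b"] == pytest.approx(np.exp(0.175), rel=1e-9)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert mc.table["dAICc"].min() == 0.0

    def test_full_averaging_zero_substitution(self):
        models = [
            _mock_model("a", -100.0, 3, 500, {"intercept": -1.0, "x": 0.4}),
            _mock_model("b", -100.0, 3, 500, {"intercept": -1.0}),
        ]
        mc = compare_and_average(models, average_top=2)
        # x enters model b as 0 with half the weight
        assert mc.consensus.loc["x", "estimate"] == pytest.approx(0.2)
        # unconditional SE includes the between-model spread
        assert mc.consensus.loc["x", "unconditional_se"] == pytest.approx(
            0.5 * np.sqrt(0.1**2 + 0.2**2) + 0.5 * np.sqrt(0.0 + 0.2**2),
            rel=1e-9,
        )

    def test_delta_cutoff_selects_averaged_set(self):
        models = [
            _mock_model("a", -100.0, 3, 500, {"intercept": -1.0}),
            _mock_model("b", -100.1, 3, 500, {"intercept": -1.1}),
            _mock_model("c", -120.0, 3, 500, {"intercept": -2.0}),
        ]
        mc = compare_and_average(models, delta_cutoff=2.0)
        assert set(mc.averaged_models) == {"a", "b"}

    def test_single_model_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            compare_and_average(
                [_mock_model("a", -1.0, 3, 100, {"intercept": 0.0})]
            )
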