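import shutil
import subprocess
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from countershading import (
    GLMMSpec,
    MixedGLM,
    default_params,
    fit_glmm,
    lrt,
    make_design,
    read_trials_csv,
    search_efficiency,
    simulate_trials,
    tukey_pairwise,
)

LUT = {0.0: 0.0, 15.0: 0.15, 30.0: 0.3, 45.0: 0.45, 90.0: 1.0}


@pytest.fixture(scope="module")
def trials():
    """One experiment at the study's size: 10 participants x 200 trials."""
    return simulate_trials(make_design(3), 10, LUT, seed=42)


@pytest.fixture(scope="module")
def acc_fit(trials):
    return MixedGLM.from_trials(trials).fit()


@pytest.fixture(scope="module")
def acc_null(trials):
    return MixedGLM.from_trials(trials, intercept_only=True).fit()


class TestFitGLMM:
    def test_binomial_fit_converges(self, acc_fit):
        assert acc_fit.converged
        assert np.isfinite(acc_fit.llf)
        assert acc_fit.sigma_u >= 0

    def test_glm_oracle_when_variance_vanishes(self, trials):
        """A single participant forces sigma_u to the boundary; fixed effects
        then match an ordinary GLM."""
        t1 = trials[trials["participant"] == 0]
        model = MixedGLM.from_trials(t1)
        res = model.fit()
        glm = sm.GLM(model.endog, model.exog, family=sm.families.Binomial()).fit()
        assert res.sigma_u < 1e-3
        assert np.abs(res.fe_params - glm.params).max() < 1e-4

    def test_gamma_glm_oracle_when_variance_vanishes(self, trials):
        t1 = trials[trials["participant"] == 3]
        model = MixedGLM.from_trials(t1, response="rt")
        res = model.fit()
        glm = sm.GLM(
            model.endog, model.exog,
            family=sm.families.Gamma(link=sm.families.links.Log()),
        ).fit()
        assert res.sigma_u < 1e-3
        assert np.abs(res.fe_params - glm.params).max() < 1e-4

    def test_agreement_with_lme4(self, trials):
        """Independent oracle: lme4's glmer at the same number of adaptive
        quadrature nodes agrees on log-likelihood and estimates."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        sub = trials[trials["participant"] < 6].iloc[: 6 * 100]
        res = MixedGLM.from_trials(sub).fit()
        import tempfile, os

        with tempfile.TemporaryDirectory() as td:
            csv = os.path.join(td, "t.csv")
            sub.to_csv(csv, index=False)
            script = (
                f'd <- read.csv("{csv}"); d$level <- factor(d$level); '
                "suppressMessages(library(lme4)); "
                "m <- glmer(correct ~ level + (1|participant), data=d, "
                "family=binomial, nAGQ=25); "
                'cat(logLik(m), fixef(m), sqrt(unlist(VarCorr(m))), sep=",")'
            )
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
            )
            if out.returncode != 0:
                pytest.skip(f"lme4 unavailable: {out.stderr[-200:]}")
            vals = np.array([float(x) for x in out.stdout.strip().split(",")])
        assert abs(vals[0] - res.llf) < 1e-3
        assert np.abs(vals[1:6] - res.fe_params).max() < 1e-3
        assert abs(vals[6] - res.sigma_u) < 1e-3

    def test_laplace_close_to_agq(self, trials):
        m25 = MixedGLM.from_trials(trials, n_agq=25)
        m1 = MixedGLM.from_trials(trials, n_agq=1)
        m50 = MixedGLM.from_trials(trials, n_agq=50)
        params = m25.fit().params
        assert abs(m25.loglike(params) - m50.loglike(params)) < 1e-4
        assert abs(m25.loglike(params) - m1.loglike(params)) < 0.1

    def test_separation_warning_and_penalized_fallback(self):
        rng = np.random.default_rng(0)
        n = 400
        level = np.repeat([0.0, 15.0, 30.0, 45.0, 90.0], n // 5)
        correct = np.where(level == 90.0, 1, rng.integers(0, 2, n))
        t = pd.DataFrame(
            {
                "participant": np.tile(np.arange(8), n // 8),
                "level": level,
                "correct": correct,
                "n_distractors": 20,
                "rt": 1.0,
            }
        )
        with pytest.warns(UserWarning, match="separation"):
            res = MixedGLM.from_trials(t).fit()
        assert np.abs(res.fe_params).max() < 15  # penalty keeps estimates finite

    def test_spec_wrapper_and_terms(self, trials):
        res = fit_glmm(
            trials, GLMMSpec(response="rt", include_set_size=True, rt_filter="all")
        )
        assert "log_set_size" in res.model.exog_names
        assert res.gamma_shape > 0
        assert "gamma" in res.summary()

    def test_gamma_inverse_link_available(self, trials):
        sub = trials[trials["participant"] < 4]
        res = MixedGLM.from_trials(sub, response="rt", link="inverse").fit()
        assert np.isfinite(res.llf)
        assert res.model.link == "inverse"


class TestLRT:
    def test_same_model_is_not_a_valid_null(self, acc_fit):
        with pytest.raises(ValueError):
            lrt(acc_fit, acc_fit)

    def test_five_level_factor_df_is_four(self, acc_fit, acc_null):
        r = acc_fit.lrt(acc_null)
        assert r.df == 4
        assert r.chi2 >= 0

    def test_equal_likelihood_gives_p_one(self, acc_fit, acc_null):
        clone = type(acc_null)(
            model=acc_null.model, params=acc_null.params,
            llf=acc_fit.llf, converged=True,
        )
        r = lrt(acc_fit, clone)
        assert r.chi2 == 0.0 and r.pvalue == 1.0

    def test_non_nested_rejected(self, trials, acc_fit):
        rt_null = MixedGLM.from_trials(trials, response="rt", intercept_only=True).fit()
        with pytest.raises(ValueError):
            lrt(acc_fit, rt_null)

    def test_full_likelihood_dominates_null(self, acc_fit, acc_null):
        assert acc_fit.llf >= acc_null.llf - 1e-6


class TestTukey:
    def test_table_shape_and_consistency(self, acc_fit):
        tab = acc_fit.pairwise_tukey()
        assert len(tab) == 10  # C(5, 2)
        assert (tab["p_tukey"] >= tab["p_raw"] - 1e-12).all()
        # estimates are differences of level means on the link scale
        info = acc_fit.model.factor_info
        means = {lev: (acc_fit.fe_params[0] + (acc_fit.fe_params[c] if c else 0.0))
                 for lev, c in [(info["levels"][0], 0)]
                 + list(info["columns"].items())}
        for _, row in tab.iterrows():
            assert row["estimate"] == pytest.approx(
                means[row["level_a"]] - means[row["level_b"]], rel=1e-9
            )

    def test_adjusted_p_monotone_in_raw_p(self, acc_fit):
        tab = acc_fit.pairwise_tukey().sort_values("p_raw")
        assert (np.diff(tab["p_tukey"]) >= -2e-4).all()

    def test_reproducible_for_fixed_seed(self, acc_fit):
        a = acc_fit.pairwise_tukey(seed=7)
        b = acc_fit.pairwise_tukey(seed=7)
        assert np.array_equal(a["p_tukey"], b["p_tukey"])

    def test_two_level_factor_adjustment_is_identity(self):
        d = make_design(4, levels=(0.0, 90.0), n_trials=200)
        t = simulate_trials(d, 8, LUT, seed=1)
        fit = MixedGLM.from_trials(t).fit()
        tab = fit.pairwise_tukey()
        assert len(tab) == 1
        assert tab["p_tukey"].iloc[0] == pytest.approx(tab["p_raw"].iloc[0])

    def test_family_wise_error_controlled_under_null(self):
        """With identical level means, the probability that any of the 10
        adjusted contrasts is declared significant stays at the nominal
        alpha (single-step adjustment controls FWER)."""
        null = replace(default_params(), beta1=0.0)
        design = make_design(8, n_trials=100)
        hits = 0
        n_rep = 200
        for r in range(n_rep):
            t = simulate_trials(design, 6, LUT, null, seed=60_000 + r)
            fit = MixedGLM.from_trials(t).fit()
            tab = fit.pairwise_tukey()
            hits += (tab["p_tukey"] < 0.05).any()
        rate = hits / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert rate <= 0.05 + 2 * se


class TestSearchEfficiency:
    def test_no_set_size_effect_gives_zero_slopes(self):
        p = replace(default_params("none"), alpha2=0.0)
        t = simulate_trials(make_design(5, n_trials=2000), 4, LUT, p, seed=2)
        eff = search_efficiency(t)
        assert (eff["slope"].abs() < 2 * eff["se"] + 1e-12).all()

    def test_defaults_show_efficiency_gain_at_high_departure(self):
        t = simulate_trials(make_design(6, n_trials=2000), 8, LUT, seed=3)
        eff = search_efficiency(t).set_index("level")
        assert eff.loc[0.0, "slope"] > eff.loc[90.0, "slope"]

    def test_constant_rt_gives_exactly_zero(self):
        t = pd.DataFrame(
            {
                "participant": 0,
                "level": np.repeat([0.0, 90.0], 40),
                "n_distractors": np.tile([20, 40], 40),
                "correct": 1,
                "rt": 2.5,
            }
        )
        eff = search_efficiency(t)
        assert (eff["slope"] == 0).all() and (eff["se"] == 0).all()

    def test_missing_set_size_warns_and_omits(self):
        t = pd.DataFrame(
            {
                "participant": 0,
                "level": np.repeat([0.0, 90.0], 20),
                "n_distractors": np.r_[np.tile([20, 40], 10), np.full(20, 20)],
                "correct": 1,
                "rt": 1.0,
            }
        )
        with pytest.warns(UserWarning, match="one set size"):
            eff = search_efficiency(t)
        assert eff["level"].tolist() == [0.0]


def test_read_trials_csv_column_mapping(tmp_path, trials):
    path = tmp_path / "ext.csv"
    trials.rename(
        columns={"participant": "subj", "correct": "hit", "rt": "RT_s"}
    ).to_csv(path, index=False)
    back = read_trials_csv(
        path, column_map={"subj": "participant", "hit": "correct", "RT_s": "rt"}
    )
    assert set(back.columns) >= {"participant", "level", "correct", "rt"}
    with pytest.raises(ValueError, match="required columns"):
        read_trials_csv(path)
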