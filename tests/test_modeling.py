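"""Mixed-model fitting, Satterthwaite df, model comparison, Welch tests."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aasub.modeling import (
    ModelSpec,
    compare_models,
    fit_by_steps,
    fit_lmm,
    marginal_r2,
    welch_anova,
    welch_t_test,
)
from aasub.synth import SynthScenario

from conftest import make_synth_data

TRUTH = {"PC1": -0.4, "PC2": -0.3, "min_steps": -0.4, "pyr_diff": -0.2,
         "PC1:PC2": 0.08}


def one_way_data(seed=42, g=8, m=5, sd_u=1.0, sd_e=0.7):
    rng = np.random.default_rng(seed)
    labels = [f"g{i}" for i in range(g)]
    groups = np.repeat(labels, m)
    u = dict(zip(labels, rng.normal(0, sd_u, g)))
    y = np.array([u[x] for x in groups]) + rng.normal(0, sd_e, g * m)
    return pd.DataFrame({"y": y, "grp": groups}), g, m


def test_balanced_one_way_matches_anova_closed_form():
    df, g, m = one_way_data()
    spec = ModelSpec(response="y", fixed=(), random=("grp",),
                     zscore_response=False, satterthwaite=False)
    fit = fit_lmm(df, spec)
    gm = df.groupby("grp")["y"].mean()
    msw = ((df["y"] - df["grp"].map(gm)) ** 2).sum() / (g * (m - 1))
    msb = m * ((gm - df["y"].mean()) ** 2).sum() / (g - 1)
    assert fit.sigma2 == pytest.approx(msw, abs=1e-6)
    assert fit.var_u["grp"] == pytest.approx((msb - msw) / m, abs=1e-6)


def test_noise_free_data_identifies_beta_exactly():
    sc = SynthScenario(seed=7, var_u=0.0, sigma2=1e-12)
    data = make_synth_data(sc)
    fit = fit_lmm(data, ModelSpec(zscore_response=False, satterthwaite=False))
    for term, truth in TRUTH.items():
        assert fit.beta[term] == pytest.approx(truth, abs=1e-6)
    assert fit.r2_marginal > 1 - 1e-6  # no random or residual variance left


def test_slopes_recovered_within_sampling_error(synth_data, raw_spec):
    fit = fit_lmm(synth_data, raw_spec)
    for term, truth in TRUTH.items():
        assert abs(fit.beta[term] - truth) < 3 * fit.se[term]


def test_agreement_with_lmertest(synth_data, tmp_path):
    """Estimates, GLS standard errors and Satterthwaite df against lmerTest."""
    fit = fit_lmm(synth_data, ModelSpec(zscore_response=False))
    csv = tmp_path / "d.csv"
    synth_data.to_csv(csv, index=False)
    rscript = textwrap.dedent(f"""
        suppressMessages(library(lmerTest))
        d <- read.csv("{csv}")
        zs <- function(x) (x - mean(x)) / sd(x)
        d$PC1 <- zs(d$PC1); d$PC2 <- zs(d$PC2)
        d$min_steps <- zs(d$min_steps); d$pyr_diff <- zs(d$pyr_diff)
        f <- lmer(log_rate ~ PC1 + PC2 + min_steps + pyr_diff + PC1:PC2 +
                  (1|aa_from) + (1|aa_to), data=d, REML=TRUE)
        write.csv(summary(f)$coefficients, "{tmp_path}/r_fit.csv")
    """)
    subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
    r_fit = pd.read_csv(tmp_path / "r_fit.csv", index_col=0)
    r_fit.index = ["Intercept", "PC1", "PC2", "min_steps", "pyr_diff", "PC1:PC2"]
    for term in r_fit.index:
        assert fit.beta[term] == pytest.approx(r_fit.loc[term, "Estimate"], abs=1e-5)
        assert fit.se[term] == pytest.approx(r_fit.loc[term, "Std. Error"], rel=1e-4)
        assert fit.df[term] == pytest.approx(r_fit.loc[term, "df"], rel=0.02)
        assert fit.p[term] == pytest.approx(r_fit.loc[term, "Pr(>|t|)"], abs=1e-4)


def test_satterthwaite_df_bounds(raw_spec):
    data = make_synth_data(SynthScenario(seed=5))
    fit = fit_lmm(data, raw_spec)
    assert ((fit.df > 0) & (fit.df <= fit.n - len(fit.beta))).all()


def test_satterthwaite_df_shrinks_with_group_variance():
    """Balanced one-way anchors: df(intercept) = n-1 with no group variance,
    g-1 once the between-group variance dominates, monotone in between."""
    spec = ModelSpec(response="y", fixed=(), random=("grp",),
                     zscore_response=False)
    dfs = []
    for sd_u in (0.05, 0.5, 2.0, 8.0):
        fit = fit_lmm(one_way_data(seed=1, g=10, m=10, sd_u=sd_u, sd_e=1.0)[0],
                      spec)
        dfs.append(fit.df["Intercept"])
    assert dfs[0] == pytest.approx(99, abs=0.5)   # var_u at zero boundary
    assert dfs[-1] == pytest.approx(9, abs=0.5)   # g - 1
    assert all(a >= b - 1e-4 for a, b in zip(dfs, dfs[1:]))


def test_rank_deficient_design_rejected(synth_data):
    data = synth_data.copy()
    data["gc_diff"] = data["min_steps"]  # alias
    spec = ModelSpec(fixed=("min_steps", "gc_diff"), zscore_response=False)
    with pytest.raises(ValueError, match="rank deficient"):
        fit_lmm(data, spec)


def test_interaction_requires_main_effects():
    with pytest.raises(ValueError, match="interaction"):
        ModelSpec(fixed=("PC1", "PC1:PC2"))


def test_reml_reduces_to_ols_when_variances_vanish():
    sc = SynthScenario(seed=9, var_u=0.0, sigma2=0.2)
    data = make_synth_data(sc)
    spec = ModelSpec(zscore_response=False, satterthwaite=False)
    fit = fit_lmm(data, spec)
    X = np.column_stack([np.ones(len(data))] + [
        stats.zscore(data[t], ddof=1) for t in ("PC1", "PC2", "min_steps", "pyr_diff")
    ])
    X = np.column_stack([X, X[:, 1] * X[:, 2]])
    ols = np.linalg.lstsq(X, data["log_rate"].to_numpy(), rcond=None)[0]
    # random variances estimated near zero -> GLS collapses to OLS
    assert sum(fit.var_u.values()) < 0.02
    assert np.allclose(fit.beta.to_numpy(), ols, atol=0.02)


def test_compare_models_identical_specs_degenerate(synth_data):
    spec = ModelSpec(zscore_response=False, reml=False, satterthwaite=False)
    fit = fit_lmm(synth_data, spec)
    res = compare_models(fit, fit)
    assert res["chi2"] == pytest.approx(0.0, abs=1e-8)
    assert res["df"] == 0
    assert res["p"] == 1.0


def test_compare_models_detects_strong_interaction(synth_data):
    ml = ModelSpec(zscore_response=False, reml=False, satterthwaite=False)
    full = fit_lmm(synth_data, ml)
    reduced = fit_lmm(synth_data, ml.without("PC1:PC2"))
    res = compare_models(full, reduced)
    assert res["df"] == 1
    assert res["p"] < 0.05
    assert res["chi2"] > 0
    # AIC and LRT agree in sign
    assert (res["delta_aic"] > 0) == (res["chi2"] > 2 * res["df"])


def test_compare_models_requires_ml_and_nesting(synth_data):
    reml_fit = fit_lmm(synth_data, ModelSpec(zscore_response=False,
                                             satterthwaite=False))
    with pytest.raises(ValueError, match="ML"):
        compare_models(reml_fit, reml_fit)
    ml = ModelSpec(zscore_response=False, reml=False, satterthwaite=False)
    a = fit_lmm(synth_data, ml.without("PC1:PC2", "PC2"))
    b = fit_lmm(synth_data, ml.without("pyr_diff"))
    with pytest.raises(ValueError, match="nested"):
        compare_models(a, b)


def test_marginal_r2_limits():
    # fixed effects only, vanishing noise -> marginal R2 -> 1
    data = make_synth_data(SynthScenario(seed=3, var_u=0.0, sigma2=1e-12))
    fit = fit_lmm(data, ModelSpec(zscore_response=False, satterthwaite=False))
    assert marginal_r2(fit) > 0.999
    # intercept-only fixed part -> marginal R2 = 0
    data2 = make_synth_data(SynthScenario(seed=4))
    fit2 = fit_lmm(data2, ModelSpec(fixed=(), zscore_response=False,
                                    satterthwaite=False))
    assert marginal_r2(fit2) == pytest.approx(0.0, abs=1e-12)
    assert 0.0 <= marginal_r2(fit2) <= marginal_r2(fit2, conditional=True) <= 1.0


def test_marginal_r2_recovers_known_variance_share(raw_spec):
    # default scenario: var(X beta) approx 0.40, random 2*0.05, residual 0.15
    data = make_synth_data(SynthScenario(seed=13))
    fit = fit_lmm(data, raw_spec)
    assert fit.r2_marginal == pytest.approx(0.62, abs=0.12)
    assert fit.r2_conditional > fit.r2_marginal


def test_fit_by_steps_partitions_data(synth_data, raw_spec):
    import warnings

    spec = raw_spec.without("min_steps", "PC1:PC2")
    sizes = []
    for k in (1, 2, 3):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small step-3 subset may hit boundary
            f = fit_by_steps(synth_data, spec, k)
        sizes.append(f.n)
        assert f.n == int((synth_data["min_steps"] == k).sum())
    assert sum(sizes) == len(synth_data)


def test_fit_by_steps_rejects_min_steps_term(synth_data, raw_spec):
    with pytest.raises(ValueError, match="min_steps"):
        fit_by_steps(synth_data, raw_spec, 1)
    with pytest.raises(ValueError, match="no pairs"):
        fit_by_steps(synth_data, raw_spec.without("min_steps"), 4)


def test_noise_free_subset_slopes_equal_full(raw_spec):
    # with no noise and no z-scoring the model is exactly linear, so slopes
    # estimated on any subset coincide with the full-data slopes
    sc = SynthScenario(
        seed=8, var_u=0.0, sigma2=1e-12,
        beta={"Intercept": 0.0, "PC1": -0.4, "PC2": -0.3},
    )
    data = make_synth_data(sc)
    spec = ModelSpec(fixed=("PC1", "PC2"), zscore_response=False,
                     zscore_predictors=False, satterthwaite=False)
    full = fit_lmm(data, spec)
    sub = fit_by_steps(data, spec, 1)
    for term in ("PC1", "PC2"):
        assert sub.beta[term] == pytest.approx(full.beta[term], abs=1e-5)


def test_welch_t_identities():
    rng = np.random.default_rng(0)
    x = rng.normal(size=30)
    res = welch_t_test(x, x)
    assert res["t"] == pytest.approx(0.0, abs=1e-12)
    assert res["p"] == pytest.approx(1.0)
    # equal variances, equal n: Welch t equals pooled t
    y = rng.normal(0.5, 1.0, 30)
    pooled = stats.ttest_ind(x, y, equal_var=True)
    welch = welch_t_test(x, y)
    assert welch["t"] == pytest.approx(pooled.statistic, rel=1e-6)


def test_welch_t_textbook_formula():
    rng = np.random.default_rng(5)
    x, y = rng.normal(0, 1, 25), rng.normal(0.8, 2.0, 40)
    res = welch_t_test(x, y)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    assert res["t"] == pytest.approx(t, rel=1e-10)
    assert res["df"] == pytest.approx(df, rel=1e-10)
    assert res["p"] == pytest.approx(2 * stats.t.sf(abs(t), df), rel=1e-10)


def test_welch_anova_two_groups_equals_t_squared():
    rng = np.random.default_rng(6)
    x, y = rng.normal(0, 1, 20), rng.normal(1, 2, 35)
    values = np.concatenate([x, y])
    groups = np.array(["a"] * 20 + ["b"] * 35)
    anova = welch_anova(values, groups)
    t = welch_t_test(x, y)
    assert anova["F"] == pytest.approx(t["t"] ** 2, rel=1e-8)
    assert anova["p"] == pytest.approx(t["p"], rel=1e-8)
    assert anova["df2"] == pytest.approx(t["df"], rel=1e-8)


def test_welch_anova_separated_means():
    rng = np.random.default_rng(7)
    values = np.concatenate(
        [rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(5, 1, 30)]
    )
    groups = np.repeat(["a", "b", "c"], 30)
    assert welch_anova(values, groups)["p"] < 1e-6


def test_welch_anova_input_validation():
    with pytest.raises(ValueError, match="two groups"):
        welch_anova([1.0, 2.0], ["a", "a"])
    with pytest.raises(ValueError, match="zero variance"):
        welch_anova([1.0, 1.0, 2.0, 3.0], ["a", "a", "b", "b"])
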