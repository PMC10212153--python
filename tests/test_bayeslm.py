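"""Flat-prior posterior, Bayes factors, scale selection and evidence tiers.

statsmodels OLS serves as the independent least-squares oracle (the
flat-prior posterior mean must coincide with it); arviz cross-checks the
split-chain R-hat.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from dielshift import (
    NocturnalityLM,
    bayes_factor_vs_null,
    classify_evidence,
    collinearity_screen,
    scale_analysis,
    simulate_regression_dataset,
    zscale,
)


def _random_table(rng, n=60, p=4, beta=None, sigma=1.0):
    X = rng.standard_normal((n, p))
    if beta is None:
        beta = rng.normal(0, 1, size=p + 1)
    y = beta[0] + X @ beta[1:] + rng.normal(0, sigma, size=n)
    df = pd.DataFrame(X, columns=[f"x{i+1}" for i in range(p)])
    df.insert(0, "nocturnality", y)
    return df, np.asarray(beta)


# --- z-scaling -------------------------------------------------------------

def test_zscale_example():
    scaled, mean, sd = zscale([1.0, 2.0, 3.0])
    assert np.allclose(scaled, [-1.0, 0.0, 1.0])
    assert mean == 2.0 and sd == 1.0


def test_zscale_idempotent_and_exact():
    rng = np.random.default_rng(0)
    x = rng.normal(5, 3, size=500)
    scaled, _, _ = zscale(x)
    assert abs(scaled.mean()) < 1e-12
    assert abs(scaled.std(ddof=1) - 1.0) < 1e-12
    again, m2, s2 = zscale(scaled)
    assert np.allclose(again, scaled, atol=1e-12)
    assert abs(m2) < 1e-12 and abs(s2 - 1.0) < 1e-12


def test_zscale_constant_column_is_error():
    with pytest.raises(ValueError, match="degenerate"):
        zscale(pd.Series([2.0, 2.0, 2.0], name="crown_closure"))


# --- collinearity ----------------------------------------------------------

def test_collinearity_flags_perfect_pairs():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(50)
    df = pd.DataFrame({"a": x, "b": 2 * x, "c": -x, "d": rng.standard_normal(50)})
    flagged = collinearity_screen(df, threshold=0.7)
    pairs = {frozenset((r.var1, r.var2)): r.r for r in flagged.itertuples()}
    assert pairs[frozenset(("a", "b"))] == pytest.approx(1.0)
    assert pairs[frozenset(("a", "c"))] == pytest.approx(-1.0)
    assert frozenset(("a", "d")) not in pairs


def test_collinearity_no_false_flags_on_independent_columns():
    rng = np.random.default_rng(2)
    df = pd.DataFrame(rng.standard_normal((10_000, 5)),
                      columns=list("abcde"))
    assert collinearity_screen(df, threshold=0.7).empty


# --- flat-prior fit vs least squares ---------------------------------------

def test_noiseless_fit_recovers_beta_exactly():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((40, 3))
    beta = np.array([2.0, 0.5, -1.0, 0.25])
    y = beta[0] + X @ beta[1:]
    res = NocturnalityLM(y, X).fit()
    assert np.allclose(res.params.to_numpy(), beta, atol=1e-10)


def test_posterior_mean_equals_ols_oracle():
    rng = np.random.default_rng(4)
    for _ in range(20):
        table, _ = _random_table(rng)
        model = NocturnalityLM.from_dataframe(table, standardize=False)
        res = model.fit()
        ols = sm.OLS(table["nocturnality"],
                     sm.add_constant(table.drop(columns="nocturnality"))).fit()
        assert np.allclose(res.params.to_numpy(), ols.params.to_numpy(), atol=1e-8)
        # flat-prior CI == frequentist t-interval under this model
        ci = res.conf_int(0.95)
        sm_ci = ols.conf_int(alpha=0.05)
        assert np.allclose(ci.to_numpy(), sm_ci.to_numpy(), atol=1e-8)


def test_credible_interval_quantile_oracle():
    rng = np.random.default_rng(5)
    table, _ = _random_table(rng, n=25, p=2)
    res = NocturnalityLM.from_dataframe(table, standardize=False).fit()
    ci90 = res.conf_int(0.90)
    # independent t-quantile arithmetic
    X = np.column_stack([np.ones(25), table[["x1", "x2"]].to_numpy()])
    y = table["nocturnality"].to_numpy()
    bh = np.linalg.solve(X.T @ X, X.T @ y)
    rss = ((y - X @ bh) ** 2).sum()
    df = 25 - 3
    se = np.sqrt(rss / df * np.diag(np.linalg.inv(X.T @ X)))
    tq = stats.t.ppf(0.95, df)
    assert np.allclose(ci90["lower"].to_numpy(), bh - tq * se, atol=1e-10)
    assert np.allclose(ci90["upper"].to_numpy(), bh + tq * se, atol=1e-10)
    # symmetric about the posterior mean, and nested within the 95% interval
    mid = (ci90["lower"] + ci90["upper"]) / 2
    assert np.allclose(mid.to_numpy(), res.params.to_numpy(), atol=1e-10)
    ci95 = res.conf_int(0.95)
    assert (ci95["lower"] <= ci90["lower"]).all()
    assert (ci95["upper"] >= ci90["upper"]).all()


def test_rank_deficient_design_is_error():
    rng = np.random.default_rng(6)
    x = rng.standard_normal(30)
    X = np.column_stack([x, 2 * x])
    y = rng.standard_normal(30)
    with pytest.raises(np.linalg.LinAlgError):
        NocturnalityLM(y, X).fit()


def test_insufficient_rows_is_error():
    with pytest.raises(ValueError, match="insufficient"):
        NocturnalityLM([1.0, 2.0, 3.0], np.eye(3)).fit()


# --- Gibbs sampler ---------------------------------------------------------

@pytest.fixture(scope="module")
def sampled_fit():
    rng = np.random.default_rng(7)
    table, _ = _random_table(rng, n=120, p=3, sigma=1.5)
    model = NocturnalityLM.from_dataframe(table, standardize=False)
    return model.fit(method="sampling", chains=4, iterations=40_000,
                     burn_in=2_000, seed=11), model.fit(method="analytic")


def test_sampler_agrees_with_analytic_posterior(sampled_fit):
    samp, exact = sampled_fit
    n_draws = samp.beta_draws.shape[0] * samp.beta_draws.shape[1]
    mc_se = exact.bse.to_numpy() / np.sqrt(n_draws) * 10  # generous ESS margin
    assert np.all(np.abs(samp.params.to_numpy() - exact.params.to_numpy())
                  <= 3 * np.maximum(mc_se, 1e-4))
    ci_s, ci_a = samp.conf_int(0.95), exact.conf_int(0.95)
    tol = 3 * exact.bse.to_numpy() / np.sqrt(n_draws) * 30
    assert np.all(np.abs(ci_s.to_numpy() - ci_a.to_numpy()) <= tol[:, None])


def test_rhat_near_one_and_matches_arviz(sampled_fit):
    samp, _ = sampled_fit
    assert samp.converged(threshold=1.1)
    az = pytest.importorskip("arviz")
    ref = az.rhat(az.convert_to_dataset(samp.beta_draws[:, :, 0][:, :, None]))
    ours = samp.rhat.iloc[0]
    assert ours == pytest.approx(float(ref.to_array().values.ravel()[0]), abs=0.01)


def test_sampler_is_seed_deterministic():
    rng = np.random.default_rng(8)
    table, _ = _random_table(rng, n=50, p=2)
    model = NocturnalityLM.from_dataframe(table, standardize=False)
    a = model.fit(method="sampling", iterations=8_000, burn_in=500, seed=5)
    b = model.fit(method="sampling", iterations=8_000, burn_in=500, seed=5)
    assert np.array_equal(a.beta_draws, b.beta_draws)


# --- Bayes factors ---------------------------------------------------------

def test_bayes_factor_matches_hand_arithmetic():
    # n=6 toy table, BF computed by independent BIC arithmetic
    table = pd.DataFrame({
        "nocturnality": [1.0, 2.0, 3.0, 4.0, 5.0, 7.0],
        "x": [0.1, 0.4, 0.2, 0.8, 0.9, 1.0],
    })
    y = table["nocturnality"].to_numpy()
    z = (table["x"] - table["x"].mean()) / table["x"].std(ddof=1)
    n = 6

    def bic(X):
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = ((y - X @ b) ** 2).sum()
        k = X.shape[1] + 1
        return n * np.log(2 * np.pi * rss / n) + n + k * np.log(n)

    expected = np.exp((bic(np.ones((n, 1)))
                       - bic(np.column_stack([np.ones(n), z]))) / 2)
    assert bayes_factor_vs_null(table, "x") == pytest.approx(expected, rel=1e-12)


def test_bayes_factor_under_null_and_alternative():
    rng = np.random.default_rng(9)
    null_below_1 = 0
    for _ in range(200):
        y = rng.standard_normal(10_000)
        x = rng.standard_normal(10_000)
        bf = bayes_factor_vs_null(pd.DataFrame({"nocturnality": y, "x": x}), "x")
        null_below_1 += bf < 1
    assert null_below_1 >= 190  # >= 95% of pure-noise replicates

    alt_above_1 = 0
    for _ in range(100):
        x = rng.standard_normal(500)
        y = x + rng.standard_normal(500)  # beta=1, sigma=1
        bf = bayes_factor_vs_null(pd.DataFrame({"nocturnality": y, "x": x}), "x")
        alt_above_1 += bf > 1
    assert alt_above_1 >= 99


def test_scale_analysis_selection_rule():
    rng = np.random.default_rng(10)
    n = 400
    daily = rng.standard_normal(n)
    weekly = rng.standard_normal(n)
    monthly = rng.standard_normal(n)
    # only the weekly measure carries signal
    y = 6 + 0.8 * weekly + rng.normal(0, 1, n)
    table = pd.DataFrame({
        "species": "coyote", "nocturnality": y,
        "daily_human_detections": daily, "weekly_human_rate": weekly,
        "monthly_human_rate": monthly,
    })
    sel = scale_analysis(table)
    assert sel.chosen == "weekly"
    assert sel.chosen_column == "weekly_human_rate"
    assert max(sel.bayes_factors.values()) == sel.bayes_factors["weekly"]
    assert sel.bayes_factors["weekly"] > 1

    # no signal anywhere: all BFs <= 1 at this n means no human variable
    y0 = rng.normal(6, 1, n)
    table0 = table.assign(nocturnality=y0)
    sel0 = scale_analysis(table0)
    if all(v <= 1 for v in sel0.bayes_factors.values()):
        assert sel0.chosen == "none"
        assert sel0.chosen_column is None


# --- evidence tiers --------------------------------------------------------

@pytest.mark.parametrize(
    "ci90, ci95, mean, tier, sign",
    [
        # strong positive: 95% interval excludes zero
        ((0.52, 1.11), (0.46, 1.17), 0.81, "strong", "positive"),
        # moderate positive: only the 90% interval excludes zero
        ((0.04, 0.65), (-0.02, 0.71), 0.35, "moderate", "positive"),
        ((-0.1, 0.2), (-0.16, 0.26), 0.05, "none", "positive"),
        ((-1.29, -0.52), (-1.35, -0.46), -0.87, "strong", "negative"),
    ],
)
def test_classify_evidence(ci90, ci95, mean, tier, sign):
    assert classify_evidence(ci90, ci95, mean) == (tier, sign)


def test_sign_probability_when_90ci_excludes_zero():
    rng = np.random.default_rng(12)
    checked = 0
    for _ in range(200):
        table, _ = _random_table(rng, n=40, p=3, sigma=2.0)
        res = NocturnalityLM.from_dataframe(table, standardize=False).fit()
        ci90 = res.conf_int(0.90)
        prob = res.sign_probability()
        for name in res.param_names:
            if ci90.at[name, "lower"] > 0 or ci90.at[name, "upper"] < 0:
                checked += 1
                assert prob[name] >= 0.95 - 1e-12
    assert checked > 50


def test_calibration_smoke():
    # quick coverage sanity at n=200 (the full 500-replicate audit is in the
    # acceptance suite)
    beta = np.array([6.0, 0.5, -0.5, 0.25])
    hits = 0
    for seed in range(60):
        table = simulate_regression_dataset(200, beta, sigma=2.0, seed=seed)
        res = NocturnalityLM.from_dataframe(table, standardize=False).fit()
        ci = res.conf_int(0.90)
        hits += int(ci.at["x1", "lower"] <= beta[1] <= ci.at["x1", "upper"])
    assert 0.78 <= hits / 60 <= 0.99


def test_summary_mentions_key_fields():
    rng = np.random.default_rng(13)
    table, _ = _random_table(rng, n=50, p=2)
    res = NocturnalityLM.from_dataframe(table, species="coyote",
                                        standardize=False).fit()
    text = res.summary()
    assert "coyote" in text and "n_obs: 50" in text
    assert "ci90_lower" in text and "tier" in text
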