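"""Flat-prior Bayesian linear regression of nocturnality, with Bayes-factor
temporal-scale selection and credible-interval evidence tiers.

Model
-----
For each species, nocturnality y_i (decimal hours from solar noon) is modelled
as

    y_i = b0 + sum_k b_k z_ik + e_i,    e_i ~ N(0, sigma^2),

with every predictor z-scaled (mean 0, SD 1) so coefficients are comparable
effect sizes in decimal hours per SD of predictor. Coefficients carry the
improper flat prior p(b) ~ 1, completed by the reference prior
p(sigma^2) ~ 1/sigma^2. Under this prior the posterior is available in closed
form: b | y is a multivariate Student-t centred on the least-squares solution
b_hat with scale s^2 (X'X)^-1 and n - p degrees of freedom, and sigma^2 | y is
scaled inverse-chi-square. The default ``fit(method="analytic")`` uses these
closed forms; ``method="sampling"`` runs a conjugate Gibbs sampler (multiple
chains, split-chain Gelman-Rubin R-hat) that mirrors the MCMC workflow the
analysis was designed around and must agree with the analytic path to Monte
Carlo error.

Evidence tiers: a coefficient shows *strong* evidence of an effect when its
95% equal-tailed credible interval excludes zero, *moderate* when only the
90% interval does, else *none*. A 90% equal-tailed interval excluding zero
implies posterior sign probability >= 0.95. Tier is about evidence, not
effect size; both are reported.

Temporal-scale selection: daily human detections, weekly and monthly human
detection rates are too collinear to enter one model, so each is screened in
a univariate model against the intercept-only null via a Bayes factor. With
improper flat priors the marginal likelihood is undefined, so the Bayes
factor is computed by the Schwarz/BIC approximation
BF = exp((BIC_null - BIC_model) / 2); the scale with the largest BF is kept,
and only if that BF exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

__all__ = [
    "zscale",
    "collinearity_screen",
    "NocturnalityLM",
    "NocturnalityLMResults",
    "bayes_factor_vs_null",
    "scale_analysis",
    "ScaleSelection",
    "classify_evidence",
    "HUMAN_SCALE_COLUMNS",
]

HUMAN_SCALE_COLUMNS: Mapping[str, str] = {
    "daily": "daily_human_detections",
    "weekly": "weekly_human_rate",
    "monthly": "monthly_human_rate",
}
_SCALE_ORDER = ("daily", "weekly", "monthly")  # deterministic tie-break


def zscale(column) -> Tuple[np.ndarray, float, float]:
    """Standardize a column to sample mean 0 and sample SD 1 (ddof=1).

    Returns ``(scaled, mean, sd)``; the constants are retained by the model
    for back-transformation. Raises on a constant column.
    """
    x = np.asarray(column, dtype=float)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        name = getattr(column, "name", None)
        raise ValueError(f"degenerate (constant) predictor{f' {name!r}' if name else ''}")
    return (x - mean) / sd, mean, sd


def collinearity_screen(predictors: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """All unordered predictor pairs with |Pearson r| >= threshold.

    Returns a DataFrame with columns ``var1``, ``var2``, ``r`` sorted by |r|
    descending. The three human-presence measures are expected to flag each
    other on field data; collinear pairs must not enter one model together.
    """
    if len(predictors) < 3:
        raise ValueError("need at least 3 rows to screen collinearity")
    corr = predictors.corr(method="pearson")
    cols = list(corr.columns)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = corr.iloc[i, j]
            if np.isfinite(r) and abs(r) >= threshold:
                rows.append((cols[i], cols[j], float(r)))
    out = pd.DataFrame(rows, columns=["var1", "var2", "r"])
    return out.reindex(out["r"].abs().sort_values(ascending=False).index).reset_index(drop=True)


class NocturnalityLM:
    """Bayesian linear model with flat coefficient priors.

    Parameters
    ----------
    endog : array-like
        Response (nocturnality in decimal hours).
    exog : array-like, shape (n, p)
        Design matrix *without* intercept; an intercept column is prepended.
    exog_names : sequence of str, optional
        Names of the ``exog`` columns.
    species : str, optional
        Carried through to results and summaries.

    Use :meth:`from_dataframe` to build from an assembled model table with
    automatic z-scaling of predictors.
    """

    def __init__(self, endog, exog, exog_names: Optional[Sequence[str]] = None,
                 species: Optional[str] = None,
                 scaling: Optional[pd.DataFrame] = None):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if len(y) != len(X):
            raise ValueError("endog and exog lengths differ")
        if not (np.isfinite(y).all() and np.isfinite(X).all()):
            raise ValueError("model table contains missing or non-finite values")
        n, k = X.shape
        if exog_names is None:
            exog_names = [f"x{i + 1}" for i in range(k)]
        if n < k + 3:
            raise ValueError(f"insufficient data: {n} rows for {k} predictors")
        self.endog = y
        self.exog = np.column_stack([np.ones(n), X])
        self.param_names = ["intercept", *exog_names]
        self.species = species
        self.scaling = scaling
        self.n_obs = n

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, response: str = "nocturnality",
                       predictors: Optional[Sequence[str]] = None,
                       species: Optional[str] = None,
                       standardize: bool = True) -> "NocturnalityLM":
        """Build the model from a model table, z-scaling each predictor.

        Scaling constants are computed on this table (after any row drops)
        and retained on the model for back-transformation.
        """
        if predictors is None:
            predictors = [c for c in table.columns
                          if c != response and pd.api.types.is_numeric_dtype(table[c])]
        if species is None and "species" in table.columns and len(table):
            species = str(table["species"].iloc[0])
        y = table[response].to_numpy(dtype=float)
        cols, rows = [], []
        for name in predictors:
            if standardize:
                scaled, mean, sd = zscale(table[name])
            else:
                scaled = table[name].to_numpy(dtype=float)
                mean, sd = 0.0, 1.0
            cols.append(scaled)
            rows.append((name, mean, sd))
        X = np.column_stack(cols) if cols else np.empty((len(y), 0))
        scaling = pd.DataFrame(rows, columns=["predictor", "mean", "sd"]).set_index("predictor")
        return cls(y, X, exog_names=list(predictors), species=species, scaling=scaling)

    # -- fitting -----------------------------------------------------------

    def _decompose(self):
        X, y = self.exog, self.endog
        n, p = X.shape
        xtx = X.T @ X
        try:
            chol = linalg.cholesky(xtx, lower=True)
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("singular (rank-deficient) design matrix") from exc
        beta_hat = linalg.cho_solve((chol, True), X.T @ y)
        resid = y - X @ beta_hat
        rss = float(resid @ resid)
        if n <= p:
            raise ValueError(f"insufficient data: n={n} <= p={p}")
        vinv_chol = chol  # lower L with L L' = X'X
        V = linalg.cho_solve((chol, True), np.eye(p))
        return beta_hat, V, vinv_chol, rss, n - p

    def fit(self, method: str = "analytic", chains: int = 4, iterations: int = 100_000,
            burn_in: int = 5_000, thinning: int = 1,
            seed: Optional[int] = None) -> "NocturnalityLMResults":
        """Fit the model.

        ``method="analytic"`` evaluates the closed-form multivariate-t
        posterior. ``method="sampling"`` runs ``chains`` conjugate Gibbs
        chains with ``iterations`` total draws split across chains,
        ``burn_in`` discarded per chain, keeping every ``thinning``-th draw,
        and reports split-chain R-hat per parameter.
        """
        beta_hat, V, chol, rss, df = self._decompose()
        s2 = rss / df
        if method == "analytic":
            return NocturnalityLMResults(
                model=self, method=method, beta_hat=beta_hat, cov_unscaled=V,
                s2=s2, df_resid=df)
        if method != "sampling":
            raise ValueError(f"unknown method {method!r}")
        draws_per_chain = iterations // chains
        if draws_per_chain <= burn_in:
            raise ValueError("iterations per chain must exceed burn_in")
        rng = np.random.default_rng(seed)
        n, p = self.exog.shape
        kept = (draws_per_chain - burn_in) // thinning
        beta_draws = np.empty((chains, kept, p))
        sigma2_draws = np.empty((chains, kept))
        # Gibbs: beta | sigma2 ~ N(beta_hat, sigma2 V); sigma2 | beta ~
        # Inv-Gamma(n/2, RSS(beta)/2) with RSS(beta) = rss + sigma2*|z|^2
        # when beta = beta_hat + sigma L^-T z, z ~ N(0, I).
        Linv_T = linalg.solve_triangular(chol, np.eye(p), lower=True).T
        for c in range(chains):
            sigma2 = s2 * (1.0 + rng.uniform(-0.5, 1.0))  # overdispersed start
            zs = rng.standard_normal((draws_per_chain, p))
            znorm2 = np.einsum("ij,ij->i", zs, zs)
            gammas = rng.standard_gamma(n / 2.0, size=draws_per_chain)
            sig = np.empty(draws_per_chain)
            for t in range(draws_per_chain):
                sig[t] = sigma2
                rss_beta = rss + sigma2 * znorm2[t]
                sigma2 = rss_beta / (2.0 * gammas[t])
            keep_idx = np.arange(burn_in, draws_per_chain, thinning)[:kept]
            sig_kept = sig[keep_idx]
            z_kept = zs[keep_idx]
            beta_draws[c] = beta_hat + (np.sqrt(sig_kept)[:, None] * z_kept) @ Linv_T.T
            sigma2_draws[c] = sig_kept
        rhat = _split_rhat(np.concatenate([beta_draws, sigma2_draws[:, :, None]], axis=2))
        return NocturnalityLMResults(
            model=self, method=method, beta_hat=beta_hat, cov_unscaled=V,
            s2=s2, df_resid=df, beta_draws=beta_draws, sigma2_draws=sigma2_draws,
            rhat=pd.Series(rhat, index=[*self.param_names, "sigma"]))


def _split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-chain Gelman-Rubin R-hat. ``draws``: (chains, iters, params)."""
    c, t, p = draws.shape
    half = t // 2
    split = np.concatenate([draws[:, :half, :], draws[:, half:2 * half, :]], axis=0)
    m, n = split.shape[0], split.shape[1]
    chain_means = split.mean(axis=1)           # (m, p)
    chain_vars = split.var(axis=1, ddof=1)     # (m, p)
    W = chain_vars.mean(axis=0)
    B = n * chain_means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B / n
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.sqrt(var_plus / W)
    return rhat


@dataclass
class NocturnalityLMResults:
    """Posterior summaries of a flat-prior linear fit.

    Attributes
    ----------
    params : posterior means of coefficients (== least-squares estimates).
    bse : posterior standard deviations.
    sigma : posterior mean of the residual SD.
    rhat : per-parameter split-chain Gelman-Rubin statistic (sampling only).
    """

    model: NocturnalityLM
    method: str
    beta_hat: np.ndarray
    cov_unscaled: np.ndarray
    s2: float
    df_resid: int
    beta_draws: Optional[np.ndarray] = None
    sigma2_draws: Optional[np.ndarray] = None
    rhat: Optional[pd.Series] = field(default=None)

    # -- posterior summaries ------------------------------------------------

    @property
    def param_names(self) -> Sequence[str]:
        return self.model.param_names

    @property
    def n_obs(self) -> int:
        return self.model.n_obs

    @property
    def params(self) -> pd.Series:
        if self.method == "sampling":
            flat = self.beta_draws.reshape(-1, self.beta_draws.shape[-1])
            return pd.Series(flat.mean(axis=0), index=self.param_names)
        return pd.Series(self.beta_hat, index=self.param_names)

    @property
    def scale_se(self) -> np.ndarray:
        """Student-t scale of each marginal: s * sqrt(V_jj)."""
        return np.sqrt(self.s2 * np.diag(self.cov_unscaled))

    @property
    def bse(self) -> pd.Series:
        if self.method == "sampling":
            flat = self.beta_draws.reshape(-1, self.beta_draws.shape[-1])
            return pd.Series(flat.std(axis=0, ddof=1), index=self.param_names)
        df = self.df_resid
        sd = self.scale_se * np.sqrt(df / (df - 2)) if df > 2 else np.full_like(
            self.scale_se, np.nan)
        return pd.Series(sd, index=self.param_names)

    @property
    def sigma(self) -> float:
        """Posterior mean of the residual SD."""
        if self.method == "sampling":
            return float(np.sqrt(self.sigma2_draws).mean())
        df = self.df_resid
        # E[sigma] under scaled-inv-chi2(df, s2)
        return float(np.sqrt(df * self.s2 / 2.0)
                     * np.exp(special.gammaln((df - 1) / 2.0) - special.gammaln(df / 2.0)))

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Equal-tailed credible interval for every coefficient.

        Analytic: marginal Student-t quantiles. Sampling: empirical quantiles
        of the pooled draws.
        """
        if not 0.0 < level < 1.0:
            raise ValueError("level must be in (0, 1)")
        alpha = 1.0 - level
        if self.method == "sampling":
            flat = self.beta_draws.reshape(-1, self.beta_draws.shape[-1])
            lo = np.quantile(flat, alpha / 2.0, axis=0)
            hi = np.quantile(flat, 1.0 - alpha / 2.0, axis=0)
        else:
            tq = stats.t.ppf(1.0 - alpha / 2.0, self.df_resid)
            lo = self.beta_hat - tq * self.scale_se
            hi = self.beta_hat + tq * self.scale_se
        return pd.DataFrame({"lower": lo, "upper": hi}, index=self.param_names)

    def sign_probability(self) -> pd.Series:
        """Posterior probability that each coefficient shares the sign of its mean."""
        if self.method == "sampling":
            flat = self.beta_draws.reshape(-1, self.beta_draws.shape[-1])
            mean = flat.mean(axis=0)
            prob = np.where(mean >= 0, (flat > 0).mean(axis=0), (flat < 0).mean(axis=0))
            return pd.Series(prob, index=self.param_names)
        tstat = np.abs(self.beta_hat) / self.scale_se
        return pd.Series(stats.t.cdf(tstat, self.df_resid), index=self.param_names)

    def evidence(self) -> pd.DataFrame:
        """Evidence tier (none/moderate/strong) and sign per coefficient."""
        ci90 = self.conf_int(0.90)
        ci95 = self.conf_int(0.95)
        rows = []
        for name in self.param_names:
            tier, sign = classify_evidence(
                (ci90.at[name, "lower"], ci90.at[name, "upper"]),
                (ci95.at[name, "lower"], ci95.at[name, "upper"]),
                self.params[name],
            )
            rows.append((name, tier, sign))
        return pd.DataFrame(rows, columns=["parameter", "tier", "sign"]).set_index("parameter")

    def to_frame(self) -> pd.DataFrame:
        """Flat per-coefficient table: estimate, SD, 90%/95% CI, tier, sign."""
        ci90, ci95 = self.conf_int(0.90), self.conf_int(0.95)
        ev = self.evidence()
        out = pd.DataFrame({
            "estimate": self.params,
            "sd": self.bse,
            "ci90_lower": ci90["lower"], "ci90_upper": ci90["upper"],
            "ci95_lower": ci95["lower"], "ci95_upper": ci95["upper"],
            "tier": ev["tier"], "sign": ev["sign"],
        })
        if self.rhat is not None:
            out["rhat"] = self.rhat.reindex(out.index)
        out.insert(0, "species", self.model.species)
        return out

    def converged(self, threshold: float = 1.1) -> bool:
        """All R-hat below threshold (trivially True on the analytic path)."""
        if self.rhat is None:
            return True
        return bool((self.rhat.dropna() < threshold).all())

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "Flat-prior Bayesian linear model"
            + (f" — {self.model.species}" if self.model.species else ""),
            f"  method: {self.method}   n_obs: {self.n_obs}   df_resid: {self.df_resid}",
            f"  residual SD (posterior mean): {self.sigma:.4f}",
        ]
        if self.rhat is not None:
            lines.append(f"  max R-hat: {self.rhat.max():.4f} (converged: {self.converged()})")
        frame = self.to_frame().drop(columns="species")
        with pd.option_context("display.float_format", lambda v: f"{v: .4f}"):
            lines.append(frame.to_string())
        return "\n".join(lines)


def classify_evidence(ci90: Tuple[float, float], ci95: Tuple[float, float],
                      posterior_mean: float) -> Tuple[str, str]:
    """Tier an effect: strong if the 95% CI excludes 0, moderate if only the
    90% CI does, else none; sign from the posterior mean.

    The tier reflects strength of *evidence*, never strength of effect.
    """
    sign = "positive" if posterior_mean > 0 else ("negative" if posterior_mean < 0 else "zero")
    lo95, hi95 = ci95
    lo90, hi90 = ci90
    if lo95 > 0 or hi95 < 0:
        return "strong", sign
    if lo90 > 0 or hi90 < 0:
        return "moderate", sign
    return "none", sign


# --- Bayes factors and temporal-scale selection ----------------------------

def _gaussian_bic(y: np.ndarray, X: np.ndarray) -> float:
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    k = p + 1  # coefficients + residual variance
    loglik = -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)
    return -2.0 * loglik + k * np.log(n)


def bayes_factor_vs_null(table: pd.DataFrame, predictor: str,
                         response: str = "nocturnality") -> float:
    """BIC-approximate Bayes factor of the one-predictor model over the
    intercept-only null: ``exp((BIC_null - BIC_model) / 2)``.

    BF > 1 favours including the predictor. The predictor is z-scaled first
    (errors on a constant column).
    """
    y = table[response].to_numpy(dtype=float)
    z, _, _ = zscale(table[predictor])
    n = len(y)
    X1 = np.column_stack([np.ones(n), z])
    X0 = np.ones((n, 1))
    return float(np.exp((_gaussian_bic(y, X0) - _gaussian_bic(y, X1)) / 2.0))


@dataclass(frozen=True)
class ScaleSelection:
    """Outcome of the temporal-scale analysis for one species."""

    species: Optional[str]
    bayes_factors: Dict[str, float]
    chosen: str  # "daily" | "weekly" | "monthly" | "none"

    @property
    def chosen_column(self) -> Optional[str]:
        return HUMAN_SCALE_COLUMNS.get(self.chosen)


def scale_analysis(table: pd.DataFrame, response: str = "nocturnality",
                   candidates: Mapping[str, str] = HUMAN_SCALE_COLUMNS) -> ScaleSelection:
    """Pick the temporal scale of human presence whose univariate model has
    the largest BIC-approximate Bayes factor against the intercept-only null;
    pick "none" when no Bayes factor exceeds 1.

    Ties break deterministically daily > weekly > monthly. All candidate
    models are fit on the same rows.
    """
    species = str(table["species"].iloc[0]) if "species" in table.columns and len(table) else None
    bfs: Dict[str, float] = {}
    for scale in _SCALE_ORDER:
        if scale not in candidates:
            continue
        bfs[scale] = bayes_factor_vs_null(table, candidates[scale], response=response)
    best = max(bfs, key=lambda s: (bfs[s], -_SCALE_ORDER.index(s)))
    chosen = best if bfs[best] > 1.0 else "none"
    return ScaleSelection(species=species, bayes_factors=bfs, chosen=chosen)
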