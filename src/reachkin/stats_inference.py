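"""Between-group inferential toolkit for the reaching measures.

Covers the designs used throughout the analysis:

* ANCOVA with one covariate (intact-arm performance) and a between-
  subject group factor, Type III sums of squares with sum-to-zero group
  coding, partial eta squared, covariate-adjusted group means, Tukey HSD
  post hocs and Cohen's d (adjusted-mean difference over sqrt(MSE));
* one-way ANOVA as the covariate-free special case;
* the Watson-Williams k-sample test for equal circular means (used as a
  one-way ANOVA for bias-angle data);
* default (JZS) Bayes factors for t designs with a Cauchy effect-size
  prior, Jeffreys-style Bayes factors for Pearson correlations, and a
  BIC-based approximation to the inclusion Bayes factor of an effect;
* Steiger's Z for comparing two dependent correlations sharing a
  variable, and the basic two-sample/correlation tests.

The frequentist machinery sits on statsmodels OLS; the Bayes factors are
computed by adaptive quadrature over the prior.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
from scipy import integrate, special, stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "AncovaResult",
    "CircularTestResult",
    "BayesFactorResult",
    "PosthocContrast",
    "ancova",
    "oneway_anova",
    "watson_williams",
    "jzs_bf_ttest",
    "jeffreys_bf_correlation",
    "steiger_z",
    "pooled_t",
    "mann_whitney",
    "pearson",
    "spearman",
    "bf_inclusion_approx",
    "results_to_frame",
]

DEFAULT_CAUCHY_SCALE = 0.707


class NumericalError(RuntimeError):
    """Numerical integration failed to converge."""


@dataclass
class PosthocContrast:
    pair: tuple
    t: float
    p_tukey: float
    cohens_d: float


@dataclass
class AncovaResult:
    """Covariate-adjusted group comparison."""

    F: float
    df_effect: int
    df_error: int
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float
    mse: float
    adjusted_means: dict
    posthoc: list
    covariate_F: float | None = None
    covariate_p: float | None = None


@dataclass
class CircularTestResult:
    F: float
    df1: int
    df2: int
    p: float
    group_mean_angles: dict


@dataclass
class BayesFactorResult:
    bf10: float
    prior_scale: float
    method: str

    def __post_init__(self):
        if not (np.isfinite(self.bf10) and self.bf10 > 0):
            raise NumericalError(f"BF10 must be finite and positive, "
                                 f"got {self.bf10}")


# ---------------------------------------------------------------------------
# ANCOVA / ANOVA
# ---------------------------------------------------------------------------

def _tukey_p(t_value: float, k: int, df: int) -> float:
    q = abs(t_value) * np.sqrt(2.0)
    return float(stats.studentized_range.sf(q, k, df))


def ancova(dependent, covariate, group) -> AncovaResult:
    """ANCOVA ``dependent ~ covariate + group`` (Type III, Sum coding).

    ``covariate=None`` drops the covariate and yields the one-way ANOVA.
    Adjusted group means are evaluated at the grand covariate mean; Tukey
    HSD post hocs use the model's covariance of the adjusted means, with
    Cohen's d defined as adjusted-mean difference / sqrt(MSE).
    """
    y = np.asarray(dependent, float)
    g = np.asarray(group)
    levels = list(pd.unique(g))
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    counts = {lev: int(np.sum(g == lev)) for lev in levels}
    if min(counts.values()) < 2:
        raise ValueError("every group needs n >= 2")
    data = pd.DataFrame({"y": y, "g": pd.Categorical(g, categories=levels)})
    if covariate is not None:
        x = np.asarray(covariate, float)
        if np.ptp(x) == 0:
            raise np.linalg.LinAlgError(
                "covariate is constant: design matrix is rank deficient")
        data["x"] = x
        formula = "y ~ x + C(g, Sum)"
    else:
        formula = "y ~ C(g, Sum)"
    model = smf.ols(formula, data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(model, typ=3)
    grp_row = table.loc["C(g, Sum)"]
    res_row = table.loc["Residual"]
    ss_eff = float(grp_row["sum_sq"])
    ss_err = float(res_row["sum_sq"])
    df_eff = int(grp_row["df"])
    df_err = int(res_row["df"])
    mse = ss_err / df_err
    F = float(grp_row["F"])
    p = float(grp_row["PR(>F)"])
    cov_F = cov_p = None
    if covariate is not None:
        cov_F = float(table.loc["x", "F"])
        cov_p = float(table.loc["x", "PR(>F)"])

    pred = pd.DataFrame({"g": pd.Categorical(levels, categories=levels)})
    if covariate is not None:
        pred["x"] = float(np.mean(data["x"]))
    design = model.model.data.design_info
    (exog,) = patsy.build_design_matrices([design], pred)
    exog = np.asarray(exog)
    adj = exog @ model.params.to_numpy()
    adjusted_means = dict(zip(levels, map(float, adj)))

    cov_beta = model.cov_params().to_numpy()
    posthoc = []
    for i, j in itertools.combinations(range(k), 2):
        c = exog[i] - exog[j]
        diff = float(adj[i] - adj[j])
        se = float(np.sqrt(c @ cov_beta @ c))
        t_val = diff / se
        posthoc.append(PosthocContrast(
            pair=(levels[i], levels[j]),
            t=t_val,
            p_tukey=_tukey_p(t_val, k, df_err),
            cohens_d=diff / np.sqrt(mse),
        ))
    return AncovaResult(
        F=F, df_effect=df_eff, df_error=df_err, p=p,
        partial_eta_sq=ss_eff / (ss_eff + ss_err),
        ss_effect=ss_eff, ss_error=ss_err, mse=mse,
        adjusted_means=adjusted_means, posthoc=posthoc,
        covariate_F=cov_F, covariate_p=cov_p,
    )


def oneway_anova(dependent, group) -> AncovaResult:
    """One-way between-subject ANOVA (ANCOVA without the covariate)."""
    return ancova(dependent, None, group)


# ---------------------------------------------------------------------------
# Circular statistics
# ---------------------------------------------------------------------------

def _kappa_from_r(r: float) -> float:
    """Standard approximation to the von Mises concentration MLE."""
    if r < 0.53:
        return 2 * r + r ** 3 + 5 * r ** 5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r ** 3 - 4 * r ** 2 + 3 * r)


def watson_williams(samples, warn_r: float = 0.45) -> CircularTestResult:
    """Watson-Williams k-sample test for equal circular means (degrees).

    F = K * (N-k)(sum R_i - R) / ((k-1)(N - sum R_i)) with R_i the group
    resultant lengths, R the pooled resultant length and K = 1 + 3/(8k)
    the concentration correction; p from F(k-1, N-k).  Warns when the
    pooled mean resultant length is below ``warn_r`` (test assumptions
    require concentrated samples).
    """
    groups = [np.radians(np.asarray(s, float)) for s in samples]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(len(gr) < 2 for gr in groups):
        raise ValueError("every group needs n >= 2")
    N = sum(len(gr) for gr in groups)
    Ci = np.array([np.sum(np.cos(gr)) for gr in groups])
    Si = np.array([np.sum(np.sin(gr)) for gr in groups])
    Ri = np.hypot(Ci, Si)
    R = float(np.hypot(Ci.sum(), Si.sum()))
    sum_Ri = float(Ri.sum())
    rw = sum_Ri / N
    if rw < warn_r:
        warnings.warn(
            f"mean resultant length {rw:.3f} < {warn_r}: Watson-Williams "
            "assumptions may be violated (samples too dispersed)")
    kappa = _kappa_from_r(rw)
    K = 1 + 3 / (8 * kappa)
    df1, df2 = k - 1, N - k
    denom = N - sum_Ri
    if denom <= 0:
        F = 0.0
    else:
        F = float(K * (df2 * (sum_Ri - R)) / (df1 * denom))
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df1, df2))
    means = {i: float(np.degrees(np.arctan2(Si[i], Ci[i])))
             for i in range(k)}
    return CircularTestResult(F=F, df1=df1, df2=df2, p=p,
                              group_mean_angles=means)


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------

def jzs_bf_ttest(t: float, n1: int, n2: int | None = None,
                 prior_scale: float = DEFAULT_CAUCHY_SCALE) -> BayesFactorResult:
    """Default JZS Bayes factor for a t statistic.

    BF10 = marginal likelihood of t under a Cauchy(0, scale) prior on the
    standardized effect size, over the point-null likelihood.  Two-sample
    designs use the effective sample size n1*n2/(n1+n2) and df n1+n2-2.
    """
    if n1 < 2 or (n2 is not None and n2 < 2):
        raise ValueError("sample sizes must be >= 2")
    if prior_scale <= 0:
        raise ValueError("prior_scale must be positive")
    if n2 is None:
        n_eff, df = float(n1), n1 - 1
    else:
        n_eff, df = n1 * n2 / (n1 + n2), n1 + n2 - 2

    def integrand(delta):
        return (stats.nct.pdf(t, df, delta * np.sqrt(n_eff))
                * stats.cauchy.pdf(delta, 0.0, prior_scale))

    lo, elo = integrate.quad(integrand, -np.inf, 0.0, limit=200)
    hi, ehi = integrate.quad(integrand, 0.0, np.inf, limit=200)
    num, err = lo + hi, elo + ehi
    if not np.isfinite(num) or (num > 0 and err / num > 1e-4):
        raise NumericalError(
            f"marginal likelihood integration did not converge "
            f"(value={num}, abserr={err})")
    denom = stats.t.pdf(t, df)
    return BayesFactorResult(bf10=num / denom, prior_scale=prior_scale,
                             method="jzs_t")


def _corr_likelihood_kernel(rho: float, r: float, n: int) -> float:
    """Sampling density of Pearson r given rho, up to rho-free factors."""
    return ((1 - rho ** 2) ** ((n - 1) / 2)
            * (1 - rho * r) ** (1.5 - n)
            * special.hyp2f1(0.5, 0.5, (2 * n - 1) / 2, (rho * r + 1) / 2))


def jeffreys_bf_correlation(r: float, n: int,
                            kappa: float = 1.0) -> BayesFactorResult:
    """Jeffreys-style Bayes factor for a Pearson correlation.

    The alternative places a stretched symmetric beta prior (width
    ``kappa``; kappa=1 is uniform on (-1, 1)) on the population
    correlation; the marginal likelihood is integrated numerically.
    """
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    if n < 4:
        raise ValueError("need n >= 4")
    a = 1.0 / kappa

    def prior(rho):
        # rho = 2u - 1, u ~ Beta(a, a)
        return stats.beta.pdf((rho + 1) / 2, a, a) / 2

    num, err = integrate.quad(
        lambda rho: _corr_likelihood_kernel(rho, r, n) * prior(rho),
        -1, 1, limit=200)
    if not np.isfinite(num) or (num > 0 and err / num > 1e-4):
        raise NumericalError("correlation BF integration did not converge")
    denom = _corr_likelihood_kernel(0.0, r, n)
    return BayesFactorResult(bf10=num / denom, prior_scale=kappa,
                             method="jeffreys_r")


def bf_inclusion_approx(model_with, model_without) -> BayesFactorResult:
    """BIC approximation to the inclusion Bayes factor of an effect.

    ``exp((BIC_without - BIC_with) / 2)`` for a nested pair of fitted
    linear models on identical data.  This approximates — it is not — the
    model-averaged inclusion BF reported by Bayesian-ANOVA software.
    """
    if model_with.nobs != model_without.nobs:
        raise ValueError("models were not fit on identical data")
    if model_with.df_model < model_without.df_model:
        raise ValueError("model_with must nest model_without")
    bf = float(np.exp((model_without.bic - model_with.bic) / 2.0))
    return BayesFactorResult(bf10=bf, prior_scale=np.nan,
                             method="bic_inclusion")


# ---------------------------------------------------------------------------
# Dependent correlations
# ---------------------------------------------------------------------------

def steiger_z(r_jk: float, r_jh: float, r_kh: float, n: int):
    """Steiger's Z for two dependent correlations sharing variable j.

    Tests r_jk = r_jh given the correlation r_kh between the two non-
    shared variables.  Returns (Z, two-sided p).
    """
    for r in (r_jk, r_jh, r_kh):
        if not abs(r) < 1:
            raise ValueError("all |r| must be < 1")
    if n < 4:
        raise ValueError("need n >= 4")
    det = (1 - r_jk ** 2 - r_jh ** 2 - r_kh ** 2
           + 2 * r_jk * r_jh * r_kh)
    if det < 0:
        warnings.warn("correlation triple is not positive semi-definite")
    z1, z2 = np.arctanh(r_jk), np.arctanh(r_jh)
    rbar = (r_jk + r_jh) / 2.0
    # covariance of the two dependent correlations (pooled-r form)
    psi = (r_kh * (1 - 2 * rbar ** 2)
           - 0.5 * rbar ** 2 * (1 - 2 * rbar ** 2 - r_kh ** 2))
    s = psi / (1 - rbar ** 2) ** 2
    Z = float(np.sqrt(n - 3) * (z1 - z2) / np.sqrt(2 - 2 * s))
    p = float(2 * stats.norm.sf(abs(Z)))
    return Z, p


# ---------------------------------------------------------------------------
# Basic tests
# ---------------------------------------------------------------------------

def pooled_t(x, y):
    """Pooled-variance two-sample t test: (t, df, p)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need n >= 2")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), len(x) + len(y) - 2, float(p)


def mann_whitney(x, y):
    """Mann-Whitney test: (W, p).

    W is the rank-sum-derived statistic of the first sample (its rank sum
    minus the minimum possible), with a tie-corrected normal
    approximation for p.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples need n >= 1")
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def pearson(x, y):
    """Pearson correlation with t-based p: (r, p)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def spearman(x, y):
    """Spearman rank correlation: (rs, p)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    rs, p = stats.spearmanr(x, y)
    return float(rs), float(p)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def results_to_frame(rows) -> pd.DataFrame:
    """Flatten (name, statistic, df, p, effect_size, bf) tuples/dicts."""
    out = []
    for row in rows:
        if isinstance(row, dict):
            out.append(row)
        else:
            name, statistic, df, p, effect, bf = row
            out.append({"test": name, "statistic": statistic, "df": df,
                        "p": p, "effect_size": effect, "bf": bf})
    return pd.DataFrame(out, columns=["test", "statistic", "df", "p",
                                      "effect_size", "bf"])
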