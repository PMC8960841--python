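"""Potential denitrification / N2O kinetics and fertilization-change tests.

In the acetylene-block assay each soil slurry is incubated in two bottles:
one with acetylene (blocking N2O reduction, so N2O accumulation measures the
full denitrification rate) and one without (measuring net potential N2O
production).  Headspace N2O is sampled every 0.5 h for 2.5 h; the
accumulation rate per bottle comes from regression of concentration on time,
and the denitrification end-product ratio N2O/(N2O + N2) is the rate without
acetylene divided by the rate with it.

Fertilization effects across field trials are summarized as per-site percent
change of site-mean metrics (fertilized vs unfertilized) and tested with an
exact two-sided Wilcoxon signed-rank test — exact because the number of
trials, not plots, is the experimental unit (N = 14 in the motivating
design).  An ANCOVA utility tests whether a covariate's effect (e.g. pH)
differs between treatments.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, stats

__all__ = [
    "RateFit",
    "fit_accumulation_rate",
    "end_product_ratio",
    "wilcoxon_exact",
    "percent_change_test",
    "ancova_interaction",
]

log = logging.getLogger(__name__)


@dataclass
class RateFit:
    rate: float
    model: str           # "linear" or "saturating"
    params: dict
    rss: float
    aic: float
    fallback: bool = False


def _aicc(rss: float, n: int, k: int) -> float:
    # small-sample AIC for least squares: n ln(rss/n) + 2k + correction
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return float(aic)


def fit_accumulation_rate(times, concentrations, model: str = "auto") -> RateFit:
    """Estimate the N2O accumulation rate of one bottle.

    linear: ``c(t) = c0 + rate * t`` (least squares).
    saturating: ``c(t) = c0 + A (1 - exp(-k t))`` with the rate taken as the
    initial slope ``A * k``.
    auto: both are fitted and the small-sample AIC picks the winner.
    Non-convergent saturating fits fall back to linear (flagged).  Rates are
    floored at zero.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 time points")
    if model not in ("linear", "saturating", "auto"):
        raise ValueError(f"unknown model {model!r}")

    A_ = np.column_stack([np.ones_like(t), t])
    coef, rss_lin, *_ = np.linalg.lstsq(A_, c, rcond=None)
    rss_lin = float(((c - A_ @ coef) ** 2).sum())
    lin = RateFit(
        rate=max(0.0, float(coef[1])),
        model="linear",
        params={"c0": float(coef[0]), "slope": float(coef[1])},
        rss=rss_lin,
        aic=_aicc(rss_lin, len(t), 2),
    )
    if model == "linear":
        return lin

    def sat(tv, c0, A, k):
        return c0 + A * (1 - np.exp(-k * tv))

    sat_fit = None
    try:
        span = max(c.max() - c.min(), 1e-9)
        p0 = (float(c[0]), float(span), 1.0)
        with np.errstate(over="ignore"):
            popt, _ = optimize.curve_fit(sat, t, c, p0=p0, maxfev=5000)
        resid = c - sat(t, *popt)
        rss = float((resid**2).sum())
        sat_fit = RateFit(
            rate=max(0.0, float(popt[1] * popt[2])),
            model="saturating",
            params={"c0": float(popt[0]), "A": float(popt[1]), "k": float(popt[2])},
            rss=rss,
            aic=_aicc(rss, len(t), 3),
        )
    except (RuntimeError, optimize.OptimizeWarning):
        pass

    if model == "saturating":
        if sat_fit is None:
            log.warning("saturating fit did not converge; falling back to linear")
            lin.fallback = True
            return lin
        return sat_fit
    # auto: AIC selection
    if sat_fit is None:
        lin.fallback = True
        return lin
    return sat_fit if sat_fit.aic < lin.aic else lin


def end_product_ratio(rate_no_acetylene: float, rate_acetylene: float) -> float:
    """N2O/(N2O + N2) proxy: potential N2O rate over potential denitrification."""
    if rate_acetylene <= 0:
        raise ValueError("denitrification rate must be positive for a defined ratio")
    ratio = rate_no_acetylene / rate_acetylene
    if ratio > 1:
        log.warning("end-product ratio %.3f exceeds 1 (flagged)", ratio)
    return float(ratio)


def wilcoxon_exact(diffs, enumerate_max: int = 20) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test; exact for small samples.

    Zero differences are dropped (Wilcoxon convention); ties in |d| get
    mid-ranks, and for n <= ``enumerate_max`` the p-value is computed by full
    enumeration of the 2^n sign assignments conditional on the observed
    |d|-ranks, which remains exact under mid-ranks.  Larger samples use the
    normal approximation with tie correction.
    Returns (W statistic = sum of positive ranks, p).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= enumerate_max:
        # distribution of sum of "positive" ranks over all sign assignments
        signs = np.array(list(itertools.product([0, 1], repeat=n)), dtype=float)
        w_all = signs @ ranks
        total = ranks.sum()
        # two-sided: distance from the null mean
        mu = total / 2.0
        p = float(np.mean(np.abs(w_all - mu) >= abs(w_pos - mu) - 1e-12))
        return w_pos, min(1.0, p)
    res = stats.wilcoxon(d, alternative="two-sided", method="approx")
    return w_pos, float(res.pvalue)


def percent_change_test(
    sample_frame: pd.DataFrame,
    metrics: list[str],
    site_col: str = "site",
    treatment_col: str = "treatment",
    fertilized: str = "fertilized",
    unfertilized: str = "unfertilized",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site percent change of site-mean metrics plus exact Wilcoxon p.

    ``change = 100 * (mean_fert - mean_unfert) / mean_unfert`` computed on
    site means (the trial, not the plot, is the unit).  Sites missing a
    treatment or with non-positive unfertilized mean are excluded (logged).
    Returns (long change table, per-metric test table).
    """
    changes = []
    tests = []
    for metric in metrics:
        means = (
            sample_frame.pivot_table(index=site_col, columns=treatment_col,
                                     values=metric, aggfunc="mean")
        )
        ok = means.notna().all(axis=1)
        if not ok.all():
            log.info("%s: excluding site(s) missing a treatment: %s",
                     metric, list(means.index[~ok]))
        means = means[ok]
        defined = means[unfertilized] > 0
        if not defined.all():
            log.warning("%s: percent change undefined for site(s) %s",
                        metric, list(means.index[~defined]))
        means = means[defined]
        pc = 100.0 * (means[fertilized] - means[unfertilized]) / means[unfertilized]
        for site, v in pc.items():
            changes.append({"site": site, "metric": metric, "percent_change": float(v)})
        w, p = wilcoxon_exact(pc.to_numpy())
        tests.append({"metric": metric, "n_sites": len(pc), "statistic": w,
                      "p_value": p, "median_change": float(pc.median())})
    return pd.DataFrame(changes), pd.DataFrame(tests).set_index("metric")


@dataclass
class AncovaResult:
    f_interaction: float
    df_num: int
    df_den: int
    p_interaction: float
    slopes: dict          # group -> standardized slope


def ancova_interaction(response, covariate, group) -> AncovaResult:
    """Does the covariate's slope differ between groups?

    Fits ``response ~ covariate * group`` and reports the interaction F with
    its degrees of freedom, plus the per-group standardized regression
    coefficient (slope on within-group z-scored variables).
    """
    df = pd.DataFrame({
        "y": np.asarray(response, dtype=float),
        "x": np.asarray(covariate, dtype=float),
        "g": np.asarray(group).astype(str),
    })
    if df["g"].nunique() < 2:
        raise ValueError("need at least two groups")
    fit = smf.ols("y ~ x * C(g)", data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("singular design")
    anova = sm.stats.anova_lm(fit, typ=2)
    inter = [i for i in anova.index if ":" in i][0]
    slopes = {}
    for g, sub in df.groupby("g"):
        zx = (sub["x"] - sub["x"].mean()) / sub["x"].std(ddof=1)
        zy = (sub["y"] - sub["y"].mean()) / sub["y"].std(ddof=1)
        slopes[g] = float(np.polyfit(zx, zy, 1)[0])
    return AncovaResult(
        f_interaction=float(anova.loc[inter, "F"]),
        df_num=int(anova.loc[inter, "df"]),
        df_den=int(anova.loc["Residual", "df"]),
        p_interaction=float(anova.loc[inter, "PR(>F)"]),
        slopes=slopes,
    )
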