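"""Community-level statistics: diversity, ordination, perMANOVA with strata,
per-balance mixed models and FDR control.

The centrepiece is :func:`fit_balance_lmm`: for every phylogenetic balance a
linear mixed model ``y = b0 + b1 * fertilized + u_site + e`` is fitted by REML
(random site intercept, fixed treatment), and the fertilization effect is
tested with a Wald F whose denominator degrees of freedom come from the
Satterthwaite approximation.  The REML profile is one-dimensional in the
variance ratio ``lambda = sigma_site^2 / sigma_e^2``, which makes fitting
thousands of balances cheap.  Paired designs (both treatments within each
site) mean the treatment contrast is a within-site comparison, so the site
variance cancels from its standard error — the reason multi-site designs have
power despite overwhelming between-site differences.

perMANOVA supports permutations restricted to within strata (field sites):
with unbalanced site/treatment allocation, free permutation confounds site
with treatment and inflates type-I error; restricted permutation does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.manifold import MDS
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BalanceTest",
    "PermanovaResult",
    "diversity",
    "nmds",
    "permanova",
    "fit_balance_lmm",
    "balance_test_table",
    "fdr_adjust",
    "associate_balances_ratio",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# diversity

def faith_pd_vector(matrix: pd.DataFrame, tree) -> np.ndarray:
    """Faith's PD per sample: branch length spanning present tips and root."""
    presence = {}
    pd_acc = np.zeros(matrix.shape[0])
    X = matrix.to_numpy(dtype=float)
    col = {c: j for j, c in enumerate(matrix.columns)}
    for node in tree.postorder():
        if node.is_tip():
            j = col.get(node.name)
            mask = (X[:, j] > 0) if j is not None else np.zeros(len(X), dtype=bool)
        else:
            mask = np.zeros(len(X), dtype=bool)
            for ch in node.children:
                mask |= presence.pop(id(ch))
        presence[id(node)] = mask
        if node.parent is not None and node.length:
            pd_acc += node.length * mask
    return pd_acc


def diversity(matrix: pd.DataFrame, tree=None) -> pd.DataFrame:
    """Shannon H' (natural log), richness S and Faith's PD per sample."""
    X = matrix.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("abundances must be non-negative")
    totals = X.sum(axis=1)
    empty = totals == 0
    if empty.any():
        log.warning("%d empty sample(s): diversity set to 0", int(empty.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(totals[:, None] > 0, X / np.where(totals[:, None] > 0, totals[:, None], 1), 0)
        H = -np.nansum(np.where(P > 0, P * np.log(P), 0.0), axis=1)
    out = pd.DataFrame(
        {"shannon": H, "richness": (X > 0).sum(axis=1)}, index=matrix.index
    )
    if tree is not None:
        out["faith_pd"] = faith_pd_vector(matrix, tree)
    return out


# ---------------------------------------------------------------------------
# ordination

def nmds(dist: np.ndarray, k: int = 2, seed: int | None = None, n_init: int = 4):
    """Non-metric MDS of a distance matrix; returns (coords, Kruskal stress-1)."""
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0, atol=1e-12):
        raise ValueError("distance matrix must have zero diagonal")
    m = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        n_init=n_init,
        random_state=seed,
        normalized_stress="auto",
        max_iter=500,
        eps=1e-9,
    )
    coords = m.fit_transform(D)
    return coords, float(m.stress_)


# ---------------------------------------------------------------------------
# perMANOVA

@dataclass
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int


def _ss_within(D2: np.ndarray, labels: np.ndarray, levels: np.ndarray) -> float:
    ssw = 0.0
    for lev in levels:
        idx = np.flatnonzero(labels == lev)
        ssw += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ssw


def permanova(
    dist: np.ndarray,
    groups,
    strata=None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational MANOVA on a distance matrix (Gower partition pseudo-F).

    ``R^2 = SS_between / SS_total``;
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.  When ``strata`` is
    given, group labels are permuted only within each stratum (restricted
    permutation); otherwise freely.
    """
    D = np.asarray(dist, dtype=float)
    labels = np.asarray(groups)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix / groups length mismatch")
    levels = np.unique(labels)
    if len(levels) < 2:
        raise ValueError("groups must have at least two levels")
    a = len(levels)
    D2 = D**2
    ss_total = D2.sum() / (2.0 * n)
    ssw = _ss_within(D2, labels, levels)
    ssa = ss_total - ssw
    f_obs = (ssa / (a - 1)) / (ssw / (n - a))
    rng = np.random.default_rng(seed)
    if strata is not None:
        strata = np.asarray(strata)
        groups_idx = [np.flatnonzero(strata == s) for s in np.unique(strata)]
        for g in groups_idx:
            if len(g) == 1:
                log.warning("stratum with a single sample contributes no permutation")
    count = 0
    for _ in range(n_perm):
        perm = labels.copy()
        if strata is None:
            perm = rng.permutation(labels)
        else:
            for g in groups_idx:
                perm[g] = labels[g][rng.permutation(len(g))]
        ssw_p = _ss_within(D2, perm, levels)
        f_p = ((ss_total - ssw_p) / (a - 1)) / (ssw_p / (n - a))
        if f_p >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(float(ssa / ss_total), float(f_obs), float(p), n_perm)


# ---------------------------------------------------------------------------
# per-balance linear mixed model

@dataclass
class BalanceTest:
    node: str
    beta: float
    f_ratio: float
    df_num: int
    df_den: float
    p_value: float
    direction: int
    sigma_site: float
    sigma_resid: float
    method: str
    singular: bool


class _GroupedDesign:
    """Sufficient statistics for a random-intercept model, grouped by site."""

    def __init__(self, X: np.ndarray, y: np.ndarray, site_codes: np.ndarray):
        order = np.argsort(site_codes, kind="stable")
        self.X = X[order]
        self.y = y[order]
        self.codes = site_codes[order]
        self.sizes = np.bincount(self.codes)
        self.bounds = np.concatenate([[0], np.cumsum(self.sizes)])
        self.n, self.p = X.shape
        # per-group cross products
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        self.Xs = np.array([
            self.X[a:b].sum(axis=0) for a, b in zip(self.bounds[:-1], self.bounds[1:])
        ])  # groups x p
        self.ys = np.array([
            self.y[a:b].sum() for a, b in zip(self.bounds[:-1], self.bounds[1:])
        ])

    def gls_parts(self, lam: float):
        """X'V0^-1 X, X'V0^-1 y, y'V0^-1 y for V0 = I + lam * ZZ'."""
        w = lam / (1.0 + self.sizes * lam)  # per group
        XtVX = self.XtX - (self.Xs.T * w) @ self.Xs
        XtVy = self.Xty - (self.Xs.T * w) @ self.ys
        ytVy = self.yty - float((w * self.ys) @ self.ys)
        return XtVX, XtVy, ytVy

    def reml_neg2(self, lam: float) -> float:
        XtVX, XtVy, ytVy = self.gls_parts(lam)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - float(beta @ XtVy)
        if rss <= 0:
            return np.inf
        logdetV = float(np.sum(np.log1p(self.sizes * lam)))
        sign, logdetXVX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        return (self.n - self.p) * np.log(rss) + logdetV + logdetXVX


def _satterthwaite(des: _GroupedDesign, lam: float, sig2e: float, contrast: np.ndarray):
    """Satterthwaite denominator df for c'beta in the random-intercept model."""
    n = des.n
    Z = np.zeros((n, len(des.sizes)))
    Z[np.arange(n), des.codes] = 1.0
    sig2s = lam * sig2e
    V = sig2e * np.eye(n) + sig2s * (Z @ Z.T)
    Vinv = np.linalg.inv(V)
    X = des.X
    XtVX = X.T @ Vinv @ X
    C = np.linalg.inv(XtVX)
    g = float(contrast @ C @ contrast)
    VinvX = Vinv @ X
    P = Vinv - VinvX @ C @ VinvX.T
    Vj = [Z @ Z.T, np.eye(n)]
    # gradient of c'Cc wrt (sig2s, sig2e)
    grad = np.array([
        float(contrast @ (C @ (X.T @ Vinv @ Vj[j] @ Vinv @ X) @ C) @ contrast)
        for j in range(2)
    ])
    # expected REML information of the variance components
    info = np.empty((2, 2))
    for j in range(2):
        for k in range(j, 2):
            info[j, k] = info[k, j] = 0.5 * np.trace(P @ Vj[j] @ P @ Vj[k])
    try:
        A = np.linalg.inv(info)
        denom = float(grad @ A @ grad)
        df = 2.0 * g**2 / denom if denom > 0 else n - des.p
    except np.linalg.LinAlgError:
        df = n - des.p
    return max(df, 1.0), g


def fit_balance_lmm(y, treatment, site, node: str = "") -> BalanceTest:
    """Mixed-model F-test of a fertilization effect on one balance.

    ``y = b0 + b1 * fertilized + u_site + e`` with ``u_site ~ N(0, s_site^2)``
    fitted by REML; returns the Wald F for the treatment term with
    Satterthwaite denominator df.  If the site variance collapses to zero the
    model is refitted as plain fixed-intercept OLS (pooled two-sample ANOVA F)
    and flagged singular.
    """
    y = np.asarray(y, dtype=float)
    tr = np.asarray(treatment)
    if tr.dtype.kind in "US O":
        levels = list(np.unique(tr))
        if len(levels) != 2:
            raise ValueError("treatment must have exactly two levels")
        # code the treated level as 1: "fertilized" when present, else the
        # second level in sorted order
        one = "fertilized" if "fertilized" in levels else levels[1]
        tr = (tr == one).astype(float)
    else:
        tr = tr.astype(float)
    sites, codes = np.unique(site, return_inverse=True)
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    X = np.column_stack([np.ones_like(y), tr])
    des = _GroupedDesign(X, y, codes)

    res = optimize.minimize_scalar(
        lambda phi: des.reml_neg2(np.exp(phi)), bounds=(-14.0, 14.0), method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(np.exp(res.x))
    if des.reml_neg2(0.0) <= res.fun:
        lam = 0.0
    singular = lam < 1e-6
    if singular:
        return _ols_fallback(y, tr, node)

    XtVX, XtVy, ytVy = des.gls_parts(lam)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - float(beta @ XtVy)
    sig2e = rss / (des.n - des.p)
    contrast = np.array([0.0, 1.0])
    df_den, var_b1 = _satterthwaite(des, lam, sig2e, contrast)
    f = float(beta[1] ** 2 / var_b1)
    p = float(stats.f.sf(f, 1, df_den))
    return BalanceTest(
        node=node,
        beta=float(beta[1]),
        f_ratio=f,
        df_num=1,
        df_den=float(df_den),
        p_value=p,
        direction=int(np.sign(beta[1])),
        sigma_site=float(np.sqrt(lam * sig2e)),
        sigma_resid=float(np.sqrt(sig2e)),
        method="reml_satterthwaite",
        singular=False,
    )


def _ols_fallback(y: np.ndarray, tr: np.ndarray, node: str) -> BalanceTest:
    n = len(y)
    X = np.column_stack([np.ones(n), tr])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sig2 = float(resid @ resid) / (n - 2)
    var_b1 = sig2 * np.linalg.inv(X.T @ X)[1, 1]
    f = float(beta[1] ** 2 / var_b1)
    return BalanceTest(
        node=node,
        beta=float(beta[1]),
        f_ratio=f,
        df_num=1,
        df_den=float(n - 2),
        p_value=float(stats.f.sf(f, 1, n - 2)),
        direction=int(np.sign(beta[1])),
        sigma_site=0.0,
        sigma_resid=float(np.sqrt(sig2)),
        method="ols_pooled",
        singular=True,
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def associate_balances_ratio(balances: pd.DataFrame, ratio) -> pd.DataFrame:
    """Spearman rho (and two-sided p) of each balance vs the end-product ratio.

    Constant balances get NaN rho with a flag.
    """
    r = np.asarray(ratio, dtype=float)
    rows = []
    for col in balances.columns:
        b = balances[col].to_numpy(dtype=float)
        if np.allclose(b, b[0]):
            rows.append({"node": col, "rho": np.nan, "p_rho": np.nan, "flag": "constant"})
            continue
        rho, p = stats.spearmanr(b, r)
        rows.append({"node": col, "rho": float(rho), "p_rho": float(p), "flag": ""})
    return pd.DataFrame(rows).set_index("node")


def balance_test_table(
    balances: pd.DataFrame,
    treatment,
    site,
    ratio=None,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Run the full per-balance testing chain used for tree annotation.

    Mixed-model F for every balance, BH correction over the family, and —
    for balances significant at ``q < q_threshold`` — Spearman association
    with the denitrification end-product ratio.
    """
    results = [fit_balance_lmm(balances[c], treatment, site, node=c) for c in balances.columns]
    tab = pd.DataFrame(
        {
            "node": [r.node for r in results],
            "beta": [r.beta for r in results],
            "f_ratio": [r.f_ratio for r in results],
            "df_num": [r.df_num for r in results],
            "df_den": [r.df_den for r in results],
            "p_raw": [r.p_value for r in results],
            "direction": [r.direction for r in results],
            "method": [r.method for r in results],
            "singular": [r.singular for r in results],
        }
    ).set_index("node")
    tab["q_fdr"] = fdr_adjust(tab["p_raw"].to_numpy())
    tab["rho_ratio"] = np.nan
    tab["p_rho"] = np.nan
    if ratio is not None:
        sig = tab.index[tab["q_fdr"] < q_threshold]
        if len(sig):
            assoc = associate_balances_ratio(balances[list(sig)], ratio)
            tab.loc[assoc.index, "rho_ratio"] = assoc["rho"]
            tab.loc[assoc.index, "p_rho"] = assoc["p_rho"]
    return tab
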