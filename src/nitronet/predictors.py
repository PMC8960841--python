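"""Boosted-regression modelling of denitrification end-product ratios.

The response is the ratio of potential N2O production (no acetylene) to
potential denitrification (acetylene block), modelled per treatment from
abiotic predictors (pH, Ca, C/N, nutrient pools), functional-gene abundances
(nirK, nirS, nosZ clades and the nosZ:nir ratio), community diversity and
module-eigengene abundances.  The contribution here is the procedure around
the estimator — grid-search tuning with K-fold CV, permutation variable
importance on the RMSE scale, and first-order accumulated local effects
(ALE) — so the booster itself is pluggable: anything with fit/predict works,
defaulting to scikit-learn's GradientBoostingRegressor.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold

__all__ = [
    "DEFAULT_GRID",
    "FittedModel",
    "ImportanceReport",
    "ALECurve",
    "tune_boosted_model",
    "permutation_importance",
    "ale_curve",
    "build_predictor_table",
]

log = logging.getLogger(__name__)

DEFAULT_GRID = {
    "n_estimators": [500, 1000, 2000],
    "learning_rate": [0.01, 0.05, 0.1],
    "max_depth": [1, 2, 3],
    "min_samples_leaf": [5, 10],
}


@dataclass
class FittedModel:
    model: object
    params: dict
    cv_rmse: float
    cv_table: pd.DataFrame


def _rmse(a, b) -> float:
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


def tune_boosted_model(
    X: pd.DataFrame,
    y,
    grid: dict | None = None,
    folds: int = 10,
    seed: int | None = None,
    estimator_factory=GradientBoostingRegressor,
) -> FittedModel:
    """Grid-search a boosted regression ensemble by K-fold CV RMSE.

    Ties are broken toward fewer trees, then smaller depth.  The winning
    configuration is refitted on all data.
    """
    y = np.asarray(y, dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError("response is constant; nothing to model")
    if len(y) < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    grid = grid or DEFAULT_GRID
    keys = list(grid)
    combos = [dict(zip(keys, v)) for v in itertools.product(*(grid[k] for k in keys))]
    if not combos:
        raise ValueError("empty hyperparameter grid")
    Xv = X.to_numpy(dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xv))
    rows = []
    for params in combos:
        errs = []
        for tr, te in splits:
            est = estimator_factory(random_state=seed, **params)
            est.fit(Xv[tr], y[tr])
            errs.append(_rmse(y[te], est.predict(Xv[te])))
        rows.append({**params, "cv_rmse": float(np.mean(errs))})
    tab = pd.DataFrame(rows)
    order = ["cv_rmse"]
    for k in ("n_estimators", "max_depth"):
        if k in tab.columns:
            order.append(k)
    best = tab.sort_values(order, kind="stable").iloc[0]
    params = {k: best[k] for k in keys}
    params = {k: (int(v) if float(v).is_integer() else float(v)) for k, v in params.items()}
    final = estimator_factory(random_state=seed, **params)
    final.fit(Xv, y)
    return FittedModel(model=final, params=params, cv_rmse=float(best["cv_rmse"]), cv_table=tab)


@dataclass
class ImportanceReport:
    table: pd.DataFrame  # per predictor: median_increase, rel_importance, quantiles
    top: list = field(default_factory=list)
    threshold_pct: float = 5.0


def permutation_importance(
    model,
    X: pd.DataFrame,
    y,
    n_perm: int = 500,
    seed: int | None = None,
    threshold_pct: float = 5.0,
) -> ImportanceReport:
    """Permutation variable importance on the RMSE scale.

    For each predictor, each of ``n_perm`` permutations shuffles that column
    and records the increase in RMSE over the unpermuted baseline.  The
    per-predictor importance is the median increase, floored at zero, and
    rescaled so the relative importances sum to 100%.  The top set holds
    predictors with median relative importance above ``threshold_pct``.
    """
    y = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    base = _rmse(y, model.predict(Xv))
    rows = []
    for j, name in enumerate(X.columns):
        inc = np.empty(n_perm)
        Xp = Xv.copy()
        for k in range(n_perm):
            Xp[:, j] = Xv[rng.permutation(len(y)), j]
            inc[k] = _rmse(y, model.predict(Xp)) - base
        Xp[:, j] = Xv[:, j]
        rows.append({
            "predictor": name,
            "median_increase": float(np.median(inc)),
            "q25": float(np.quantile(inc, 0.25)),
            "q75": float(np.quantile(inc, 0.75)),
        })
    tab = pd.DataFrame(rows).set_index("predictor")
    floored = tab["median_increase"].clip(lower=0.0)
    total = floored.sum()
    tab["rel_importance"] = 100.0 * floored / total if total > 0 else 0.0
    top = list(tab.index[tab["rel_importance"] > threshold_pct])
    return ImportanceReport(table=tab, top=top, threshold_pct=threshold_pct)


@dataclass
class ALECurve:
    predictor: str
    grid: np.ndarray       # bin edges (K+1 values)
    effects: np.ndarray    # centred accumulated effects at the edges
    counts: np.ndarray     # observations per bin
    flag: str = ""

    def slope(self) -> float:
        """Least-squares slope of the curve (effect per unit of predictor)."""
        if len(self.grid) < 2 or np.ptp(self.grid) == 0:
            return 0.0
        A = np.column_stack([np.ones_like(self.grid), self.grid])
        coef, *_ = np.linalg.lstsq(A, self.effects, rcond=None)
        return float(coef[1])


def ale_curve(model, X: pd.DataFrame, predictor: str, grid: int = 10) -> ALECurve:
    """First-order accumulated local effect of one predictor.

    The predictor range is cut at ``grid`` quantiles; within each bin the mean
    difference between model predictions at the upper and lower bin edge
    (other columns at their observed values) is accumulated, then centred by
    the observation-weighted mean so the curve averages ~0.
    """
    x = X[predictor].to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        return ALECurve(predictor, np.array([x[0], x[0]]), np.zeros(2),
                        np.array([len(x), 0]), flag="constant")
    qs = np.quantile(x, np.linspace(0, 1, grid + 1))
    edges = np.unique(qs)
    if len(edges) - 1 < grid:
        log.info("ALE for %r: %d distinct bins after merging duplicate quantiles",
                 predictor, len(edges) - 1)
    K = len(edges) - 1
    # assign observations to bins (left-closed, last bin right-closed)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, K - 1)
    local = np.zeros(K)
    counts = np.zeros(K, dtype=int)
    for k in range(K):
        sel = idx == k
        counts[k] = int(sel.sum())
        if counts[k] == 0:
            continue
        Xlo_k = X.loc[sel].copy()
        Xhi_k = X.loc[sel].copy()
        Xlo_k[predictor] = edges[k]
        Xhi_k[predictor] = edges[k + 1]
        local[k] = float(np.mean(model.predict(Xhi_k.to_numpy(dtype=float))
                                 - model.predict(Xlo_k.to_numpy(dtype=float))))
    acc = np.concatenate([[0.0], np.cumsum(local)])
    # centre: observation-weighted mean of per-bin midpoint effects
    mid = 0.5 * (acc[:-1] + acc[1:])
    centre = float(np.sum(mid * counts) / counts.sum())
    return ALECurve(predictor, edges, acc - centre, counts)


def build_predictor_table(
    sample_frame: pd.DataFrame,
    diversity: pd.DataFrame | None = None,
    eigengenes: pd.DataFrame | None = None,
    treatment: str | None = None,
    response: str = "end_product_ratio",
    gene_cols: tuple[str, str, str, str] = ("nosZI", "nosZII", "nirK", "nirS"),
    exclude: tuple[str, ...] = ("site", "treatment", "plot"),
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the (X, y) table for one treatment's end-product-ratio model.

    Adds ``nosZ_nir = (nosZI + nosZII) / (nirK + nirS)``, joins diversity
    indices and module eigengene values, subsets to ``treatment`` when given,
    drops samples missing the response (logged) and constant predictor
    columns (logged).
    """
    df = sample_frame.copy()
    zi, zii, nk, ns = gene_cols
    if all(c in df.columns for c in gene_cols):
        df["nosZ_nir"] = (df[zi] + df[zii]) / (df[nk] + df[ns])
    if treatment is not None:
        df = df[df["treatment"] == treatment]
    if diversity is not None:
        df = df.join(diversity, how="left")
    if eigengenes is not None:
        df = df.join(eigengenes, how="left")
    if response not in df.columns:
        raise ValueError(f"response column {response!r} missing")
    missing = df[response].isna()
    if missing.any():
        log.info("dropping %d sample(s) with missing response", int(missing.sum()))
        df = df[~missing]
    y = df[response].astype(float)
    X = df.drop(columns=[response, *[c for c in exclude if c in df.columns]])
    X = X.select_dtypes(include=[np.number]).astype(float)
    drop_activity = [c for c in ("potential_denitrification", "potential_n2o") if c in X.columns]
    X = X.drop(columns=drop_activity)
    const = [c for c in X.columns if X[c].nunique(dropna=True) <= 1]
    if const:
        log.info("dropping constant predictor column(s): %s", const)
        X = X.drop(columns=const)
    return X, y
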