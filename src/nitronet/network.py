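"""Treatment-wise co-association networks with random-matrix-theory
threshold selection, topology metrics, edge-betweenness modules and module
eigengenes.

The threshold is not a tuning knob: for each candidate cutoff the correlation
matrix is hard-thresholded and the nearest-neighbour spacing distribution
(NNSD) of its unfolded eigenvalue spectrum is tested against the exponential
law.  Below the threshold the matrix behaves like a Gaussian orthogonal
ensemble (level repulsion, Wigner surmise); once noise correlations are
removed the surviving block structure has uncorrelated eigenvalues and
Poisson (exponential) spacings.  The chosen cutoff r_T is the first one at
which a KS test no longer rejects the exponential (p > alpha).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .stats import fdr_adjust

__all__ = [
    "RMTScan",
    "TopologyReport",
    "ModuleEigengene",
    "correlation_matrix",
    "nnsd_test",
    "rmt_threshold",
    "build_graph",
    "topology_metrics",
    "er_null_test",
    "detect_modules",
    "module_eigengene",
    "correlate_modules",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# correlation + RMT threshold

def correlation_matrix(clr: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between CLR-transformed OTU profiles.

    Zero-variance OTUs are excluded (logged): their correlation is undefined.
    """
    X = clr.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for correlations")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        log.info("excluding %d zero-variance OTU(s) from correlation", int((~keep).sum()))
    cols = clr.columns[keep]
    R = np.corrcoef(X[:, keep], rowvar=False)
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=cols, columns=cols)


def _unfold(eigs: np.ndarray, n_knots: int = 25, merge_tol: float = 1e-10) -> np.ndarray:
    """Spacings of the spline-unfolded spectrum, normalized to unit mean.

    Degenerate eigenvalues (within ``merge_tol``) are merged before unfolding;
    the cumulative spectral function is approximated by a monotone cubic
    (PCHIP) interpolant through ~``n_knots`` quantile knots.
    """
    lam = np.sort(eigs)
    keep = np.concatenate([[True], np.diff(lam) > merge_tol])
    lam = lam[keep]
    m = len(lam)
    if m < 10:
        return np.array([])
    cdf = np.arange(1, m + 1, dtype=float)
    k = min(n_knots, max(4, m // 3))
    idx = np.unique(np.linspace(0, m - 1, k).round().astype(int))
    interp = PchipInterpolator(lam[idx], cdf[idx])
    unfolded = interp(lam)
    s = np.diff(unfolded)
    s = s[s > 0]
    if len(s) == 0:
        return np.array([])
    return s / s.mean()


def nnsd_test(spacings: np.ndarray, n_bins: int = 30) -> tuple[float, float, float]:
    """KS statistic/p of spacings vs Exp(1), plus SSE of the histogram vs e^-s."""
    if len(spacings) < 10:
        return np.nan, np.nan, np.nan
    ks, p = stats.kstest(spacings, "expon")
    hist, edges = np.histogram(spacings, bins=n_bins, range=(0, max(3.0, spacings.max())),
                               density=True)
    mids = 0.5 * (edges[:-1] + edges[1:])
    sse = float(np.sum((hist - np.exp(-mids)) ** 2))
    return float(ks), float(p), sse


@dataclass
class RMTScan:
    thresholds: np.ndarray
    ks_stat: np.ndarray
    ks_p: np.ndarray
    sse: np.ndarray
    n_eigen: np.ndarray
    r_t: float | None
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "ks_stat": self.ks_stat,
                "ks_p": self.ks_p,
                "sse": self.sse,
                "n_eigen": self.n_eigen,
            }
        )


def rmt_threshold(
    corr: pd.DataFrame,
    t_grid=None,
    alpha: float = 0.05,
    min_dim: int = 20,
) -> RMTScan:
    """Scan correlation cutoffs for the GOE-to-Poisson NNSD transition.

    For each threshold t the matrix entries with |r| < t are zeroed (diagonal
    kept), rows that lose all off-diagonal support are dropped, and the NNSD
    of the unfolded spectrum is KS-tested against Exp(1).  ``r_t`` is the
    smallest t whose KS p exceeds ``alpha``; ``None`` when no threshold in the
    grid passes ("no transition").
    """
    R = corr.to_numpy(dtype=float)
    n = R.shape[0]
    if n < 50:
        log.warning("correlation matrix is %dx%d; RMT spectra below 50x50 are noisy", n, n)
    if t_grid is None:
        t_grid = np.arange(0.50, 0.981, 0.01)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0) or t_grid.min() <= 0 or t_grid.max() >= 1:
        raise ValueError("t_grid must be strictly increasing within (0, 1)")
    ks_s, ks_p, sse_v, n_eig = [], [], [], []
    r_t = None
    for t in t_grid:
        A = np.where(np.abs(R) >= t, R, 0.0)
        np.fill_diagonal(A, 1.0)
        deg = (np.abs(A) > 0).sum(axis=1) - 1
        keep = deg > 0
        if keep.sum() < min_dim:
            ks_s.append(np.nan); ks_p.append(np.nan); sse_v.append(np.nan)
            n_eig.append(int(keep.sum()))
            continue
        lam = np.linalg.eigvalsh(A[np.ix_(keep, keep)])
        s = _unfold(lam)
        ks, p, sse = nnsd_test(s)
        ks_s.append(ks); ks_p.append(p); sse_v.append(sse); n_eig.append(len(lam))
        if r_t is None and np.isfinite(p) and p > alpha:
            r_t = float(t)
    return RMTScan(
        thresholds=t_grid,
        ks_stat=np.array(ks_s),
        ks_p=np.array(ks_p),
        sse=np.array(sse_v),
        n_eigen=np.array(n_eig),
        r_t=r_t,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# graph construction + topology

def build_graph(
    corr: pd.DataFrame,
    r_t: float,
    n_samples: int,
    fdr_q: float = 0.001,
) -> nx.Graph:
    """Signed weighted graph of correlations with |r| >= r_t.

    Correlation p-values (t-distribution) are BH-corrected over all pairs and
    any retained edge with q >= ``fdr_q`` is dropped (none expected at a high
    RMT threshold; logged if any).  Degree-zero nodes are removed; an empty
    result carries ``graph.graph["empty"] = True``.
    """
    if not (0 < r_t <= 1):
        raise ValueError("r_t must lie in (0, 1]")
    R = corr.to_numpy(dtype=float)
    names = list(corr.columns)
    iu = np.triu_indices_from(R, k=1)
    r = R[iu]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n_samples - 2) / np.maximum(1e-300, 1 - r**2))
    pvals = 2 * stats.t.sf(np.abs(tstat), df=n_samples - 2)
    qvals = fdr_adjust(np.clip(pvals, 0, 1))
    keep = np.abs(r) >= r_t
    insig = keep & (qvals >= fdr_q)
    if insig.any():
        log.warning("%d thresholded edge(s) failed the FDR filter and were dropped",
                    int(insig.sum()))
    keep &= qvals < fdr_q
    G = nx.Graph()
    for i, j, w in zip(iu[0][keep], iu[1][keep], r[keep]):
        G.add_edge(names[i], names[j], weight=float(w))
    G.graph["r_t"] = float(r_t)
    if G.number_of_edges() == 0:
        G.graph["empty"] = True
    return G


def positive_subgraph(G: nx.Graph) -> nx.Graph:
    H = nx.Graph()
    H.add_nodes_from(G.nodes(data=True))
    H.add_edges_from((u, v, d) for u, v, d in G.edges(data=True) if d.get("weight", 1) > 0)
    H.remove_nodes_from([n for n in H if H.degree(n) == 0])
    return H


@dataclass
class TopologyReport:
    nodes: int
    edges: int
    diameter: int
    avg_path_length: float
    avg_connectivity: float
    clustering_coefficient: float
    modularity: float
    connectance: float
    avg_jaccard: float
    connected: bool
    null_p: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _avg_jaccard(G: nx.Graph) -> float:
    vals = []
    for n in G:
        nb = set(G[n])
        if not nb:
            continue
        sims = []
        for m in nb:
            mb = set(G[m])
            union = nb | mb
            sims.append(len(nb & mb) / len(union) if union else 0.0)
        vals.append(np.mean(sims))
    return float(np.mean(vals)) if vals else 0.0


def topology_metrics(G: nx.Graph, positive_only: bool = True,
                     partition: list[set] | None = None) -> TopologyReport:
    """Topology of the (positive-edge) network.

    Path metrics are computed on the largest connected component (flagged when
    the graph is disconnected).  Modularity refers to the edge-betweenness
    partition (computed here if not supplied).
    """
    H = positive_subgraph(G) if positive_only else G
    if H.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    n, m = H.number_of_nodes(), H.number_of_edges()
    connected = nx.is_connected(H)
    lcc = H if connected else H.subgraph(max(nx.connected_components(H), key=len))
    diam = nx.diameter(lcc)
    apl = nx.average_shortest_path_length(lcc)
    if partition is None:
        partition = detect_modules(H, min_size=1)
    # complete the partition: nodes left unassigned by the min-size filter
    # (or absent from it) count as singletons for the modularity score
    covered = set().union(*partition) if partition else set()
    full = [set(p) & set(H.nodes()) for p in partition if set(p) & set(H.nodes())]
    full += [{n} for n in H.nodes() if n not in covered]
    modularity = nx.community.modularity(H, full) if m else 0.0
    return TopologyReport(
        nodes=n,
        edges=m,
        diameter=int(diam),
        avg_path_length=float(apl),
        avg_connectivity=float(2 * m / n),
        clustering_coefficient=float(nx.transitivity(H)),
        modularity=float(modularity),
        connectance=float(m / (n * (n - 1) / 2)),
        avg_jaccard=_avg_jaccard(H),
        connected=connected,
    )


_METRIC_FUNS = {
    "clustering_coefficient": nx.transitivity,
    "avg_path_length": lambda g: nx.average_shortest_path_length(
        g.subgraph(max(nx.connected_components(g), key=len))
    ),
    "diameter": lambda g: nx.diameter(g.subgraph(max(nx.connected_components(g), key=len))),
    "modularity": lambda g: nx.community.modularity(g, detect_modules(g, min_size=1)),
    "avg_connectivity": lambda g: 2 * g.number_of_edges() / g.number_of_nodes(),
    "avg_jaccard": _avg_jaccard,
}


def er_null_test(
    metric: str,
    observed: float,
    n_nodes: int,
    n_edges: int,
    reps: int = 1000,
    seed: int | None = None,
) -> float:
    """Two-tailed empirical p of a metric vs Erdos–Renyi G(n, m) nulls.

    ``p = 2 * min(#{null >= obs}, #{null <= obs}) / reps`` floored at 1/reps
    and capped at 1.  Null draws on which the metric is undefined are excluded
    (counted against ``reps``).
    """
    if n_edges > n_nodes * (n_nodes - 1) // 2:
        raise ValueError("n_edges exceeds the complete-graph capacity")
    fun = _METRIC_FUNS[metric]
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(reps):
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=int(rng.integers(2**31)))
        try:
            vals.append(fun(g))
        except (nx.NetworkXError, ZeroDivisionError, ValueError):
            continue
    vals = np.asarray(vals, dtype=float)
    if len(vals) == 0:
        return np.nan
    ge = int((vals >= observed).sum())
    le = int((vals <= observed).sum())
    p = 2 * min(ge, le) / reps
    return float(min(1.0, max(p, 1.0 / reps)))


# ---------------------------------------------------------------------------
# modules + eigengenes

def detect_modules(G: nx.Graph, min_size: int = 5) -> list[set]:
    """Edge-betweenness (Girvan–Newman) modules at maximum modularity.

    The full removal dendrogram is cut at the partition maximizing modularity;
    modules with >= ``min_size`` nodes are returned (smaller groups are left
    unassigned).  Positive-edge graphs are expected.
    """
    nodes = list(G.nodes())
    if not nodes:
        return []
    if G.number_of_edges() == 0:
        return [{n} for n in nodes if min_size <= 1]
    g = ig.Graph()
    g.add_vertices(len(nodes))
    index = {n: i for i, n in enumerate(nodes)}
    g.add_edges([(index[u], index[v]) for u, v in G.edges()])
    dendro = g.community_edge_betweenness(directed=False)
    clustering = dendro.as_clustering()  # cut maximizing modularity
    modules = [
        {nodes[i] for i in comm} for comm in clustering if len(comm) >= min_size
    ]
    return modules


@dataclass
class ModuleEigengene:
    module_id: str
    members: tuple[str, ...]
    eigenvector: np.ndarray  # per-sample values, unit norm
    sample_ids: tuple[str, ...]
    variance_explained: float
    oriented: bool


def module_eigengene(
    abundance: pd.DataFrame,
    members,
    module_id: str = "",
    orient_to_mean: bool = True,
) -> ModuleEigengene:
    """First principal component of a module's member abundance profiles.

    Columns (members) are standardized; the eigengene is the first left
    singular vector (unit norm, one value per sample) and variance explained
    is lambda_1 / sum(lambda).  The sign is oriented so the eigengene
    correlates positively with the mean standardized member abundance.
    """
    members = [m for m in members if m in abundance.columns]
    if len(members) < 5:
        raise ValueError("module must have at least 5 members present in the matrix")
    X = abundance[members].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        log.warning("dropping %d constant member column(s)", int((~keep).sum()))
        X = X[:, keep]
        members = [m for m, k in zip(members, keep) if k]
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    U, S, _ = np.linalg.svd(Xs, full_matrices=False)
    eig = U[:, 0]
    ve = float(S[0] ** 2 / np.sum(S**2))
    oriented = False
    if orient_to_mean:
        mean_profile = Xs.mean(axis=1)
        if np.dot(eig, mean_profile) < 0:
            eig = -eig
        oriented = True
    return ModuleEigengene(
        module_id=module_id,
        members=tuple(members),
        eigenvector=eig,
        sample_ids=tuple(abundance.index),
        variance_explained=ve,
        oriented=oriented,
    )


def correlate_modules(
    eigengenes: pd.DataFrame,
    covariates: pd.DataFrame,
    p_blank: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and p for every (module eigengene, covariate) pair.

    Returns (rho, p) DataFrames, modules x covariates.  All-missing covariate
    columns are skipped.  Rendering code may blank cells with p > ``p_blank``;
    the values themselves are always retained here.
    """
    cov = covariates.loc[eigengenes.index]
    rho = pd.DataFrame(index=eigengenes.columns, dtype=float)
    pv = pd.DataFrame(index=eigengenes.columns, dtype=float)
    for c in cov.columns:
        x = cov[c].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if ok.sum() < 3:
            log.warning("covariate %r all-missing or too short; skipped", c)
            continue
        rs, ps = [], []
        for m in eigengenes.columns:
            r_, p_ = stats.spearmanr(eigengenes[m].to_numpy()[ok], x[ok])
            rs.append(r_); ps.append(p_)
        rho[c] = rs
        pv[c] = ps
    return rho, pv
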