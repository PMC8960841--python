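"""Synthetic multi-site fertilization studies with recorded ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a multi-site paired design (default 14 sites x 2 treatments x 4 field
plots), frequently occurring OTUs with log-normal abundance and planted
correlated modules, sparse low-occupancy rare OTUs, treatment effects
concentrated on a phylogenetic clade, edaphic covariates with realistic
fertilization responses, and denitrification end-product ratios generated
from known biotic/abiotic drivers through a logistic link.

Co-association structure is planted at both the site and the plot level:
module members share one multivariate-normal latent factor per site and one
per sample, both with the module's block correlation.  Across-site
correlations of log abundances therefore approach ``rho_in`` within modules —
the signal the RMT-thresholded networks are meant to recover — while sites
still dominate total variance (site SD defaults to 1.5x the residual SD,
mirroring field studies where location explains most compositional
variance).

Every planted quantity is returned in a :class:`StudyTruth` so each pipeline
stage has a recovery test against known truth.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from skbio import TreeNode

__all__ = [
    "StudyTruth",
    "GasTimeseries",
    "generate_planted_correlation",
    "generate_gas_timeseries",
    "random_coalescent_tree",
    "generate_study",
]


@dataclass
class StudyTruth:
    """Ground truth of a generated study."""

    modules: dict                 # module name -> tuple of OTU ids
    rho_in: dict                  # treatment -> within-module latent correlation
    rho_out: float
    fert_effects: dict            # OTU id -> log-fold treatment effect
    effect_clade: tuple           # OTU ids carrying the planted clade effect
    site_sd: float
    resid_sd: float
    ratio_model: dict             # driver name -> coefficient (+ noise_sd, intercept)
    ratio_drivers: pd.DataFrame   # per-sample z-scored driver values actually used
    seed: int | None


@dataclass
class GasTimeseries:
    times: np.ndarray             # hours
    concentrations: np.ndarray    # N2O amount per bottle
    true_rate: float


def generate_planted_correlation(
    n_otus: int,
    modules: list[tuple[list[int], float]],
    rho_out: float = 0.0,
) -> np.ndarray:
    """Block-structured correlation matrix, repaired to PSD by eigenvalue clipping.

    ``modules`` is a list of (member index list, rho_in) pairs; indices must be
    disjoint.  Entries between distinct modules (and involving unassigned
    OTUs) are ``rho_out``.
    """
    seen: set[int] = set()
    for idx, rho in modules:
        if abs(rho) > 1:
            raise ValueError("|rho_in| must be <= 1")
        if seen & set(idx):
            raise ValueError("modules must be disjoint")
        if max(idx, default=-1) >= n_otus:
            raise ValueError("module index exceeds n_otus")
        seen |= set(idx)
    C = np.full((n_otus, n_otus), float(rho_out))
    for idx, rho in modules:
        ix = np.asarray(idx)
        C[np.ix_(ix, ix)] = rho
    np.fill_diagonal(C, 1.0)
    lam, U = np.linalg.eigh(C)
    if lam.min() < -1e-12:
        lam = np.clip(lam, 0.0, None)
        C = (U * lam) @ U.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
    else:
        C[np.abs(C) < 1e-15] = 0.0
    return C


def _factor(C: np.ndarray) -> np.ndarray:
    """Square-root factor of a PSD matrix (eigh-based; tolerates singularity)."""
    lam, U = np.linalg.eigh(C)
    return U * np.sqrt(np.clip(lam, 0.0, None))


def generate_gas_timeseries(
    true_rate: float,
    model: str = "linear",
    noise_sd: float = 0.0,
    seed: int | None = None,
    c0: float = 0.5,
    k: float = 1.0,
    t_max: float = 2.5,
    dt: float = 0.5,
) -> GasTimeseries:
    """One bottle's N2O series: 0.5-h sampling over 2.5 h (6 points).

    linear: ``c(t) = c0 + rate * t``; saturating: ``c(t) = c0 + A (1 - e^{-kt})``
    with ``A = rate / k`` so the initial slope equals ``true_rate``.  Gaussian
    noise is added; concentrations are floored at 0.
    """
    if true_rate < 0:
        raise ValueError("true_rate must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = np.arange(0.0, t_max + dt / 2, dt)
    if model == "linear":
        c = c0 + true_rate * t
    elif model == "saturating":
        if k <= 0:
            raise ValueError("k must be positive")
        c = c0 + (true_rate / k) * (1 - np.exp(-k * t))
    else:
        raise ValueError(f"unknown model {model!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        c = c + rng.normal(0, noise_sd, size=len(t))
    return GasTimeseries(times=t, concentrations=np.clip(c, 0.0, None),
                         true_rate=float(true_rate))


def random_coalescent_tree(labels: list[str], seed: int | None = None) -> TreeNode:
    """Kingman-coalescent tree over ``labels``: binary, heights scaled to 1."""
    rng = np.random.default_rng(seed)
    nodes = [(lab, 0.0) for lab in labels]
    k = len(nodes)
    height = 0.0
    while len(nodes) > 1:
        m = len(nodes)
        height += rng.exponential(2.0 / (m * (m - 1)))
        i, j = rng.choice(m, size=2, replace=False)
        (si, hi), (sj, hj) = nodes[i], nodes[j]
        merged = (f"({si}:{height - hi:.10g},{sj}:{height - hj:.10g})", height)
        nodes = [n for x, n in enumerate(nodes) if x not in (i, j)] + [merged]
    newick, h = nodes[0]
    tree = TreeNode.read(io.StringIO(newick + ";"))
    if h > 0:  # scale total height to 1
        for node in tree.traverse():
            if node.length is not None:
                node.length /= h
    return tree


def _pick_effect_clade(tree: TreeNode, frequent: set[str], lo: int, hi: int) -> tuple[str, ...]:
    """First preorder clade whose frequent-tip count falls within [lo, hi]."""
    for node in tree.preorder():
        if node.is_tip():
            continue
        tips = [t.name for t in node.tips() if t.name in frequent]
        if lo <= len(tips) <= hi:
            return tuple(tips)
    # fallback: first `lo` frequent tips
    return tuple(sorted(frequent))[:lo]


def generate_study(
    n_sites: int = 14,
    plots_per_treatment: int = 4,
    n_frequent: int = 600,
    n_rare: int = 3000,
    module_sizes: tuple[int, ...] = (40, 40, 30, 30),
    rho_in: float | dict = 0.8,
    rho_out: float = 0.0,
    fert_effect_size: float = 0.5,
    site_sd: float = 1.5,
    resid_sd: float = 1.0,
    sad_sd: float = 1.5,
    depth_mean: float = 4e4,
    depth_sigma: float = 0.3,
    ratio_coefs: dict | None = None,
    ratio_noise_sd: float = 0.3,
    ratio_fert_effect: float = 0.3,
    baseline_ratio: float = 0.35,
    seed: int | None = None,
):
    """Generate one study: (counts, sample frame, tree, truth).

    Defaults reproduce the design this package targets: 14 sites x
    {unfertilized, fertilized} x 4 plots (112 samples), 600 frequent OTUs with
    four planted modules, 3000 rare OTUs with occupancy < 25%, multinomial
    counts at log-normal depth (mean 4e4), and end-product ratios driven by
    pH (-), the abundance of module "B" (+) and the nosZ:nir gene ratio (-)
    through a logistic link.  ``fert_effect_size`` (log units) is applied to
    one phylogenetic clade of frequent OTUs; set it to 0 for a null study.
    """
    if n_sites < 2 or plots_per_treatment < 2:
        raise ValueError("need n_sites >= 2 and plots_per_treatment >= 2")
    if sum(module_sizes) > n_frequent:
        raise ValueError("module sizes exceed n_frequent")
    ss = np.random.SeedSequence(seed)
    (s_tree, s_sad, s_site, s_plot, s_rare, s_depth, s_counts,
     s_cov, s_ratio) = [np.random.default_rng(c) for c in ss.spawn(9)]

    treatments = ("unfertilized", "fertilized")
    if not isinstance(rho_in, dict):
        rho_in = {t: float(rho_in) for t in treatments}

    frequent_ids = [f"OTU{j:05d}" for j in range(n_frequent)]
    rare_ids = [f"OTU{j:05d}" for j in range(n_frequent, n_frequent + n_rare)]
    otu_ids = frequent_ids + rare_ids

    tree = random_coalescent_tree(otu_ids, seed=int(s_tree.integers(2**31)))

    # planted modules over the first sum(module_sizes) frequent OTUs
    names = [chr(ord("A") + i) for i in range(len(module_sizes))]
    modules: dict[str, tuple[str, ...]] = {}
    start = 0
    module_index: list[tuple[list[int], float]] = []
    for nm, size in zip(names, module_sizes):
        idx = list(range(start, start + size))
        modules[nm] = tuple(frequent_ids[i] for i in idx)
        module_index.append((idx, 1.0))  # rho filled per treatment below
        start += size

    factors = {}
    for t in treatments:
        C = generate_planted_correlation(
            n_frequent, [(idx, rho_in[t]) for idx, _ in module_index], rho_out
        )
        factors[t] = _factor(C)
    # site-level factor: treatment-average correlation (shared niche response)
    C_site = generate_planted_correlation(
        n_frequent,
        [(idx, float(np.mean([rho_in[t] for t in treatments]))) for idx, _ in module_index],
        rho_out,
    )
    F_site = _factor(C_site)

    # fertilization effect on one clade of frequent OTUs
    fert_effects: dict[str, float] = {}
    clade: tuple[str, ...] = ()
    if fert_effect_size != 0.0:
        lo = max(5, n_frequent // 40)
        hi = max(lo + 1, n_frequent // 10)
        clade = _pick_effect_clade(tree, set(frequent_ids), lo, hi)
        fert_effects = {o: float(fert_effect_size) for o in clade}

    sad = s_sad.normal(0.0, sad_sd, n_frequent)          # log-normal SAD
    site_latent = {
        s: site_sd * (F_site @ s_site.standard_normal(n_frequent))
        for s in range(n_sites)
    }

    rows = []
    meta = []
    rare_occ = s_rare.uniform(0.02, 0.20, n_rare)
    rare_logab = s_rare.normal(-2.5, 1.0, n_rare)
    delta = np.array([fert_effects.get(o, 0.0) for o in frequent_ids])

    for s in range(n_sites):
        for t in treatments:
            for p in range(plots_per_treatment):
                eps = resid_sd * (factors[t] @ s_plot.standard_normal(n_frequent))
                lat = sad + site_latent[s] + (delta if t == "fertilized" else 0.0) + eps
                w_freq = np.exp(lat)
                present = s_rare.random(n_rare) < rare_occ
                w_rare = np.where(present, np.exp(rare_logab), 0.0)
                rows.append((np.concatenate([w_freq, w_rare]), lat))
                meta.append({"site": f"S{s + 1:02d}", "treatment": t, "plot": p + 1})

    sample_ids = [
        f"{m['site']}-{'F' if m['treatment'] == 'fertilized' else 'U'}-{m['plot']}"
        for m in meta
    ]
    n_samples = len(rows)
    W = np.stack([r[0] for r in rows])
    latents = np.stack([r[1] for r in rows])
    P = W / W.sum(axis=1, keepdims=True)
    depths = np.round(
        np.exp(s_depth.normal(np.log(depth_mean), depth_sigma, n_samples))
    ).astype(np.int64)
    counts = np.stack([
        s_counts.multinomial(depths[i], P[i]) for i in range(n_samples)
    ])
    count_df = pd.DataFrame(counts, index=sample_ids, columns=otu_ids)

    # ----- covariates -----
    frame = pd.DataFrame(meta, index=sample_ids)
    fert = (frame["treatment"] == "fertilized").to_numpy()
    site_codes = pd.Categorical(frame["site"]).codes

    def site_based(base_mu, site_sigma, plot_sigma, fert_mult=1.0, lognorm=True):
        base = s_cov.normal(base_mu, site_sigma, n_sites)[site_codes]
        v = base + s_cov.normal(0, plot_sigma, n_samples)
        if lognorm:
            v = np.exp(v)
        return v * np.where(fert, fert_mult, 1.0)

    frame["pH"] = site_based(6.3, 0.6, 0.1, 1.0, lognorm=False)
    frame["org_C"] = site_based(np.log(2.0), 0.4, 0.08, 1.10)
    frame["tot_N"] = site_based(np.log(0.18), 0.4, 0.08, 1.12)
    frame["C_N"] = frame["org_C"] / frame["tot_N"]
    frame["NO3"] = site_based(np.log(8.0), 0.5, 0.15, 1.50)
    frame["NH4"] = site_based(np.log(4.0), 0.5, 0.15, 1.30)
    frame["P"] = site_based(np.log(50.0), 0.4, 0.10, 1.00)
    frame["Ca"] = site_based(np.log(2500.0), 0.4, 0.08, 1.14)
    frame["gene_16S"] = site_based(np.log(1e9), 0.5, 0.15, 1.05)
    frame["nirK"] = site_based(np.log(0.02), 0.4, 0.12, 1.30)
    frame["nirS"] = site_based(np.log(0.015), 0.4, 0.12, 1.00)
    frame["nosZI"] = site_based(np.log(0.01), 0.4, 0.12, 1.20)
    frame["nosZII"] = site_based(np.log(0.008), 0.4, 0.12, 1.13)

    # ----- end-product ratio from planted drivers -----
    if ratio_coefs is None:
        ratio_coefs = {"pH": -1.0, "module_B": 1.0, "nosZ_nir": -1.0}
    mod_b = modules.get("B", modules[names[0]])
    bidx = [frequent_ids.index(o) for o in mod_b]
    module_abund = latents[:, bidx].mean(axis=1)
    nosz_nir = (frame["nosZI"] + frame["nosZII"]) / (frame["nirK"] + frame["nirS"])

    def z(v):
        v = np.asarray(v, dtype=float)
        return (v - v.mean()) / v.std(ddof=0)

    drivers = pd.DataFrame(
        {"pH": z(frame["pH"]), "module_B": z(module_abund), "nosZ_nir": z(nosz_nir)},
        index=sample_ids,
    )
    eta = logit(baseline_ratio) + sum(
        ratio_coefs[k] * drivers[k].to_numpy() for k in ratio_coefs
    )
    # direct fertilization shift of the end-product ratio (log-odds scale),
    # on top of what flows through the drivers
    eta = eta + ratio_fert_effect * fert.astype(float)
    eta = eta + s_ratio.normal(0, ratio_noise_sd, n_samples)
    ratio = expit(eta)
    denit = site_based(np.log(100.0), 0.5, 0.2, 1.5)
    frame["potential_denitrification"] = denit
    frame["potential_n2o"] = ratio * denit
    frame["end_product_ratio"] = ratio

    truth = StudyTruth(
        modules=modules,
        rho_in=rho_in,
        rho_out=rho_out,
        fert_effects=fert_effects,
        effect_clade=clade,
        site_sd=site_sd,
        resid_sd=resid_sd,
        ratio_model={**ratio_coefs, "noise_sd": ratio_noise_sd,
                     "fert_effect": ratio_fert_effect,
                     "intercept": float(logit(baseline_ratio))},
        ratio_drivers=drivers,
        seed=seed,
    )
    return count_df, frame, tree, truth
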