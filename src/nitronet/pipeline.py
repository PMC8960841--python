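"""Pipeline orchestration: run the full analysis chain from a config dict.

A config names the inputs (or asks for a simulated study), an output
directory, a master seed and a set of stage toggles.  The master seed
deterministically derives one child seed per stage, so re-running any subset
of stages reproduces the same numbers.  Upstream results a stage depends on
are computed in memory as needed; only the outputs of *enabled* stages are
written to disk.  A JSON log records package versions, the config and the
derived seeds.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import __version__, activity, compare, composition, io, network, occupancy, predictors
from . import simulate as sim
from . import stats as cstats

__all__ = ["ConfigError", "STAGES", "default_config", "run_pipeline"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "transform", "diversity", "balances",
          "network", "compare", "gbm", "activity")


class ConfigError(ValueError):
    """Missing or inconsistent pipeline configuration."""


def default_config() -> dict:
    return {
        "seed": 0,
        "outdir": "nitronet_out",
        "simulate": {"enabled": True, "params": {}},
        "inputs": {},
        "stages": {s: True for s in STAGES},
        "filter": {"n_reps": 100, "alpha": 0.05, "depth": None},
        "network": {"t_start": 0.50, "t_stop": 0.98, "t_step": 0.01,
                    "er_reps": 0, "min_module": 5},
        "gbm": {"grid": None, "folds": 10, "n_perm": 500},
        "activity": {"metrics": ["potential_denitrification", "potential_n2o",
                                  "end_product_ratio"]},
    }


def _merge(base, override) -> dict:
    out = dict(base or {})
    for k, v in (override or {}).items():
        out[k] = _merge(base.get(k) or {}, v) if isinstance(v, dict) else v
    return out


def _seed_map(master: int | None) -> dict:
    children = np.random.SeedSequence(master).spawn(len(STAGES))
    return {s: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(STAGES, children)}


_FLOAT_FMT = "%.10g"


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, **kw)


def run_pipeline(config: dict) -> dict:
    """Run the enabled stages; returns {stage: [written paths]}."""
    cfg = _merge(default_config(), config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _seed_map(cfg["seed"])
    enabled = {s for s in STAGES if cfg["stages"].get(s, True)}
    written: dict[str, list[str]] = {s: [] for s in STAGES}

    def emit(stage: str, name: str, obj) -> None:
        if stage not in enabled:
            return
        path = outdir / name
        if isinstance(obj, pd.DataFrame):
            _write_tsv(obj, path)
        elif isinstance(obj, dict):
            path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
        else:
            obj(path)  # callable writer
        written[stage].append(str(path))

    # ----- inputs -----
    if cfg["simulate"]["enabled"]:
        counts, frame, tree, truth = sim.generate_study(
            seed=seeds["simulate"], **cfg["simulate"]["params"]
        )
        emit("simulate", "counts.tsv", counts)
        emit("simulate", "metadata.csv", lambda p: frame.to_csv(p, float_format=_FLOAT_FMT))
        emit("simulate", "tree.nwk", lambda p: io.write_tree(tree, p))
        emit("simulate", "truth.json", {
            "modules": {k: list(v) for k, v in truth.modules.items()},
            "rho_in": truth.rho_in, "rho_out": truth.rho_out,
            "fert_effects": truth.fert_effects,
            "ratio_model": truth.ratio_model, "seed": truth.seed,
        })
    else:
        inputs = cfg["inputs"]
        for key in ("counts", "tree", "metadata"):
            if key not in inputs:
                raise ConfigError(f"simulate disabled and inputs.{key} missing")
        counts = io.read_count_table(inputs["counts"],
                                     orientation=inputs.get("orientation", "auto"))
        tree = io.read_tree(inputs["tree"], resolve=True, seed=seeds["simulate"])
        frame = io.read_sample_frame(inputs["metadata"], exclude=inputs.get("exclude"))
        truth = None
    common = counts.index.intersection(frame.index)
    counts, frame = counts.loc[common], frame.loc[common]

    # ----- occupancy filter -----
    fcfg = cfg["filter"]
    depth = fcfg["depth"] or int(counts.sum(axis=1).min())
    rare_mean = occupancy.rarefy_mean(counts, depth, n_reps=fcfg["n_reps"],
                                      seed=seeds["filter"])
    disp = occupancy.dispersion_table(rare_mean)
    frequent, rare = occupancy.partition_frequent(disp, rare_mean.shape[0],
                                                  alpha=fcfg["alpha"])
    freq_cols = [c for c in counts.columns if c in frequent]
    emit("filter", "dispersion.tsv", disp)
    emit("filter", "frequent_otus.txt", lambda p: p.write_text("\n".join(freq_cols) + "\n"))
    emit("filter", "rare_otus.txt",
         lambda p: p.write_text("\n".join(sorted(rare)) + "\n"))

    # ----- compositional transforms (frequent OTUs, non-rarefied) -----
    fcounts = counts[freq_cols]
    imputed = composition.impute_zeros(fcounts)
    clr = composition.clr_transform(imputed)
    ftree = tree.shear(freq_cols)
    ftree.prune()
    balances, balance_meta = composition.philr_transform(imputed, ftree)
    emit("transform", "clr.tsv", clr)
    emit("transform", "balances.tsv", balances)
    emit("transform", "balance_nodes.json", {
        b.name: {"numerator": list(b.numerator), "denominator": list(b.denominator)}
        for b in balance_meta
    })

    # ----- diversity + ordination + perMANOVA -----
    if "diversity" in enabled:
        div = cstats.diversity(rare_mean[freq_cols], tree=ftree)
        emit("diversity", "diversity.tsv", div)
        D = squareform(pdist(balances.to_numpy()))
        coords, stress = cstats.nmds(D, seed=seeds["diversity"])
        emit("diversity", "nmds.tsv",
             pd.DataFrame(coords, index=balances.index, columns=["axis1", "axis2"]))
        res_t = cstats.permanova(D, frame["treatment"], strata=frame["site"],
                                 n_perm=1000, seed=seeds["diversity"])
        res_s = cstats.permanova(D, frame["site"], n_perm=1000, seed=seeds["diversity"])
        emit("diversity", "permanova.json", {
            "treatment_strata": res_t.__dict__, "site_free": res_s.__dict__,
            "nmds_stress": stress,
        })

    # ----- per-balance mixed models -----
    if "balances" in enabled:
        tab = cstats.balance_test_table(
            balances, frame["treatment"], frame["site"],
            ratio=frame.get("end_product_ratio"),
        )
        emit("balances", "balance_tests.tsv", tab)

    # ----- networks per treatment -----
    graphs, modules, eigengene_frames = {}, {}, {}
    if enabled & {"network", "compare", "gbm"}:
        ncfg = cfg["network"]
        t_grid = np.arange(ncfg["t_start"], ncfg["t_stop"] + ncfg["t_step"] / 2,
                           ncfg["t_step"])
        for treat in ("unfertilized", "fertilized"):
            mask = frame["treatment"] == treat
            sub = clr.loc[mask]
            corr = network.correlation_matrix(sub)
            scan = network.rmt_threshold(corr, t_grid=t_grid)
            r_t = scan.r_t if scan.r_t is not None else float(t_grid[-1])
            G = network.build_graph(corr, r_t, n_samples=int(mask.sum()))
            mods = network.detect_modules(network.positive_subgraph(G),
                                          min_size=ncfg["min_module"])
            graphs[treat], modules[treat] = G, mods
            eg = {}
            for i, mod in enumerate(mods):
                me = network.module_eigengene(sub, mod, module_id=f"M{i + 1}")
                eg[f"{treat[:1]}M{i + 1}"] = pd.Series(me.eigenvector, index=sub.index)
            eigengene_frames[treat] = pd.DataFrame(eg, index=sub.index)
            if "network" in enabled:
                emit("network", f"rmt_scan_{treat}.tsv", scan.to_frame())
                emit("network", f"network_{treat}.graphml",
                     lambda p, G=G: io.write_network(G, p, fmt="graphml"))
                emit("network", f"modules_{treat}.tsv", pd.DataFrame(
                    [(f"M{i + 1}", o) for i, mod in enumerate(mods) for o in sorted(mod)],
                    columns=["module", "otu"]))
                if G.number_of_edges():
                    topo = network.topology_metrics(G, partition=mods if mods else None)
                    if ncfg["er_reps"]:
                        for metric in ("clustering_coefficient", "avg_path_length",
                                       "modularity"):
                            topo.null_p[metric] = network.er_null_test(
                                metric, getattr(topo, metric), topo.nodes, topo.edges,
                                reps=ncfg["er_reps"], seed=seeds["network"])
                    emit("network", f"topology_{treat}.json", topo.to_dict())
                if not eigengene_frames[treat].empty:
                    emit("network", f"eigengenes_{treat}.tsv", eigengene_frames[treat])
                    cov_cols = [c for c in frame.columns
                                if c not in ("site", "treatment", "plot")]
                    rho, pv = network.correlate_modules(
                        eigengene_frames[treat], frame.loc[mask, cov_cols])
                    emit("network", f"module_correlations_{treat}.tsv", rho)
                    emit("network", f"module_correlation_p_{treat}.tsv", pv)

    # ----- network comparison -----
    if "compare" in enabled:
        diff = compare.diff_edges(graphs["unfertilized"], graphs["fertilized"])
        emit("compare", "edge_diff.tsv", diff.provenance())
        if set(graphs["unfertilized"]) & set(graphs["fertilized"]):
            emit("compare", "rewiring.tsv",
                 compare.rewiring_scores(graphs["unfertilized"], graphs["fertilized"]))
        emit("compare", "module_correspondence.json", {
            "pairs": compare.classify_module_membership(
                modules["unfertilized"], modules["fertilized"]
            ).to_dict(orient="records")
        })

    # ----- boosted regression -----
    if "gbm" in enabled:
        gcfg = cfg["gbm"]
        div = cstats.diversity(rare_mean[freq_cols], tree=ftree)
        for treat in ("unfertilized", "fertilized"):
            eg = eigengene_frames.get(treat)
            X, y = predictors.build_predictor_table(
                frame, diversity=div, eigengenes=eg if eg is not None and not eg.empty else None,
                treatment=treat)
            fit = predictors.tune_boosted_model(X, y, grid=gcfg["grid"],
                                                folds=gcfg["folds"], seed=seeds["gbm"])
            imp = predictors.permutation_importance(fit.model, X, y,
                                                    n_perm=gcfg["n_perm"],
                                                    seed=seeds["gbm"])
            emit("gbm", f"importance_{treat}.tsv", imp.table)
            emit("gbm", f"model_card_{treat}.json", {
                "params": fit.params, "cv_rmse": fit.cv_rmse,
                "seed": seeds["gbm"], "top_predictors": imp.top,
            })
            for pred in imp.top:
                curve = predictors.ale_curve(fit.model, X, pred)
                emit("gbm", f"ale_{treat}_{pred}.tsv", pd.DataFrame(
                    {"grid": curve.grid, "effect": curve.effects}))

    # ----- activity -----
    if "activity" in enabled:
        metrics = [m for m in cfg["activity"]["metrics"] if m in frame.columns]
        if not metrics:
            raise ConfigError("activity stage enabled but no activity columns present")
        changes, tests = activity.percent_change_test(frame, metrics)
        emit("activity", "site_changes.tsv", changes)
        emit("activity", "wilcoxon.tsv", tests)
        anc = activity.ancova_interaction(frame["end_product_ratio"], frame["pH"],
                                          frame["treatment"])
        emit("activity", "ancova_ph.json", anc.__dict__)

    log_doc = {
        "nitronet_version": __version__,
        "numpy_version": np.__version__,
        "seeds": seeds,
        "config": {k: v for k, v in cfg.items()},
    }
    (outdir / "run_log.json").write_text(
        json.dumps(log_doc, indent=2, sort_keys=True, default=str))
    return {s: p for s, p in written.items() if p}
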