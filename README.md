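# nitronet

Soil microbial communities control whether denitrification releases nitrous
oxide (N₂O, a potent greenhouse gas) or reduces it fully to harmless N₂.
Decades of mineral-N fertilization leave a legacy in these communities —
shifted clades, rewired co-occurrence structure, altered gene inventories —
and with it, altered controls of the denitrification end-product ratio
N₂O/(N₂O + N₂).  `nitronet` is a reusable, tested implementation of the
analysis chain needed to quantify that legacy from multi-site paired
fertilization trials:

1. **Occupancy filtering** — partition OTUs into *frequent* and *rare* by the
   index of dispersion `I = (σ²/μ)·O` on mean rarefied abundances, tested
   against the upper tail of χ²₍ₙ₋₁₎.
2. **Compositional transforms** — Bayesian-multiplicative zero replacement,
   centred log-ratio (CLR), and the phylogenetic isometric log-ratio (PhILR):
   one orthonormal balance per internal node of the OTU phylogeny,
   `b_v = √(n_L n_R/(n_L+n_R)) · ln(g(x_L)/g(x_R))`.
3. **Community statistics** — Shannon H′, richness, Faith's PD, non-metric
   MDS, perMANOVA with permutations restricted to within field sites, and a
   per-balance linear mixed model `y = β₀ + β₁·fertilized + u_site + ε` (REML,
   Satterthwaite denominator df) with Benjamini–Hochberg control across
   balances.
4. **Co-association networks** — Pearson correlations of CLR abundances per
   treatment, hard threshold `r_T` chosen by random-matrix theory (the
   GOE → Poisson transition of the nearest-neighbour eigenvalue spacing
   distribution), topology metrics with Erdős–Rényi nulls, edge-betweenness
   (Girvan–Newman) modules, and module eigengenes (first PC of member
   abundances).
5. **Network comparison** — common/unique edge sets and per-node DyNet-style
   rewiring scores between unfertilized and fertilized networks.
6. **Drivers of the end-product ratio** — gradient-boosted regression with
   grid-search CV, permutation variable importance (median RMSE increase,
   rescaled to %), and accumulated local effects (ALE) curves.
7. **Activity kinetics** — N₂O accumulation rates from 0.5-h gas series
   (linear or saturating fits, AIC-selected), end-product ratios, per-site
   percent-change with exact Wilcoxon signed-rank tests, and ANCOVA of
   covariate × treatment interactions.

A synthetic-study generator (`nitronet.simulate`) produces multi-site paired
designs with planted correlation modules, clade-level treatment effects and
known drivers of the end-product ratio, so every stage has a recovery test
against recorded ground truth.

## Worked example

```python
import numpy as np
from nitronet import simulate, occupancy, composition, network

counts, frame, tree, truth = simulate.generate_study(
    n_frequent=150, n_rare=600, module_sizes=(25, 25, 20, 20), seed=3)
print(counts.shape)                       # (112, 750): 14 sites x 2 x 4 plots

depth = int(counts.sum(axis=1).min())
rarefied = occupancy.rarefy_mean(counts, depth, n_reps=100, seed=0)
disp = occupancy.dispersion_table(rarefied)
frequent, rare = occupancy.partition_frequent(disp, counts.shape[0])
print(len(frequent & set(counts.columns[:150])) / 150)   # 1.0

clr = composition.clr_transform(
    composition.impute_zeros(counts[sorted(frequent)]))
sub = clr.loc[frame["treatment"] == "unfertilized"]
corr = network.correlation_matrix(sub)
scan = network.rmt_threshold(corr)
print(scan.r_t)                           # 0.56
G = network.build_graph(corr, scan.r_t, n_samples=len(sub))
modules = network.detect_modules(network.positive_subgraph(G))
print([len(m) for m in modules])          # [25, 20, 25, 22]
```

All 150 planted frequent OTUs pass the dispersion filter.  The RMT scan
chooses `r_T = 0.56`, above the bulk of noise correlations (|r| ≲ 0.5 at 56
samples) and below the planted within-module correlations (mean |r| ≈ 0.76),
and edge-betweenness module detection recovers the four planted modules
(adjusted Rand index 1.0 against truth).

The same analyses run from the shell on simulated or real inputs:

```bash
nitronet all --seed 11 --outdir results/      # full chain
nitronet network --config my_study.yaml       # one stage
```

where a config names a count table (TSV or BIOM 1.0 JSON), a Newick
phylogeny and a sample metadata CSV.

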