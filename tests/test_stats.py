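import io

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from statsmodels.regression.mixed_linear_model import MixedLM

from nitronet import stats


class TestDiversity:
    def test_uniform_shannon(self):
        m = pd.DataFrame([[1.0] * 10])
        out = stats.diversity(m)
        assert out["shannon"].iloc[0] == pytest.approx(np.log(10))
        assert out["richness"].iloc[0] == 10

    def test_single_otu(self):
        out = stats.diversity(pd.DataFrame([[5.0, 0.0]]))
        assert out["shannon"].iloc[0] == 0.0
        assert out["richness"].iloc[0] == 1

    def test_star_tree_pd(self):
        tree = TreeNode.read(io.StringIO("(A:1,B:1,C:1,D:1,E:1,F:1,G:1,H:1);"))
        m = pd.DataFrame([[1, 1, 1, 1, 1, 0, 0, 0]], columns=list("ABCDEFGH"),
                         dtype=float)
        out = stats.diversity(m, tree=tree)
        assert out["faith_pd"].iloc[0] == pytest.approx(5.0)

    def test_empty_sample_zeroes_with_warning(self, caplog):
        out = stats.diversity(pd.DataFrame([[0.0, 0.0], [1.0, 1.0]]))
        assert out.iloc[0].tolist() == [0.0, 0]

    def test_shannon_bounded_by_log_richness(self, rng):
        m = pd.DataFrame(rng.poisson(2.0, size=(20, 30)).astype(float))
        out = stats.diversity(m)
        ok = out["richness"] > 0
        assert (out.loc[ok, "shannon"] <= np.log(out.loc[ok, "richness"]) + 1e-9).all()


class TestNMDS:
    def test_equilateral_three_points(self):
        D = np.ones((3, 3)) - np.eye(3)
        coords, stress = stats.nmds(D, seed=0)
        d = pdist(coords)
        assert stress < 0.01
        assert np.allclose(d, d[0], rtol=0.05)

    def test_planar_configuration_recovered(self, rng):
        pts = rng.normal(size=(12, 2))
        D = squareform(pdist(pts))
        _, stress = stats.nmds(D, seed=0, n_init=8)
        assert stress < 0.01

    def test_asymmetric_input_errors(self):
        with pytest.raises(ValueError, match="symmetric"):
            stats.nmds(np.array([[0, 1.0], [2.0, 0]]))


class TestPermanova:
    def test_identical_labels_error(self):
        D = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="two levels"):
            stats.permanova(D, ["a", "a", "a", "a"])

    def test_perfect_separation(self, rng):
        a = np.tile([0.0, 0.0], (8, 1)) + rng.normal(0, 1e-6, (8, 2))
        b = np.tile([10.0, 10.0], (8, 1)) + rng.normal(0, 1e-6, (8, 2))
        D = squareform(pdist(np.vstack([a, b])))
        res = stats.permanova(D, ["g1"] * 8 + ["g2"] * 8, n_perm=199, seed=0)
        assert res.r_squared > 0.999
        # every permuted F is smaller (regrouping collisions are ~2/C(16,8))
        assert res.p_value == pytest.approx(1 / 200)

    def test_matches_skbio_pseudo_f(self, rng):
        """Dual route: our Gower-partition F equals skbio's permanova F."""
        X = rng.normal(size=(18, 4))
        D = squareform(pdist(X))
        groups = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        ours = stats.permanova(D, groups, n_perm=99, seed=1)
        ids = [str(i) for i in range(18)]
        theirs = skbio_permanova(DistanceMatrix(D, ids), grouping=groups,
                                 permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_strata_restriction_controls_site_confounding(self, rng):
        """With unbalanced site/treatment allocation and strong site effects,
        free permutation is anticonservative; within-site permutation is not.
        (Small-scale version of the type-I error contrast.)"""
        reject_free = reject_strata = 0
        n_sims = 60
        for s in range(n_sims):
            r = np.random.default_rng(s)
            site = np.repeat(np.arange(6), 6)
            # alternate 5:1 and 1:5 allocation -> treatment confounded w/ site
            tr = np.concatenate([([0]*5 + [1]) if k % 2 else ([0] + [1]*5)
                                 for k in range(6)])
            X = np.repeat(r.normal(0, 3, (6, 2)), 6, axis=0) + r.normal(0, 1, (36, 2))
            D = squareform(pdist(X))
            free = stats.permanova(D, tr, n_perm=99, seed=s)
            strat = stats.permanova(D, tr, strata=site, n_perm=99, seed=s)
            reject_free += free.p_value < 0.05
            reject_strata += strat.p_value < 0.05
        assert reject_strata / n_sims < 0.12
        assert reject_free / n_sims > reject_strata / n_sims


class TestBalanceLMM:
    def _design(self, n_sites=8, plots=4, seed=1, beta=0.5, s_site=1.2, s_e=1.0):
        rng = np.random.default_rng(seed)
        site = np.repeat(np.arange(n_sites), 2 * plots)
        treat = np.tile([0] * plots + [1] * plots, n_sites)
        y = beta * treat + np.repeat(rng.normal(0, s_site, n_sites), 2 * plots) \
            + rng.normal(0, s_e, n_sites * 2 * plots)
        return y, treat, site

    def test_matches_statsmodels_reml(self):
        """Dual route: REML variance components and Wald F vs MixedLM."""
        y, treat, site = self._design()
        ours = stats.fit_balance_lmm(y, treat, site)
        X = np.column_stack([np.ones_like(y), treat])
        sm = MixedLM(y, X, groups=site).fit(reml=True)
        assert ours.beta == pytest.approx(sm.params[1], abs=1e-5)
        assert ours.sigma_site == pytest.approx(
            np.sqrt(float(np.asarray(sm.cov_re)[0, 0])), abs=1e-4)
        assert ours.sigma_resid == pytest.approx(np.sqrt(sm.scale), abs=1e-4)
        assert ours.f_ratio == pytest.approx(sm.tvalues[1] ** 2, rel=1e-4)

    def test_zero_site_variance_matches_pooled_anova(self):
        from scipy.stats import f_oneway
        y, treat, site = self._design(s_site=0.0, seed=7)
        # remove between-site mean differences entirely so the REML estimate
        # of the site variance collapses to the boundary
        for s in np.unique(site):
            y[site == s] -= y[site == s].mean()
        y += 0.3 * treat
        res = stats.fit_balance_lmm(y, treat, site)
        ref = f_oneway(y[treat == 0], y[treat == 1]).statistic
        assert res.singular
        assert res.method == "ols_pooled"
        assert res.f_ratio == pytest.approx(ref, abs=1e-6)

    def test_effect_recovery(self):
        y, treat, site = self._design(n_sites=14, plots=6, beta=1.0, s_e=0.1, seed=2)
        res = stats.fit_balance_lmm(y, treat, site)
        assert res.beta == pytest.approx(1.0, abs=0.05)
        assert res.direction == 1

    def test_null_rejection_rate_calibrated(self):
        """Type-I error of the Satterthwaite F at alpha = 0.01."""
        n_reps, alpha, rejections = 400, 0.01, 0
        for s in range(n_reps):
            y, treat, site = self._design(n_sites=14, plots=4, beta=0.0, seed=s)
            if stats.fit_balance_lmm(y, treat, site).p_value < alpha:
                rejections += 1
        assert abs(rejections / n_reps - alpha) < 0.012

    def test_one_site_errors(self):
        with pytest.raises(ValueError, match="2 sites"):
            stats.fit_balance_lmm([1.0, 2, 3, 4], [0, 1, 0, 1], [0, 0, 0, 0])


class TestFDR:
    def test_flat_p_unchanged(self):
        assert np.allclose(stats.fdr_adjust([0.5] * 4), 0.5)

    def test_bh_hand_computation(self):
        # p=(.01,.02,.03), m=3: q_i = min over j>=i of p_j * m / j -> all .03
        q = stats.fdr_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=50)
        assert (stats.fdr_adjust(p) >= p - 1e-12).all()

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            stats.fdr_adjust([0.5, 1.5])


class TestRatioAssociation:
    def test_perfect_monotone(self, rng):
        ratio = rng.uniform(size=20)
        b = pd.DataFrame({"n1": np.argsort(np.argsort(ratio)).astype(float),
                          "n2": -ratio})
        out = stats.associate_balances_ratio(b, ratio)
        assert out.loc["n1", "rho"] == pytest.approx(1.0)
        assert out.loc["n2", "rho"] == pytest.approx(-1.0)

    def test_constant_balance_flagged(self):
        b = pd.DataFrame({"n1": [1.0, 1.0, 1.0, 1.0]})
        out = stats.associate_balances_ratio(b, [0.1, 0.2, 0.3, 0.4])
        assert np.isnan(out.loc["n1", "rho"])
        assert out.loc["n1", "flag"] == "constant"


class TestBalanceTestTable:
    def test_full_chain_on_planted_effect(self, rng):
        site = np.repeat([f"S{i}" for i in range(10)], 8)
        treat = np.tile(["unfertilized"] * 4 + ["fertilized"] * 4, 10)
        n = len(site)
        bal = pd.DataFrame({
            "hit": 1.0 * (treat == "fertilized") + rng.normal(0, 0.3, n),
            "null1": rng.normal(0, 1, n),
            "null2": rng.normal(0, 1, n),
        })
        ratio = bal["hit"] * 0.1 + rng.normal(0, 0.01, n)
        tab = stats.balance_test_table(bal, treat, site, ratio=ratio)
        assert tab.loc["hit", "q_fdr"] < 0.01
        assert tab.loc["hit", "direction"] == 1
        assert tab.loc["hit", "rho_ratio"] > 0.8
        assert (tab["q_fdr"] >= tab["p_raw"] - 1e-12).all()
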