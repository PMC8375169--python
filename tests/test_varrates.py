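"""Variable-rates regression: GLS likelihood, RJ-MCMC, stepping stone, BF."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from ratelink import simdata as sd
from ratelink import treedata as td
from ratelink import varrates as vr


@pytest.fixture(scope="module")
def trait_setup():
    rng = np.random.default_rng(7)
    tree = sd.simulate_tree(48, 300.0, rng)
    scn = sd.SimulationScenario(n_taxa=48)
    traits, r_true, info = sd.simulate_varrates_traits(tree, scn, rng)
    design = vr.design_from_traits(traits)
    return tree, scn, traits, r_true, info, design


class TestGlsLoglik:
    def test_identity_covariance_zero_residuals(self):
        y = np.array([1.0, 2.0])
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        d = vr.RegressionDesign(y, X, ["a", "b"], ["s1", "s2"])
        st = vr.VarRatesState(beta=np.array([1.0, 2.0]), sigma2=1.0)
        ll = vr.gls_loglik(d, np.eye(2), st)
        assert ll == pytest.approx(-math.log(2 * math.pi), abs=1e-9)

    def test_matches_mvn_oracle_three_taxa(self, three_taxon_tree):
        V, order = td.phylo_covariance(three_taxon_tree)
        y = np.array([0.4, -0.1, 0.3])
        X = np.column_stack([np.ones(3), [0.2, 0.5, -0.3]])
        d = vr.RegressionDesign(y, X, ["int", "x"], order)
        st = vr.VarRatesState(beta=np.array([0.1, 0.2]), sigma2=0.6)
        oracle = multivariate_normal.logpdf(y, mean=X @ st.beta, cov=0.6 * V)
        assert vr.gls_loglik(d, V, st) == pytest.approx(oracle, abs=1e-8)

    def test_scale_confounding_identity(self, three_taxon_tree):
        # multiplying branch lengths by c and sigma2 by 1/c leaves lnL unchanged
        V, order = td.phylo_covariance(three_taxon_tree)
        y = np.array([0.4, -0.1, 0.3])
        X = np.ones((3, 1))
        d = vr.RegressionDesign(y, X, ["int"], order)
        st1 = vr.VarRatesState(beta=np.array([0.0]), sigma2=0.5)
        st2 = vr.VarRatesState(beta=np.array([0.0]), sigma2=0.5 / 3.0)
        assert vr.gls_loglik(d, V, st1) == pytest.approx(
            vr.gls_loglik(d, 3.0 * V, st2), abs=1e-9)

    def test_brute_force_on_random_small_trees(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            tree = sd.simulate_tree(6, 20.0, rng)
            V, order = td.phylo_covariance(tree)
            y = rng.normal(size=6)
            X = np.column_stack([np.ones(6), rng.normal(size=6)])
            d = vr.RegressionDesign(y, X, ["int", "x"], order)
            st = vr.VarRatesState(beta=rng.normal(size=2), sigma2=0.8)
            oracle = multivariate_normal.logpdf(
                y, mean=X @ st.beta,
                cov=0.8 * (V + np.eye(6) * 1e-10 * V.diagonal().mean()))
            assert vr.gls_loglik(d, V, st) == pytest.approx(oracle, abs=1e-8)


class TestMcmc:
    def test_determinism(self, trait_setup):
        tree, _, _, _, _, design = trait_setup
        cfg = vr.VarRatesConfig(iterations=5_000, n_samples=50)
        t1 = vr.varrates_mcmc(design, tree, cfg, seed=3)
        t2 = vr.varrates_mcmc(design, tree, cfg, seed=3)
        assert np.array_equal(t1.loglik, t2.loglik)
        assert np.array_equal(t1.sigma2, t2.sigma2)
        assert t1.scalars == t2.scalars

    def test_recovery_of_fast_branches(self, trait_setup):
        tree, scn, traits, r_true, info, design = trait_setup
        cfg = vr.VarRatesConfig(iterations=300_000, n_samples=500)
        trace = vr.varrates_mcmc(design, tree, cfg, seed=11)
        rmap, rt_tree = vr.median_rate_tree(trace, tree)
        fast = info["fast_keys"]
        mf = np.array([v for k, v in rmap.values.items() if k in fast])
        ms = np.array([v for k, v in rmap.values.items() if k not in fast])
        # the strongest rate signals all sit on planted branches, and the
        # planted set exceeds the background on aggregate
        top = sorted(rmap.values.items(), key=lambda kv: -kv[1])[:3]
        assert all(k in fast for k, _ in top)
        assert mf.mean() > ms.mean()
        assert mf.max() > 2.0

    def test_sigma2_recovery_homogeneous(self):
        rng = np.random.default_rng(19)
        tree = sd.simulate_tree(48, 300.0, rng)
        scn = sd.SimulationScenario(n_taxa=48, r_fast=1.0 + 1e-9)
        traits, _, _ = sd.simulate_varrates_traits(tree, scn, rng)
        design = vr.design_from_traits(traits)
        cfg = vr.VarRatesConfig(iterations=60_000, n_samples=300)
        trace = vr.varrates_mcmc(design, tree, cfg, seed=2, rj=False)
        lo, hi = np.percentile(trace.sigma2, [2.5, 97.5])
        assert lo < scn.sigma2_b < hi

    def test_median_rate_tree_counts_unscaled_as_one(self, trait_setup):
        tree, _, _, _, _, design = trait_setup
        cfg = vr.VarRatesConfig(iterations=3_000, n_samples=30)
        trace = vr.varrates_mcmc(design, tree, cfg, seed=5)
        # fabricate a trace where one branch is scaled in 1 of 3 samples
        key = trace.branch_keys[0]
        trace.scalars = [{key: 3.0}, {}, {}]
        trace.iterations = np.array([1, 2, 3])
        trace.loglik = trace.loglik[:3]
        rmap, scaled = vr.median_rate_tree(trace, tree)
        assert rmap.values[key] == 1.0
        assert np.allclose(scaled.lengths, tree.lengths)


class TestSteppingStone:
    def test_ladder_shape(self):
        betas = vr.ss_ladder(10, (0.40, 1.0))
        assert betas[0] == 0.0 and betas[-1] == 1.0
        assert np.all(np.diff(betas) > 0)
        # Beta(0.4, 1) quantiles: q(u) = u^(1/0.4)
        assert betas[5] == pytest.approx(0.5 ** 2.5)

    def test_accumulate_point_mass(self):
        # a "model" whose likelihood is constant L: evidence equals L exactly
        lls = [np.full(50, -3.7) for _ in range(4)]
        betas = np.linspace(0, 1, 5)
        assert vr.ss_accumulate(lls, betas) == pytest.approx(-3.7, abs=1e-12)

    def test_conjugate_normal_evidence(self):
        # y ~ N(mu, 1), mu ~ N(0, tau2): closed-form evidence vs stepping stone
        rng = np.random.default_rng(0)
        tau2 = 4.0
        y = np.array([0.8, 1.3, 0.2, 1.1, 0.9])
        n = len(y)
        # closed form: y ~ N(0, I + tau2 * 11')
        cov = np.eye(n) + tau2 * np.ones((n, n))
        exact = multivariate_normal.logpdf(y, mean=np.zeros(n), cov=cov)

        def loglik(mu):
            return float(norm.logpdf(y, loc=mu, scale=1.0).sum())

        betas = vr.ss_ladder(24, (0.40, 1.0))
        per_stone = []
        mu = 0.0
        for k in range(len(betas) - 1):
            power = betas[k]
            lls = []
            for it in range(2500):
                prop = mu + rng.normal() * 0.8
                dpost = (power * (loglik(prop) - loglik(mu))
                         + norm.logpdf(prop, 0, math.sqrt(tau2))
                         - norm.logpdf(mu, 0, math.sqrt(tau2)))
                if math.log(rng.random() + 1e-300) < dpost:
                    mu = prop
                if it >= 400:
                    lls.append(loglik(mu))
            per_stone.append(np.array(lls))
        est = vr.ss_accumulate(per_stone, betas)
        assert est == pytest.approx(exact, abs=0.25)

    def test_model_selection_on_heterogeneous_data(self, trait_setup):
        tree, _, traits, _, _, design = trait_setup
        cfg = vr.VarRatesConfig()
        m1 = vr.stepping_stone_logml(design, tree, "variable", stones=16,
                                     iters_per_stone=1200, seed=5, config=cfg)
        m0 = vr.stepping_stone_logml(design, tree, "single", stones=16,
                                     iters_per_stone=1200, seed=6, config=cfg)
        bf, cat = vr.bayes_factor(m1, m0)
        assert bf > 10
        assert cat == "very strong"

    def test_stones_floor(self, trait_setup):
        tree, _, _, _, _, design = trait_setup
        with pytest.raises(ValueError, match="stones"):
            vr.stepping_stone_logml(design, tree, "variable", stones=1)


class TestBayesFactor:
    def test_equal_marginals_zero(self):
        m = vr.MarginalLikelihoodEstimate(logml=-50.0, stones=10, iters_per_stone=10)
        bf, cat = vr.bayes_factor(m, m)
        assert bf == 0.0 and cat == "weak"

    def test_arithmetic_and_antisymmetry(self):
        m1 = vr.MarginalLikelihoodEstimate(logml=-100.0, stones=10, iters_per_stone=10)
        m0 = vr.MarginalLikelihoodEstimate(logml=-110.0, stones=10, iters_per_stone=10)
        bf, cat = vr.bayes_factor(m1, m0)
        assert bf == pytest.approx(20.0)
        assert cat == "very strong"
        assert vr.bayes_factor(m0, m1)[0] == pytest.approx(-20.0)

    def test_raftery_scale(self):
        assert vr.raftery_category(1.0) == "weak"
        assert vr.raftery_category(4.0) == "positive"
        assert vr.raftery_category(8.0) == "strong"
        assert vr.raftery_category(50.0) == "very strong"


class TestDesign:
    def test_rank_deficient_rejected(self):
        y = np.zeros(4)
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError, match="rank"):
            vr.RegressionDesign(y, X, ["a", "b"], list("abcd"))

    def test_clade_design_columns(self, trait_setup):
        _, _, traits, _, _, design = trait_setup
        n_clades = traits["clade"].nunique()
        assert sum(c.startswith("intercept") for c in design.colnames) == n_clades
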