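"""MG94xREV rate matrices, pruning likelihood and global/local fits."""

import numpy as np
import pytest

from ratelink import codon_mg94 as cm
from ratelink import simdata as sd
from ratelink import treedata as td
from ratelink.codon_mg94 import _EigCache


def _params_for(aln, rho=(1, 4, 1, 1, 4, 1)):
    pi, pi_pos = cm.codon_frequencies_f3x4(aln)
    return cm.MG94Params(rho=np.array(rho, dtype=float), pi=pi, pi_pos=pi_pos)


def _brute_force_star_loglik(aln, tree, params, rates):
    """Enumeration oracle: explicit sum over the internal state of a star tree."""
    cache = _EigCache(params)
    Ps = {v: cache.p_matrix(*rates[tree.branch_key(v)]) for v in tree.branch_ids()}
    tip_row = {s: aln.matrix[aln.species.index(s)] for s in aln.species}
    total = 0.0
    for s in range(aln.n_codons):
        site = 0.0
        for x in range(61):
            val = params.pi[x]
            for v in tree.tip_ids():
                st = tip_row[tree.labels[v]][s]
                if st >= 0:
                    val *= Ps[v][x, st]
            site += val
        total += np.log(site)
    return total


class TestFrequencies:
    def test_codon_freqs_are_positional_products(self):
        code = cm.UNIVERSAL_CODE
        seq = "".join(code.codons)
        aln = cm.CodonAlignment.from_sequences([("a", seq), ("b", seq), ("c", seq)])
        pi, pi_pos = cm.codon_frequencies_f3x4(aln)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        raw = np.array([
            pi_pos[0, cm.NUC_INDEX[c[0]]] * pi_pos[1, cm.NUC_INDEX[c[1]]]
            * pi_pos[2, cm.NUC_INDEX[c[2]]] for c in code.codons])
        assert np.allclose(pi, raw / raw.sum(), atol=1e-12)

    def test_degenerate_alignment_floored(self):
        aln = cm.CodonAlignment.from_sequences(
            [("a", "ATGATG"), ("b", "ATGATG"), ("c", "ATGATG")])
        pi, _ = cm.codon_frequencies_f3x4(aln)
        atg = cm.UNIVERSAL_CODE.codon_index["ATG"]
        assert pi[atg] > 0.99
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_random_alignment_normalised(self, small_alignment):
        aln = small_alignment[0]
        pi, _ = cm.codon_frequencies_f3x4(aln)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)


class TestRateMatrix:
    def test_p_at_zero_is_identity(self, small_alignment):
        params = _params_for(small_alignment[0])
        _, P = cm.mg94_q_and_p(params, 0.0, 0.0, 0.0)
        assert np.allclose(P, np.eye(61))

    def test_matrix_identities(self, small_alignment):
        params = _params_for(small_alignment[0], rho=(0.7, 2.5, 1.1, 0.9, 3.0, 0.6))
        Q, P = cm.mg94_q_and_p(params, 0.4, 0.15, 1.0)
        assert np.abs(Q.sum(axis=1)).max() < 1e-10
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
        flux = params.pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-10  # detailed balance

    def test_neutral_rates_normalised(self, small_alignment):
        # with dS = dN = 1 the expected substitutions per codon are 1 + 1
        params = _params_for(small_alignment[0])
        Q, _ = cm.mg94_q_and_p(params, 1.0, 1.0, 1.0)
        assert -float(params.pi @ np.diag(Q)) == pytest.approx(2.0, rel=1e-10)

    def test_only_single_nucleotide_changes(self, small_alignment):
        params = _params_for(small_alignment[0])
        Q, _ = cm.mg94_q_and_p(params, 1.0, 0.5, 1.0)
        code = cm.UNIVERSAL_CODE
        multi = np.ones((61, 61), dtype=bool)
        np.fill_diagonal(multi, False)
        multi[code.pair_i, code.pair_j] = False
        assert np.all(Q[multi] == 0)


class TestPruning:
    def test_zero_distance_identical_pair(self):
        code = cm.UNIVERSAL_CODE
        seq = "ATGAAACCCGGG"
        aln = cm.CodonAlignment.from_sequences([("A", seq), ("B", seq), ("C", seq)])
        tree = td.read_newick("(A:0,B:0,C:0);")
        params = _params_for(aln)
        rates = {tree.branch_key(v): (0.0, 0.0) for v in tree.branch_ids()}
        ll = cm.pruning_loglik(aln, tree, params, rates)
        states = aln.matrix[0]
        assert ll == pytest.approx(np.log(params.pi[states]).sum(), abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_enumeration_oracle_star(self, seed):
        rng = np.random.default_rng(seed)
        tree = td.read_newick("(A:1,B:1,C:1,D:1);" if seed else "(A:1,B:1,C:1);")
        scn = sd.SimulationScenario(n_taxa=8, n_codons=25)
        aln, _, _, _ = sd.simulate_codon_alignment(tree, scn, rng)
        params = _params_for(aln, rho=(0.8, 3.0, 1.2, 0.7, 2.0, 1.0))
        rates = {tree.branch_key(v): (0.05 * (i + 1), 0.02 * (i + 1))
                 for i, v in enumerate(tree.branch_ids())}
        ll = cm.pruning_loglik(aln, tree, params, rates)
        oracle = _brute_force_star_loglik(aln, tree, params, rates)
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_virtual_root_invariance(self):
        # same branch rates keyed by splits, evaluated on rooted vs unrooted
        # representations of the same topology: the pulley principle
        rng = np.random.default_rng(5)
        tree = sd.simulate_tree(8, 50.0, rng)
        scn = sd.SimulationScenario(n_taxa=8, n_codons=40)
        aln, dsm, dnm, _ = sd.simulate_codon_alignment(tree, scn, rng)
        params = _params_for(aln)
        un = td.unroot(tree)
        rates_un = {un.branch_key(v): (0.08, 0.02) for v in un.branch_ids()}
        ll_un = cm.pruning_loglik(aln, un, params, rates_un)
        # re-root on an arbitrary tip's split: likelihood must not move
        reroot = td.root_on_outgroup(un, un.tip_labels[0], remove_outgroup=False)
        all_tips = frozenset(un.tip_labels)
        by_side = {}
        for k, v in rates_un.items():
            side = frozenset(k)
            by_side[side] = v
            by_side[all_tips - side] = v
        rates_re = {}
        for v in reroot.branch_ids():
            key = frozenset(reroot.branch_key(v))
            rates_re[reroot.branch_key(v)] = by_side.get(key, (0.0, 0.0))
        ll_re = cm.pruning_loglik(aln, reroot, params, rates_re)
        assert ll_re == pytest.approx(ll_un, abs=1e-6)

    def test_species_mismatch_errors(self, small_alignment):
        aln = small_alignment[0]
        tree = td.read_newick("(X:1,Y:1,Z:1);")
        params = _params_for(aln)
        with pytest.raises(ValueError, match="mismatch"):
            cm.pruning_loglik(aln, tree, params, {})


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(21)
    tree = sd.simulate_tree(12, 100.0, rng)
    tree_og = sd.add_outgroup(tree, 0.3)
    scn = sd.SimulationScenario(
        n_taxa=12, n_codons=200, omega=0.4,
        mean_ds_per_myr=0.002, branch_rate_sd=0.0)
    aln, dsm, dnm, _ = sd.simulate_codon_alignment(tree_og, scn, rng)
    g = cm.fit_global(aln, tree_og, seed=0)
    l = cm.fit_local(aln, tree_og, seed=0, init=g)
    return tree_og, aln, g, l


class TestFits:
    def test_global_recovers_omega(self, fitted):
        _, _, g, _ = fitted
        assert g.omega == pytest.approx(0.4, abs=0.15)

    def test_nesting_holds(self, fitted):
        _, _, g, l = fitted
        assert l.loglik >= g.loglik - 1e-4

    def test_local_rates_nonnegative(self, fitted):
        _, _, _, l = fitted
        assert all(v >= 0 for v in l.branch_ds.values())
        assert all(v >= 0 for v in l.branch_dn.values())

    def test_fitted_loglik_at_least_truth(self, fitted):
        # MLE likelihood must top the likelihood at the generating parameters
        tree_og, aln, g, _ = fitted
        pi, pi_pos = cm.codon_frequencies_f3x4(aln)
        params = cm.MG94Params(rho=np.array([1, 4, 1, 1, 4, 1.0]),
                               pi=pi, pi_pos=pi_pos)
        ftree = g.tree
        # evaluate the global fit's own tree/keys at true-ish rates
        rates = {ftree.branch_key(v): (0.1, 0.04) for v in ftree.branch_ids()}
        ll_true = cm.pruning_loglik(aln, ftree, params, rates)
        assert g.loglik >= ll_true

    def test_lrt_identical_fits(self, fitted):
        _, _, g, _ = fitted
        D, df, p = cm.lrt_global_vs_local(
            g, cm.CodonFitResult(model="local", loglik=g.loglik,
                                 n_params=g.n_params + 5, params=g.params,
                                 tree=g.tree, branch_ds=g.branch_ds,
                                 branch_dn=g.branch_dn))
        assert D == 0.0 and p == pytest.approx(1.0)

    def test_lrt_non_nested_errors(self, fitted):
        _, _, g, _ = fitted
        with pytest.raises(ValueError, match="nested"):
            cm.lrt_global_vs_local(g, g)

    def test_branch_value_trees_roundtrip(self, fitted):
        _, _, _, l = fitted
        dn_tree, ds_tree, dn_map, ds_map = cm.branch_value_trees(
            l, sd.OUTGROUP_NAME)
        assert sd.OUTGROUP_NAME not in dn_tree.tip_labels
        dn_map.validate_for(dn_tree)
        ds_map.validate_for(ds_tree)
        # tree lengths carry the branch values
        for v in dn_tree.branch_ids():
            assert dn_tree.lengths[v] == pytest.approx(
                dn_map.values[dn_tree.branch_key(v)])


class TestAlignmentContainer:
    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop codon"):
            cm.CodonAlignment.from_sequences(
                [("a", "ATGTAA"), ("b", "ATGAAA"), ("c", "ATGAAA")])

    def test_needs_three_sequences(self):
        with pytest.raises(ValueError, match="at least 3"):
            cm.CodonAlignment.from_sequences([("a", "ATG"), ("b", "ATG")])

    def test_gaps_become_missing(self):
        aln = cm.CodonAlignment.from_sequences(
            [("a", "ATG---"), ("b", "ATGAAA"), ("c", "ATGANA")])
        assert aln.matrix[0, 1] == -1
        assert aln.matrix[2, 1] == -1

    def test_fasta_roundtrip(self, tmp_path, small_alignment):
        aln = small_alignment[0]
        p = tmp_path / "aln.fasta"
        aln.to_fasta(p)
        again = cm.CodonAlignment.from_fasta(p)
        assert again.species == aln.species
        assert np.array_equal(again.matrix, aln.matrix)
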