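"""Tree I/O, taxon matching, branch scaling and path-sum machinery."""

import numpy as np
import pytest

from ratelink import simdata as sd
from ratelink import treedata as td


class TestNewickIO:
    def test_basic_structure(self, three_taxon_tree):
        t = three_taxon_tree
        assert sorted(t.tip_labels) == ["A", "B", "C"]
        assert len(t.children[t.root]) == 2

    def test_missing_lengths_default_to_zero(self):
        t = td.read_newick("(A,B);")
        assert np.all(t.lengths == 0)

    def test_malformed_input_raises(self):
        with pytest.raises(td.NewickError):
            td.read_newick("((A:1,B:1;")

    def test_duplicate_tips_raise(self):
        with pytest.raises(td.NewickError, match="duplicate"):
            td.read_newick("((A:1,A:1):1,C:2);")

    @pytest.mark.parametrize("seed", range(10))
    def test_roundtrip_random_trees(self, seed):
        tree = sd.simulate_tree(50, 100.0, np.random.default_rng(seed))
        text = td.write_newick(tree)
        again = td.write_newick(td.read_newick(text))
        assert text == again

    def test_spaces_normalised_to_underscores(self):
        t = td.read_newick("('Mus musculus':1,'Rattus norvegicus':1);")
        assert "Mus_musculus" in t.tip_labels


class TestMatchAndPrune:
    def test_exact_match(self):
        t = td.read_newick("((Mus_musculus:1,Rattus_norvegicus:1):1,Gallus_gallus:2);")
        pruned, rep = td.match_and_prune(t, ["Mus_musculus"], genus_fallback=False)
        assert rep.exact == {"Mus_musculus": "Mus_musculus"}
        assert pruned.tip_labels == ["Mus_musculus"]

    def test_genus_fallback_single_congener(self):
        t = td.read_newick("((Mus_musculus:1,Rattus_norvegicus:1):1,Gallus_gallus:2);")
        pruned, rep = td.match_and_prune(t, ["Mus_spretus"], genus_fallback=True)
        assert rep.genus == {"Mus_spretus": "Mus_musculus"}
        # tip relabelled to the data's species name
        assert "Mus_spretus" in pruned.tip_labels

    def test_ambiguous_genus_refused(self):
        t = td.read_newick("((Mus_musculus:1,Mus_caroli:1):1,Gallus_gallus:2);")
        pruned, rep = td.match_and_prune(
            t, ["Mus_spretus", "Gallus_gallus"], genus_fallback=True)
        assert rep.unmatched == ["Mus_spretus"]
        assert pruned.tip_labels == ["Gallus_gallus"]

    def test_zero_matches_error(self):
        t = td.read_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="no query species"):
            td.match_and_prune(t, ["X_y"], genus_fallback=True)

    def test_pruning_preserves_path_lengths(self):
        tree = sd.simulate_tree(20, 100.0, np.random.default_rng(3))
        keep = sorted(tree.tip_labels)[:8]
        pruned = td.prune_to_tips(tree, keep)
        d_full = tree.node_depths()
        d_sub = pruned.node_depths()
        full = {tree.labels[t]: d_full[t] for t in tree.tip_ids()}
        sub = {pruned.labels[t]: d_sub[t] for t in pruned.tip_ids()}
        for sp in keep:
            assert sub[sp] == pytest.approx(full[sp], abs=1e-9)


class TestBranchValues:
    def test_scale_identity(self, three_taxon_tree):
        ones = td.BranchValueMap.constant(three_taxon_tree, 1.0, "r")
        scaled = td.scale_branches(three_taxon_tree, ones)
        assert np.allclose(scaled.lengths, three_taxon_tree.lengths)

    def test_scale_single_branch(self):
        t = td.read_newick("(A:2,B:1);")
        r = {t.branch_key(v): (3.0 if t.labels[v] == "A" else 1.0)
             for v in t.branch_ids()}
        scaled = td.scale_branches(t, td.BranchValueMap("r", r))
        a = [v for v in scaled.tip_ids() if scaled.labels[v] == "A"][0]
        assert scaled.lengths[a] == pytest.approx(6.0)

    def test_scaled_total_length_matches_sum(self):
        rng = np.random.default_rng(5)
        tree = sd.simulate_tree(20, 50.0, rng)
        r = {tree.branch_key(v): float(rng.uniform(0.1, 4.0))
             for v in tree.branch_ids()}
        scaled = td.scale_branches(tree, td.BranchValueMap("r", r))
        expected = sum(tree.lengths[v] * r[tree.branch_key(v)]
                       for v in tree.branch_ids())
        assert scaled.total_length() == pytest.approx(expected, rel=1e-12)

    def test_missing_scalar_errors(self, three_taxon_tree):
        partial = td.BranchValueMap("r", {})
        with pytest.raises(ValueError, match="cover"):
            td.scale_branches(three_taxon_tree, partial)

    def test_value_map_rejects_negative(self):
        with pytest.raises(ValueError):
            td.BranchValueMap("dN", {("A",): -0.1})


class TestPathSums:
    def test_hand_computed_sums(self, three_taxon_tree):
        t = three_taxon_tree
        key_of = {t.labels[v] if not t.children[v] else "AB": t.branch_key(v)
                  for v in t.branch_ids()}
        vals = {key_of["A"]: 3.0, key_of["AB"]: 1.0, key_of["B"]: 1.0,
                key_of["C"]: 5.0}
        sums = td.root_to_tip_sum(t, td.BranchValueMap("dN", vals))
        assert sums.totals == {"A": 4.0, "B": 2.0, "C": 5.0}

    def test_unrooted_tree_refused(self, three_taxon_tree):
        u = td.unroot(sd.simulate_tree(8, 10.0, np.random.default_rng(0)))
        with pytest.raises(ValueError, match="root"):
            td.root_to_tip_sum(u, td.BranchValueMap.from_lengths(u))

    @pytest.mark.parametrize("seed", range(5))
    def test_sums_equal_covariance_diagonal(self, seed):
        tree = sd.simulate_tree(20, 80.0, np.random.default_rng(seed))
        sums = td.root_to_tip_sum(tree, td.BranchValueMap.from_lengths(tree))
        V, order = td.phylo_covariance(tree)
        assert np.allclose([sums.totals[s] for s in order], np.diag(V),
                           atol=1e-10)


class TestCovariance:
    def test_hand_computed(self, three_taxon_tree):
        V, order = td.phylo_covariance(three_taxon_tree, ["A", "B", "C"])
        assert np.allclose(V, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_star_tree_is_diagonal(self):
        V, _ = td.phylo_covariance(td.read_newick("(A:1,B:2,C:3,D:4);"))
        assert np.allclose(V, np.diag(np.diag(V)))

    def test_positive_semidefinite(self):
        tree = sd.simulate_tree(20, 100.0, np.random.default_rng(11))
        V, _ = td.phylo_covariance(tree)
        assert np.linalg.eigvalsh(V).min() >= -1e-9

    def test_uniform_scaling_scales_covariance(self):
        tree = sd.simulate_tree(12, 40.0, np.random.default_rng(2))
        V, order = td.phylo_covariance(tree)
        scaled = td.scale_branches(tree, td.BranchValueMap.constant(tree, 2.5, "r"))
        V2, _ = td.phylo_covariance(scaled, order)
        assert np.allclose(V2, 2.5 * V, rtol=1e-12)


class TestTraitTable:
    def test_log10_applied_once(self, tmp_path):
        p = tmp_path / "traits.tsv"
        p.write_text("species\ttestes_mass_g\tbody_mass_g\tclade\n"
                     "Mus musculus\t0.1\t20\tmammals\n")
        df = td.read_trait_table(p)
        assert df.loc[0, "species"] == "Mus_musculus"
        assert df.loc[0, "testes_mass_log10"] == pytest.approx(-1.0)
        assert df.loc[0, "body_mass_log10"] == pytest.approx(np.log10(20))

    def test_duplicate_species_rejected(self, tmp_path):
        p = tmp_path / "traits.tsv"
        p.write_text("species\ttestes_mass_g\tbody_mass_g\tclade\n"
                     "A_b\t1\t10\tx\nA_b\t2\t20\tx\n")
        with pytest.raises(ValueError, match="duplicate"):
            td.read_trait_table(p)

    def test_nonpositive_mass_rejected(self, tmp_path):
        p = tmp_path / "traits.tsv"
        p.write_text("species\ttestes_mass_g\tbody_mass_g\tclade\n"
                     "A_b\t0\t10\tx\n")
        with pytest.raises(ValueError, match="finite"):
            td.read_trait_table(p)


class TestRooting:
    def test_root_on_outgroup_drops_outgroup(self):
        tree = sd.add_outgroup(
            sd.simulate_tree(10, 50.0, np.random.default_rng(4)), 0.3)
        un = td.unroot(tree)
        rooted = td.root_on_outgroup(un, sd.OUTGROUP_NAME)
        assert sd.OUTGROUP_NAME not in rooted.tip_labels
        assert rooted.rooted
        assert sorted(rooted.tip_labels) == sorted(
            x for x in tree.tip_labels if x != sd.OUTGROUP_NAME)

    def test_unroot_preserves_total_length_and_splits(self):
        tree = sd.simulate_tree(10, 50.0, np.random.default_rng(6))
        un = td.unroot(tree)
        assert un.total_length() == pytest.approx(tree.total_length())
        assert not un.rooted
        assert len(un.branch_ids()) == len(tree.branch_ids()) - 1
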