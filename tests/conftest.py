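import numpy as np
import pytest

from ratelink import simdata as sd
from ratelink import treedata as td


@pytest.fixture
def three_taxon_tree():
    return td.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_yule_tree():
    return sd.simulate_tree(16, 100.0, np.random.default_rng(42))


@pytest.fixture
def small_scenario():
    return sd.SimulationScenario(n_taxa=16, n_codons=120)


@pytest.fixture
def small_alignment(small_yule_tree, small_scenario):
    aln, ds, dn, counts = sd.simulate_codon_alignment(
        small_yule_tree, small_scenario, np.random.default_rng(7))
    return aln, ds, dn, counts
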