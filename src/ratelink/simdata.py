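"""Synthetic trees, trait tables and codon alignments with known rate structure.

This module is the study's test harness: it emulates the three real inputs of
the analysis — a time-calibrated phylogeny, a species table of testes and
body masses with clade labels, and per-gene in-frame codon alignments with an
outgroup — under a fully known generative model, so that every estimator in
the package can be checked against planted truth.

* Trees are pure-birth (Yule) and rescaled to a requested depth in Myr, so
  they are ultrametric like a time tree.
* Body mass evolves by Brownian motion on the log10 scale; testes mass is a
  clade-specific allometric regression on body mass whose phylogenetic
  residual evolves by Brownian motion with branch-specific rate scalars
  (background rate sigma^2_b, a planted set of fast branches scaled by
  r_true).
* Codon alignments evolve under MG94xREV along the same tree (plus a basal
  outgroup) by exact Gillespie simulation, which also yields true per-branch
  substitution counts.  The non-synonymous branch rate can be coupled to the
  phenotypically fast (driver archetypes) or slow (moderator archetypes)
  branches, and/or to the *direction* of residual trait change (directional
  archetypes).

``generate_benchmark`` writes one tree + trait table + six gene alignments —
one per association archetype — together with the planted truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_mg94 import (
    CodonAlignment,
    MG94Params,
    UNIVERSAL_CODE,
    _build_rate_parts,
)
from .treedata import (
    BranchValueMap,
    Phylogeny,
    write_newick,
    write_trait_table,
)

__all__ = [
    "SimulationScenario",
    "simulate_tree",
    "add_outgroup",
    "assign_clades",
    "simulate_varrates_traits",
    "simulate_codon_alignment",
    "generate_benchmark",
    "ARCHETYPES",
    "OUTGROUP_NAME",
]

OUTGROUP_NAME = "Outgroup_taxon"


@dataclass
class SimulationScenario:
    """All knobs of the coupled genotype-phenotype generative model.

    Defaults are the desk-scale study conditions: 64 taxa, 300 Myr deep,
    five clades, a x16 rate scalar on ~30% of branches (scattered subtrees,
    or one clade when ``fast_clade`` is set), 300 codons.
    """

    n_taxa: int = 64
    depth: float = 300.0               # Myr, root to tip
    n_clades: int = 5
    clade_intercepts: tuple = (-1.4, -1.3, -1.2, -1.1, -1.0)   # log10 g
    clade_slopes: tuple = (0.62, 0.66, 0.70, 0.74, 0.78)
    body_sigma2: float = 0.004         # log10 units^2 / Myr, body-mass BM
    body_root: float = 2.0             # log10 g at the root
    sigma2_b: float = 0.001            # background residual BM rate
    r_fast: float = 16.0               # rate scalar on the fast branches
    fast_clade: int | None = None      # plant the fast set on one clade...
    fast_frac: float = 0.30            # ...or disperse it over subtrees (default)
    # molecular side
    n_codons: int = 300
    rho: tuple = (1.0, 4.0, 1.0, 1.0, 4.0, 1.0)    # GTR, transitions elevated
    pi_nuc: tuple = (0.30, 0.20, 0.26, 0.24)       # A C G T, all positions
    mean_ds_per_myr: float = 0.0015    # expected syn subs/codon/Myr
    omega: float = 0.2                 # baseline dN/dS
    branch_rate_sd: float = 0.7        # lognormal sd of baseline branch noise
    coupling: float = 1.0              # multiplier on dN over the coupled set
    coupling_target: str | None = None  # "fast" | "slow" | None
    directional: float = 0.0           # dN *= exp(directional * sign(step))
    outgroup_stem_frac: float = 0.3    # outgroup divergence, fraction of depth
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling <= 0 or self.r_fast <= 0 or self.sigma2_b <= 0:
            raise ValueError("rates and couplings must be positive")
        if self.coupling_target not in (None, "fast", "slow"):
            raise ValueError("coupling_target must be None, 'fast' or 'slow'")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def simulate_tree(n_taxa: int, depth: float, rng) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_taxa`` tips rescaled to ``depth``.

    The tree is ultrametric: every root-to-tip distance equals ``depth``.
    """
    rng = np.random.default_rng(rng)
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    parent = [-1]
    birth = [0.0]
    split: list[float | None] = [None]
    active = []
    t = 0.0
    for _ in range(2):          # root bifurcates at time 0
        parent.append(0)
        birth.append(0.0)
        split.append(None)
        active.append(len(parent) - 1)
    split[0] = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        split[node] = t
        for _ in range(2):
            parent.append(node)
            birth.append(t)
            split.append(None)
            active.append(len(parent) - 1)
    present = t + rng.exponential(1.0 / len(active))
    scale = depth / present
    lengths = []
    labels: list[str | None] = []
    n_tip = 0
    for i in range(len(parent)):
        end = split[i] if split[i] is not None else present
        lengths.append((end - birth[i]) * scale)
        if split[i] is None:
            n_tip += 1
            labels.append(f"sp{n_tip:03d}")
        else:
            labels.append(None)
    return Phylogeny(parent, lengths, labels, rooted=True)


def add_outgroup(tree: Phylogeny, stem_frac: float = 0.3,
                 name: str = OUTGROUP_NAME) -> Phylogeny:
    """Attach a basal outgroup: a new root above the old one, with the
    outgroup tip diverging ``(1+stem_frac) * depth`` ago."""
    depth = float(tree.node_depths()[tree.tip_ids()[0]])
    offset = 2  # new root at 0, outgroup tip at 1
    parent = [-1, 0] + [p + offset if p != -1 else 0 for p in tree.parent]
    lengths = [0.0, depth * (1 + stem_frac)] + [
        float(tree.lengths[i]) if i != tree.root else depth * stem_frac
        for i in range(tree.n_nodes)
    ]
    labels: list[str | None] = [None, name] + list(tree.labels)
    return Phylogeny(parent, lengths, labels, rooted=True)


def assign_clades(tree: Phylogeny, n_clades: int) -> dict[str, int]:
    """Partition the tips into ``n_clades`` monophyletic groups by repeatedly
    splitting the largest frontier subtree.  Returns species -> clade index."""
    n_below = np.zeros(tree.n_nodes, dtype=int)
    for n in tree.postorder():
        n_below[n] = 1 if not tree.children[n] else sum(n_below[c] for c in tree.children[n])
    frontier = [tree.root]
    while len(frontier) < n_clades:
        splittable = [n for n in frontier if tree.children[n]]
        if not splittable:
            break
        big = max(splittable, key=lambda n: n_below[n])
        frontier.remove(big)
        frontier.extend(tree.children[big])
    clade_of: dict[str, int] = {}
    for ci, node in enumerate(sorted(frontier, key=lambda n: -n_below[n])):
        stack = [node]
        while stack:
            m = stack.pop()
            if not tree.children[m]:
                clade_of[tree.labels[m]] = ci
            stack.extend(tree.children[m])
    return clade_of


def _clade_subtree_branches(tree: Phylogeny, clade_of: dict[str, int],
                            clade: int) -> set[tuple[str, ...]]:
    """Branch keys whose entire below-set lies in the clade (incl. its stem)."""
    members = {sp for sp, c in clade_of.items() if c == clade}
    keys = set()
    for v in tree.branch_ids():
        key = tree.branch_key(v)
        if set(key) <= members:
            keys.add(key)
    return keys


def _scattered_fast_branches(tree: Phylogeny, frac: float,
                             min_size: int = 4, max_size: int = 10
                             ) -> tuple[set[tuple[str, ...]], set[tuple[str, ...]]]:
    """Fast and slow branch sets made of subtrees scattered across the tree.

    Maximal subtrees of ``min_size``..``max_size`` tips are enumerated in
    preorder; alternate ones are planted *fast* (stem plus descendants, until
    about ``frac`` of the tips is covered) and the remaining ones form the
    complementary *slow* set used by moderator gene archetypes.  Units of
    this size span enough branch time for a rate burst to be statistically
    detectable, while spreading them over several independent parts of the
    tree keeps the planted shift from coinciding with any single clade.
    Returns (fast_keys, slow_keys).
    """
    n_below = np.zeros(tree.n_nodes, dtype=int)
    for v in tree.postorder():
        n_below[v] = 1 if not tree.children[v] else sum(
            n_below[c] for c in tree.children[v])
    candidates = []
    stack = [tree.root]
    while stack:
        v = stack.pop(0)
        if v != tree.root and min_size <= n_below[v] <= max_size:
            candidates.append(v)
            continue
        if n_below[v] > max_size:
            stack.extend(tree.children[v])

    def subtree_keys(top: int) -> set[tuple[str, ...]]:
        keys: set[tuple[str, ...]] = set()
        sub = [top]
        while sub:
            v = sub.pop()
            keys.add(tree.branch_key(v))
            sub.extend(tree.children[v])
        return keys

    target = max(min_size, int(round(frac * int(n_below[tree.root]))))
    fast: set[tuple[str, ...]] = set()
    slow: set[tuple[str, ...]] = set()
    covered = 0
    for idx, top in enumerate(candidates):
        if idx % 2 == 0 and covered < target:
            fast |= subtree_keys(top)
            covered += int(n_below[top])
        else:
            slow |= subtree_keys(top)
    if not fast and candidates:
        fast = subtree_keys(candidates[0])
    return fast, slow


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


def simulate_varrates_traits(
    tree: Phylogeny, scenario: SimulationScenario, rng
) -> tuple[pd.DataFrame, BranchValueMap, dict]:
    """Simulate the trait table under the variable-rates regression model.

    Body mass evolves by Brownian motion; the residual of testes mass on the
    clade-specific allometry evolves by Brownian motion with per-branch
    variance sigma^2_b * t_b * r_b, where r_b = r_fast on the planted fast
    clade and 1 elsewhere.

    Returns (trait table, true BranchValueMap[r], info) where info carries
    the clade map, the fast branch keys and the per-branch residual
    increments (used for directional gene coupling).
    """
    rng = np.random.default_rng(rng)
    clade_of = assign_clades(tree, scenario.n_clades)
    if scenario.fast_clade is not None:
        fast_clade = scenario.fast_clade
        fast_keys = _clade_subtree_branches(tree, clade_of, fast_clade)
        slow_keys = set()
    else:
        fast_clade = None
        fast_keys, slow_keys = _scattered_fast_branches(tree, scenario.fast_frac)

    r_true = {}
    for v in tree.branch_ids():
        key = tree.branch_key(v)
        r_true[key] = scenario.r_fast if key in fast_keys else 1.0

    body = np.zeros(tree.n_nodes)
    resid = np.zeros(tree.n_nodes)
    dresid = {}
    body[tree.root] = scenario.body_root
    for v in tree.preorder():
        p = tree.parent[v]
        if p == -1:
            continue
        t_b = tree.lengths[v]
        key = tree.branch_key(v)
        body[v] = body[p] + rng.normal(0.0, np.sqrt(scenario.body_sigma2 * t_b))
        sd_b = np.sqrt(scenario.sigma2_b * t_b * r_true[key])
        step = sd_b * rng.normal()
        resid[v] = resid[p] + step
        # raw trait innovation and its conditional sd (directional genes
        # couple to the step with a mean-one multiplier, see _gene_branch_rates)
        dresid[key] = (float(step), float(sd_b))

    rows = []
    for tid in tree.tip_ids():
        sp = tree.labels[tid]
        ci = clade_of[sp]
        testes = (scenario.clade_intercepts[ci % len(scenario.clade_intercepts)]
                  + scenario.clade_slopes[ci % len(scenario.clade_slopes)] * body[tid]
                  + resid[tid])
        rows.append((sp, testes, body[tid], f"clade_{ci}"))
    traits = pd.DataFrame(rows, columns=["species", "testes_mass_log10",
                                         "body_mass_log10", "clade"])
    info = {
        "clade_of": clade_of,
        "fast_clade": fast_clade,
        "fast_keys": fast_keys,
        "slow_keys": slow_keys,
        "residual_steps": dresid,
        "residual_tip": {tree.labels[t]: float(resid[t]) for t in tree.tip_ids()},
    }
    return traits, BranchValueMap("r", r_true), info


# ---------------------------------------------------------------------------
# Codon alignments (Gillespie along branches)
# ---------------------------------------------------------------------------


def _gene_branch_rates(
    tree: Phylogeny, scenario: SimulationScenario, rng,
    fast_keys: set | None = None,
    slow_keys: set | None = None,
    residual_steps: dict | None = None,
) -> tuple[dict, dict]:
    """Per-branch true (dS_b, dN_b) with baseline lognormal heterogeneity and
    the scenario's fast/slow and directional couplings."""
    rng = np.random.default_rng(rng)
    sd = scenario.branch_rate_sd
    steps = residual_steps or {}   # branch key -> (raw step, conditional sd)
    if steps:
        sg = float(np.sqrt(np.mean([s[1] ** 2 for s in steps.values()]))) or 1.0
    ds_map, dn_map = {}, {}
    for v in tree.branch_ids():
        key = tree.branch_key(v)
        t_b = tree.lengths[v]
        noise_s = np.exp(rng.normal(-sd ** 2 / 2, sd))
        noise_n = np.exp(rng.normal(-sd ** 2 / 2, sd))
        ds = scenario.mean_ds_per_myr * t_b * noise_s
        dn = scenario.omega * scenario.mean_ds_per_myr * t_b * noise_n
        in_fast = fast_keys is not None and key in fast_keys
        in_slow = (key in slow_keys) if slow_keys else (
            fast_keys is not None and not in_fast)
        if scenario.coupling_target == "fast" and in_fast:
            dn *= scenario.coupling
        elif scenario.coupling_target == "slow" and in_slow:
            dn *= scenario.coupling
        if scenario.directional and key in steps:
            step_b, _sd_b = steps[key]
            # sign-based coupling: dN up where the trait went up, down where
            # it went down.  The multiplier's magnitude is identical on every
            # branch, so no rate signal (mean or variance) leaks in.
            dn *= np.exp(scenario.directional * np.sign(step_b))
        ds_map[key] = float(max(ds, 1e-8))
        dn_map[key] = float(max(dn, 1e-9))
    return ds_map, dn_map


def simulate_codon_alignment(
    tree: Phylogeny,
    scenario: SimulationScenario,
    rng,
    ds_map: dict | None = None,
    dn_map: dict | None = None,
):
    """Evolve a codon alignment under MG94xREV by Gillespie simulation.

    The root sequence is drawn from the stationary F3x4 frequencies; each
    branch then evolves site-by-site under Q(dS_b, dN_b).  Returns
    (CodonAlignment, BranchValueMap[dS], BranchValueMap[dN], counts) where
    ``counts`` holds the realised synonymous / non-synonymous event counts
    per branch — the counting oracle for recovery tests.
    """
    rng = np.random.default_rng(rng)
    code = UNIVERSAL_CODE
    pi_pos = np.tile(np.asarray(scenario.pi_nuc, dtype=float), (3, 1))
    pi_pos /= pi_pos.sum(axis=1, keepdims=True)
    codon_nucs = np.array([[ "ACGT".index(c[k]) for k in range(3)] for c in code.codons])
    pi = pi_pos[0, codon_nucs[:, 0]] * pi_pos[1, codon_nucs[:, 1]] * pi_pos[2, codon_nucs[:, 2]]
    pi /= pi.sum()
    params = MG94Params(rho=np.asarray(scenario.rho, dtype=float), pi=pi, pi_pos=pi_pos)
    Qs, Qn = _build_rate_parts(params)

    if ds_map is None or dn_map is None:
        ds_map, dn_map = _gene_branch_rates(tree, scenario, rng)

    L = scenario.n_codons
    seqs = {tree.root: rng.choice(code.n, size=L, p=pi)}
    syn_counts: dict[tuple[str, ...], int] = {}
    nonsyn_counts: dict[tuple[str, ...], int] = {}
    syn_is = Qs.sum(axis=1)  # per-state synonymous leave rate at unit dS

    for v in tree.preorder():
        p = tree.parent[v]
        if p == -1:
            continue
        key = tree.branch_key(v)
        Q = ds_map[key] * Qs + dn_map[key] * Qn
        leave = Q.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            jump = np.where(leave[:, None] > 0, Q / np.maximum(leave, 1e-300)[:, None], 0.0)
        syn_frac = np.where(leave > 0, ds_map[key] * syn_is / np.maximum(leave, 1e-300), 0.0)
        seq = seqs[p].copy()
        ns = nn = 0
        # first waiting time for every site at once, then per-site event loops
        rates = leave[seq]
        waits = np.full(L, np.inf)
        pos = rates > 0
        waits[pos] = rng.exponential(1.0 / rates[pos])
        for s in np.nonzero(waits < 1.0)[0]:
            t_s = waits[s]
            state = seq[s]
            while t_s < 1.0:
                nxt = rng.choice(code.n, p=jump[state])
                if code.aa[state] == code.aa[nxt]:
                    ns += 1
                else:
                    nn += 1
                state = nxt
                lr = leave[state]
                if lr <= 0:
                    break
                t_s += rng.exponential(1.0 / lr)
            seq[s] = state
        seqs[v] = seq
        syn_counts[key] = ns
        nonsyn_counts[key] = nn

    species = [tree.labels[t] for t in tree.tip_ids()]
    matrix = np.array([seqs[t] for t in tree.tip_ids()], dtype=np.int16)
    aln = CodonAlignment(species, matrix, code)
    counts = {"syn": syn_counts, "nonsyn": nonsyn_counts}
    return aln, BranchValueMap("dS", ds_map), BranchValueMap("dN", dn_map), counts


# ---------------------------------------------------------------------------
# Benchmark bundle
# ---------------------------------------------------------------------------

# archetype -> (coupling target, coupling strength key, directional key, label)
ARCHETYPES: dict[str, dict] = {
    "bidirectional_rapid_driver": dict(
        target="fast", coupled=True, directional=False,
        label="bidirectional_rapid_driver"),
    "directional_rapid_driver": dict(
        target="fast", coupled=True, directional=True,
        label="directional_rapid_driver"),
    "moderator": dict(
        target="slow", coupled=True, directional=False,
        label="moderator"),
    "directional_moderator": dict(
        target="slow", coupled=True, directional=True,
        label="directional_moderator"),
    "directional_nonrapid_driver": dict(
        target=None, coupled=False, directional=True,
        label="directional_nonrapid_driver"),
    "null": dict(
        target=None, coupled=False, directional=False,
        label="no_association"),
}

# effect sizes fixed by pilot simulation runs (see docs/methods.md);
# moderator archetypes need a stronger multiplier because up-weighting the
# slow set produces a smaller log-contrast than the driver coupling does
COUPLING_STRENGTH = 32.0
MODERATOR_COUPLING = 32.0
DIRECTIONAL_STRENGTH = 1.4


def generate_benchmark(outdir, seed: int,
                       scenario: SimulationScenario | None = None,
                       gene_subsample: int = 2) -> dict:
    """Write the six-gene benchmark bundle: tree, traits, alignments, truth.

    Every archetype's alignment shares the same tree and trait table (one
    phenotypic history, six genes), mirroring how the real analysis reuses
    one phenotypic rate tree across genes.  As in the real study — where
    phenotypic rates come from a far larger species table than any single
    gene's sequence set — trait data cover every tip while each gene
    alignment keeps only every ``gene_subsample``-th species (plus the
    outgroup).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if scenario is None:
        # bundle default: a quick but statistically meaningful benchmark size
        scenario = SimulationScenario(n_taxa=64, n_codons=210, r_fast=32.0,
                                      branch_rate_sd=0.55, seed=seed)
    root_rng = np.random.default_rng(seed)
    tree_rng, trait_rng, *gene_rngs = root_rng.spawn(2 + len(ARCHETYPES))

    tree = simulate_tree(scenario.n_taxa, scenario.depth, tree_rng)
    traits, r_true, info = simulate_varrates_traits(tree, scenario, trait_rng)
    full_tree = add_outgroup(tree, scenario.outgroup_stem_frac)

    # the fast-branch keys are identical on the outgrouped tree (same tip sets)
    fast_keys = info["fast_keys"]
    steps = info["residual_steps"]

    (outdir / "tree.nwk").write_text(write_newick(full_tree) + "\n")
    (outdir / "ingroup_tree.nwk").write_text(write_newick(tree) + "\n")
    write_trait_table(traits, outdir / "traits.tsv")

    truth: dict = {
        "seed": seed,
        "scenario": {k: v for k, v in asdict(scenario).items()},
        "fast_clade": info["fast_clade"],
        "fast_branches": [list(k) for k in sorted(fast_keys)],
        "r_true": {";".join(k): v for k, v in r_true.values.items()},
        "outgroup": OUTGROUP_NAME,
        "genes": {},
    }

    for (name, spec), grng in zip(ARCHETYPES.items(), gene_rngs):
        if spec["coupled"]:
            strength = (MODERATOR_COUPLING if spec["target"] == "slow"
                        else COUPLING_STRENGTH)
        else:
            strength = 1.0
        gene_scn = SimulationScenario(
            **{**asdict(scenario),
               "coupling": strength,
               "coupling_target": spec["target"],
               "directional": DIRECTIONAL_STRENGTH if spec["directional"] else 0.0}
        )
        r1, r2 = grng.spawn(2)
        ds_map, dn_map = _gene_branch_rates(
            full_tree, gene_scn, r1, fast_keys=fast_keys,
            slow_keys=info.get("slow_keys"), residual_steps=steps)
        aln, ds_bvm, dn_bvm, counts = simulate_codon_alignment(
            full_tree, gene_scn, r2, ds_map=ds_map, dn_map=dn_map)
        ingroup = sorted(s for s in aln.species if s != OUTGROUP_NAME)
        gene_species = ingroup[::gene_subsample] + [OUTGROUP_NAME]
        aln = aln.subset([s for s in aln.species if s in set(gene_species)])
        aln.to_fasta(outdir / f"gene_{name}.fasta")
        truth["genes"][name] = {
            "label": spec["label"],
            "coupling": gene_scn.coupling,
            "coupling_target": gene_scn.coupling_target,
            "directional": gene_scn.directional,
            "true_ds": {";".join(k): v for k, v in ds_map.items()},
            "true_dn": {";".join(k): v for k, v in dn_map.items()},
        }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
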