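"""Phylogenies, trait tables and per-branch value maps.

This module is the data backbone of the package: it reads and writes rooted
time trees (Newick), loads species trait tables (testes mass, body mass,
clade), matches trait species to tree tips (with an optional genus-level
fallback), and computes the path quantities every downstream model needs —
root-to-tip sums of arbitrary per-branch values and the phylogenetic
covariance matrix of shared path lengths.

Branches are identified by the set of tip labels below them (their clade),
so per-branch annotations survive serialisation, pruning order changes and
re-reading from disk.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "BranchValueMap",
    "RootToTipSums",
    "MatchReport",
    "read_newick",
    "write_newick",
    "read_trait_table",
    "validate_trait_table",
    "match_and_prune",
    "scale_branches",
    "root_to_tip_sum",
    "phylo_covariance",
    "path_indicator_matrix",
    "root_on_outgroup",
    "unroot",
]

TRAIT_COLUMNS = ("species", "testes_mass_g", "body_mass_g", "clade")


class NewickError(ValueError):
    """Raised for malformed or inconsistent Newick input."""


def normalize_species_name(name: str) -> str:
    """Spaces become underscores so TimeTree-style and GenBank-style labels agree."""
    return name.strip().replace(" ", "_")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


class Phylogeny:
    """A rooted (or explicitly unrooted) phylogeny with branch lengths.

    Nodes are integers ``0..n_nodes-1``; ``parent[i]`` is ``-1`` for the
    root.  ``lengths[i]`` is the length of the branch *above* node ``i``
    (0 for the root).  Tips carry species labels; internal labels are kept
    if present but play no structural role.
    """

    def __init__(
        self,
        parent: list[int],
        lengths: list[float] | np.ndarray,
        labels: list[str | None],
        rooted: bool = True,
    ):
        self.parent = list(parent)
        self.lengths = np.asarray(lengths, dtype=float).copy()
        self.labels = list(labels)
        self.rooted = rooted
        n = len(self.parent)
        if not (len(self.lengths) == len(self.labels) == n):
            raise ValueError("parent, lengths and labels must have equal length")
        roots = [i for i, p in enumerate(self.parent) if p == -1]
        if len(roots) != 1:
            raise NewickError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        if np.any(self.lengths < 0):
            raise NewickError("negative branch lengths are not allowed")
        self.lengths[self.root] = 0.0
        tips = self.tip_ids()
        seen: set[str] = set()
        for t in tips:
            lab = self.labels[t]
            if lab is None or lab == "":
                raise NewickError("every tip must be labelled")
            if lab in seen:
                raise NewickError(f"duplicate tip label: {lab!r}")
            seen.add(lab)
        # connectivity / acyclicity: everything reachable from the root, once
        seen_n = 0
        stack = [self.root]
        while stack:
            seen_n += 1
            stack.extend(self.children[stack.pop()])
        if seen_n != n:
            raise NewickError("tree is not connected (or contains a cycle)")
        self._branch_keys: dict[int, tuple[str, ...]] | None = None

    # -- basic structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def tip_ids(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_ids()]

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    def branch_ids(self) -> list[int]:
        """Nodes that have a branch above them (everything but the root)."""
        return [i for i in range(self.n_nodes) if i != self.root]

    def branch_key(self, node: int) -> tuple[str, ...]:
        """Stable identity of the branch above ``node``: sorted tip labels below it."""
        if self._branch_keys is None:
            keys: dict[int, tuple[str, ...]] = {}
            below: dict[int, list[str]] = {}
            for n in self.postorder():
                if not self.children[n]:
                    below[n] = [self.labels[n]]
                else:
                    acc: list[str] = []
                    for c in self.children[n]:
                        acc.extend(below[c])
                    below[n] = acc
                keys[n] = tuple(sorted(below[n]))
            self._branch_keys = keys
        return self._branch_keys[node]

    def branch_keys(self) -> dict[tuple[str, ...], int]:
        return {self.branch_key(i): i for i in self.branch_ids()}

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.parent, self.lengths, self.labels, rooted=self.rooted)

    def total_length(self) -> float:
        return float(self.lengths.sum())

    def node_depths(self) -> np.ndarray:
        depth = np.zeros(self.n_nodes)
        for n in self.preorder():
            if self.parent[n] != -1:
                depth[n] = depth[self.parent[n]] + self.lengths[n]
        return depth

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Phylogeny {len(self.tip_ids())} tips, rooted={self.rooted}>"


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Branch lengths default to 0 where absent.  Raises :class:`NewickError`
    naming the offending token for malformed input or duplicate tips.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickError(f"malformed Newick: {exc}") from exc
    index: dict[int, int] = {}
    parent: list[int] = []
    lengths: list[float] = []
    labels: list[str | None] = []
    for node in dtree.preorder_node_iter():
        idx = len(parent)
        index[id(node)] = idx
        parent.append(index[id(node.parent_node)] if node.parent_node else -1)
        lengths.append(node.edge.length if node.edge.length is not None else 0.0)
        lab = None
        if node.taxon is not None:
            lab = node.taxon.label
        elif node.label:
            lab = node.label
        labels.append(normalize_species_name(lab) if lab else None)
    return Phylogeny(parent, lengths, labels, rooted=True)


def write_newick(tree: Phylogeny, precision: int = 12, canonical: bool = True) -> str:
    """Serialise to Newick.

    With ``canonical=True`` children are ordered by their smallest descendant
    tip label, so topologically identical trees serialise identically.
    """

    def fmt(x: float) -> str:
        return f"{x:.{precision}g}"

    def rec(node: int, out: io.StringIO) -> None:
        kids = tree.children[node]
        if kids:
            if canonical:
                kids = sorted(kids, key=lambda c: tree.branch_key(c)[0])
            out.write("(")
            for i, c in enumerate(kids):
                if i:
                    out.write(",")
                rec(c, out)
            out.write(")")
            if tree.labels[node]:
                out.write(tree.labels[node])
        else:
            out.write(tree.labels[node])
        if node != tree.root:
            out.write(":" + fmt(tree.lengths[node]))

    out = io.StringIO()
    rec(tree.root, out)
    out.write(";")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Branch values and path sums
# ---------------------------------------------------------------------------


@dataclass
class BranchValueMap:
    """Per-branch non-negative scalar field (rate scalars r, rt, dN or dS).

    Keys are branch identities (sorted tip-label tuples); ``kind`` tags the
    quantity stored.
    """

    kind: str
    values: dict[tuple[str, ...], float] = field(default_factory=dict)

    VALID_KINDS = ("r", "rt", "dN", "dS")

    def __post_init__(self) -> None:
        if self.kind not in self.VALID_KINDS:
            raise ValueError(f"kind must be one of {self.VALID_KINDS}, got {self.kind!r}")
        for k, v in self.values.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"branch value for {k} must be finite and >= 0, got {v}")

    def validate_for(self, tree: Phylogeny) -> None:
        keys = set(tree.branch_keys())
        mine = set(self.values)
        if keys != mine:
            missing = keys - mine
            extra = mine - keys
            raise ValueError(
                f"BranchValueMap[{self.kind}] does not cover the tree exactly: "
                f"{len(missing)} missing, {len(extra)} extraneous branches"
            )

    @classmethod
    def from_lengths(cls, tree: Phylogeny, kind: str = "rt") -> "BranchValueMap":
        return cls(kind, {tree.branch_key(i): float(tree.lengths[i]) for i in tree.branch_ids()})

    @classmethod
    def constant(cls, tree: Phylogeny, value: float, kind: str = "r") -> "BranchValueMap":
        return cls(kind, {tree.branch_key(i): value for i in tree.branch_ids()})


@dataclass
class RootToTipSums:
    """Per-species totals of a branch field summed root-to-tip (R_phen, R_dN, R_dS)."""

    kind: str
    totals: dict[str, float] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(self.totals, name=self.kind).sort_index()


def scale_branches(tree: Phylogeny, scalars: BranchValueMap) -> Phylogeny:
    """Multiply each branch length by its rate scalar: t becomes t*r.

    This is the rate-scaled tree whose branch lengths are rt; topology is
    untouched.  Every branch must have a scalar.
    """
    scalars.validate_for(tree)
    out = tree.copy()
    for i in out.branch_ids():
        out.lengths[i] = tree.lengths[i] * scalars.values[tree.branch_key(i)]
    return out


def root_to_tip_sum(tree: Phylogeny, values: BranchValueMap) -> RootToTipSums:
    """Sum a per-branch field along each species' unique root-to-tip path."""
    if not tree.rooted:
        raise ValueError("tree is unrooted: root it (e.g. on the outgroup) before summing paths")
    values.validate_for(tree)
    kind_map = {"rt": "R_phen", "dN": "R_dN", "dS": "R_dS", "r": "R_phen"}
    acc = np.zeros(tree.n_nodes)
    for n in tree.preorder():
        p = tree.parent[n]
        if p != -1:
            acc[n] = acc[p] + values.values[tree.branch_key(n)]
    totals = {tree.labels[t]: float(acc[t]) for t in tree.tip_ids()}
    return RootToTipSums(kind_map[values.kind], totals)


def path_indicator_matrix(tree: Phylogeny, order: list[str] | None = None):
    """Species-by-branch 0/1 matrix A: A[i,b]=1 iff branch b lies on species i's
    root-to-tip path.  Returns (A, species order, branch node ids)."""
    if order is None:
        order = sorted(tree.tip_labels)
    tip_of = {tree.labels[t]: t for t in tree.tip_ids()}
    branches = tree.branch_ids()
    col = {b: j for j, b in enumerate(branches)}
    A = np.zeros((len(order), len(branches)))
    for i, sp in enumerate(order):
        n = tip_of[sp]
        while tree.parent[n] != -1:
            A[i, col[n]] = 1.0
            n = tree.parent[n]
    return A, order, branches


def phylo_covariance(tree: Phylogeny, order: list[str] | None = None):
    """Shared-path-length covariance matrix V.

    V[i,j] is the summed branch length common to the root-to-tip paths of
    species i and j; the diagonal is each species' root-to-tip distance.
    Returns (V, species order).
    """
    if not tree.rooted:
        raise ValueError("phylogenetic covariance requires a rooted tree")
    A, order, branches = path_indicator_matrix(tree, order)
    t = tree.lengths[branches]
    V = (A * t) @ A.T
    return V, order


# ---------------------------------------------------------------------------
# Taxon matching and pruning
# ---------------------------------------------------------------------------


@dataclass
class MatchReport:
    """Outcome of matching query species names to tree tips."""

    exact: dict[str, str] = field(default_factory=dict)
    genus: dict[str, str] = field(default_factory=dict)
    unmatched: list[str] = field(default_factory=list)

    @property
    def matched(self) -> dict[str, str]:
        return {**self.exact, **self.genus}


def prune_to_tips(tree: Phylogeny, keep: list[str]) -> Phylogeny:
    """Restrict the tree to the given tip labels, suppressing unifurcations
    (their lengths are summed) and discarding the stale root path."""
    keep_set = set(keep)
    missing = keep_set - set(tree.tip_labels)
    if missing:
        raise ValueError(f"tips not in tree: {sorted(missing)}")
    retain = np.zeros(tree.n_nodes, dtype=bool)
    for n in tree.postorder():
        if not tree.children[n]:
            retain[n] = tree.labels[n] in keep_set
        else:
            retain[n] = any(retain[c] for c in tree.children[n])
    if not retain[tree.root]:
        raise ValueError("no tips retained")

    parent: list[int] = []
    lengths: list[float] = []
    labels: list[str | None] = []

    def build(node: int, new_parent: int, carried: float) -> None:
        kids = [c for c in tree.children[node] if retain[c]]
        is_tip = not tree.children[node]
        if not is_tip and len(kids) == 1 and new_parent != -2:
            # unifurcation (not at the new root): splice through
            build(kids[0], new_parent, carried + tree.lengths[kids[0]])
            return
        idx = len(parent)
        parent.append(new_parent if new_parent >= 0 else -1)
        lengths.append(carried if new_parent >= 0 else 0.0)
        labels.append(tree.labels[node])
        for c in kids:
            build(c, idx, tree.lengths[c])

    # descend past any chain of single-retained-child nodes at the root
    top = tree.root
    while True:
        kids = [c for c in tree.children[top] if retain[c]]
        if len(kids) == 1 and tree.children[top]:
            top = kids[0]
        else:
            break
    build(top, -2, 0.0)
    return Phylogeny(parent, lengths, labels, rooted=tree.rooted)


def match_and_prune(
    tree: Phylogeny, names: list[str], genus_fallback: bool = True
) -> tuple[Phylogeny, MatchReport]:
    """Match query species to tree tips and prune the tree to the matches.

    Exact (normalised) name matches are taken first.  With the genus
    fallback, a remaining query may bind to a single congeneric tip; if the
    genus is ambiguous (two or more candidate tips) the query is recorded as
    unmatched rather than guessed.  Genus-matched tips are relabelled with
    the query name so downstream joins use the data's species names.
    """
    if not names:
        raise ValueError("names must be non-empty")
    queries = [normalize_species_name(n) for n in names]
    tips = set(tree.tip_labels)
    report = MatchReport()
    used: set[str] = set()
    for q in queries:
        if q in tips and q not in used:
            report.exact[q] = q
            used.add(q)
    for q in queries:
        if q in report.exact:
            continue
        if genus_fallback:
            genus = q.split("_")[0]
            cands = [t for t in tips if t.split("_")[0] == genus and t not in used]
            if len(cands) == 1:
                report.genus[q] = cands[0]
                used.add(cands[0])
                continue
        report.unmatched.append(q)
    if not report.matched:
        raise ValueError("no query species could be matched to the tree")
    pruned = prune_to_tips(tree, sorted(used))
    if report.genus:
        rename = {tip: query for query, tip in report.genus.items()}
        for t in pruned.tip_ids():
            if pruned.labels[t] in rename:
                pruned.labels[t] = rename[pruned.labels[t]]
        pruned._branch_keys = None
    return pruned, report


# ---------------------------------------------------------------------------
# Rooting helpers (used by the codon module's dN / dS trees)
# ---------------------------------------------------------------------------


def unroot(tree: Phylogeny) -> Phylogeny:
    """Collapse a bifurcating root into a basal multifurcation and mark the
    tree unrooted (the representation codon models are fitted on).

    The two root branches are merged into one (their lengths summed), which
    is the standard loss of rooting information under a reversible model.
    """
    root_kids = tree.children[tree.root]
    internal_kids = [c for c in root_kids if tree.children[c]]
    if len(root_kids) != 2 or not internal_kids:
        out = tree.copy()
        out.rooted = False
        return out
    keep = internal_kids[0]
    move = root_kids[1] if keep == root_kids[0] else root_kids[0]
    parent = list(tree.parent)
    lengths = [float(x) for x in tree.lengths]
    parent[move] = keep
    lengths[move] = lengths[root_kids[0]] + lengths[root_kids[1]]
    parent[keep] = -1
    lengths[keep] = 0.0
    keep_ids = [i for i in range(tree.n_nodes) if i != tree.root]
    remap = {old: new for new, old in enumerate(keep_ids)}
    new_parent = [-1 if old == keep else remap[parent[old]] for old in keep_ids]
    new_lengths = [lengths[old] for old in keep_ids]
    new_labels = [tree.labels[old] for old in keep_ids]
    return Phylogeny(new_parent, new_lengths, new_labels, rooted=False)


def root_on_outgroup(tree: Phylogeny, outgroup: str, remove_outgroup: bool = True) -> Phylogeny:
    """Root an (un)rooted tree at the attachment point of the outgroup tip and
    optionally drop the outgroup, as done for branch-rate (dN/dS) trees."""
    tip_of = {tree.labels[t]: t for t in tree.tip_ids()}
    if outgroup not in tip_of:
        raise ValueError(f"outgroup {outgroup!r} is not a tip of the tree")
    og = tip_of[outgroup]
    attach = tree.parent[og]
    if attach == -1:
        raise ValueError("outgroup is already the root")
    # re-hang the tree from `attach`: reverse parent pointers along attach->root
    path = [attach]
    while tree.parent[path[-1]] != -1:
        path.append(tree.parent[path[-1]])
    parent = list(tree.parent)
    lengths = list(tree.lengths)
    for child, par in zip(path[:-1], path[1:]):
        parent[par] = child
        lengths[par] = lengths[child]
    parent[attach] = -1
    lengths[attach] = 0.0
    rerooted = Phylogeny(parent, lengths, tree.labels, rooted=True)
    # drop nodes left with a single child (old root) by pruning to tips
    keep = [lab for lab in rerooted.tip_labels if not (remove_outgroup and lab == outgroup)]
    return prune_to_tips(rerooted, keep)


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------


def read_trait_table(path_or_buffer) -> pd.DataFrame:
    """Load a species trait TSV (species, testes_mass_g, body_mass_g, clade).

    Masses are stored in raw grams on disk; log10 is applied exactly once
    here, yielding columns ``testes_mass_log10`` and ``body_mass_log10``.
    """
    df = pd.read_csv(path_or_buffer, sep="\t")
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table is missing columns: {missing}")
    out = pd.DataFrame(
        {
            "species": df["species"].map(normalize_species_name),
            "testes_mass_log10": np.log10(df["testes_mass_g"].astype(float)),
            "body_mass_log10": np.log10(df["body_mass_g"].astype(float)),
            "clade": df["clade"].astype(str),
        }
    )
    validate_trait_table(out)
    return out


def write_trait_table(df: pd.DataFrame, path) -> None:
    """Inverse of :func:`read_trait_table`: write raw grams to TSV."""
    raw = pd.DataFrame(
        {
            "species": df["species"],
            "testes_mass_g": 10.0 ** df["testes_mass_log10"],
            "body_mass_g": 10.0 ** df["body_mass_log10"],
            "clade": df["clade"],
        }
    )
    raw.to_csv(path, sep="\t", index=False)


def validate_trait_table(df: pd.DataFrame) -> None:
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species in trait table: {dups}")
    for col in ("testes_mass_log10", "body_mass_log10"):
        if not np.isfinite(df[col]).all():
            raise ValueError(f"non-finite values in {col} (masses must be positive)")
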