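"""MG94xREV codon substitution likelihoods with branch-wise dN and dS.

The model crosses the Muse–Gaut (1994) synonymous/non-synonymous rate
structure with GTR (REV) nucleotide exchangeabilities: only single-nucleotide
codon changes have non-zero rate, each weighted by the exchangeability of the
nucleotide pair, the F3x4 frequency of the target nucleotide at the changed
position, and a synonymous (dS) or non-synonymous (dN) rate multiplier.
No site-to-site rate variation is modelled.

Two nested fits are provided:

* the *global* model — one shared dN/dS ratio across the tree, with free
  branch scales, so branch b contributes (dS_b, dN_b) = (t_b, omega * t_b);
* the *local* model — free (dS_b, dN_b) on every branch.

The likelihood-ratio statistic D = 2(lnL_local - lnL_global) against
chi-square tests for branch-to-branch variation in molecular rates.  After a
local fit, the per-branch dN and dS values can be exported as two trees
rooted on an outgroup (which is then removed) for root-to-tip summation.

Rates are normalised so that dS_b (dN_b) is the expected number of
synonymous (non-synonymous) substitutions per codon along branch b at the
stationary frequencies, making branch values time-independent.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from Bio import SeqIO
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .treedata import (
    BranchValueMap,
    Phylogeny,
    normalize_species_name,
    root_on_outgroup,
    unroot,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticCode",
    "UNIVERSAL_CODE",
    "CodonAlignment",
    "MG94Params",
    "CodonFitResult",
    "codon_frequencies_f3x4",
    "mg94_q_and_p",
    "pruning_loglik",
    "fit_global",
    "fit_local",
    "lrt_global_vs_local",
    "branch_value_trees",
]

BASES = "ACGT"
NUC_INDEX = {b: i for i, b in enumerate(BASES)}
RHO_PAIRS = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))
RHO_INDEX = {p: i for i, p in enumerate(RHO_PAIRS)}
AG_INDEX = RHO_INDEX[("A", "G")]  # exchangeability fixed to 1 for identifiability

_TINY = 1e-300


class GeneticCode:
    """Sense codons and single-nucleotide neighbour structure for one code table."""

    def __init__(self, table_id: int = 1):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.stop_codons = set(table.stop_codons)
        self.codons = [
            "".join(c) for c in itertools.product(BASES, repeat=3)
            if "".join(c) not in self.stop_codons
        ]
        self.n = len(self.codons)
        self.codon_index = {c: i for i, c in enumerate(self.codons)}
        self.aa = [table.forward_table[c] for c in self.codons]
        # all ordered codon pairs differing at exactly one position
        pi_, pj_, pos_, tgt_, rho_, syn_ = [], [], [], [], [], []
        for i, ci in enumerate(self.codons):
            for j, cj in enumerate(self.codons):
                if i == j:
                    continue
                diffs = [k for k in range(3) if ci[k] != cj[k]]
                if len(diffs) != 1:
                    continue
                k = diffs[0]
                pi_.append(i)
                pj_.append(j)
                pos_.append(k)
                tgt_.append(NUC_INDEX[cj[k]])
                rho_.append(RHO_INDEX[tuple(sorted((ci[k], cj[k])))])
                syn_.append(self.aa[i] == self.aa[j])
        self.pair_i = np.array(pi_)
        self.pair_j = np.array(pj_)
        self.pair_pos = np.array(pos_)
        self.pair_target = np.array(tgt_)
        self.pair_rho = np.array(rho_)
        self.pair_syn = np.array(syn_, dtype=bool)


UNIVERSAL_CODE = GeneticCode(1)


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------


class CodonAlignment:
    """In-frame codon alignment as an integer matrix over the 61 sense codons.

    Gap or ambiguous codons are coded -1 and treated as missing data during
    likelihood computation.  Stop codons among observed states are rejected.
    """

    def __init__(self, species: list[str], codon_matrix: np.ndarray,
                 code: GeneticCode = UNIVERSAL_CODE):
        if len(species) < 3:
            raise ValueError("a codon alignment needs at least 3 sequences")
        if len(set(species)) != len(species):
            raise ValueError("duplicate species names in alignment")
        self.species = list(species)
        self.matrix = np.asarray(codon_matrix, dtype=np.int16)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(species):
            raise ValueError("codon matrix must be (n_species, n_codons)")
        self.code = code

    @property
    def n_codons(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_sequences(cls, named_seqs: list[tuple[str, str]],
                       code: GeneticCode = UNIVERSAL_CODE) -> "CodonAlignment":
        lengths = {len(s) for _, s in named_seqs}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} is not a multiple of 3")
        species, rows = [], []
        for name, seq in named_seqs:
            species.append(normalize_species_name(name))
            seq = seq.upper().replace("U", "T")
            row = []
            for k in range(0, length, 3):
                codon = seq[k:k + 3]
                if codon in code.codon_index:
                    row.append(code.codon_index[codon])
                elif codon in code.stop_codons:
                    raise ValueError(
                        f"stop codon {codon} at codon position {k // 3 + 1} in {name}"
                    )
                else:
                    row.append(-1)  # gap / ambiguity -> missing
            rows.append(row)
        return cls(species, np.array(rows, dtype=np.int16), code)

    @classmethod
    def from_fasta(cls, path, code: GeneticCode = UNIVERSAL_CODE) -> "CodonAlignment":
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no sequences found in {path}")
        return cls.from_sequences(records, code)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sp, row in zip(self.species, self.matrix):
                seq = "".join(
                    self.code.codons[c] if c >= 0 else "---" for c in row
                )
                fh.write(f">{sp}\n{seq}\n")

    def subset(self, species: list[str]) -> "CodonAlignment":
        idx = [self.species.index(s) for s in species]
        return CodonAlignment(list(species), self.matrix[idx], self.code)


# ---------------------------------------------------------------------------
# Parameters and rate matrices
# ---------------------------------------------------------------------------


@dataclass
class MG94Params:
    """GTR exchangeabilities, F3x4 frequencies, and rate multipliers."""

    rho: np.ndarray                      # 6 exchangeabilities, AG fixed to 1
    pi: np.ndarray                       # 61 codon frequencies (sum 1)
    pi_pos: np.ndarray                   # 3x4 positional nucleotide frequencies
    alpha: float | None = None           # global synonymous rate (fixed to 1 in fits)
    beta: float | None = None            # global non-synonymous rate (= omega here)
    code: GeneticCode = field(default=UNIVERSAL_CODE, repr=False)

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.shape != (6,) or np.any(self.rho <= 0):
            raise ValueError("rho must be 6 positive exchangeabilities")
        self.pi = np.asarray(self.pi, dtype=float)
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-8):
            raise ValueError("pi must sum to 1")


def codon_frequencies_f3x4(aln: CodonAlignment) -> tuple[np.ndarray, np.ndarray]:
    """F3x4 equilibrium codon frequencies.

    Per-position nucleotide frequencies are estimated from the observed
    codons and multiplied across the three positions; stop codons are
    excluded and the 61-vector renormalised.  A zero nucleotide frequency at
    any position is floored at 1e-6 (then renormalised) so the chain stays
    irreducible.

    Returns (pi_61, pi_pos_3x4).
    """
    code = aln.code
    counts = np.zeros((3, 4))
    codon_nucs = np.array([[NUC_INDEX[c[k]] for k in range(3)] for c in code.codons])
    observed = aln.matrix[aln.matrix >= 0]
    for k in range(3):
        counts[k] = np.bincount(codon_nucs[observed, k], minlength=4)
    if counts.sum() == 0:
        counts[:] = 1.0
    pi_pos = counts / counts.sum(axis=1, keepdims=True)
    floored = pi_pos < 1e-6
    if floored.any():
        logger.info("F3x4: flooring %d zero nucleotide frequencies at 1e-6", floored.sum())
        pi_pos = np.maximum(pi_pos, 1e-6)
        pi_pos /= pi_pos.sum(axis=1, keepdims=True)
    pi = pi_pos[0, codon_nucs[:, 0]] * pi_pos[1, codon_nucs[:, 1]] * pi_pos[2, codon_nucs[:, 2]]
    pi /= pi.sum()
    return pi, pi_pos


def _build_rate_parts(params: MG94Params) -> tuple[np.ndarray, np.ndarray]:
    """Off-diagonal synonymous and non-synonymous rate matrices, each scaled
    to one expected substitution per codon per unit at stationarity."""
    code = params.code
    rates = params.rho[code.pair_rho] * params.pi_pos[code.pair_pos, code.pair_target]
    Qs = np.zeros((code.n, code.n))
    Qn = np.zeros((code.n, code.n))
    syn = code.pair_syn
    Qs[code.pair_i[syn], code.pair_j[syn]] = rates[syn]
    Qn[code.pair_i[~syn], code.pair_j[~syn]] = rates[~syn]
    flux_s = float(params.pi @ Qs.sum(axis=1))
    flux_n = float(params.pi @ Qn.sum(axis=1))
    return Qs / flux_s, Qn / flux_n


class _EigCache:
    """Eigendecompositions of the reversible generator, keyed by the dN:dS mix.

    Q(dS, dN) = dS*Qs + dN*Qn = c * M(u) with u = dN/(dS+dN), c = dS+dN, so a
    single symmetric eigendecomposition of M serves every branch scale."""

    def __init__(self, params: MG94Params):
        self.Qs, self.Qn = _build_rate_parts(params)
        self.pi = params.pi
        sq = np.sqrt(params.pi)
        self._d = sq
        self._dinv = 1.0 / sq
        self._cache: dict[float, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def decompose(self, u: float):
        key = round(float(u), 12)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        M = (1.0 - u) * self.Qs + u * self.Qn
        np.fill_diagonal(M, 0.0)
        M[np.diag_indices_from(M)] = -M.sum(axis=1)
        S = (self._d[:, None] * M) * self._dinv[None, :]
        S = 0.5 * (S + S.T)  # exact symmetry (reversibility) up to rounding
        w, U = np.linalg.eigh(S)
        left = self._dinv[:, None] * U           # D^-1/2 U
        right = U.T * self._d[None, :]           # U^T D^1/2
        out = (w, left, right)
        if len(self._cache) > 512:
            self._cache.clear()
        self._cache[key] = out
        return out

    def p_matrix(self, ds: float, dn: float) -> np.ndarray:
        c = ds + dn
        if c <= 0:
            return np.eye(len(self.pi))
        w, left, right = self.decompose(dn / c)
        P = (left * np.exp(w * c)) @ right
        np.clip(P, 0.0, None, out=P)
        return P

    def q_matrix(self, ds: float, dn: float) -> np.ndarray:
        Q = ds * self.Qs + dn * self.Qn
        np.fill_diagonal(Q, 0.0)
        Q[np.diag_indices_from(Q)] = -Q.sum(axis=1)
        return Q


def mg94_q_and_p(params: MG94Params, s: float, n: float, t: float = 1.0):
    """Instantaneous rate matrix Q for branch rates (s, n) and its transition
    matrix P = exp(Q t).  Rows of Q sum to 0, rows of P to 1, and detailed
    balance pi_i q_ij = pi_j q_ji holds."""
    if s < 0 or n < 0 or t < 0:
        raise ValueError("rates and time scale must be non-negative")
    cache = _EigCache(params)
    Q = cache.q_matrix(s, n)
    P = cache.p_matrix(s * t, n * t)
    return Q, P


# ---------------------------------------------------------------------------
# Pruning engine
# ---------------------------------------------------------------------------


class _PruningContext:
    """Felsenstein pruning over site patterns with per-site scaling.

    Holds the fitting tree (any rooted representation; reversibility makes
    the virtual root placement irrelevant), the tip states compressed to
    unique alignment columns, and scratch message arrays for fast per-branch
    likelihood curves.
    """

    def __init__(self, tree: Phylogeny, aln: CodonAlignment):
        tree_tips = set(tree.tip_labels)
        aln_sp = set(aln.species)
        if not tree_tips <= aln_sp:
            raise ValueError(
                "species mismatch between tree and alignment: "
                f"tree-only={sorted(tree_tips - aln_sp)}"
            )
        self.tree = tree
        self.code = aln.code
        order = [aln.species.index(tree.labels[t]) for t in tree.tip_ids()]
        cols = aln.matrix[order].T  # (sites, tips)
        patterns, inverse, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True
        )
        self.weights = counts.astype(float)
        self.n_patterns = patterns.shape[0]
        self.n_sites = cols.shape[0]
        self.tip_states = {
            tid: patterns[:, k] for k, tid in enumerate(tree.tip_ids())
        }
        self.post = [n for n in tree.postorder() if tree.children[n]]
        self.parent = tree.parent
        self.children = tree.children
        self.root = tree.root
        self.branches = tree.branch_ids()

    # -- tip up-message: rows of P.T picked by state ------------------------

    def _up_from_tip(self, tid: int, P: np.ndarray) -> np.ndarray:
        states = self.tip_states[tid]
        up = np.empty((self.n_patterns, P.shape[0]))
        ok = states >= 0
        up[ok] = P[:, states[ok]].T
        if (~ok).any():
            up[~ok] = 1.0  # missing data: partial likelihood 1
        return up

    def compute_up(self, Ps: dict[int, np.ndarray]):
        """Post-order partials.  Returns (L, Llog, up, uplog) keyed by node:
        L[v] are scaled subtree partials at v, up[v] the message from v to its
        parent (over parent states)."""
        L: dict[int, np.ndarray] = {}
        Llog: dict[int, np.ndarray] = {}
        up: dict[int, np.ndarray] = {}
        uplog: dict[int, np.ndarray] = {}
        for v in self.tree.postorder():
            kids = self.children[v]
            if kids:
                arr = up[kids[0]].copy()
                lg = uplog[kids[0]].copy()
                for c in kids[1:]:
                    arr *= up[c]
                    lg += uplog[c]
                mx = arr.max(axis=1)
                mx[mx <= 0] = 1.0
                arr /= mx[:, None]
                lg += np.log(mx)
                L[v] = arr
                Llog[v] = lg
            if v != self.root:
                P = Ps[v]
                if kids:
                    up[v] = L[v] @ P.T
                    uplog[v] = Llog[v]
                else:
                    up[v] = self._up_from_tip(v, P)
                    uplog[v] = np.zeros(self.n_patterns)
        return L, Llog, up, uplog

    def loglik(self, Ps: dict[int, np.ndarray], pi: np.ndarray) -> float:
        L, Llog, _, _ = self.compute_up(Ps)
        site = L[self.root] @ pi
        return float(self.weights @ (np.log(np.maximum(site, _TINY)) + Llog[self.root]))

    def compute_down(self, Ps, pi, L, Llog, up, uplog):
        """Pre-order outside messages.  down[u] is, per pattern, the partial
        likelihood of everything outside the subtree of u, expressed over the
        states at u (prior pi folded in at the root)."""
        down: dict[int, np.ndarray] = {}
        downlog: dict[int, np.ndarray] = {}
        down[self.root] = np.broadcast_to(pi, (self.n_patterns, len(pi))).copy()
        downlog[self.root] = np.zeros(self.n_patterns)
        for u in self.tree.preorder():
            kids = self.children[u]
            if not kids:
                continue
            for v in kids:
                F = down[u].copy()
                lg = downlog[u].copy()
                for c in kids:
                    if c != v:
                        F *= up[c]
                        lg += uplog[c]
                mx = F.max(axis=1)
                mx[mx <= 0] = 1.0
                F /= mx[:, None]
                lg += np.log(mx)
                down[v] = F @ Ps[v]
                downlog[v] = lg
                # keep the pre-propagation outside message for branch curves
                down[v + self.tree.n_nodes] = F  # type: ignore[index]
                downlog[v + self.tree.n_nodes] = lg
        return down, downlog


# ---------------------------------------------------------------------------
# Public likelihood
# ---------------------------------------------------------------------------


def pruning_loglik(
    aln: CodonAlignment,
    tree: Phylogeny,
    params: MG94Params,
    branch_rates: dict[tuple[str, ...], tuple[float, float]],
) -> float:
    """Log-likelihood of the alignment under MG94xREV with per-branch
    (dS_b, dN_b), by Felsenstein pruning over the 61 sense codons.

    ``branch_rates`` maps branch identities (tip-set keys) to (dS, dN).
    """
    ctx = _PruningContext(tree, aln)
    cache = _EigCache(params)
    Ps = {}
    for v in tree.branch_ids():
        key = tree.branch_key(v)
        if key not in branch_rates:
            raise ValueError(f"no branch rates supplied for branch {key}")
        ds, dn = branch_rates[key]
        Ps[v] = cache.p_matrix(ds, dn)
    return ctx.loglik(Ps, params.pi)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class CodonFitResult:
    """Maximised codon-model fit: likelihood, parameters and diagnostics."""

    model: str                       # "global" | "local"
    loglik: float
    n_params: int
    params: MG94Params
    tree: Phylogeny                  # the (unrooted) fitting representation
    branch_ds: dict[tuple[str, ...], float]
    branch_dn: dict[tuple[str, ...], float]
    omega: float | None = None
    converged: bool = True
    n_iter: int = 0

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "omega": self.omega,
            "rho": list(self.params.rho),
            "converged": self.converged,
        }


_LOG_T_BOUNDS = (np.log(1e-7), np.log(8.0))
_LOG_W_BOUNDS = (np.log(1e-4), np.log(40.0))
_RATE_FLOOR = 1e-7


def _branch_curve(F, Flog, Lv, Lvlog, tip_states, w, left, right, weights):
    """Site likelihood curve along one branch as a function of its scale c:
    lnL(c) = sum_s w_s log( sum_k A_sk B_sk exp(w_k c) ) + const."""
    A = F @ left
    if tip_states is not None:
        B = np.empty_like(A)
        ok = tip_states >= 0
        B[ok] = right[:, tip_states[ok]].T
        if (~ok).any():
            B[~ok] = right.sum(axis=1)
        lg = Flog
    else:
        B = Lv @ right.T
        lg = Flog + Lvlog
    C = A * B
    const = float(weights @ lg)

    def negloglik(c: float) -> float:
        site = C @ np.exp(w * c)
        return -(float(weights @ np.log(np.maximum(site, _TINY))) + const)

    return negloglik


def _optimize_branch_scale(curve, eig, xatol=2e-3):
    """Optimise one branch's scale t with the generator eigendecomposition fixed
    (global model: dS_b = t, dN_b = omega * t)."""
    w, left, right = eig
    neg = curve(w, left, right)
    res = minimize_scalar(
        lambda lt: neg(np.exp(lt)),
        bounds=_LOG_T_BOUNDS, method="bounded",
        options={"xatol": xatol},
    )
    return float(np.exp(res.x)), -float(res.fun)


def _optimize_branch_local(curve, cache, ds0, dn0, xatol=2e-3, window=4.5):
    """Optimise one branch's free (dS, dN) by nested Brent line searches on the
    mix u = dN/(dS+dN) (outer, one eigendecomposition each) and the total
    scale c = dS+dN (inner, nearly free given the decomposition)."""
    best = {"neg": np.inf, "u": dn0 / max(ds0 + dn0, _RATE_FLOOR), "c": ds0 + dn0}

    def outer(lu: float) -> float:
        # quantise the mix so the eigendecomposition cache is shared across
        # branches and sweeps; the scale is re-optimised exactly at each mix
        lu = round(lu / 0.04) * 0.04
        u = 1.0 / (1.0 + np.exp(-lu))
        w, left, right = cache.decompose(u)
        neg = curve(w, left, right)
        res = minimize_scalar(
            lambda lc: neg(np.exp(lc)),
            bounds=(np.log(2e-7), np.log(12.0)), method="bounded",
            options={"xatol": xatol},
        )
        if res.fun < best["neg"]:
            best.update(neg=float(res.fun), u=u, c=float(np.exp(res.x)))
        return float(res.fun)

    lu0 = np.log(max(dn0, _RATE_FLOOR)) - np.log(max(ds0, _RATE_FLOOR))
    minimize_scalar(
        outer, bounds=(max(lu0 - window, -14.0), min(lu0 + window, 10.0)),
        method="bounded", options={"xatol": 0.03},
    )
    u, c = best["u"], best["c"]
    return (max(c * (1 - u), _RATE_FLOOR), max(c * u, _RATE_FLOOR)), -best["neg"]


def _fitting_tree(tree: Phylogeny, aln: CodonAlignment) -> Phylogeny:
    """Prune to alignment species and unroot, discarding time information."""
    from .treedata import prune_to_tips

    keep = [lab for lab in tree.tip_labels if lab in set(aln.species)]
    if len(keep) < 3:
        raise ValueError("fewer than 3 species shared between tree and alignment")
    return unroot(prune_to_tips(tree, keep))


def _all_p(cache, dsn: dict[int, tuple[float, float]]):
    return {v: cache.p_matrix(ds, dn) for v, (ds, dn) in dsn.items()}


def fit_global(
    aln: CodonAlignment,
    tree: Phylogeny,
    seed: int = 0,
    *,
    max_outer: int = 8,
    tol: float = 1e-3,
    n_starts: int = 1,
) -> CodonFitResult:
    """Fit the global MG94xREV model: shared omega, free branch scales.

    Branch b contributes dS_b = t_b and dN_b = omega * t_b.  Optimisation is
    cyclic: branch scales by per-branch Brent line searches against cached
    outside messages, omega by Brent, exchangeabilities by L-BFGS-B.
    """
    rng = np.random.default_rng(seed)
    ftree = _fitting_tree(tree, aln)
    ctx = _PruningContext(ftree, aln)
    pi, pi_pos = codon_frequencies_f3x4(aln)

    best = None
    for start in range(max(1, n_starts)):
        if start == 0:
            omega, t0, log_rho = 0.3, 0.08, np.zeros(6)
        else:
            omega = float(np.exp(rng.uniform(np.log(0.05), np.log(2.0))))
            t0 = float(np.exp(rng.uniform(np.log(0.01), np.log(0.5))))
            log_rho = rng.normal(0.0, 0.3, size=6)
            log_rho[AG_INDEX] = 0.0
        fit = _fit_global_once(ctx, pi, pi_pos, omega, t0, log_rho,
                               max_outer=max_outer, tol=tol)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


_FREE_RHO = [i for i in range(6) if i != AG_INDEX]


def _fit_global_once(ctx, pi, pi_pos, omega, t0, log_rho, max_outer, tol):
    ftree = ctx.tree
    branches = ftree.branch_ids()
    B = len(branches)
    t = {v: t0 for v in branches}
    rho = np.exp(log_rho)
    cache = _EigCache(MG94Params(rho=rho, pi=pi, pi_pos=pi_pos))

    def full_ll() -> float:
        Ps = _all_p(cache, {v: (tv, omega * tv) for v, tv in t.items()})
        return ctx.loglik(Ps, pi)

    ll = full_ll()
    n_outer = 0
    for it in range(max_outer):
        n_outer += 1
        # branch scales, eigendecomposition shared across the sweep
        eig = cache.decompose(omega / (1.0 + omega))
        Ps = _all_p(cache, {v: (tv, omega * tv) for v, tv in t.items()})

        def assign(v, val, _Ps=Ps):
            # the line search is over the total scale c = dS + dN = t*(1+omega)
            t[v] = val / (1.0 + omega)
            _Ps[v] = cache.p_matrix(t[v], omega * t[v])

        _sweep(ctx, Ps, pi, branches,
               lambda v, curve: _optimize_branch_scale(curve, eig),
               assign)

        # shared omega line search
        def neg_omega(lw):
            om = float(np.exp(lw))
            P = _all_p(cache, {v: (tv, om * tv) for v, tv in t.items()})
            return -ctx.loglik(P, pi)

        res = minimize_scalar(neg_omega, bounds=_LOG_W_BOUNDS, method="bounded",
                              options={"xatol": 1e-3})
        omega = float(np.exp(res.x))

        # exchangeabilities (AG fixed at 1); expensive, so optimised once the
        # branch scales and omega have settled
        if it == 1:
            def neg_rho(x):
                r = rho.copy()
                r[_FREE_RHO] = np.exp(x)
                c = _EigCache(MG94Params(rho=r, pi=pi, pi_pos=pi_pos))
                P = _all_p(c, {v: (tv, omega * tv) for v, tv in t.items()})
                return -ctx.loglik(P, pi)

            resr = minimize(neg_rho, np.log(rho[_FREE_RHO]), method="L-BFGS-B",
                            bounds=[(np.log(1e-3), np.log(100.0))] * 5,
                            options={"maxiter": 12, "ftol": 1e-9})
            rho = rho.copy()
            rho[_FREE_RHO] = np.exp(resr.x)
        cache = _EigCache(MG94Params(rho=rho, pi=pi, pi_pos=pi_pos))
        new_ll = full_ll()
        if new_ll - ll < tol and it >= 1:
            ll = new_ll
            break
        ll = new_ll

    params = MG94Params(rho=rho, pi=pi, pi_pos=pi_pos, alpha=1.0, beta=omega)
    branch_ds = {ftree.branch_key(v): t[v] for v in branches}
    branch_dn = {ftree.branch_key(v): omega * t[v] for v in branches}
    return CodonFitResult(
        model="global", loglik=ll, n_params=5 + B + 1,
        params=params, tree=ftree,
        branch_ds=branch_ds, branch_dn=branch_dn,
        omega=omega, n_iter=n_outer,
    )


def _sweep(ctx, Ps, pi, branches, optimize_one, assign, refresh_every: int = 8):
    """One pass of per-branch optimisation against cached outside messages.

    Messages are refreshed every ``refresh_every`` branch updates (stale
    siblings only shift the line-search target slightly; a final refresh
    restores exactness).  Returns the final full log-likelihood.
    """
    L, Llog, up, uplog = ctx.compute_up(Ps)
    down, downlog = ctx.compute_down(Ps, pi, L, Llog, up, uplog)
    n_nodes = ctx.tree.n_nodes
    since = 0
    for v in branches:
        u_node = ctx.parent[v]
        if u_node == -1:
            continue
        F = down[v + n_nodes]
        Flog = downlog[v + n_nodes]
        is_tip = not ctx.children[v]
        tip_states = ctx.tip_states[v] if is_tip else None
        Lv = None if is_tip else L[v]
        Lvlog = None if is_tip else Llog[v]

        def curve(w, left, right):
            return _branch_curve(F, Flog, Lv, Lvlog, tip_states, w, left, right,
                                 ctx.weights)

        val, _ = optimize_one(v, curve)
        assign(v, val)
        since += 1
        if since >= refresh_every:
            L, Llog, up, uplog = ctx.compute_up(Ps)
            down, downlog = ctx.compute_down(Ps, pi, L, Llog, up, uplog)
            since = 0
    return ctx.loglik(Ps, pi)


def fit_local(
    aln: CodonAlignment,
    tree: Phylogeny,
    seed: int = 0,
    *,
    init: CodonFitResult | None = None,
    max_sweeps: int = 5,
    sweep_tol: float = 0.02,
) -> CodonFitResult:
    """Fit the local MG94xREV model: free (dS_b, dN_b) on every branch.

    Initialised from the global fit (run here if not supplied); the shared
    exchangeabilities stay at the global-model estimates.  The fit is nested
    above the global model, so lnL_local >= lnL_global up to optimiser
    tolerance.
    """
    if init is None:
        init = fit_global(aln, tree, seed=seed)
    ftree = init.tree
    ctx = _PruningContext(ftree, aln)
    pi, pi_pos = init.params.pi, init.params.pi_pos
    rho = init.params.rho.copy()
    branches = ftree.branch_ids()
    B = len(branches)
    dsn = {
        v: (max(init.branch_ds[ftree.branch_key(v)], 1e-5),
            max(init.branch_dn[ftree.branch_key(v)], 1e-6))
        for v in branches
    }

    params = MG94Params(rho=rho, pi=pi, pi_pos=pi_pos)
    cache = _EigCache(params)

    def full_ll():
        return ctx.loglik(_all_p(cache, dsn), pi)

    # shared exchangeabilities are held at the global-model estimates: they
    # are common to both models, so the likelihood-ratio difference is (if
    # anything) slightly conservative
    ll = full_ll()
    n_sweeps = 0
    for sweep_no in range(max_sweeps):
        n_sweeps += 1
        Ps = _all_p(cache, dsn)
        window = 4.5 if sweep_no == 0 else 2.0

        def assign(v, val, _Ps=Ps, _cache=cache):
            dsn[v] = val
            _Ps[v] = _cache.p_matrix(*val)

        ll_new = _sweep(
            ctx, Ps, pi, branches,
            lambda v, curve, _cache=cache, _w=window: _optimize_branch_local(
                curve, _cache, *dsn[v], window=_w),
            assign,
        )
        if ll_new - ll < sweep_tol and sweep_no >= 1:
            ll = ll_new
            break
        ll = ll_new

    converged = True
    if ll < init.loglik - 1e-4:
        warnings.warn(
            f"local fit ({ll:.4f}) below nested global fit ({init.loglik:.4f}); "
            "optimiser did not converge", RuntimeWarning,
        )
        converged = False

    result = CodonFitResult(
        model="local", loglik=ll, n_params=5 + 2 * B,
        params=params, tree=ftree,
        branch_ds={ftree.branch_key(v): dsn[v][0] for v in branches},
        branch_dn={ftree.branch_key(v): dsn[v][1] for v in branches},
        omega=None, converged=converged, n_iter=n_sweeps,
    )
    return result


def lrt_global_vs_local(global_fit: CodonFitResult,
                        local_fit: CodonFitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test D = 2(lnL_local - lnL_global), clipped at 0,
    against chi-square with df = difference in parameter counts."""
    df = local_fit.n_params - global_fit.n_params
    if df <= 0:
        raise ValueError(
            f"models are not nested: local has {local_fit.n_params} parameters, "
            f"global {global_fit.n_params}"
        )
    D = max(0.0, 2.0 * (local_fit.loglik - global_fit.loglik))
    p = float(chi2.sf(D, df))
    return D, df, p


# ---------------------------------------------------------------------------
# Branch-value tree export
# ---------------------------------------------------------------------------


def branch_value_trees(
    local_fit: CodonFitResult, outgroup: str
) -> tuple[Phylogeny, Phylogeny, BranchValueMap, BranchValueMap]:
    """Export dN and dS trees from a local fit.

    The unrooted fitting tree is rooted on the outgroup, the outgroup is
    removed, and each remaining branch carries its fitted dN (resp. dS) as
    its length.  Returns (dn_tree, ds_tree, BranchValueMap[dN],
    BranchValueMap[dS]) keyed on the rooted, outgroup-free tree.
    """
    ftree = local_fit.tree
    rooted = root_on_outgroup(ftree, outgroup, remove_outgroup=True)
    all_tips = frozenset(ftree.tip_labels)

    def side_of(key: tuple[str, ...]) -> frozenset:
        s = frozenset(key)
        return s if outgroup not in s else all_tips - s

    by_side_dn = {side_of(k): v for k, v in local_fit.branch_dn.items()}
    by_side_ds = {side_of(k): v for k, v in local_fit.branch_ds.items()}

    dn_map: dict[tuple[str, ...], float] = {}
    ds_map: dict[tuple[str, ...], float] = {}
    for node in rooted.branch_ids():
        key = rooted.branch_key(node)
        side = frozenset(key)
        if side not in by_side_dn:
            raise KeyError(f"no fitted rates for branch {key}")
        dn_map[key] = by_side_dn[side]
        ds_map[key] = by_side_ds[side]

    dn_tree = rooted.copy()
    ds_tree = rooted.copy()
    for node in rooted.branch_ids():
        key = rooted.branch_key(node)
        dn_tree.lengths[node] = dn_map[key]
        ds_tree.lengths[node] = ds_map[key]
    return dn_tree, ds_tree, BranchValueMap("dN", dn_map), BranchValueMap("dS", ds_map)
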