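"""Bayesian variable-rates phylogenetic regression.

The trait regression (log10 testes mass on clade-specific allometries of
log10 body mass) has phylogenetically structured residuals: under the base
model they follow Brownian motion with a single background rate sigma^2_b,
so the residual covariance is sigma^2_b * V where V holds shared root-to-tip
path lengths.  The variable-rates extension assigns a subset of branches
rate scalars r != 1 that stretch (r > 1) or compress (r < 1) their lengths,
and explores that subset by reversible-jump MCMC alongside Metropolis
updates of the regression coefficients, sigma^2_b and the scalar values.

Model support is compared by stepping-stone estimates of the log marginal
likelihood, combined into a log Bayes factor BF = 2(log m1 - log m0), with
positive values favouring the variable-rates model; BF is read against
Raftery's scale.  The posterior median scalar per branch defines the
rate-scaled tree (branch lengths rt) whose root-to-tip sums are R_phen.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from .treedata import BranchValueMap, Phylogeny, path_indicator_matrix, scale_branches

__all__ = [
    "RegressionDesign",
    "VarRatesConfig",
    "VarRatesState",
    "PosteriorTrace",
    "MarginalLikelihoodEstimate",
    "design_from_traits",
    "gls_loglik",
    "varrates_mcmc",
    "median_rate_tree",
    "stepping_stone_logml",
    "ss_ladder",
    "ss_accumulate",
    "bayes_factor",
    "raftery_category",
]


# ---------------------------------------------------------------------------
# Design and likelihood
# ---------------------------------------------------------------------------


@dataclass
class RegressionDesign:
    """Response and predictor matrix bound to a species order."""

    y: np.ndarray
    X: np.ndarray
    colnames: list[str]
    species: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[0] != len(self.y) or len(self.species) != len(self.y):
            raise ValueError("design rows must align with species")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("predictor matrix is rank deficient")


def design_from_traits(traits: pd.DataFrame,
                       species_order: list[str] | None = None) -> RegressionDesign:
    """Clade-specific allometric design: one intercept and one log-body-mass
    slope per clade, with log testes mass as the response."""
    df = traits.set_index("species")
    if species_order is None:
        species_order = sorted(df.index)
    df = df.loc[species_order]
    clades = sorted(df["clade"].unique())
    cols, names = [], []
    body = df["body_mass_log10"].to_numpy()
    for cl in clades:
        ind = (df["clade"] == cl).to_numpy(dtype=float)
        cols.append(ind)
        names.append(f"intercept[{cl}]")
        # a clade-specific slope is only identifiable with enough spread
        if ind.sum() >= 3 and np.std(body[ind > 0]) > 1e-8:
            cols.append(ind * body)
            names.append(f"slope_body[{cl}]")
    X = np.column_stack(cols)
    return RegressionDesign(df["testes_mass_log10"].to_numpy(), X, names,
                            list(species_order))


@dataclass
class VarRatesState:
    """One point in the variable-rates parameter space."""

    beta: np.ndarray
    sigma2: float
    scalars: dict[tuple[str, ...], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if any(r <= 0 for r in self.scalars.values()):
            raise ValueError("rate scalars must be positive")


def gls_loglik(design: RegressionDesign, V: np.ndarray,
               state: VarRatesState, jitter: float = 1e-10) -> float:
    """Log density of the residuals under N(0, sigma2 * V).

    ``V`` must already reflect any rate scaling of the tree.  A relative
    jitter keeps the factorisation stable; a matrix still singular after
    jitter raises with its condition number.
    """
    n = len(design.y)
    e = design.y - design.X @ state.beta
    Vj = V + np.eye(n) * (jitter * float(np.mean(np.diag(V))))
    try:
        c, low = cho_factor(Vj, lower=True)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(Vj)
        raise np.linalg.LinAlgError(
            f"covariance matrix singular after jitter (cond={cond:.3e})"
        ) from exc
    z = cho_solve((c, low), e)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c)))) + n * math.log(state.sigma2)
    quad = float(e @ z) / state.sigma2
    return -0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)


# ---------------------------------------------------------------------------
# Chain configuration and output containers
# ---------------------------------------------------------------------------


@dataclass
class VarRatesConfig:
    """Chain settings.  The defaults are desk-scale (2e6 single-parameter
    updates, 10% burn-in, 1000 retained samples); heavier published settings
    are reached by raising ``iterations``."""

    iterations: int = 2_000_000
    burnin_frac: float = 0.1
    n_samples: int = 1000
    lnr_sd: float = 1.5                # prior sd of ln r for assigned branches
    beta_bound: float = 100.0          # flat prior box half-width per coefficient
    log_s2_bounds: tuple = (math.log(1e-8), math.log(1e3))
    jitter: float = 1e-10
    ess_warn: float = 50.0


@dataclass
class PosteriorTrace:
    """Thinned MCMC output (iteration numbers strictly increasing)."""

    iterations: np.ndarray
    loglik: np.ndarray
    sigma2: np.ndarray
    beta: np.ndarray                       # (S, p)
    k: np.ndarray                          # number of scaled branches
    scalars: list[dict[tuple[str, ...], float]]
    colnames: list[str]
    branch_keys: list[tuple[str, ...]]
    acceptance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.iterations) == 0:
            raise ValueError("empty trace")
        if np.any(np.diff(self.iterations) <= 0):
            raise ValueError("iteration numbers must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"iteration": self.iterations, "lnL": self.loglik,
                           "sigma2_b": self.sigma2, "k": self.k})
        for j, name in enumerate(self.colnames):
            df[name] = self.beta[:, j]
        return df


@dataclass
class MarginalLikelihoodEstimate:
    """Stepping-stone log marginal likelihood."""

    logml: float
    stones: int
    iters_per_stone: int
    shape: tuple = (0.40, 1.0)

    def __post_init__(self) -> None:
        if self.stones < 2:
            raise ValueError("need at least 2 stones")
        if not math.isfinite(self.logml):
            raise ValueError("log marginal likelihood must be finite")


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------


class _VRModel:
    """Likelihood machinery over branch scalars, with cached covariance."""

    def __init__(self, design: RegressionDesign, tree: Phylogeny,
                 config: VarRatesConfig):
        self.design = design
        self.cfg = config
        A, order, branch_nodes = path_indicator_matrix(tree, design.species)
        self.A = A
        self.t = tree.lengths[branch_nodes].astype(float)
        self.keys = [tree.branch_key(b) for b in branch_nodes]
        self.B = len(branch_nodes)
        self.n = len(design.y)
        self.jit = config.jitter

    def V_of(self, r: np.ndarray) -> np.ndarray:
        V = (self.A * (self.t * r)) @ self.A.T
        V[np.diag_indices_from(V)] += self.jit * max(float(np.mean(np.diag(V))), 1e-12)
        return V

    def chol(self, V):
        return cho_factor(V, lower=True)

    def loglik(self, beta, sigma2, chol) -> float:
        e = self.design.y - self.design.X @ beta
        z = cho_solve(chol, e)
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0])))) + self.n * math.log(sigma2)
        quad = float(e @ z) / sigma2
        return -0.5 * (self.n * math.log(2 * math.pi) + logdet + quad)


def _gls_beta_start(design: RegressionDesign) -> np.ndarray:
    X, y = design.X, design.y
    return np.linalg.lstsq(X, y, rcond=None)[0]


# ---------------------------------------------------------------------------
# Compiled chain kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _ll_of(A, tr, y, X, beta, sigma2, jit):
    """MVN log density of residuals with V = A diag(tr) A^T (+ jitter)."""
    n = A.shape[0]
    V = (A * tr) @ A.T
    mdiag = 0.0
    for i in range(n):
        mdiag += V[i, i]
    mdiag = max(mdiag / n, 1e-12)
    for i in range(n):
        V[i, i] += jit * mdiag
    L = np.linalg.cholesky(V)
    e = y - X @ beta
    # solve L z = e
    z = np.empty(n)
    for i in range(n):
        s = e[i]
        for j in range(i):
            s -= L[i, j] * z[j]
        z[i] = s / L[i, i]
    logdet = 0.0
    quad = 0.0
    for i in range(n):
        logdet += 2.0 * np.log(L[i, i])
        quad += z[i] * z[i]
    return -0.5 * (n * np.log(2 * np.pi) + logdet + n * np.log(sigma2)
                   + quad / sigma2)


@njit(cache=True)
def _chain_kernel(A, t, y, X, bstep_dir, iterations, burnin, n_collect,
                  power, rj, seed, beta0, log_s2_0, r0,
                  lnr_sd, beta_bound, lo_s2, hi_s2, jit, adapt):
    """Metropolis / reversible-jump sweep kernel.

    Returns thinned samples (iteration, lnL, sigma2, beta, k, r rows), the
    final state, acceptance counters and, when n_collect == 0, the raw
    post-burn-in lnL series (for stepping-stone stones).
    """
    np.random.seed(seed)
    n, p = X.shape
    B = len(t)
    beta = beta0.copy()
    log_s2 = log_s2_0
    r = r0.copy()
    active = np.zeros(B, dtype=np.bool_)
    for b in range(B):
        if r[b] != 1.0:
            active[b] = True
    k = int(active.sum())

    tr = t * r
    ll = _ll_of(A, tr, y, X, beta, np.exp(log_s2), jit)

    s_beta, s_sigma, s_rval = 0.5, 0.5, 0.5
    acc = np.zeros(5, dtype=np.int64)    # beta, sigma, rval, birth, death
    tries = np.zeros(5, dtype=np.int64)
    awin = np.zeros(3, dtype=np.int64)
    twin = np.zeros(3, dtype=np.int64)

    thin = 1
    if n_collect > 0:
        thin = max(1, (iterations - burnin) // n_collect)
    max_samp = n_collect if n_collect > 0 else 0
    out_iter = np.zeros(max_samp, dtype=np.int64)
    out_ll = np.zeros(max_samp)
    out_s2 = np.zeros(max_samp)
    out_beta = np.zeros((max_samp, p))
    out_k = np.zeros(max_samp, dtype=np.int64)
    out_r = np.zeros((max_samp, B))
    n_out = 0
    stone_ll = np.zeros(iterations - burnin if n_collect == 0 else 0)
    n_stone = 0

    n_moves = 4 if rj else 2
    for it in range(iterations):
        move = np.random.randint(n_moves)
        if move == 0:
            twin[0] += 1
            tries[0] += 1
            prop = beta + s_beta * (bstep_dir @ np.random.standard_normal(p))
            ok = True
            for j in range(p):
                if abs(prop[j]) >= beta_bound:
                    ok = False
            if ok:
                ll_new = _ll_of(A, tr, y, X, prop, np.exp(log_s2), jit)
                if np.log(np.random.random() + 1e-300) < power * (ll_new - ll):
                    beta = prop
                    ll = ll_new
                    acc[0] += 1
                    awin[0] += 1
        elif move == 1:
            twin[1] += 1
            tries[1] += 1
            prop_ls = log_s2 + s_sigma * np.random.standard_normal()
            if lo_s2 < prop_ls < hi_s2:
                ll_new = _ll_of(A, tr, y, X, beta, np.exp(prop_ls), jit)
                if np.log(np.random.random() + 1e-300) < power * (ll_new - ll):
                    log_s2 = prop_ls
                    ll = ll_new
                    acc[1] += 1
                    awin[1] += 1
        elif move == 2:
            if k > 0:
                twin[2] += 1
                tries[2] += 1
                pick = np.random.randint(k)
                b = -1
                cnt = -1
                for bb in range(B):
                    if active[bb]:
                        cnt += 1
                        if cnt == pick:
                            b = bb
                            break
                lnr_old = np.log(r[b])
                lnr_new = lnr_old + s_rval * np.random.standard_normal()
                r_old = r[b]
                r[b] = np.exp(lnr_new)
                tr[b] = t[b] * r[b]
                ll_new = _ll_of(A, tr, y, X, beta, np.exp(log_s2), jit)
                dprior = -0.5 * ((lnr_new / lnr_sd) ** 2 - (lnr_old / lnr_sd) ** 2)
                if np.log(np.random.random() + 1e-300) < power * (ll_new - ll) + dprior:
                    ll = ll_new
                    acc[2] += 1
                    awin[2] += 1
                else:
                    r[b] = r_old
                    tr[b] = t[b] * r_old
        else:
            # reversible jump; proposal for a new scalar equals its prior and
            # the prior on k is uniform, so only the likelihood ratio and the
            # birth/death asymmetry at the k boundaries remain
            pb = 0.5
            if k == 0:
                pb = 1.0
            elif k == B:
                pb = 0.0
            if np.random.random() < pb:
                tries[3] += 1
                pick = np.random.randint(B - k)
                b = -1
                cnt = -1
                for bb in range(B):
                    if not active[bb]:
                        cnt += 1
                        if cnt == pick:
                            b = bb
                            break
                r[b] = np.exp(lnr_sd * np.random.standard_normal())
                tr[b] = t[b] * r[b]
                ll_new = _ll_of(A, tr, y, X, beta, np.exp(log_s2), jit)
                pb_rev = 0.5 if (k + 1) < B else 0.0
                log_q = np.log(max(1.0 - pb_rev, 1e-300)) - np.log(pb)
                if np.log(np.random.random() + 1e-300) < power * (ll_new - ll) + log_q:
                    active[b] = True
                    k += 1
                    ll = ll_new
                    acc[3] += 1
                else:
                    r[b] = 1.0
                    tr[b] = t[b]
            elif k > 0:
                tries[4] += 1
                pick = np.random.randint(k)
                b = -1
                cnt = -1
                for bb in range(B):
                    if active[bb]:
                        cnt += 1
                        if cnt == pick:
                            b = bb
                            break
                r_old = r[b]
                r[b] = 1.0
                tr[b] = t[b]
                ll_new = _ll_of(A, tr, y, X, beta, np.exp(log_s2), jit)
                pb_prev = 1.0 if (k - 1) == 0 else 0.5
                log_q = np.log(pb_prev) - np.log(1.0 - pb)
                if np.log(np.random.random() + 1e-300) < power * (ll_new - ll) + log_q:
                    active[b] = False
                    k -= 1
                    ll = ll_new
                    acc[4] += 1
                else:
                    r[b] = r_old
                    tr[b] = t[b] * r_old

        if adapt and it < burnin and (it + 1) % 100 == 0:
            if twin[0] >= 20:
                s_beta = min(max(s_beta * np.exp(0.5 * (awin[0] / twin[0] - 0.3)),
                                 1e-4), 50.0)
                awin[0] = 0
                twin[0] = 0
            if twin[1] >= 20:
                s_sigma = min(max(s_sigma * np.exp(0.5 * (awin[1] / twin[1] - 0.3)),
                                  1e-4), 50.0)
                awin[1] = 0
                twin[1] = 0
            if twin[2] >= 20:
                s_rval = min(max(s_rval * np.exp(0.5 * (awin[2] / twin[2] - 0.3)),
                                 1e-4), 50.0)
                awin[2] = 0
                twin[2] = 0

        if it >= burnin:
            if n_collect > 0:
                if (it - burnin) % thin == 0 and n_out < max_samp:
                    out_iter[n_out] = it + 1
                    out_ll[n_out] = ll
                    out_s2[n_out] = np.exp(log_s2)
                    out_beta[n_out] = beta
                    out_k[n_out] = k
                    out_r[n_out] = r
                    n_out += 1
            else:
                stone_ll[n_stone] = ll
                n_stone += 1

    return (out_iter[:n_out], out_ll[:n_out], out_s2[:n_out],
            out_beta[:n_out], out_k[:n_out], out_r[:n_out],
            beta, log_s2, r, acc, tries, stone_ll[:n_stone])


def _run_chain(model: _VRModel, config: VarRatesConfig, rng, *,
               iterations: int, power: float = 1.0, rj: bool = True,
               collect: int = 0, burnin: int = 0, init=None, adapt: bool = True):
    """Core Metropolis / reversible-jump chain at likelihood power ``power``.

    A thin wrapper over the compiled kernel.  Returns (thinned samples,
    final state, acceptance rates, post-burn-in lnL series).
    """
    p = model.design.X.shape[1]
    lo_s2, hi_s2 = config.log_s2_bounds

    if init is None:
        beta = _gls_beta_start(model.design)
        resid = model.design.y - model.design.X @ beta
        V0 = model.V_of(np.ones(model.B))
        s2 = max(float(resid @ np.linalg.solve(V0, resid)) / model.n, 1e-8)
        log_s2 = float(np.clip(math.log(s2), lo_s2, hi_s2))
        r = np.ones(model.B)
    else:
        beta, log_s2, r, _ = init
        beta = np.asarray(beta, dtype=float).copy()
        r = np.asarray(r, dtype=float).copy()

    XtX = model.design.X.T @ model.design.X
    bstep_dir = np.linalg.cholesky(np.linalg.inv(XtX + 1e-8 * np.eye(p)))
    seed = int(rng.integers(2 ** 31))

    (it_arr, ll_arr, s2_arr, beta_arr, k_arr, r_arr,
     beta_f, log_s2_f, r_f, acc, tries, stone_ll) = _chain_kernel(
        model.A, model.t, model.design.y, model.design.X, bstep_dir,
        int(iterations), int(burnin), int(collect),
        float(power), bool(rj), seed,
        beta, float(log_s2), r,
        float(config.lnr_sd), float(config.beta_bound),
        float(lo_s2), float(hi_s2), float(config.jitter), bool(adapt))

    samples = {
        "iter": list(it_arr), "ll": list(ll_arr), "s2": list(s2_arr),
        "beta": [row.copy() for row in beta_arr], "k": list(k_arr),
        "scal": [
            {model.keys[b]: float(row[b]) for b in np.nonzero(row != 1.0)[0]}
            for row in r_arr
        ],
    }
    names = ("beta", "sigma", "rval", "birth", "death")
    rates = {m: (acc[i] / tries[i] if tries[i] else 0.0)
             for i, m in enumerate(names)}
    active = [int(b) for b in np.nonzero(r_f != 1.0)[0]]
    state = (beta_f, float(log_s2_f), r_f, active)
    return samples, state, rates, list(stone_ll)


def _ess(x: np.ndarray) -> float:
    """Crude effective sample size from the initial positive autocorrelations."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for lag in range(1, min(n // 2, 200)):
        if acf[lag] <= 0.05:
            break
        s += acf[lag]
    return n / (1.0 + 2.0 * s)


def varrates_mcmc(design: RegressionDesign, tree: Phylogeny,
                  config: VarRatesConfig | None = None,
                  seed: int = 0, rj: bool = True) -> PosteriorTrace:
    """Sample the variable-rates posterior by reversible-jump MCMC.

    Deterministic given ``seed``.  With ``rj=False`` the chain samples the
    single-rate base model (no branch scalars).  A low effective sample size
    for sigma^2_b triggers a warning, not a failure.
    """
    config = config or VarRatesConfig()
    rng = np.random.default_rng(seed)
    model = _VRModel(design, tree, config)
    burnin = int(config.iterations * config.burnin_frac)
    samples, _, rates, _ = _run_chain(
        model, config, rng, iterations=config.iterations, rj=rj,
        collect=config.n_samples, burnin=burnin,
    )
    trace = PosteriorTrace(
        iterations=np.array(samples["iter"]),
        loglik=np.array(samples["ll"]),
        sigma2=np.array(samples["s2"]),
        beta=np.array(samples["beta"]),
        k=np.array(samples["k"]),
        scalars=samples["scal"],
        colnames=design.colnames,
        branch_keys=model.keys,
        acceptance=rates,
    )
    ess = _ess(trace.sigma2)
    if ess < config.ess_warn:
        warnings.warn(
            f"effective sample size for sigma2_b is low ({ess:.0f}); "
            "consider a longer chain", RuntimeWarning,
        )
    return trace


def median_rate_tree(trace: PosteriorTrace, tree: Phylogeny
                     ) -> tuple[BranchValueMap, Phylogeny]:
    """Posterior median rate scalar per branch and the rate-scaled tree.

    A branch not scaled in a sample counts as r = 1 in that sample; branch
    lengths of the returned tree are t * median(r), i.e. rt.
    """
    S = len(trace.iterations)
    if S == 0:
        raise ValueError("empty trace")
    med = {}
    for key in (tree.branch_key(b) for b in tree.branch_ids()):
        vals = np.ones(S)
        for s, scal in enumerate(trace.scalars):
            if key in scal:
                vals[s] = scal[key]
        med[key] = float(np.median(vals))
    bvm = BranchValueMap("r", med)
    return bvm, scale_branches(tree, bvm)


# ---------------------------------------------------------------------------
# Stepping-stone marginal likelihoods and Bayes factors
# ---------------------------------------------------------------------------


def ss_ladder(stones: int, shape: tuple = (0.40, 1.0)) -> np.ndarray:
    """Power ladder 0 = b_0 < ... < b_K = 1 at Beta(alpha, 1) quantiles."""
    alpha, beta_shape = shape
    if beta_shape != 1.0:
        from scipy.stats import beta as beta_dist
        return beta_dist.ppf(np.linspace(0, 1, stones + 1), alpha, beta_shape)
    return np.linspace(0.0, 1.0, stones + 1) ** (1.0 / alpha)


def ss_accumulate(loglik_per_stone: list[np.ndarray], betas: np.ndarray) -> float:
    """Combine per-stone likelihood samples into the log marginal likelihood.

    Stone k's samples are drawn from the power posterior at beta_k and
    estimate log E[ exp((beta_{k+1}-beta_k) lnL) ] by a log-sum-exp-stable
    average; the estimates telescope to log m = log p(y)."""
    total = 0.0
    for k, lls in enumerate(loglik_per_stone):
        lls = np.asarray(lls, dtype=float)
        if len(lls) == 0 or not np.all(np.isfinite(lls * (betas[k + 1] - betas[k]))):
            raise ValueError(f"non-finite contribution at stone {k}")
        delta = betas[k + 1] - betas[k]
        total += float(logsumexp(delta * lls) - math.log(len(lls)))
    return total


def _prior_draw_state(model: _VRModel, config: VarRatesConfig, rng, rj: bool):
    p = model.design.X.shape[1]
    beta = rng.uniform(-config.beta_bound, config.beta_bound, size=p)
    log_s2 = rng.uniform(*config.log_s2_bounds)
    r = np.ones(model.B)
    active: list[int] = []
    if rj:
        k = int(rng.integers(model.B + 1))
        active = list(rng.choice(model.B, size=k, replace=False))
        for b in active:
            r[b] = math.exp(rng.normal(0.0, config.lnr_sd))
    return beta, log_s2, r, active


def stepping_stone_logml(design: RegressionDesign, tree: Phylogeny,
                         model_flag: str = "variable",
                         stones: int = 100, iters_per_stone: int = 10_000,
                         shape: tuple = (0.40, 1.0), seed: int = 0,
                         config: VarRatesConfig | None = None
                         ) -> MarginalLikelihoodEstimate:
    """Stepping-stone log marginal likelihood for the variable-rates model
    (``model_flag='variable'``) or the single-rate base model (``'single'``).

    Powers sit at Beta(alpha=0.40, beta=1) quantiles; each stone runs a short
    tempered chain warm-started from the previous stone.
    """
    if stones < 2:
        raise ValueError("need at least 2 stones")
    if model_flag not in ("variable", "single"):
        raise ValueError("model_flag must be 'variable' or 'single'")
    rj = model_flag == "variable"
    config = config or VarRatesConfig()
    rng = np.random.default_rng(seed)
    model = _VRModel(design, tree, config)
    betas = ss_ladder(stones, shape)
    per_stone: list[np.ndarray] = []

    # stone 0 at power 0: iid prior draws
    lls0 = []
    for _ in range(max(200, iters_per_stone // 10)):
        beta, log_s2, r, active = _prior_draw_state(model, config, rng, rj)
        ch = model.chol(model.V_of(r))
        lls0.append(model.loglik(beta, math.exp(log_s2), ch))
    per_stone.append(np.array(lls0))

    state = None
    for k in range(1, stones):
        burn = max(1, iters_per_stone // 5)
        _, state, _, lls = _run_chain(
            model, config, rng, iterations=iters_per_stone + burn,
            power=float(betas[k]), rj=rj, collect=0, burnin=burn,
            init=state, adapt=(k == 1),
        )
        per_stone.append(np.array(lls))

    logml = ss_accumulate(per_stone, betas)
    return MarginalLikelihoodEstimate(logml=logml, stones=stones,
                                      iters_per_stone=iters_per_stone, shape=shape)


def raftery_category(bf: float) -> str:
    """Verbal evidence category for a log Bayes factor on the 2*ln scale."""
    if bf < 2:
        return "weak"
    if bf < 6:
        return "positive"
    if bf < 10:
        return "strong"
    return "very strong"


def bayes_factor(m1: MarginalLikelihoodEstimate,
                 m0: MarginalLikelihoodEstimate) -> tuple[float, str]:
    """Log Bayes factor BF = 2(log m1 - log m0); positive favours m1 (the
    variable-rates model when called as bayes_factor(variable, single))."""
    bf = 2.0 * (m1.logml - m0.logml)
    if not math.isfinite(bf):
        raise ValueError("non-finite marginal likelihoods")
    return bf, raftery_category(bf)
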