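"""Bayesian phylogenetic generalised least squares with Pagel's lambda.

The regression residuals are multivariate normal with covariance
sigma^2 * V(lambda), where V holds shared root-to-tip path lengths of the
time tree and lambda in [0, 1] multiplies its off-diagonal entries: lambda=0
is an ordinary (star-tree) regression, lambda=1 full Brownian covariance.

Sampling is Metropolis-within-Gibbs — exact Gaussian draws for the
coefficients, a conjugate inverse-gamma draw for sigma^2 (flat and
log-uniform priors respectively), and a reflected random walk for lambda
(uniform prior on [0, 1]).

Coefficient significance is summarised by p_x: the fraction of the posterior
on the minority side of zero (samples exactly at zero count as crossing), so
p_x in [0, 0.5] and p_x < 0.05 is read as a significant effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "PglsSpec",
    "PglsConfig",
    "PglsPosterior",
    "build_pgls_spec",
    "pgls_loglik",
    "pgls_mcmc",
    "p_x_summary",
]


@dataclass
class PglsSpec:
    """Response, covariates (intercept included) and the time-tree V matrix."""

    y: np.ndarray
    X: np.ndarray
    colnames: list[str]
    species: list[str]
    V: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        n, p = self.X.shape
        if not (len(self.y) == n == len(self.species) == self.V.shape[0] == self.V.shape[1]):
            raise ValueError("y, X, species and V must agree in size")
        if np.linalg.matrix_rank(self.X) < p:
            # name the offending columns via tiny R diagonal in a QR factorisation
            R = np.linalg.qr(self.X, mode="r")
            bad = [self.colnames[j] for j in range(p)
                   if abs(R[j, j]) < 1e-10 * max(1.0, abs(R[0, 0]))]
            raise ValueError(f"design is rank deficient; collinear columns: {bad}")


def build_pgls_spec(data: pd.DataFrame, response: str, covariates: list[str],
                    V: np.ndarray, species_order: list[str]) -> PglsSpec:
    """Assemble a PGLS model from a merged per-species table.

    ``V`` must be indexed by ``species_order``; rows of ``data`` are aligned
    to that order.  An intercept column is prepended.
    """
    df = data.set_index("species").loc[species_order]
    for col in [response, *covariates]:
        if not np.isfinite(df[col]).all():
            raise ValueError(f"non-finite values in {col}")
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy() for c in covariates])
    return PglsSpec(df[response].to_numpy(), X, ["intercept", *covariates],
                    list(species_order), V)


def _v_lambda(V: np.ndarray, lam: float) -> np.ndarray:
    Vl = lam * V
    Vl[np.diag_indices_from(Vl)] = np.diag(V)
    return Vl


def pgls_loglik(spec: PglsSpec, beta: np.ndarray, sigma2: float, lam: float) -> float:
    """Multivariate-normal log density with covariance sigma^2 * V(lambda)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    n = len(spec.y)
    e = spec.y - spec.X @ beta
    Vl = _v_lambda(spec.V, lam)
    c = cho_factor(Vl, lower=True)
    z = cho_solve(c, e)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0])))) + n * math.log(sigma2)
    return -0.5 * (n * math.log(2 * math.pi) + logdet + float(e @ z) / sigma2)


@dataclass
class PglsConfig:
    """Desk-scale defaults: 5e5 updates, 10% burn-in, 1000 retained samples."""

    iterations: int = 500_000
    burnin_frac: float = 0.1
    n_samples: int = 1000
    lambda_step: float = 0.15


@dataclass
class PglsPosterior:
    """Thinned traces of beta, sigma^2 and lambda, with p_x per coefficient."""

    beta: np.ndarray                 # (S, p)
    sigma2: np.ndarray
    lam: np.ndarray
    loglik: np.ndarray
    colnames: list[str]
    p_x: dict[str, float] = field(default_factory=dict)
    accept_lambda: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.beta, columns=self.colnames)
        df.insert(0, "lnL", self.loglik)
        df["sigma2"] = self.sigma2
        df["lambda"] = self.lam
        return df

    def summary(self) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.colnames):
            tr = self.beta[:, j]
            rows.append((name, tr.mean(), tr.std(), *np.percentile(tr, [2.5, 97.5]),
                         self.p_x[name]))
        return pd.DataFrame(rows, columns=["coef", "mean", "sd", "q2.5", "q97.5", "p_x"])

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                name: {"mean": float(self.beta[:, j].mean()),
                       "sd": float(self.beta[:, j].std()),
                       "p_x": self.p_x[name]}
                for j, name in enumerate(self.colnames)
            },
            "lambda_mean": float(self.lam.mean()),
            "sigma2_mean": float(self.sigma2.mean()),
        }


def p_x_summary(trace: np.ndarray) -> float:
    """Fraction of the posterior crossing zero (minority side; exact zeros
    count as crossing).  Always in [0, 0.5]."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty coefficient trace")
    below = np.count_nonzero(trace <= 0)
    above = np.count_nonzero(trace >= 0)
    return min(below, above) / trace.size


def pgls_mcmc(spec: PglsSpec, config: PglsConfig | None = None,
              seed: int = 0) -> PglsPosterior:
    """Metropolis-within-Gibbs sampler for the PGLS posterior.

    beta | sigma^2, lambda is drawn exactly from its conditional Gaussian,
    sigma^2 | beta, lambda from its conditional inverse gamma, and lambda by
    a reflected random walk.  Deterministic given ``seed``.
    """
    config = config or PglsConfig()
    rng = np.random.default_rng(seed)
    n, p = spec.X.shape
    lam = 0.5
    beta = np.linalg.lstsq(spec.X, spec.y, rcond=None)[0]
    sigma2 = 1.0

    def chol_for(lam_):
        return cho_factor(_v_lambda(spec.V, lam_), lower=True)

    ch = chol_for(lam)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(ch[0]))))

    def resid_quad(ch_, b):
        e = spec.y - spec.X @ b
        return float(e @ cho_solve(ch_, e))

    def ll(ch_, logdetV_, b, s2):
        return -0.5 * (n * math.log(2 * math.pi) + logdetV_ + n * math.log(s2)
                       + resid_quad(ch_, b) / s2)

    burnin = int(config.iterations * config.burnin_frac)
    thin = max(1, (config.iterations - burnin) // config.n_samples)
    out_beta, out_s2, out_lam, out_ll = [], [], [], []
    acc_lam = try_lam = 0

    def beta_conditional(ch_):
        Xs = cho_solve(ch_, spec.X)
        XtVX = spec.X.T @ Xs
        XtVy = Xs.T @ spec.y
        return np.linalg.cholesky(XtVX), np.linalg.solve(XtVX, XtVy)

    prec_chol, bmean = beta_conditional(ch)

    for it in range(config.iterations):
        sub = it % 3
        if sub == 0:  # beta: exact Gaussian conditional (flat prior)
            z = rng.normal(size=p)
            beta = bmean + math.sqrt(sigma2) * np.linalg.solve(prec_chol.T, z)
        elif sub == 1:  # sigma2: inverse gamma (prior 1/sigma2)
            q = resid_quad(ch, beta)
            sigma2 = q / (2.0 * rng.gamma(n / 2.0, 1.0))
            sigma2 = float(np.clip(sigma2, 1e-12, 1e12))
        else:  # lambda: reflected random walk
            try_lam += 1
            prop = lam + config.lambda_step * rng.normal()
            while prop < 0 or prop > 1:
                prop = abs(prop) if prop < 0 else 2 - prop
            ch_new = chol_for(prop)
            logdet_new = 2.0 * float(np.sum(np.log(np.diag(ch_new[0]))))
            ll_old = ll(ch, logdetV, beta, sigma2)
            ll_new = ll(ch_new, logdet_new, beta, sigma2)
            if math.log(rng.random() + 1e-300) < ll_new - ll_old:
                lam, ch, logdetV = prop, ch_new, logdet_new
                prec_chol, bmean = beta_conditional(ch)
                acc_lam += 1
        if it >= burnin and (it - burnin) % thin == 0:
            out_beta.append(beta.copy())
            out_s2.append(sigma2)
            out_lam.append(lam)
            out_ll.append(ll(ch, logdetV, beta, sigma2))

    beta_arr = np.array(out_beta)
    post = PglsPosterior(
        beta=beta_arr,
        sigma2=np.array(out_s2),
        lam=np.array(out_lam),
        loglik=np.array(out_ll),
        colnames=spec.colnames,
        p_x={name: p_x_summary(beta_arr[:, j]) for j, name in enumerate(spec.colnames)},
        accept_lambda=acc_lam / max(try_lam, 1),
    )
    return post
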