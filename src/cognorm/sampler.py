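"""MCMC engine for the Bayesian GLMs.

Posteriors in this package are low-dimensional (3–5 parameters) and, at the
cohort sizes involved, close to Gaussian.  Two samplers are provided:

``imh``
    Independence Metropolis–Hastings with a multivariate Student-t proposal
    (df = 7) centred on the posterior mode, with covariance a modestly
    inflated inverse Hessian (Laplace approximation).  This is the default:
    with a well-matched proposal the chain is close to i.i.d. sampling and
    mixes far faster per iteration than a random walk.
``rwm``
    Preconditioned adaptive random-walk Metropolis.  Proposal covariance is
    the Laplace covariance scaled by ``2.38^2/d``, with the global scale
    adapted during warmup towards a 0.234 acceptance rate.  Slower-mixing
    but robust if the Laplace approximation is poor.

Both run ``chains`` independent chains (default 4) with ``warmup_iters``
discarded iterations and ``sampling_iters`` retained iterations each, so
the post-warmup draw count is exactly ``chains * sampling_iters`` (20,000
at the production default of 4 x 5,000).  Convergence is summarised by
rank-normalised split R-hat and bulk ESS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import linalg, optimize
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "SamplerConfig",
    "PRODUCTION_SAMPLER",
    "REDUCED_TEST_SAMPLER",
    "ConvergenceError",
    "laplace_approximation",
    "run_mcmc",
    "rhat",
    "ess_bulk",
]


class ConvergenceError(RuntimeError):
    """The sampler failed its convergence gate; carries the diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC configuration.

    Defaults are the production settings: 4 chains x 5,000 warmup + 5,000
    sampling iterations, i.e. 20,000 post-warmup draws.  ``rhat_max`` is
    the convergence gate applied before a fit is used downstream.
    """

    chains: int = 4
    warmup_iters: int = 5000
    sampling_iters: int = 5000
    seed: int = 0
    algorithm: str = "imh"          # {"imh", "rwm"}
    rhat_max: float = 1.01
    proposal_df: float = 7.0
    proposal_inflation: float = 1.3

    def __post_init__(self):
        if self.chains < 1 or self.warmup_iters < 0 or self.sampling_iters < 1:
            raise ValueError("invalid sampler configuration")
        if self.algorithm not in ("imh", "rwm"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @property
    def total_draws(self) -> int:
        return self.chains * self.sampling_iters


PRODUCTION_SAMPLER = SamplerConfig()
# reduced settings for tests and replicate studies; the looser R-hat gate
# reflects the shorter chains
REDUCED_TEST_SAMPLER = SamplerConfig(
    warmup_iters=500, sampling_iters=500, rhat_max=1.05
)


# --------------------------------------------------------------------------
# Laplace approximation
# --------------------------------------------------------------------------

def laplace_approximation(
    log_post: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: list[tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and inverse-Hessian covariance.

    The mode is found by L-BFGS-B on the negative log posterior; the
    covariance is the inverse of a finite-difference Hessian at the mode,
    symmetrised and floored to be positive definite.
    """
    x0 = np.asarray(x0, dtype=float)

    def neg(x):
        v = log_post(x)
        return 1e12 if not np.isfinite(v) else -v

    res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
    # polish with Nelder-Mead if L-BFGS-B stalled on the numeric gradient
    if not res.success:
        res2 = optimize.minimize(neg, res.x, method="Nelder-Mead",
                                 options={"maxiter": 2000, "xatol": 1e-8})
        if res2.fun < res.fun:
            res = res2
    mode = np.asarray(res.x, dtype=float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hess = approx_hess(mode, neg)
    hess = 0.5 * (hess + hess.T)
    try:
        cov = linalg.inv(hess)
        # validate positive definiteness via Cholesky
        linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError:
        cov = None
    if cov is None or not np.all(np.isfinite(cov)):
        # fall back to a diagonal covariance from curvature magnitudes
        d = np.abs(np.diag(hess))
        d[d < 1e-8] = 1e-8
        cov = np.diag(1.0 / d)
    return mode, cov


# --------------------------------------------------------------------------
# proposal distributions
# --------------------------------------------------------------------------

class _StudentTProposal:
    """Multivariate Student-t proposal with cached Cholesky factor."""

    def __init__(self, mean, cov, df):
        self.mean = np.asarray(mean, dtype=float)
        self.df = float(df)
        self.d = self.mean.size
        self.chol = linalg.cholesky(np.asarray(cov, dtype=float), lower=True)
        self._logdet = 2.0 * np.log(np.diag(self.chol)).sum()
        from scipy.special import gammaln

        self._lognorm = (
            gammaln((self.df + self.d) / 2.0)
            - gammaln(self.df / 2.0)
            - 0.5 * self.d * np.log(self.df * np.pi)
            - 0.5 * self._logdet
        )

    def rvs(self, size, rng):
        z = rng.standard_normal((size, self.d)) @ self.chol.T
        u = rng.chisquare(self.df, size=size) / self.df
        return self.mean + z / np.sqrt(u)[:, None]

    def logpdf(self, x):
        x = np.atleast_2d(x)
        w = linalg.solve_triangular(self.chol, (x - self.mean).T, lower=True)
        q = np.sum(w * w, axis=0)
        return self._lognorm - 0.5 * (self.df + self.d) * np.log1p(q / self.df)


# --------------------------------------------------------------------------
# chain drivers
# --------------------------------------------------------------------------

def _run_chain_imh(log_post, proposal, x_init, n_iter, rng):
    draws = np.empty((n_iter, x_init.size))
    x = np.asarray(x_init, dtype=float)
    lp_x = log_post(x)
    lq_x = float(proposal.logpdf(x)[0])
    props = proposal.rvs(n_iter, rng)
    lq_props = proposal.logpdf(props)
    lu = np.log(rng.random(n_iter))
    accepted = 0
    for i in range(n_iter):
        xp = props[i]
        lp_p = log_post(xp)
        if np.isfinite(lp_p) and lu[i] < (lp_p - lq_props[i]) - (lp_x - lq_x):
            x, lp_x, lq_x = xp, lp_p, lq_props[i]
            accepted += 1
        draws[i] = x
    return draws, accepted / max(n_iter, 1)


def _run_chain_rwm(log_post, chol, x_init, n_warm, n_keep, rng):
    d = x_init.size
    log_scale = np.log(2.38 / np.sqrt(d))
    x = np.asarray(x_init, dtype=float)
    lp_x = log_post(x)
    draws = np.empty((n_keep, d))
    accepted = 0
    total = n_warm + n_keep
    target = 0.234
    for i in range(total):
        step = np.exp(log_scale) * (chol @ rng.standard_normal(d))
        xp = x + step
        lp_p = log_post(xp)
        acc = np.isfinite(lp_p) and np.log(rng.random()) < lp_p - lp_x
        if acc:
            x, lp_x = xp, lp_p
        if i < n_warm:
            # Robbins-Monro adaptation of the global scale during warmup
            log_scale += ((1.0 if acc else 0.0) - target) / np.sqrt(i + 1.0)
        else:
            draws[i - n_warm] = x
            accepted += bool(acc)
    return draws, accepted / max(n_keep, 1)


def run_mcmc(
    log_post: Callable[[np.ndarray], float],
    x0: np.ndarray,
    config: SamplerConfig,
    bounds: list[tuple[float, float]] | None = None,
) -> dict:
    """Run the configured sampler; returns draws plus diagnostics.

    Returns a dict with ``draws`` of shape (chains, sampling_iters, d),
    ``mode``, ``cov`` (Laplace), ``accept_rate`` per chain, ``rhat`` and
    ``ess`` per parameter.  Fully deterministic given ``config.seed``.
    """
    mode, cov = laplace_approximation(log_post, x0, bounds)
    d = mode.size
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    all_draws = np.empty((config.chains, config.sampling_iters, d))
    accept = np.empty(config.chains)

    if config.algorithm == "imh":
        proposal = _StudentTProposal(
            mode, config.proposal_inflation * cov, config.proposal_df
        )
        for c, ss in enumerate(seeds):
            rng = np.random.default_rng(ss)
            x_init = proposal.rvs(1, rng)[0]
            if not np.isfinite(log_post(x_init)):
                x_init = mode
            warm, _ = _run_chain_imh(
                log_post, proposal, x_init, config.warmup_iters, rng
            )
            start = warm[-1] if config.warmup_iters else x_init
            all_draws[c], accept[c] = _run_chain_imh(
                log_post, proposal, start, config.sampling_iters, rng
            )
    else:
        chol = linalg.cholesky(cov, lower=True)
        for c, ss in enumerate(seeds):
            rng = np.random.default_rng(ss)
            jitter = chol @ rng.standard_normal(d)
            x_init = mode + jitter
            if not np.isfinite(log_post(x_init)):
                x_init = mode
            all_draws[c], accept[c] = _run_chain_rwm(
                log_post, chol, x_init, config.warmup_iters,
                config.sampling_iters, rng,
            )

    return {
        "draws": all_draws,
        "mode": mode,
        "cov": cov,
        "accept_rate": accept,
        "rhat": np.array([rhat(all_draws[:, :, j]) for j in range(d)]),
        "ess": np.array([ess_bulk(all_draws[:, :, j]) for j in range(d)]),
    }


# --------------------------------------------------------------------------
# diagnostics (thin wrappers over arviz)
# --------------------------------------------------------------------------

def rhat(chains_draws: np.ndarray) -> float:
    """Rank-normalised split R-hat for one parameter (chains x draws)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(np.asarray(chains_draws)))


def ess_bulk(chains_draws: np.ndarray) -> float:
    """Bulk effective sample size for one parameter (chains x draws)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(np.asarray(chains_draws)))
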