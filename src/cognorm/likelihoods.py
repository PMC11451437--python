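"""Exact densities, links and samplers for the three response families.

Cognitive test scores rarely look Gaussian: error counts pile up at zero,
accuracy measures pile up at ceiling, and bounded proportions live on the
unit interval.  The three families used throughout this package cover those
shapes:

``beta``
    Mean–precision beta on the open unit interval: shapes ``(mu*phi,
    (1-mu)*phi)``, so ``mu`` is the mean and ``phi`` the precision.
``zoib``
    Zero–one-inflated beta: a point mass ``zoi*(1-coi)`` at 0, a point mass
    ``zoi*coi`` at 1, and ``(1-zoi)`` times a mean–precision beta on the
    interior.
``hurdle_nb``
    Hurdle negative binomial: a point mass ``hu`` at 0 and ``(1-hu)`` times
    a zero-truncated negative binomial (mean ``mu`` of the untruncated NB,
    dispersion ``shape``) on the positive integers.

All log-density functions are vectorised over ``y`` and validate their
parameters.  Sampling routines take a :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "BetaParams",
    "ZoibParams",
    "HurdleNbParams",
    "beta_logpdf",
    "zoib_logpdf",
    "hurdle_nb_logpmf",
    "beta_rvs",
    "zoib_rvs",
    "hurdle_nb_rvs",
    "zoib_cdf",
    "hurdle_nb_cdf",
    "link",
    "logit",
    "inv_logit",
    "FAMILIES",
]

FAMILIES = ("beta", "zoib", "hurdle_nb")

# epsilon used to nudge observed boundary values into the interior for the
# plain (non-inflated) beta family, which has no boundary mass
BETA_BOUNDARY_EPS = 1e-6


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaParams:
    """Mean–precision beta parameters: ``mu`` in (0,1), ``phi`` > 0."""

    mu: float
    phi: float

    def validate(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        phi = np.asarray(self.phi, dtype=float)
        if np.any(~((mu > 0.0) & (mu < 1.0))):
            raise ValueError(f"beta: mu must lie in (0,1), got {self.mu!r}")
        if np.any(~(phi > 0.0)):
            raise ValueError(f"beta: phi must be positive, got {self.phi!r}")


@dataclass(frozen=True)
class ZoibParams:
    """Zero–one-inflated beta parameters.

    ``mu``/``phi`` parameterise the interior beta; ``zoi`` is the total
    boundary probability and ``coi`` the conditional probability that a
    boundary outcome is a one, so P(0) = zoi*(1-coi) and P(1) = zoi*coi.
    """

    mu: float
    phi: float
    zoi: float
    coi: float

    def validate(self) -> None:
        BetaParams(self.mu, self.phi).validate()
        for name in ("zoi", "coi"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(~((v >= 0.0) & (v <= 1.0))):
                raise ValueError(f"zoib: {name} must lie in [0,1], got {v!r}")


@dataclass(frozen=True)
class HurdleNbParams:
    """Hurdle negative binomial parameters.

    ``mu`` > 0 is the mean of the *untruncated* NB, ``shape`` > 0 its
    dispersion (variance = mu + mu^2/shape) and ``hu`` in [0,1] the hurdle
    (zero) probability.
    """

    mu: float
    shape: float
    hu: float

    def validate(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        shape = np.asarray(self.shape, dtype=float)
        hu = np.asarray(self.hu, dtype=float)
        if np.any(~(mu > 0.0)):
            raise ValueError(f"hurdle_nb: mu must be positive, got {self.mu!r}")
        if np.any(~(shape > 0.0)):
            raise ValueError(f"hurdle_nb: shape must be positive, got {self.shape!r}")
        if np.any(~((hu >= 0.0) & (hu <= 1.0))):
            raise ValueError(f"hurdle_nb: hu must lie in [0,1], got {self.hu!r}")


# --------------------------------------------------------------------------
# link functions
# --------------------------------------------------------------------------

def logit(p):
    return special.logit(p)


def inv_logit(x):
    return special.expit(x)


def link(family: str) -> dict:
    """Return the link/inverse-link pair for each parameter of a family.

    Probabilities (``mu`` of beta/zoib, ``zoi``, ``coi``, ``hu``) use the
    logit link; positive parameters (``mu`` of counts, ``phi``, ``shape``)
    use the log link.  Exponentiating an age coefficient therefore yields an
    odds ratio for the logit-linked families and an incidence risk ratio for
    the count family.
    """
    if family in ("beta", "zoib"):
        out = {"mu": (logit, inv_logit), "phi": (np.log, np.exp)}
        if family == "zoib":
            out["zoi"] = (logit, inv_logit)
            out["coi"] = (logit, inv_logit)
        return out
    if family == "hurdle_nb":
        return {
            "mu": (np.log, np.exp),
            "shape": (np.log, np.exp),
            "hu": (logit, inv_logit),
        }
    raise ValueError(f"unknown family {family!r}")


def effect_label(family: str) -> str:
    """Human label for exp(beta_age): OR on logit-mu links, IRR on log-mu."""
    return "Incidence risk ratio" if family == "hurdle_nb" else "Odds ratio"


# --------------------------------------------------------------------------
# log densities
# --------------------------------------------------------------------------

def beta_logpdf(y, params: BetaParams):
    """Log density of the mean–precision beta at interior points.

    Raises on boundary values: the plain beta family carries no boundary
    mass; observed 0/1 values must be nudged by the caller (see
    ``BETA_BOUNDARY_EPS``).
    """
    params.validate()
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0.0) | (y >= 1.0)):
        raise ValueError("beta_logpdf requires 0 < y < 1 (no boundary mass)")
    a = params.mu * params.phi
    b = (1.0 - params.mu) * params.phi
    return stats.beta.logpdf(y, a, b)


def zoib_logpdf(y, params: ZoibParams):
    """Log density/mass of the zero–one-inflated beta.

    Returns log of a point mass at exactly 0 or 1, and log of the
    continuous density ``(1-zoi) * Beta(y; mu*phi, (1-mu)*phi)`` on the
    interior.
    """
    params.validate()
    y = np.asarray(y, dtype=float)
    if np.any((y < 0.0) | (y > 1.0)):
        raise ValueError("zoib_logpdf requires 0 <= y <= 1")
    with np.errstate(divide="ignore"):
        lp_zero = np.log(params.zoi) + np.log1p(-params.coi)
        lp_one = np.log(params.zoi) + np.log(params.coi)
    a = params.mu * params.phi
    b = (1.0 - params.mu) * params.phi
    interior = np.where((y > 0.0) & (y < 1.0), y, 0.5)
    with np.errstate(divide="ignore"):
        lp_int = np.log1p(-params.zoi) + stats.beta.logpdf(interior, a, b)
    out = np.where(y == 0.0, lp_zero, np.where(y == 1.0, lp_one, lp_int))
    return out if out.ndim else float(out)


def _nb_logpmf(y, mu, shape):
    # scipy parameterisation: n = shape, p = shape / (shape + mu)
    return stats.nbinom.logpmf(y, shape, shape / (shape + mu))


def hurdle_nb_logpmf(y, params: HurdleNbParams):
    """Log mass of the hurdle negative binomial on non-negative integers.

    P(0) = hu; P(y>0) = (1-hu) * NB(y; mu, shape) / (1 - NB(0; mu, shape)).
    """
    params.validate()
    y = np.asarray(y)
    if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("hurdle_nb_logpmf requires non-negative integer y")
    y = y.astype(float)
    with np.errstate(divide="ignore"):
        lp_zero = np.log(params.hu)
        # log(1 - NB(0)) computed stably from the NB log zero-mass
        log_nb0 = _nb_logpmf(0, params.mu, params.shape)
        lp_pos = (
            np.log1p(-params.hu)
            + _nb_logpmf(y, params.mu, params.shape)
            - np.log1p(-np.exp(log_nb0))
        )
    out = np.where(y == 0, lp_zero, lp_pos)
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# analytic CDFs (used for percentile calibration and sampler validation)
# --------------------------------------------------------------------------

def zoib_cdf(y, params: ZoibParams):
    params.validate()
    y = np.asarray(y, dtype=float)
    a = params.mu * params.phi
    b = (1.0 - params.mu) * params.phi
    p0 = params.zoi * (1.0 - params.coi)
    interior = p0 + (1.0 - params.zoi) * stats.beta.cdf(np.clip(y, 0.0, 1.0), a, b)
    out = np.where(y < 0.0, 0.0, np.where(y >= 1.0, 1.0, interior))
    return out if out.ndim else float(out)


def hurdle_nb_cdf(y, params: HurdleNbParams):
    params.validate()
    y = np.floor(np.asarray(y, dtype=float))
    p = params.shape / (params.shape + params.mu)
    nb0 = stats.nbinom.pmf(0, params.shape, p)
    pos_cdf = (stats.nbinom.cdf(y, params.shape, p) - nb0) / (1.0 - nb0)
    out = np.where(
        y < 0, 0.0, params.hu + (1.0 - params.hu) * np.clip(pos_cdf, 0.0, 1.0)
    )
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# random sampling
# --------------------------------------------------------------------------

def beta_rvs(params: BetaParams, size, rng: np.random.Generator):
    params.validate()
    a = params.mu * params.phi
    b = (1.0 - params.mu) * params.phi
    return rng.beta(np.broadcast_to(a, size), np.broadcast_to(b, size))


def zoib_rvs(params: ZoibParams, size, rng: np.random.Generator):
    params.validate()
    u = rng.random(size)
    boundary = u < params.zoi
    is_one = rng.random(size) < params.coi
    interior = beta_rvs(BetaParams(params.mu, params.phi), size, rng)
    return np.where(boundary, np.where(is_one, 1.0, 0.0), interior)


def hurdle_nb_rvs(params: HurdleNbParams, size, rng: np.random.Generator):
    """Draw hurdle-NB counts; zero-truncated part sampled by inverse CDF."""
    params.validate()
    p = params.shape / (params.shape + params.mu)
    nb0 = stats.nbinom.pmf(0, params.shape, p)
    u = rng.random(size)
    zero = u < np.broadcast_to(params.hu, np.shape(u))
    # inverse-CDF draw from the zero-truncated NB: map uniform onto (nb0, 1]
    v = rng.random(size)
    q = nb0 + v * (1.0 - nb0)
    pos = stats.nbinom.ppf(np.clip(q, None, 1.0 - 1e-16), params.shape, p)
    return np.where(zero, 0, pos).astype(np.int64)


def family_rvs(family: str, params, size, rng: np.random.Generator):
    if family == "beta":
        return beta_rvs(params, size, rng)
    if family == "zoib":
        return zoib_rvs(params, size, rng)
    if family == "hurdle_nb":
        return hurdle_nb_rvs(params, size, rng)
    raise ValueError(f"unknown family {family!r}")
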