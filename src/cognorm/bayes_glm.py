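"""Bayesian GLMs of cognitive test performance against age.

The modelling core of the package.  Each demographic subgroup gets its own
GLM of one outcome on (centred) age, with the response family chosen from
the three non-normal families in :mod:`cognorm.likelihoods`.  The age
coefficient sits on the location parameter's link scale, so ``exp(b_age)``
is a per-year odds ratio (beta/zoib) or incidence risk ratio (hurdle NB).

Usage follows the statsmodels convention::

    model = NormativeGLM(cohort_frame, "PALTEA", subgroup="female_high")
    results = model.fit(SamplerConfig(warmup_iters=500, sampling_iters=500))
    print(results.summary())
    results.age_effect_summary().point      # exp(posterior median slope)

Priors: a half Student-t with 3 degrees of freedom on positive auxiliary
parameters (precision / dispersion), weakly-informative normal(0, 5) on the
age coefficient, Student-t(3) centred on the link of the sample location
for the intercept, and uniform Beta(1, 1) on probability parameters.

Model comparison uses PSIS-smoothed leave-one-out cross-validation (higher
expected log predictive density = better fit), with an exact refit-LOO
fallback for observations whose Pareto-k diagnostic exceeds 0.7.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .cohort_io import (
    DEFAULT_OUTCOMES,
    OutcomeSpec,
    ParticipantRecord,
    cohort_to_frame,
    encode_design,
)
from .likelihoods import (
    BETA_BOUNDARY_EPS,
    BetaParams,
    HurdleNbParams,
    ZoibParams,
    effect_label,
    family_rvs,
    inv_logit,
    logit,
)
from .sampler import (
    ConvergenceError,
    SamplerConfig,
    REDUCED_TEST_SAMPLER,
    PRODUCTION_SAMPLER,
    run_mcmc,
)

__all__ = [
    "SUBGROUPS",
    "PriorConfig",
    "AgeEffectSummary",
    "NormativeGLM",
    "NormativeGLMResults",
    "fit_glm",
    "fit_all_subgroups",
    "age_effect_summary",
    "age_effect_table",
    "elpd_loo",
    "exact_refit_loo",
    "posterior_predictive_check",
]

# the seven age-trend models, one per demographic subgroup
SUBGROUPS = (
    "all",
    "male",
    "female",
    "male_high",
    "male_low",
    "female_high",
    "female_low",
)

_LOG2 = np.log(2.0)


def subgroup_mask(df: pd.DataFrame, subgroup: str) -> pd.Series:
    if subgroup == "all":
        return pd.Series(True, index=df.index)
    parts = subgroup.split("_")
    mask = df["sex"] == parts[0]
    if len(parts) == 2:
        mask &= df["education_band"] == parts[1]
    if len(parts) > 2 or parts[0] not in ("male", "female"):
        raise ValueError(f"unknown subgroup {subgroup!r}")
    return mask


@dataclass(frozen=True)
class PriorConfig:
    """Prior hyperparameters (all priors are proper at the defaults)."""

    coef_sd: float = 5.0            # normal sd on the age coefficient
    intercept_df: float = 3.0
    intercept_scale: float = 5.0
    aux_df: float = 3.0             # half Student-t df on phi / shape
    aux_scale: float = 10.0


@dataclass(frozen=True)
class AgeEffectSummary:
    """Exponentiated age effect: posterior median and equal-tailed 95% CI."""

    point: float
    ci_low: float
    ci_high: float
    label: str
    significant: bool

    def __str__(self):
        star = "*" if self.significant else ""
        return (
            f"{self.label}: {self.point:.4f} "
            f"[{self.ci_low:.4f}, {self.ci_high:.4f}]{star}"
        )


def _log1mexp(v):
    """log(1 - exp(v)) for v < 0, numerically stable near 0 and -inf."""
    v = np.asarray(v, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        small = np.log1p(-np.exp(np.minimum(v, -_LOG2)))
        near0 = np.log(-np.expm1(np.maximum(v, -_LOG2)))
    return np.where(v < -_LOG2, small, near0)


def _coerce_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        df = data
    else:  # sequence of ParticipantRecord
        df = cohort_to_frame(list(data))
    if "age_c" not in df.columns:
        df = encode_design(df)
    return df


class NormativeGLM:
    """Bayesian GLM of one outcome on age within one demographic subgroup.

    Parameters
    ----------
    data : DataFrame or sequence of ParticipantRecord
        Cohort table with demographics and outcome columns.
    outcome : str or OutcomeSpec
        Which outcome to model; strings are looked up in the bundled
        registry.
    family : str, optional
        Response family; defaults to the outcome's registered family.
    subgroup : str
        One of :data:`SUBGROUPS`; rows outside the subgroup are dropped.
    priors : PriorConfig
    age_center : float
        Age subtracted before entering the linear predictor (intercepts are
        then interpretable mid-sample).
    min_cases : int
        Minimum complete cases required to attempt a fit.
    inflation_on_age : bool
        zoib only: adds a logit-linear age trend on the boundary
        probability ``zoi`` (distributional regression), so the chance of
        an exact floor/ceiling score can change with age.  Off by default:
        the standard model carries a single age coefficient on the
        location parameter.
    """

    def __init__(
        self,
        data,
        outcome,
        family: str | None = None,
        subgroup: str = "all",
        priors: PriorConfig = PriorConfig(),
        age_center: float = 40.0,
        min_cases: int = 30,
        inflation_on_age: bool = False,
    ):
        self.spec: OutcomeSpec = (
            DEFAULT_OUTCOMES[outcome] if isinstance(outcome, str) else outcome
        )
        self.family = family or self.spec.family
        if self.family not in ("beta", "zoib", "hurdle_nb"):
            raise ValueError(f"unknown family {self.family!r}")
        self.subgroup = subgroup
        self.priors = priors
        self.age_center = float(age_center)
        if inflation_on_age and self.family != "zoib":
            raise ValueError("inflation_on_age requires the zoib family")
        self.inflation_on_age = bool(inflation_on_age)

        df = _coerce_frame(data)
        if self.spec.name not in df.columns:
            raise ValueError(f"outcome column {self.spec.name!r} not in data")
        df = df[subgroup_mask(df, subgroup)].dropna(subset=[self.spec.name])
        if len(df) == 0:
            raise ValueError(f"subgroup {subgroup!r} has no complete cases")
        if len(df) < min_cases:
            raise ValueError(
                f"subgroup {subgroup!r}: {len(df)} complete cases "
                f"< floor {min_cases}"
            )
        self.nobs = len(df)
        self.ids = df["id"].astype(str).to_numpy() if "id" in df else None
        self.age_c = df["age"].to_numpy(dtype=float) - self.age_center

        raw = df[self.spec.name].to_numpy(dtype=float)
        if np.any((raw < self.spec.score_min) | (raw > self.spec.score_max)):
            raise ValueError(f"{self.spec.name}: scores outside declared range")
        self.raw_scores = raw
        self._prepare_response(raw)
        self._prepare_priors()

    # -- response preparation ------------------------------------------------

    def _prepare_response(self, raw: np.ndarray) -> None:
        if self.family in ("beta", "zoib"):
            y = self.spec.to_unit(raw)
            # pre-nudge values, kept for posterior-predictive checks so that
            # boundary-mass misfit stays visible under the beta family
            self.y_observed = y.copy()
            if self.family == "beta":
                n_bound = int(np.sum((y == 0.0) | (y == 1.0)))
                if n_bound:
                    warnings.warn(
                        f"{self.spec.name}: {n_bound} boundary value(s) nudged "
                        f"into the interior by {BETA_BOUNDARY_EPS} for the "
                        "beta family",
                        stacklevel=3,
                    )
                    y = np.clip(y, BETA_BOUNDARY_EPS, 1.0 - BETA_BOUNDARY_EPS)
            self.y = y
            self._zero = y == 0.0
            self._one = y == 1.0
            interior = ~(self._zero | self._one)
            self._interior = interior
            self._log_y = np.log(y[interior])
            self._log_1my = np.log1p(-y[interior])
            self._age_int = self.age_c[interior]
            self._age_zero = self.age_c[self._zero]
            self._age_one = self.age_c[self._one]
            self.n_zero = int(self._zero.sum())
            self.n_one = int(self._one.sum())
            self.n_interior = int(interior.sum())
        else:
            counts = self.spec.to_count(raw)
            if np.any(np.mod(counts, 1) != 0) or np.any(counts < 0):
                raise ValueError(
                    f"{self.spec.name}: hurdle family needs non-negative "
                    "integer counts after offset removal"
                )
            self.y = counts.astype(np.int64)
            self.y_observed = self.y.astype(float)
            self._pos = self.y > 0
            self._ypos = self.y[self._pos].astype(float)
            self._age_pos = self.age_c[self._pos]
            self._gammaln_y1 = special.gammaln(self._ypos + 1.0)
            self.n_zero = int((~self._pos).sum())
            self.n_pos = int(self._pos.sum())

    def _prepare_priors(self) -> None:
        if self.family in ("beta", "zoib"):
            interior = self.y[(self.y > 0) & (self.y < 1)]
            center = np.median(interior) if interior.size else 0.5
            self._intercept_loc = float(logit(np.clip(center, 0.01, 0.99)))
        else:
            pos = self.y[self.y > 0]
            center = np.mean(pos) if pos.size else 1.0
            self._intercept_loc = float(np.log(max(center, 0.5)))

    # -- parameterisation ----------------------------------------------------

    @property
    def param_names(self) -> list[str]:
        base = ["intercept", "beta_age"]
        if self.family == "beta":
            return base + ["log_phi"]
        if self.family == "zoib":
            names = base + ["log_phi", "logit_zoi", "logit_coi"]
            if self.inflation_on_age:
                names.append("beta_zoi_age")
            return names
        return base + ["log_shape", "logit_hu"]

    @property
    def nparams(self) -> int:
        return len(self.param_names)

    def start_params(self) -> np.ndarray:
        n = self.nobs
        if self.family == "beta":
            return np.array([self._intercept_loc, 0.0, np.log(5.0)])
        if self.family == "zoib":
            zoi0 = (self.n_zero + self.n_one + 1.0) / (n + 2.0)
            coi0 = (self.n_one + 1.0) / (self.n_zero + self.n_one + 2.0)
            start = [self._intercept_loc, 0.0, np.log(2.0),
                     float(logit(zoi0)), float(logit(coi0))]
            if self.inflation_on_age:
                start.append(0.0)
            return np.array(start)
        hu0 = (self.n_zero + 1.0) / (n + 2.0)
        return np.array(
            [self._intercept_loc, 0.0, 0.0, float(logit(hu0))]
        )

    def _bounds(self) -> list[tuple[float, float]]:
        b = [(self._intercept_loc - 20.0, self._intercept_loc + 20.0),
             (-2.0, 2.0)]
        b.append((-10.0, 12.0))                   # log phi / log shape
        if self.family == "zoib":
            b += [(-15.0, 15.0), (-15.0, 15.0)]
            if self.inflation_on_age:
                b += [(-1.0, 1.0)]
        elif self.family == "hurdle_nb":
            b += [(-15.0, 15.0)]
        return b

    # -- log densities -------------------------------------------------------

    def loglike(self, params: np.ndarray) -> float:
        """Total log likelihood at an unconstrained parameter vector."""
        p = np.asarray(params, dtype=float)
        b0, b_age = p[0], p[1]
        if self.family in ("beta", "zoib"):
            phi = np.exp(p[2])
            mu = inv_logit(b0 + b_age * self._age_int)
            mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
            a, b = mu * phi, (1.0 - mu) * phi
            ll = np.sum(
                (a - 1.0) * self._log_y
                + (b - 1.0) * self._log_1my
                - special.betaln(a, b)
            )
            if self.family == "zoib":
                log_coi = special.log_expit(p[4])
                log_1mcoi = special.log_expit(-p[4])
                if self.inflation_on_age:
                    bz = p[5]
                    ll += np.sum(special.log_expit(-(p[3] + bz * self._age_int)))
                    ll += np.sum(special.log_expit(p[3] + bz * self._age_zero))
                    ll += self.n_zero * log_1mcoi
                    ll += np.sum(special.log_expit(p[3] + bz * self._age_one))
                    ll += self.n_one * log_coi
                else:
                    ll += self.n_interior * special.log_expit(-p[3])
                    ll += self.n_zero * (special.log_expit(p[3]) + log_1mcoi)
                    ll += self.n_one * (special.log_expit(p[3]) + log_coi)
            return float(ll)
        # hurdle negative binomial
        shape = np.exp(p[2])
        log_hu = special.log_expit(p[3])
        log_1mhu = special.log_expit(-p[3])
        mu = np.exp(b0 + b_age * self._age_pos)
        log_p = np.log(shape) - np.log(shape + mu)      # log NB success prob
        log_q = np.log(mu) - np.log(shape + mu)
        lp_nb = (
            special.gammaln(self._ypos + shape)
            - special.gammaln(shape)
            - self._gammaln_y1
            + shape * log_p
            + self._ypos * log_q
        )
        log_nb0 = shape * log_p
        ll = (
            self.n_zero * log_hu
            + self.n_pos * log_1mhu
            + np.sum(lp_nb - _log1mexp(log_nb0))
        )
        return float(ll)

    def logprior(self, params: np.ndarray) -> float:
        p = np.asarray(params, dtype=float)
        pr = self.priors
        lp = stats.t.logpdf(p[0], pr.intercept_df, loc=self._intercept_loc,
                            scale=pr.intercept_scale)
        lp += stats.norm.logpdf(p[1], scale=pr.coef_sd)
        # half Student-t on phi/shape, plus the log-scale Jacobian
        aux = np.exp(p[2])
        lp += (
            _LOG2
            + stats.t.logpdf(aux, pr.aux_df, scale=pr.aux_scale)
            + p[2]
        )
        # uniform Beta(1,1) on probabilities, logit-scale Jacobian
        for j, name in enumerate(self.param_names):
            if name.startswith("logit_"):
                lp += float(special.log_expit(p[j]) + special.log_expit(-p[j]))
            elif name == "beta_zoi_age":
                lp += stats.norm.logpdf(p[j], scale=pr.coef_sd)
        return float(lp)

    def logpost(self, params: np.ndarray) -> float:
        ll = self.loglike(params)
        if not np.isfinite(ll):
            return -np.inf
        return ll + self.logprior(params)

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        sampler: SamplerConfig | None = None,
        check_convergence: bool = True,
    ) -> "NormativeGLMResults":
        """Run MCMC and return a results object.

        Raises :class:`ConvergenceError` if any parameter's rank-normalised
        split R-hat exceeds the configured gate (``sampler.rhat_max``).
        """
        sampler = PRODUCTION_SAMPLER if sampler is None else sampler
        out = run_mcmc(self.logpost, self.start_params(), sampler,
                       bounds=self._bounds())
        results = NormativeGLMResults(self, sampler, out)
        if check_convergence:
            bad = results.diagnostics["rhat"] > sampler.rhat_max
            if np.any(bad):
                names = [n for n, b in zip(self.param_names, bad) if b]
                raise ConvergenceError(
                    f"{self.spec.name}/{self.subgroup}: R-hat gate "
                    f"{sampler.rhat_max} exceeded for {names} "
                    f"(rhat={results.diagnostics['rhat']})",
                    diagnostics=results.diagnostics,
                )
        return results

    # -- pointwise log likelihood (draws x observations) ---------------------

    def pointwise_loglik(self, draws: np.ndarray) -> np.ndarray:
        """Log p(y_i | theta_j) for every draw j and observation i."""
        draws = np.atleast_2d(draws)
        n_draws = draws.shape[0]
        out = np.empty((n_draws, self.nobs))
        b0 = draws[:, 0][:, None]
        b_age = draws[:, 1][:, None]
        age = self.age_c[None, :]
        if self.family in ("beta", "zoib"):
            phi = np.exp(draws[:, 2])[:, None]
            mu = np.clip(inv_logit(b0 + b_age * age), 1e-12, 1 - 1e-12)
            a, b = mu * phi, (1.0 - mu) * phi
            y = self.y[None, :]
            interior = np.clip(y, 1e-12, 1 - 1e-12)
            ll = (
                (a - 1.0) * np.log(interior)
                + (b - 1.0) * np.log1p(-interior)
                - special.betaln(a, b)
            )
            if self.family == "zoib":
                eta_z = draws[:, 3][:, None]
                if self.inflation_on_age:
                    eta_z = eta_z + draws[:, 5][:, None] * age
                lz = special.log_expit(eta_z)
                l1mz = special.log_expit(-eta_z)
                lc = special.log_expit(draws[:, 4])[:, None]
                l1mc = special.log_expit(-draws[:, 4])[:, None]
                ll = ll + l1mz
                ll = np.where(self._zero[None, :], lz + l1mc, ll)
                ll = np.where(self._one[None, :], lz + lc, ll)
            out[:] = ll
        else:
            shape = np.exp(draws[:, 2])[:, None]
            lhu = special.log_expit(draws[:, 3])[:, None]
            l1mhu = special.log_expit(-draws[:, 3])[:, None]
            mu = np.exp(b0 + b_age * age)
            log_p = np.log(shape) - np.log(shape + mu)
            log_q = np.log(mu) - np.log(shape + mu)
            y = self.y[None, :].astype(float)
            lp_nb = (
                special.gammaln(y + shape)
                - special.gammaln(shape)
                - special.gammaln(y + 1.0)
                + shape * log_p
                + y * log_q
            )
            ll = l1mhu + lp_nb - _log1mexp(shape * log_p)
            out[:] = np.where(self.y[None, :] == 0, lhu, ll)
        return out

    # -- predictive simulation ----------------------------------------------

    def family_params_at(self, draws: np.ndarray, age: float):
        """Family parameter object(s) at a given age, one per draw."""
        draws = np.atleast_2d(draws)
        eta = draws[:, 0] + draws[:, 1] * (float(age) - self.age_center)
        if self.family == "beta":
            return BetaParams(
                mu=np.clip(inv_logit(eta), 1e-12, 1 - 1e-12),
                phi=np.exp(draws[:, 2]),
            )
        if self.family == "zoib":
            eta_z = draws[:, 3]
            if self.inflation_on_age:
                eta_z = eta_z + draws[:, 5] * (float(age) - self.age_center)
            return ZoibParams(
                mu=np.clip(inv_logit(eta), 1e-12, 1 - 1e-12),
                phi=np.exp(draws[:, 2]),
                zoi=inv_logit(eta_z),
                coi=inv_logit(draws[:, 4]),
            )
        return HurdleNbParams(
            mu=np.exp(eta), shape=np.exp(draws[:, 2]), hu=inv_logit(draws[:, 3])
        )


class NormativeGLMResults:
    """Posterior fit for one subgroup x outcome model.

    Carries the post-warmup draws (``chains x sampling_iters`` vectors on
    the unconstrained scale), convergence diagnostics, and everything
    downstream needs: age-effect summaries, LOO, posterior-predictive
    simulation and checks, and norm-table construction (via
    :mod:`cognorm.normative_tables`).
    """

    def __init__(self, model: NormativeGLM, sampler: SamplerConfig, out: dict):
        self.model = model
        self.sampler = sampler
        self.draws_chains = out["draws"]            # (chains, iters, d)
        d = self.draws_chains.shape[-1]
        self.draws = self.draws_chains.reshape(-1, d)
        self.param_names = model.param_names
        self.diagnostics = {
            "rhat": out["rhat"],
            "ess": out["ess"],
            "accept_rate": out["accept_rate"],
            "divergences": 0,   # MH kernels have no divergent transitions
            "n_draws": int(self.draws.shape[0]),
            "nobs": model.nobs,
        }
        self.mode = out["mode"]

    # -- basic accessors -----------------------------------------------------

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def param_draws(self, name: str) -> np.ndarray:
        return self.draws[:, self.param_names.index(name)]

    @property
    def subgroup(self) -> str:
        return self.model.subgroup

    @property
    def outcome(self) -> str:
        return self.model.spec.name

    @property
    def family(self) -> str:
        return self.model.family

    # -- summaries -----------------------------------------------------------

    def age_effect_summary(self) -> AgeEffectSummary:
        """exp(posterior median) of the age slope with equal-tailed 95% CI."""
        b = self.param_draws("beta_age")
        lo, mid, hi = np.percentile(b, [2.5, 50.0, 97.5])
        point, ci_low, ci_high = float(np.exp(mid)), float(np.exp(lo)), float(np.exp(hi))
        return AgeEffectSummary(
            point=point,
            ci_low=ci_low,
            ci_high=ci_high,
            label=effect_label(self.family),
            significant=not (ci_low <= 1.0 <= ci_high),
        )

    def summary(self) -> str:
        eff = self.age_effect_summary()
        lines = [
            f"NormativeGLM results: {self.outcome} ~ age, "
            f"subgroup={self.subgroup}, family={self.family}",
            f"n = {self.model.nobs}, draws = {self.n_draws} "
            f"({self.sampler.chains} chains x {self.sampler.sampling_iters}), "
            f"algorithm = {self.sampler.algorithm}",
            "-" * 72,
            f"{'parameter':<12}{'mean':>10}{'sd':>10}{'2.5%':>10}"
            f"{'50%':>10}{'97.5%':>10}{'rhat':>8}{'ess':>8}",
        ]
        for j, name in enumerate(self.param_names):
            col = self.draws[:, j]
            q = np.percentile(col, [2.5, 50, 97.5])
            lines.append(
                f"{name:<12}{col.mean():>10.4f}{col.std(ddof=1):>10.4f}"
                f"{q[0]:>10.4f}{q[1]:>10.4f}{q[2]:>10.4f}"
                f"{self.diagnostics['rhat'][j]:>8.3f}"
                f"{self.diagnostics['ess'][j]:>8.0f}"
            )
        lines.append("-" * 72)
        lines.append(f"age effect  {eff}")
        return "\n".join(lines)

    # -- LOO -----------------------------------------------------------------

    def loo(self) -> dict:
        """PSIS-LOO expected log predictive density (higher = better).

        Returns ``elpd``, its standard error, per-observation ``pareto_k``
        diagnostics and the indices of observations with k > 0.7.
        """
        import arviz as az

        ll = self.model.pointwise_loglik(self.draws)
        chains = self.sampler.chains
        ll3 = ll.reshape(chains, -1, self.model.nobs)
        idata = az.from_dict(
            posterior={
                name: self.draws_chains[:, :, j]
                for j, name in enumerate(self.param_names)
            },
            log_likelihood={"y": ll3},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = az.loo(idata, pointwise=True)
        k = np.asarray(res.pareto_k)
        # common-scale elpd for cross-family comparison on integer-scored
        # outcomes: interior unit-interval densities are converted to
        # approximate bin masses (width 1/span), so a density-based fit can
        # be compared against a count pmf on the same data
        adjustment = 0.0
        if self.family in ("beta", "zoib"):
            n_int = getattr(self.model, "n_interior", self.model.nobs)
            adjustment = -float(n_int) * np.log(self.model.spec.span)
        return {
            "elpd": float(res.elpd_loo),
            "se": float(res.se),
            "p_loo": float(res.p_loo),
            "pareto_k": k,
            "flagged": np.flatnonzero(k > 0.7),
            "elpd_common_scale": float(res.elpd_loo) + adjustment,
        }

    # -- posterior predictive ------------------------------------------------

    def predictive_draws(self, age: float, n_draws: int | None = None,
                         rng: np.random.Generator | None = None) -> np.ndarray:
        """Posterior-predictive raw-scale scores at a fixed age.

        One score is simulated per posterior draw (parameter uncertainty and
        sampling noise both propagate); draws are recycled if ``n_draws``
        exceeds the stored posterior sample.
        """
        rng = np.random.default_rng(0) if rng is None else rng
        n_draws = self.n_draws if n_draws is None else int(n_draws)
        idx = np.arange(n_draws) % self.n_draws
        params = self.model.family_params_at(self.draws[idx], age)
        nat = family_rvs(self.family, params, n_draws, rng)
        spec = self.model.spec
        if self.family in ("beta", "zoib"):
            raw = spec.from_unit(nat)
        else:
            raw = spec.from_count(nat)
        return np.clip(raw, spec.score_min, spec.score_max)

    def replicate_datasets(self, n_rep: int, rng: np.random.Generator):
        """Simulate ``n_rep`` replicated datasets at the observed ages."""
        m = self.model
        idx = rng.integers(0, self.n_draws, size=n_rep)
        reps = np.empty((n_rep, m.nobs))
        for r, j in enumerate(idx):
            th = self.draws[j]
            eta = th[0] + th[1] * m.age_c
            if m.family == "beta":
                p = BetaParams(np.clip(inv_logit(eta), 1e-12, 1 - 1e-12),
                               np.exp(th[2]))
            elif m.family == "zoib":
                eta_z = th[3]
                if m.inflation_on_age:
                    eta_z = eta_z + th[5] * m.age_c
                p = ZoibParams(np.clip(inv_logit(eta), 1e-12, 1 - 1e-12),
                               np.exp(th[2]), inv_logit(eta_z),
                               float(inv_logit(th[4])))
            else:
                p = HurdleNbParams(np.exp(eta), np.exp(th[2]),
                                   float(inv_logit(th[3])))
            reps[r] = family_rvs(m.family, p, m.nobs, rng)
        return reps

    def posterior_predictive_check(self, n_rep: int = 500,
                                   seed: int = 0) -> pd.DataFrame:
        """Numeric posterior-predictive checks.

        Compares observed zero-mass, one-mass (unit-interval families) and
        deciles against replicated datasets.  The posterior predictive
        p-value uses the tie convention p = (#{rep > obs} + 0.5 #{rep ==
        obs}) / R, so a replicate identical to the observed data gives
        p = 0.5.
        """
        rng = np.random.default_rng(seed)
        m = self.model
        reps = self.replicate_datasets(n_rep, rng)
        obs = m.y_observed

        def stat_rows(name, obs_val, rep_vals):
            gt = np.sum(rep_vals > obs_val)
            eq = np.sum(rep_vals == obs_val)
            return {
                "statistic": name,
                "observed": obs_val,
                "replicated_mean": float(np.mean(rep_vals)),
                "p_value": float((gt + 0.5 * eq) / len(rep_vals)),
            }

        rows = [stat_rows("zero_mass", float(np.mean(obs == 0.0)),
                          np.mean(reps == 0.0, axis=1))]
        if m.family in ("beta", "zoib"):
            rows.append(stat_rows("one_mass", float(np.mean(obs == 1.0)),
                                  np.mean(reps == 1.0, axis=1)))
        for q in range(10, 100, 10):
            rows.append(
                stat_rows(
                    f"decile_{q}",
                    float(np.percentile(obs, q)),
                    np.percentile(reps, q, axis=1),
                )
            )
        return pd.DataFrame(rows)

    # -- persistence ---------------------------------------------------------

    def to_tidy_draws(self) -> pd.DataFrame:
        """Tidy draws table: draw, chain, parameter, value."""
        chains, iters, d = self.draws_chains.shape
        frames = []
        for j, name in enumerate(self.param_names):
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(chains), iters),
                        "draw": np.tile(np.arange(iters), chains),
                        "parameter": name,
                        "value": self.draws_chains[:, :, j].ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def save(self, prefix) -> tuple[Path, Path]:
        """Write tidy draw CSV plus a JSON summary next to ``prefix``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        csv_path = prefix.with_suffix(".draws.csv")
        json_path = prefix.with_suffix(".summary.json")
        self.to_tidy_draws().to_csv(csv_path, index=False)
        eff = self.age_effect_summary()
        payload = {
            "outcome": self.outcome,
            "subgroup": self.subgroup,
            "family": self.family,
            "nobs": self.model.nobs,
            "age_center": self.model.age_center,
            "sampler": {
                "chains": self.sampler.chains,
                "warmup_iters": self.sampler.warmup_iters,
                "sampling_iters": self.sampler.sampling_iters,
                "seed": self.sampler.seed,
                "algorithm": self.sampler.algorithm,
            },
            "diagnostics": {
                "rhat": self.diagnostics["rhat"].tolist(),
                "ess": self.diagnostics["ess"].tolist(),
                "accept_rate": self.diagnostics["accept_rate"].tolist(),
                "divergences": self.diagnostics["divergences"],
            },
            "age_effect": {
                "point": eff.point,
                "ci_low": eff.ci_low,
                "ci_high": eff.ci_high,
                "label": eff.label,
                "significant": eff.significant,
            },
            "priors": {
                "coef_sd": self.model.priors.coef_sd,
                "aux_df": self.model.priors.aux_df,
                "aux_scale": self.model.priors.aux_scale,
            },
        }
        json_path.write_text(json.dumps(payload, indent=2))
        return csv_path, json_path


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------

def fit_glm(
    cohort,
    outcome,
    subgroup: str = "all",
    family: str | None = None,
    priors: PriorConfig = PriorConfig(),
    sampler: SamplerConfig | None = None,
    check_convergence: bool = True,
    **model_kwargs,
) -> NormativeGLMResults:
    """Fit one subgroup x outcome GLM (thin wrapper over NormativeGLM)."""
    model = NormativeGLM(cohort, outcome, family=family, subgroup=subgroup,
                         priors=priors, **model_kwargs)
    return model.fit(sampler, check_convergence=check_convergence)


def fit_all_subgroups(
    cohort,
    outcome,
    family: str | None = None,
    priors: PriorConfig = PriorConfig(),
    sampler: SamplerConfig | None = None,
    subgroups: Sequence[str] = SUBGROUPS,
    **model_kwargs,
) -> tuple[dict[str, NormativeGLMResults], dict[str, str]]:
    """Fit the seven age-trend models; continue past per-subgroup failures.

    Returns (fits, errors): per-subgroup results and per-subgroup error
    messages for those that could not be fitted.
    """
    df = _coerce_frame(cohort)
    fits: dict[str, NormativeGLMResults] = {}
    errors: dict[str, str] = {}
    for sg in subgroups:
        try:
            fits[sg] = fit_glm(df, outcome, subgroup=sg, family=family,
                               priors=priors, sampler=sampler, **model_kwargs)
        except (ValueError, ConvergenceError) as exc:
            errors[sg] = str(exc)
    return fits, errors


def age_effect_summary(fit: NormativeGLMResults) -> AgeEffectSummary:
    return fit.age_effect_summary()


def age_effect_table(fits: Mapping[str, NormativeGLMResults]) -> pd.DataFrame:
    """Assemble per-subgroup age effects into one report row per subgroup."""
    rows = []
    for sg, fit in fits.items():
        eff = fit.age_effect_summary()
        rows.append(
            {
                "outcome": fit.outcome,
                "family": fit.family,
                "subgroup": sg,
                "n": fit.model.nobs,
                "label": eff.label,
                "point": eff.point,
                "ci_low": eff.ci_low,
                "ci_high": eff.ci_high,
                "significant": eff.significant,
            }
        )
    return pd.DataFrame(rows)


def elpd_loo(fit: NormativeGLMResults) -> dict:
    return fit.loo()


def exact_refit_loo(
    model: NormativeGLM,
    sampler: SamplerConfig = REDUCED_TEST_SAMPLER,
) -> dict:
    """Brute-force leave-one-out: refit without each observation in turn.

    elpd_i = log mean_j p(y_i | theta_j^{(-i)}).  O(n) refits — intended
    for small n as the oracle against which PSIS-LOO is validated, and as
    the exact fallback for high-Pareto-k observations.
    """
    df = pd.DataFrame(
        {
            "id": model.ids if model.ids is not None
            else [str(i) for i in range(model.nobs)],
            "age": model.age_c + model.age_center,
            "sex": "male",
            "education_band": "high",
            "education_level": 4,
            model.spec.name: model.raw_scores,
        }
    )
    elpds = np.empty(model.nobs)
    for i in range(model.nobs):
        sub = df.drop(df.index[i])
        m_i = NormativeGLM(sub, model.spec, family=model.family,
                           subgroup="all", priors=model.priors,
                           age_center=model.age_center, min_cases=2,
                           inflation_on_age=model.inflation_on_age)
        res_i = m_i.fit(sampler, check_convergence=False)
        # evaluate left-out point under the refit posterior
        ll = _heldout_loglik(model, i, res_i.draws)
        elpds[i] = special.logsumexp(ll) - np.log(ll.size)
    return {"elpd": float(elpds.sum()),
            "se": float(np.sqrt(model.nobs * np.var(elpds, ddof=1))),
            "pointwise": elpds}


def _heldout_loglik(model: NormativeGLM, i: int, draws: np.ndarray) -> np.ndarray:
    """Log p(y_i | theta) over draws, for the full model's observation i."""
    th = np.atleast_2d(draws)
    eta = th[:, 0] + th[:, 1] * model.age_c[i]
    if model.family in ("beta", "zoib"):
        y = float(model.y[i])
        phi = np.exp(th[:, 2])
        mu = np.clip(inv_logit(eta), 1e-12, 1 - 1e-12)
        a, b = mu * phi, (1 - mu) * phi
        yc = min(max(y, 1e-12), 1 - 1e-12)
        ll = (a - 1) * np.log(yc) + (b - 1) * np.log1p(-yc) - special.betaln(a, b)
        if model.family == "zoib":
            eta_z = th[:, 3]
            if model.inflation_on_age:
                eta_z = eta_z + th[:, 5] * model.age_c[i]
            lz = special.log_expit(eta_z)
            l1mz = special.log_expit(-eta_z)
            lc = special.log_expit(th[:, 4])
            l1mc = special.log_expit(-th[:, 4])
            if y == 0.0:
                return lz + l1mc
            if y == 1.0:
                return lz + lc
            return ll + l1mz
        return ll
    y = float(model.y[i])
    shape = np.exp(th[:, 2])
    if y == 0:
        return special.log_expit(th[:, 3])
    mu = np.exp(eta)
    log_p = np.log(shape) - np.log(shape + mu)
    lp_nb = (
        special.gammaln(y + shape) - special.gammaln(shape)
        - special.gammaln(y + 1.0) + shape * log_p
        + y * (np.log(mu) - np.log(shape + mu))
    )
    return special.log_expit(-th[:, 3]) + lp_nb - _log1mexp(shape * log_p)


def posterior_predictive_check(fit: NormativeGLMResults, n_rep: int = 500,
                               seed: int = 0) -> pd.DataFrame:
    return fit.posterior_predictive_check(n_rep=n_rep, seed=seed)
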