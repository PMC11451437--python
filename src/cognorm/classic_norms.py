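"""Classical norming baselines: stratified and regression-based z-scores.

Both end in a percentile via the standard normal CDF, with the z-score
sign flipped first for outcomes where higher raw scores mean poorer
performance, so percentiles always report goodness.

*Stratified*: means and SDs are computed within age-band x sex x education
cells (bands 18–24, 25–34, 35–44, 45–54, 55–64, 65–75) and an individual's
z is (observed - cell mean) / cell SD.

*Regression (Van der Elst)*: ordinary least squares of the score on age,
sex (male = 0, female = 1) and education band (low = 0, high = 1);
influential observations with Cook's distance above a threshold (default
4/n) are removed once and the model refitted; z is the residual divided by
the residual SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort_io import DEFAULT_OUTCOMES, OutcomeSpec, encode_design

__all__ = [
    "AGE_BANDS",
    "NotNormableError",
    "StratumStats",
    "StratifiedNorms",
    "RegressionNorms",
    "age_band",
    "fit_stratified",
    "stratified_z",
    "fit_regression",
    "regression_z",
    "z_to_percentile",
    "stratified_percentile",
    "regression_percentile",
]

AGE_BANDS = ((18, 24), (25, 34), (35, 44), (45, 54), (55, 64), (65, 75))
DEFAULT_MIN_STRATUM_N = 5


class NotNormableError(ValueError):
    """The record's stratum cannot supply a usable norm (tiny n or sd=0)."""


def age_band(age: int) -> str:
    for lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    raise ValueError(f"age {age} outside the normative range 18-75")


@dataclass(frozen=True)
class StratumStats:
    n: int
    mean: float
    sd: float       # sample SD (n-1 denominator); nan when n < 2

    @property
    def usable(self) -> bool:
        return np.isfinite(self.sd) and self.sd > 0.0


@dataclass
class StratifiedNorms:
    """Per-stratum normative statistics for one outcome."""

    outcome: str
    strata: dict[tuple[str, str, str], StratumStats]
    min_n: int = DEFAULT_MIN_STRATUM_N

    def stratum(self, age: int, sex: str, education_band: str) -> StratumStats:
        key = (age_band(age), sex, education_band)
        if key not in self.strata:
            raise NotNormableError(f"{self.outcome}: empty stratum {key}")
        return self.strata[key]

    def flagged(self) -> list[tuple[str, str, str]]:
        """Strata too small or degenerate to norm against."""
        return [
            k for k, s in self.strata.items()
            if s.n < self.min_n or not s.usable
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"age_band": k[0], "sex": k[1], "education_band": k[2],
             "n": s.n, "mean": s.mean, "sd": s.sd}
            for k, s in sorted(self.strata.items())
        ]
        return pd.DataFrame(rows)


def fit_stratified(cohort: pd.DataFrame, outcome: str,
                   min_n: int = DEFAULT_MIN_STRATUM_N) -> StratifiedNorms:
    """Cell means/SDs over the 6 x 2 x 2 stratification.

    Empty strata are simply absent (flagged at lookup); strata with n
    below ``min_n`` or zero SD are kept but reported by ``flagged()``.
    """
    df = cohort.dropna(subset=[outcome])
    strata: dict[tuple[str, str, str], StratumStats] = {}
    bands = df["age"].map(age_band)
    for (band, sex, edu), grp in df.groupby(
        [bands, df["sex"], df["education_band"]], observed=True
    ):
        vals = grp[outcome].to_numpy(dtype=float)
        strata[(band, sex, edu)] = StratumStats(
            n=vals.size,
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
        )
    return StratifiedNorms(outcome=outcome, strata=strata, min_n=min_n)


def stratified_z(record, norms: StratifiedNorms, outcome: str | None = None) -> float:
    """z = (observed - stratum mean) / stratum SD."""
    outcome = norms.outcome if outcome is None else outcome
    s = norms.stratum(int(record["age"]), record["sex"],
                      record["education_band"])
    if s.n < norms.min_n or not s.usable:
        raise NotNormableError(
            f"{outcome}: stratum n={s.n}, sd={s.sd} not usable"
        )
    return (float(record[outcome]) - s.mean) / s.sd


@dataclass
class RegressionNorms:
    """OLS demographic model for one outcome (Van der Elst norms)."""

    outcome: str
    intercept: float
    beta_age: float
    beta_sex: float
    beta_edu: float
    residual_sd: float
    removed_ids: list[str] = field(default_factory=list)
    cooks_threshold: float = float("nan")
    n_used: int = 0

    def predict(self, age, sex_code, edu_code) -> float:
        return (
            self.intercept
            + self.beta_age * age
            + self.beta_sex * sex_code
            + self.beta_edu * edu_code
        )


def _design(df: pd.DataFrame) -> np.ndarray:
    return sm.add_constant(
        df[["age", "sex_code", "edu_code"]].to_numpy(dtype=float),
        has_constant="add",
    )


def fit_regression(
    cohort: pd.DataFrame,
    outcome: str,
    cooks_threshold: float | None = None,
) -> RegressionNorms:
    """OLS with one Cook's-distance screening pass.

    Age enters on its raw scale (years), matching the reporting convention
    of demographic regression norms.  Points with Cook's distance above
    ``cooks_threshold`` (default 4/n) are removed once and the model
    refitted; removals are recorded for audit.
    """
    df = cohort.dropna(subset=[outcome]).copy()
    if "sex_code" not in df.columns:
        df = encode_design(df)
    if len(df) < 6:     # p + 2 with p = 4 coefficients
        raise ValueError(f"{outcome}: too few complete cases ({len(df)})")
    y = df[outcome].to_numpy(dtype=float)
    X = _design(df)
    res = sm.OLS(y, X).fit()
    thr = 4.0 / len(df) if cooks_threshold is None else float(cooks_threshold)
    cooks = res.get_influence().cooks_distance[0]
    drop = cooks > thr
    removed = (
        df.loc[drop, "id"].astype(str).tolist() if "id" in df.columns
        else [str(i) for i in np.flatnonzero(drop)]
    )
    if drop.any():
        df = df.loc[~drop]
        y = df[outcome].to_numpy(dtype=float)
        X = _design(df)
        res = sm.OLS(y, X).fit()
    params = res.params
    return RegressionNorms(
        outcome=outcome,
        intercept=float(params[0]),
        beta_age=float(params[1]),
        beta_sex=float(params[2]),
        beta_edu=float(params[3]),
        residual_sd=float(np.sqrt(res.scale)),
        removed_ids=removed,
        cooks_threshold=thr,
        n_used=int(res.nobs),
    )


def regression_z(record, norms: RegressionNorms, outcome: str | None = None) -> float:
    """z = (observed - predicted) / residual SD."""
    outcome = norms.outcome if outcome is None else outcome
    sex_code = record["sex_code"] if "sex_code" in record else (
        0.0 if record["sex"] == "male" else 1.0
    )
    edu_code = record["edu_code"] if "edu_code" in record else (
        1.0 if record["education_band"] == "high" else 0.0
    )
    pred = norms.predict(float(record["age"]), float(sex_code), float(edu_code))
    return (float(record[outcome]) - pred) / norms.residual_sd


def z_to_percentile(z: float, direction: str) -> int:
    """Map a z-score to an integer percentile on [1, 99].

    The sign is reversed first for lower_better (error) outcomes, so the
    percentile reports goodness; z = 0 maps to the 50th percentile.
    """
    if direction not in ("higher_better", "lower_better"):
        raise ValueError(f"bad direction {direction!r}")
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    z_adj = z if direction == "higher_better" else -z
    pct = stats.norm.cdf(z_adj) * 100.0
    return int(np.clip(np.rint(pct), 1, 99))


def stratified_percentile(record, norms: StratifiedNorms,
                          spec: OutcomeSpec | None = None) -> int:
    spec = DEFAULT_OUTCOMES[norms.outcome] if spec is None else spec
    return z_to_percentile(stratified_z(record, norms), spec.direction)


def regression_percentile(record, norms: RegressionNorms,
                          spec: OutcomeSpec | None = None) -> int:
    spec = DEFAULT_OUTCOMES[norms.outcome] if spec is None else spec
    return z_to_percentile(regression_z(record, norms), spec.direction)
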