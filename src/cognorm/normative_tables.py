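"""Age-resolved percentile norm tables from posterior fits.

For each age on a grid (default 18..75), posterior-predictive scores are
simulated from a fitted subgroup model — one score per posterior draw, so
parameter uncertainty and sampling variability both enter — and empirical
quantiles at 1% intervals become the norm thresholds.

Percentiles always report *goodness*: the k-th level holds the score at
the k-th performance percentile, so for error measures (lower is better)
level k stores the (100-k)-th raw-score quantile.  Thresholds are actual
attainable sample values (inverted-CDF quantiles), which keeps tie bands
meaningful for discrete scores.

Tables are then smoothed by recursive substitution: scanning ages left to
right within each percentile level, any threshold that moves against the
outcome's expected age trend (performance declines with age) is replaced
by the previous age's value — a running max for error measures, a running
min for accuracy measures.

Score lookup applies the mid-band tie rule: a score whose threshold is
shared by a contiguous band of levels (e.g. the 88th–99th) receives the
band midpoint rounded up to the nearest whole percentile (94th).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import DEFAULT_OUTCOMES, OutcomeSpec

__all__ = [
    "PercentileTable",
    "PercentileResult",
    "build_percentile_table",
    "smooth_table",
    "score_to_percentile",
    "midband_percentile",
    "export_norms",
    "read_norm_table",
]

LEVELS = np.arange(1, 100)      # 1% intervals: the 1st..99th percentiles


@dataclass(frozen=True)
class PercentileTable:
    """Percentile-level x age grid of score thresholds for one model.

    ``thresholds`` has shape (99, n_ages); row k-1 is the raw score at the
    k-th *performance* percentile.  ``direction`` comes from the outcome
    spec and drives both smoothing and lookup.
    """

    outcome: str
    subgroup: str
    ages: np.ndarray
    thresholds: np.ndarray
    direction: str
    smoothed: bool
    n_draws: int

    def __post_init__(self):
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=int))
        object.__setattr__(
            self, "thresholds", np.asarray(self.thresholds, dtype=float)
        )
        if self.thresholds.shape != (LEVELS.size, self.ages.size):
            raise ValueError(
                f"thresholds must be (99, {self.ages.size}), "
                f"got {self.thresholds.shape}"
            )

    def column(self, age: int) -> np.ndarray:
        idx = np.flatnonzero(self.ages == int(age))
        if idx.size == 0:
            raise ValueError(
                f"age {age} not in table grid "
                f"[{self.ages.min()}, {self.ages.max()}]"
            )
        return self.thresholds[:, idx[0]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.thresholds.T, columns=[f"p{k}" for k in LEVELS]
        )
        df.insert(0, "age", self.ages)
        return df


@dataclass(frozen=True)
class PercentileResult:
    """Lookup result: mid-band percentile plus the underlying tie band."""

    percentile: int
    band_low: int
    band_high: int
    score: float
    age: int
    subgroup: str

    def __post_init__(self):
        if not self.band_low <= self.percentile <= self.band_high:
            raise ValueError("percentile must lie within its band")


def _perf_quantile_levels(direction: str) -> np.ndarray:
    """Raw-score quantile (in %) corresponding to each performance level."""
    return LEVELS if direction == "higher_better" else 100 - LEVELS


def build_percentile_table(
    fit,
    ages: Iterable[int] | None = None,
    n_draws: int = 20_000,
    seed: int = 0,
) -> PercentileTable:
    """Raw (unsmoothed) percentile table from a posterior fit.

    ``fit`` is a :class:`~cognorm.bayes_glm.NormativeGLMResults`.  For each
    age, ``n_draws`` posterior-predictive raw scores are simulated and
    their inverted-CDF quantiles become the thresholds.
    """
    spec = fit.model.spec
    ages = np.arange(18, 76) if ages is None else np.asarray(list(ages), int)
    rng = np.random.default_rng(seed)
    q = _perf_quantile_levels(spec.direction)
    thresholds = np.empty((LEVELS.size, ages.size))
    for j, age in enumerate(ages):
        draws = fit.predictive_draws(int(age), n_draws=n_draws, rng=rng)
        thresholds[:, j] = np.percentile(draws, q, method="inverted_cdf")
    return PercentileTable(
        outcome=spec.name,
        subgroup=fit.subgroup,
        ages=ages,
        thresholds=thresholds,
        direction=spec.direction,
        smoothed=False,
        n_draws=int(n_draws),
    )


def smooth_table(table: PercentileTable) -> PercentileTable:
    """Recursive-substitution smoothing across ages within each level.

    Performance is assumed not to improve with age, so within a percentile
    level the score threshold of an error measure (lower_better) may only
    rise with age (running maximum) and that of an accuracy measure
    (higher_better) may only fall (running minimum).  Values violating the
    trend are replaced by the previous age's value.  Idempotent.
    """
    if table.direction == "lower_better":
        smoothed = np.maximum.accumulate(table.thresholds, axis=1)
    else:
        smoothed = np.minimum.accumulate(table.thresholds, axis=1)
    return replace(table, thresholds=smoothed, smoothed=True)


def midband_percentile(band_low: int, band_high: int) -> int:
    """Mid-band tie rule: midpoint rounded up (88–99 -> 94)."""
    return math.ceil((band_low + band_high) / 2)


def score_to_percentile(
    score: float,
    age: int,
    table: PercentileTable,
    spec: OutcomeSpec | None = None,
) -> PercentileResult:
    """Convert a raw score at an age into a normative percentile.

    Direction-aware: the returned percentile reports goodness (higher =
    better performance).  Tied thresholds form a band of levels; the
    mid-band rule picks the reported percentile.  Scores beyond the 1st or
    99th threshold collapse to bands [1,1] / [99,99].
    """
    spec = DEFAULT_OUTCOMES.get(table.outcome) if spec is None else spec
    if spec is not None and not (
        spec.score_min <= score <= spec.score_max
    ):
        raise ValueError(
            f"score {score} outside {table.outcome} range "
            f"[{spec.score_min}, {spec.score_max}]"
        )
    col = table.column(age)
    sign = 1.0 if table.direction == "higher_better" else -1.0
    t_perf = sign * col          # non-decreasing in level
    g = sign * float(score)

    n_met = int(np.searchsorted(t_perf, g, side="right"))
    if n_met == 0:
        lo = hi = 1
    else:
        hi = n_met               # highest level whose threshold is met
        tied = t_perf == t_perf[n_met - 1]
        lo = int(np.flatnonzero(tied)[0]) + 1
        if t_perf[n_met - 1] != g:
            lo = hi              # strictly between thresholds: single level
    return PercentileResult(
        percentile=midband_percentile(lo, hi),
        band_low=lo,
        band_high=hi,
        score=float(score),
        age=int(age),
        subgroup=table.subgroup,
    )


def plot_table(table: PercentileTable, levels: Sequence[int] = (5, 25, 50, 75, 95),
               ax=None):
    """Plot selected percentile-level threshold curves against age.

    Requires matplotlib (optional dependency); returns the Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for k in levels:
        ax.plot(table.ages, table.thresholds[int(k) - 1], label=f"p{k}")
    ax.set_xlabel("age (years)")
    ax.set_ylabel(f"{table.outcome} score")
    ax.set_title(
        f"{table.outcome} / {table.subgroup}"
        + (" (smoothed)" if table.smoothed else "")
    )
    ax.legend(fontsize="small")
    return ax


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------

def export_norms(
    tables: Sequence[PercentileTable] | Mapping[str, PercentileTable],
    outdir,
    extra_metadata: Mapping | None = None,
) -> list[Path]:
    """Write one CSV (age, p1..p99) plus JSON sidecar per table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(tables, Mapping):
        tables = list(tables.values())
    written = []
    for t in tables:
        stem = f"norms_{t.outcome}_{t.subgroup}"
        csv_path = outdir / f"{stem}.csv"
        t.to_frame().to_csv(csv_path, index=False)
        meta = {
            "outcome": t.outcome,
            "subgroup": t.subgroup,
            "direction": t.direction,
            "smoothed": t.smoothed,
            "n_draws": t.n_draws,
            "ages": [int(t.ages.min()), int(t.ages.max())],
        }
        if extra_metadata:
            meta.update(extra_metadata)
        (outdir / f"{stem}.json").write_text(json.dumps(meta, indent=2))
        written.append(csv_path)
    return written


def read_norm_table(csv_path) -> PercentileTable:
    """Round-trip reader for :func:`export_norms` output."""
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    thresholds = df[[f"p{k}" for k in LEVELS]].to_numpy().T
    return PercentileTable(
        outcome=meta["outcome"],
        subgroup=meta["subgroup"],
        ages=df["age"].to_numpy(),
        thresholds=thresholds,
        direction=meta["direction"],
        smoothed=meta["smoothed"],
        n_draws=meta["n_draws"],
    )
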