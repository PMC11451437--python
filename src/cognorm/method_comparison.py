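"""Cross-sectional sensitivity analysis comparing the three norming methods.

A random subsample (default n = 200) is scored under each method
(Bayesian percentile tables, stratified z-scores, regression z-scores),
percentiles are cut into low (<25th), mid (25th–75th) and high (>75th)
ranges, and the method x category frequency tables are compared per
stratified age band with Fisher exact tests (Freeman–Halton extension for
r x c tables: complete enumeration when the table is small enough, seeded
Monte Carlo otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .classic_norms import (
    NotNormableError,
    RegressionNorms,
    StratifiedNorms,
    age_band,
    regression_percentile,
    stratified_percentile,
)
from .cohort_io import DEFAULT_OUTCOMES, OutcomeSpec
from .normative_tables import PercentileTable, score_to_percentile

__all__ = [
    "CATEGORIES",
    "ComparisonResult",
    "draw_subsample",
    "categorise",
    "fisher_exact_rc",
    "compare_methods",
    "scatter_report",
    "bayesian_percentile",
    "sensitivity_analysis",
]

log = logging.getLogger(__name__)

CATEGORIES = ("low", "mid", "high")
METHODS = ("bayesian", "stratified", "regression")


def draw_subsample(cohort: pd.DataFrame, n: int = 200,
                   seed: int = 0) -> pd.DataFrame:
    """Simple random sample of participants without replacement."""
    if n > len(cohort):
        raise ValueError(f"subsample n={n} exceeds cohort size {len(cohort)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cohort), size=n, replace=False)
    return cohort.iloc[np.sort(idx)].copy()


def categorise(percentile: int) -> str:
    """Cut a percentile into low (<25), mid (25–75) or high (>75)."""
    if not 1 <= percentile <= 99:
        raise ValueError(f"percentile must be 1..99, got {percentile}")
    if percentile < 25:
        return "low"
    if percentile <= 75:
        return "mid"
    return "high"


# --------------------------------------------------------------------------
# Fisher exact test for r x c tables (Freeman–Halton)
# --------------------------------------------------------------------------

def _log_table_prob(table, log_fact_margins, log_n_fact):
    return log_fact_margins - log_n_fact - special.gammaln(table + 1.0).sum()


def _enumerate_log_probs(row_sums, col_sums, budget):
    """Log probabilities of every table with the given margins.

    Recursive row-by-row enumeration; returns None if the table count
    exceeds ``budget`` (caller falls back to Monte Carlo).
    """
    r, c = len(row_sums), len(col_sums)
    out: list[float] = []
    lg = special.gammaln
    log_fact_margins = lg(np.asarray(row_sums) + 1.0).sum() + lg(
        np.asarray(col_sums) + 1.0
    ).sum()
    log_n_fact = lg(sum(row_sums) + 1.0)

    def fill_row(i, cols_left, acc_cells):
        if len(out) > budget:
            raise OverflowError
        if i == r - 1:
            # last row is forced by the column margins
            cells = acc_cells + list(cols_left)
            out.append(
                log_fact_margins
                - log_n_fact
                - lg(np.asarray(cells, dtype=float) + 1.0).sum()
            )
            return
        target = row_sums[i]

        def fill_cell(j, remaining, row_acc):
            if j == c - 1:
                if remaining <= cols_left[c - 1]:
                    new_cols = tuple(
                        cols_left[k] - (row_acc + (remaining,))[k]
                        for k in range(c)
                    )
                    fill_row(i + 1, new_cols, acc_cells + list(row_acc) +
                             [remaining])
                return
            for v in range(min(remaining, cols_left[j]) + 1):
                fill_cell(j + 1, remaining - v, row_acc + (v,))

        fill_cell(0, target, ())

    try:
        fill_row(0, tuple(col_sums), [])
    except OverflowError:
        return None
    return np.asarray(out)


def fisher_exact_rc(
    table,
    budget: int = 200_000,
    n_mc: int = 100_000,
    seed: int = 0,
) -> dict:
    """Freeman–Halton Fisher exact p for an r x c contingency table.

    All-zero rows/columns are collapsed first (logged).  Exact complete
    enumeration is used while the number of candidate tables stays within
    ``budget``; otherwise a seeded Monte Carlo estimate over ``n_mc``
    tables drawn uniformly from the fixed-margin distribution.  Returns a
    dict with ``p``, ``method`` ("exact"/"monte_carlo") and the collapsed
    table.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("table must be a non-negative 2-D array")
    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        log.info("fisher_exact_rc: collapsing all-zero margins")
        table = table[keep_r][:, keep_c]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return {"p": 1.0, "method": "degenerate", "table": table}

    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    lg = special.gammaln
    log_fact_margins = lg(row_sums + 1.0).sum() + lg(col_sums + 1.0).sum()
    log_n_fact = lg(table.sum() + 1.0)
    log_p_obs = _log_table_prob(table.astype(float), log_fact_margins,
                                log_n_fact)
    tol = 1e-9 * abs(log_p_obs) + 1e-12

    log_probs = _enumerate_log_probs(row_sums.tolist(), col_sums.tolist(),
                                     budget)
    if log_probs is not None:
        mask = log_probs <= log_p_obs + tol
        p = float(np.exp(special.logsumexp(log_probs[mask])))
        return {"p": min(p, 1.0), "method": "exact", "table": table}

    rng = np.random.default_rng(seed)
    sampler = stats.random_table(row_sums, col_sums)
    draws = sampler.rvs(n_mc, method="patefield", random_state=rng)
    log_probs = (
        log_fact_margins
        - log_n_fact
        - special.gammaln(draws + 1.0).sum(axis=(1, 2))
    )
    hits = int(np.sum(log_probs <= log_p_obs + tol))
    p = (hits + 1.0) / (n_mc + 1.0)
    return {"p": float(p), "method": "monte_carlo", "table": table}


# --------------------------------------------------------------------------
# method comparison
# --------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Method x category contingency comparison within one age band."""

    outcome: str
    age_band: str
    contingency: pd.DataFrame      # methods x categories counts
    fisher_p: float
    fisher_method: str
    n_subsample: int


def compare_methods(
    percentiles_by_method: Mapping[str, Sequence[int]],
    outcome: str,
    band: str = "all",
    budget: int = 200_000,
    n_mc: int = 100_000,
    seed: int = 0,
) -> ComparisonResult:
    """Build the method x category table and its Fisher exact p-value.

    All methods must have scored the same participants (equal lengths).
    """
    lengths = {m: len(v) for m, v in percentiles_by_method.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"methods scored different participant sets: {lengths}")
    n = next(iter(lengths.values()))
    counts = {}
    for m, pcts in percentiles_by_method.items():
        cats = [categorise(int(p)) for p in pcts]
        counts[m] = [cats.count(c) for c in CATEGORIES]
    contingency = pd.DataFrame(counts, index=list(CATEGORIES)).T
    res = fisher_exact_rc(contingency.to_numpy(), budget=budget,
                          n_mc=n_mc, seed=seed)
    return ComparisonResult(
        outcome=outcome,
        age_band=band,
        contingency=contingency,
        fisher_p=res["p"],
        fisher_method=res["method"],
        n_subsample=n,
    )


def scatter_report(
    percentiles_a: Sequence[float],
    percentiles_b: Sequence[float],
    label_a: str = "A",
    label_b: str = "B",
) -> tuple[pd.DataFrame, float]:
    """Paired percentile table plus Spearman rank correlation."""
    a = np.asarray(percentiles_a, dtype=float)
    b = np.asarray(percentiles_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired percentile vectors differ in length")
    pairs = pd.DataFrame({label_a: a, label_b: b})
    rho = float(stats.spearmanr(a, b).statistic)
    return pairs, rho


def bayesian_percentile(
    record,
    tables: Mapping[str, PercentileTable],
    spec: OutcomeSpec,
) -> int:
    """Score one participant against the most specific available table.

    Preference order: sex x education subgroup, then sex, then all.
    """
    keys = (
        f"{record['sex']}_{record['education_band']}",
        str(record["sex"]),
        "all",
    )
    for key in keys:
        if key in tables:
            return score_to_percentile(
                float(record[spec.name]), int(record["age"]), tables[key], spec
            ).percentile
    raise KeyError(f"no percentile table available for {keys}")


def sensitivity_analysis(
    cohort: pd.DataFrame,
    spec: OutcomeSpec | str,
    bayes_tables: Mapping[str, PercentileTable],
    strat_norms: StratifiedNorms,
    reg_norms: RegressionNorms,
    n: int = 200,
    seed: int = 0,
    fisher_seed: int = 1,
) -> tuple[pd.DataFrame, list[ComparisonResult]]:
    """Full cross-sectional comparison for one outcome.

    Draws the subsample, scores it under all three methods, and runs the
    per-age-band Fisher comparisons (bands as in the stratified method).
    Participants not normable under the stratified method (degenerate
    stratum) are dropped from the comparison, keeping the paired design.

    Returns the per-participant percentile table and the per-band results.
    """
    spec = DEFAULT_OUTCOMES[spec] if isinstance(spec, str) else spec
    sub = draw_subsample(cohort.dropna(subset=[spec.name]), n=n, seed=seed)
    rows = []
    for _, rec in sub.iterrows():
        try:
            p_strat = stratified_percentile(rec, strat_norms, spec)
            p_bayes = bayesian_percentile(rec, bayes_tables, spec)
        except NotNormableError:
            continue
        except ValueError as exc:
            if "not in table grid" in str(exc):   # no extrapolation
                continue
            raise
        rows.append(
            {
                "id": rec.get("id", ""),
                "age": int(rec["age"]),
                "age_band": age_band(int(rec["age"])),
                "score": float(rec[spec.name]),
                "bayesian": p_bayes,
                "stratified": p_strat,
                "regression": regression_percentile(rec, reg_norms, spec),
            }
        )
    pairs = pd.DataFrame(rows)
    results = []
    for band, grp in pairs.groupby("age_band"):
        results.append(
            compare_methods(
                {m: grp[m].tolist() for m in METHODS},
                outcome=spec.name,
                band=str(band),
                seed=fisher_seed,
            )
        )
    return pairs, results
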