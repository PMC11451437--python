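"""End-to-end pipeline: simulate -> fit -> norms -> baselines -> compare.

Driven by a single YAML config with per-stage sections; all randomness
derives from one master seed via named substreams, and every stage writes
its outputs plus a manifest entry (content hash, timing, record counts).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes_glm import SUBGROUPS, age_effect_table, fit_all_subgroups
from .classic_norms import fit_regression, fit_stratified
from .cohort_io import DEFAULT_OUTCOMES, cohort_to_frame, encode_design
from .method_comparison import sensitivity_analysis
from .normative_tables import build_percentile_table, export_norms, smooth_table
from .sampler import ConvergenceError, SamplerConfig
from .synthetic_cohort import (
    DEFAULT_TRUE_EFFECTS,
    GeneratorConfig,
    generate_cohort,
)

log = logging.getLogger(__name__)

__all__ = ["RunManifest", "ConfigError", "run_pipeline", "substream_seed"]


class ConfigError(ValueError):
    """Pipeline configuration violates the schema; message names the field."""


def substream_seed(master: int, name: str) -> int:
    """Deterministic named substream seed below 2**31."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str = ""
    config_hash: str = ""
    master_seed: int = 0
    seeds: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)      # path -> sha256
    failure: dict | None = None

    def record_output(self, path: Path) -> None:
        self.outputs[str(path)] = _sha256(Path(path))

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "version": self.version,
                "config_hash": self.config_hash,
                "master_seed": self.master_seed,
                "seeds": self.seeds,
                "stages": self.stages,
                "outputs": self.outputs,
                "failure": self.failure,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


_KNOWN_FAMILIES = ("beta", "zoib", "hurdle_nb")


def _validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ConfigError("config: top level must be a mapping")
    out = dict(cfg)
    out.setdefault("seed", 0)
    out.setdefault("outdir", "cognorm_run")
    sim = dict(out.get("simulate", {}))
    sim.setdefault("n", 728)
    outcomes = sim.get("outcomes", list(DEFAULT_TRUE_EFFECTS))
    for name in outcomes:
        if name not in DEFAULT_OUTCOMES:
            raise ConfigError(f"simulate.outcomes: unknown outcome {name!r}")
    sim["outcomes"] = outcomes
    out["simulate"] = sim

    fit = dict(out.get("fit", {}))
    fams = fit.get("families", {})
    for name, fam in fams.items():
        if fam not in _KNOWN_FAMILIES:
            raise ConfigError(
                f"fit.families.{name}: unknown family {fam!r} "
                f"(expected one of {_KNOWN_FAMILIES})"
            )
    sampler = dict(fit.get("sampler", {}))
    try:
        fit["sampler_config"] = SamplerConfig(**sampler)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"fit.sampler: {exc}")
    fit.setdefault("subgroups", list(SUBGROUPS))
    for sg in fit["subgroups"]:
        if sg not in SUBGROUPS:
            raise ConfigError(f"fit.subgroups: unknown subgroup {sg!r}")
    out["fit"] = fit

    norms = dict(out.get("norms", {}))
    norms.setdefault("ages", [18, 75])
    norms.setdefault("n_draws", 20_000)
    norms.setdefault("smooth", True)
    out["norms"] = norms

    out.setdefault("baselines", {})
    cmp_cfg = dict(out.get("compare", {}))
    cmp_cfg.setdefault("n", 200)
    out["compare"] = cmp_cfg
    return out


def run_pipeline(config) -> RunManifest:
    """Run all stages; returns the manifest (also written to the outdir).

    ``config`` is a YAML path or an already-loaded mapping.  On a stage
    failure, earlier stages' outputs remain on disk and the manifest
    carries a failure record for the failing stage.
    """
    if isinstance(config, (str, Path)):
        raw = yaml.safe_load(Path(config).read_text())
    else:
        raw = config
    cfg = _validate_config(raw or {})
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    manifest = RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(
            json.dumps(raw, sort_keys=True, default=str).encode()
        ).hexdigest(),
        master_seed=master,
        seeds={
            name: substream_seed(master, name)
            for name in ("generator", "sampler", "norms", "subsample", "fisher")
        },
    )

    try:
        _run_stages(cfg, outdir, manifest)
    except (ValueError, ConvergenceError, OSError) as exc:
        manifest.failure = {
            "stage": manifest.stages.get("_current", "unknown"),
            "error": str(exc),
        }
        log.error("pipeline failed: %s", exc)
    finally:
        manifest.stages.pop("_current", None)
        manifest.to_json(outdir / "manifest.json")
    return manifest


def _stage(manifest, name):
    manifest.stages["_current"] = name
    return time.perf_counter()


def _stage_done(manifest, name, t0, **counts):
    manifest.stages[name] = {
        "seconds": round(time.perf_counter() - t0, 3),
        **counts,
    }
    log.info("stage %s done: %s", name, counts)


def _run_stages(cfg: dict, outdir: Path, manifest: RunManifest) -> None:
    # ---- simulate ----------------------------------------------------------
    t0 = _stage(manifest, "simulate")
    sim = cfg["simulate"]
    effects = {k: DEFAULT_TRUE_EFFECTS[k] for k in sim["outcomes"]}
    gen_cfg = GeneratorConfig(
        n=int(sim["n"]), effects=effects, seed=manifest.seeds["generator"]
    )
    records = generate_cohort(gen_cfg)
    cohort_path = outdir / "cohort.csv"
    cohort_to_frame(records).to_csv(cohort_path, index=False)
    (outdir / "cohort.meta.json").write_text(
        json.dumps(
            {"n": gen_cfg.n, "seed": gen_cfg.seed,
             "outcomes": sim["outcomes"], "age_range": [gen_cfg.age_min,
                                                        gen_cfg.age_max]},
            indent=2,
        )
    )
    manifest.record_output(cohort_path)
    df = encode_design(cohort_to_frame(records))
    _stage_done(manifest, "simulate", t0, n_records=len(records))

    # ---- fit ---------------------------------------------------------------
    t0 = _stage(manifest, "fit")
    fit_cfg = cfg["fit"]
    sampler = fit_cfg["sampler_config"]
    sampler = SamplerConfig(
        chains=sampler.chains,
        warmup_iters=sampler.warmup_iters,
        sampling_iters=sampler.sampling_iters,
        seed=manifest.seeds["sampler"],
        algorithm=sampler.algorithm,
        rhat_max=sampler.rhat_max,
    )
    all_fits: dict[str, dict] = {}
    n_fitted = 0
    for name in sim["outcomes"]:
        family = fit_cfg.get("families", {}).get(name)
        fits, errors = fit_all_subgroups(
            df, name, family=family, sampler=sampler,
            subgroups=fit_cfg["subgroups"],
        )
        for sg, res in fits.items():
            csv_path, json_path = res.save(outdir / f"fit_{name}_{sg}")
            manifest.record_output(csv_path)
            manifest.record_output(json_path)
            n_fitted += 1
        for sg, msg in errors.items():
            log.warning("fit %s/%s failed: %s", name, sg, msg)
        all_fits[name] = fits
        table = age_effect_table(fits)
        table_path = outdir / f"age_effects_{name}.csv"
        table.to_csv(table_path, index=False)
        manifest.record_output(table_path)
    _stage_done(manifest, "fit", t0, n_fits=n_fitted)

    # ---- norms -------------------------------------------------------------
    t0 = _stage(manifest, "norms")
    norms_cfg = cfg["norms"]
    lo, hi = norms_cfg["ages"]
    ages = range(int(lo), int(hi) + 1)
    tables_by_outcome: dict[str, dict] = {}
    norm_dir = outdir / "norms"
    n_tables = 0
    for name, fits in all_fits.items():
        tables = {}
        for sg, res in fits.items():
            tab = build_percentile_table(
                res, ages=ages, n_draws=int(norms_cfg["n_draws"]),
                seed=manifest.seeds["norms"],
            )
            if norms_cfg["smooth"]:
                tab = smooth_table(tab)
            tables[sg] = tab
            n_tables += 1
        tables_by_outcome[name] = tables
        for p in export_norms(tables, norm_dir):
            manifest.record_output(p)
    _stage_done(manifest, "norms", t0, n_tables=n_tables)

    # ---- baselines ---------------------------------------------------------
    t0 = _stage(manifest, "baselines")
    strat_by_outcome, reg_by_outcome = {}, {}
    for name in sim["outcomes"]:
        strat = fit_stratified(df, name)
        reg = fit_regression(
            df, name, cfg["baselines"].get("cooks_threshold")
        )
        strat_by_outcome[name] = strat
        reg_by_outcome[name] = reg
        sp = outdir / f"stratified_{name}.csv"
        strat.to_frame().to_csv(sp, index=False)
        manifest.record_output(sp)
        rp = outdir / f"regression_{name}.json"
        rp.write_text(
            json.dumps(
                {
                    "outcome": reg.outcome,
                    "intercept": reg.intercept,
                    "beta_age": reg.beta_age,
                    "beta_sex": reg.beta_sex,
                    "beta_edu": reg.beta_edu,
                    "residual_sd": reg.residual_sd,
                    "removed_ids": reg.removed_ids,
                    "cooks_threshold": reg.cooks_threshold,
                    "n_used": reg.n_used,
                },
                indent=2,
            )
        )
        manifest.record_output(rp)
    _stage_done(manifest, "baselines", t0, n_outcomes=len(sim["outcomes"]))

    # ---- compare -----------------------------------------------------------
    t0 = _stage(manifest, "compare")
    cmp_cfg = cfg["compare"]
    p_rows = []
    for name in sim["outcomes"]:
        pairs, results = sensitivity_analysis(
            df,
            name,
            tables_by_outcome[name],
            strat_by_outcome[name],
            reg_by_outcome[name],
            n=int(cmp_cfg["n"]),
            seed=manifest.seeds["subsample"],
            fisher_seed=manifest.seeds["fisher"],
        )
        pp = outdir / f"compare_pairs_{name}.csv"
        pairs.to_csv(pp, index=False)
        manifest.record_output(pp)
        for r in results:
            p_rows.append(
                {"outcome": r.outcome, "age_band": r.age_band,
                 "fisher_p": r.fisher_p, "method": r.fisher_method,
                 "n": r.n_subsample}
            )
    ptab = outdir / "compare_fisher.csv"
    pd.DataFrame(p_rows).to_csv(ptab, index=False)
    manifest.record_output(ptab)
    _stage_done(manifest, "compare", t0, n_tests=len(p_rows))
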