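"""Reproducible end-to-end runs: config in, result tables + manifest out.

A single YAML (or dict) config drives generate/ingest -> batch adjustment
-> ICC estimation by all three routes -> cage-permutation test -> optional
power grid and sample-size table.  Every random stage draws from an
explicit seed recorded in the manifest, so the same config + seed yields
byte-identical result CSVs.  The manifest accounts for every dropped row
(censored, nonpositive-adjusted) and every outlier flagged during batch
fitting.
"""

from __future__ import annotations

import json
import time
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import batch as _batch
from . import icc as _icc
from . import power as _power
from . import samplesize as _samplesize
from . import synthetic as _synthetic

__all__ = ["run_pipeline", "summarize_icc_table", "load_config"]

_TOP_KEYS = {"seed", "out_dir", "cohort", "batch_adjust", "icc",
             "permutation", "power_grid", "sample_size"}
_COHORT_KEYS = {"generate", "input_csv"}
_GEN_KEYS = {"n_cages_per_arm", "cluster_size", "n_arms", "icc",
             "marginal_mean", "marginal_sd", "effect", "marginal_family",
             "censor_rate"}
REQUIRED_COHORT_COLUMNS = ("animal_id", "cage_id", "lifespan_months")


def _package_version() -> str:
    try:
        return _pkg_version("cagecorr")
    except PackageNotFoundError:
        return "unknown"


def load_config(path_or_dict) -> dict:
    """Load and validate a pipeline config (YAML path or dict)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_dict)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; "
                         f"allowed: {sorted(_TOP_KEYS)}")
    if "cohort" not in cfg:
        raise ValueError("config needs a 'cohort' section")
    bad = set(cfg["cohort"]) - _COHORT_KEYS
    if bad:
        raise ValueError(f"unknown cohort keys: {sorted(bad)}")
    if "generate" in cfg["cohort"]:
        bad = set(cfg["cohort"]["generate"]) - _GEN_KEYS
        if bad:
            raise ValueError(f"unknown cohort.generate keys: {sorted(bad)}")
    return cfg


def _format_est(est: _icc.ICCEstimate) -> str:
    if np.isfinite(est.ci_low) and np.isfinite(est.ci_high):
        return f"{est.estimate:.3f} ({est.ci_low:.3f}, {est.ci_high:.3f})"
    return f"{est.estimate:.3f} (NA, NA)"


def summarize_icc_table(estimates) -> pd.DataFrame:
    """Wide table of "est (lo, hi)" strings, one column per method.

    ``estimates`` is either a list of :class:`~cagecorr.icc.ICCEstimate`
    (a single stratum labelled "all") or a mapping stratum -> list.
    Empty strata are omitted.
    """
    if isinstance(estimates, dict):
        items = estimates.items()
    else:
        items = [("all", list(estimates))]
    rows = {}
    for stratum, ests in items:
        if not ests:
            continue
        rows[stratum] = {e.method: _format_est(e) for e in ests}
    if not rows:
        raise ValueError("no estimates to summarize")
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "stratum"
    return out.reset_index()


def run_pipeline(config, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and write result CSVs + manifest.

    Returns the manifest dict.  Raises on schema violations, missing
    columns, or any stage error (CLI maps this to a nonzero exit).
    """
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "cagecorr_results"))
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {"config": cfg, "seed": seed,
                      "package_version": _package_version(),
                      "stages": {}, "started_unix": t0}

    # ---- stage 1: cohort ------------------------------------------------
    co_cfg = cfg["cohort"]
    if "generate" in co_cfg:
        g = co_cfg["generate"]
        structure = _synthetic.make_cage_structure(
            n_cages_per_arm=int(g.get("n_cages_per_arm", 100)),
            cluster_size=g.get("cluster_size", 4),
            n_arms=int(g.get("n_arms", 2)), seed=seed)
        gen_cfg = _synthetic.GeneratorConfig(
            icc=float(g.get("icc", 0.05)),
            marginal_mean=float(g.get("marginal_mean", 30.0)),
            marginal_sd=float(g.get("marginal_sd", 4.7)),
            effect=float(g.get("effect", 0.0)),
            marginal_family=g.get("marginal_family", "gaussian"),
            censor_rate=float(g.get("censor_rate", 0.0)),
            seed=seed)
        cohort = _synthetic.sample_exchangeable_outcomes(structure, gen_cfg)
    else:
        cohort = pd.read_csv(co_cfg["input_csv"])
        missing = [c for c in REQUIRED_COHORT_COLUMNS
                   if c not in cohort.columns]
        if missing:
            raise ValueError(f"input cohort missing columns: {missing}")
        if "censored" not in cohort.columns:
            cohort["censored"] = False
    cohort.to_csv(out / "cohort.csv", index=False)
    manifest["stages"]["cohort"] = {"rows_read": len(cohort)}

    # ---- stage 2: batch adjustment --------------------------------------
    ba_cfg = cfg.get("batch_adjust")
    if ba_cfg:
        spec = _batch.BatchModelSpec(
            batch_term=ba_cfg.get("batch_term", "batch"),
            fixed_terms=tuple(ba_cfg.get("fixed_terms", ())))
        adjusted = _batch.remove_batch_effects(cohort, spec)
        report = adjusted.attrs["batch_report"]
        with open(out / "batch_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        manifest["stages"]["batch_adjust"] = {
            "rows_in": report["n_rows_in"],
            "rows_out": report["n_rows_out"],
            "dropped_nonpositive": report["n_dropped_nonpositive"],
            "outliers_flagged": report["n_outliers_trimmed"]}
        cohort = adjusted
        cohort.to_csv(out / "adjusted_cohort.csv", index=False)

    # ---- stage 3: ICC estimation ----------------------------------------
    icc_cfg = cfg.get("icc", {})
    methods = icc_cfg.get("methods", ["anova", "lmm", "gee"])
    fixed = tuple(icc_cfg.get("fixed_terms", ()))
    B = int(icc_cfg.get("bootstrap_B", 500))
    n_cens = int(cohort["censored"].astype(bool).sum()) \
        if "censored" in cohort.columns else 0
    estimates = []
    if "anova" in methods:
        estimates.append(_icc.anova_icc(cohort, residualize_on=fixed))
    if "lmm" in methods:
        vc = _icc.reml_random_intercept(cohort, fixed_terms=fixed)
        estimates.append(_icc.lmm_icc(vc, B=B, seed=seed))
    if "gee" in methods:
        estimates.append(_icc.gee_exchangeable(cohort, fixed_terms=fixed,
                                               B=B, seed=seed))
    est_rows = [{"method": e.method, "estimate": e.estimate,
                 "ci_low": e.ci_low, "ci_high": e.ci_high,
                 "ci_method": e.ci_method, "n_clusters": e.n_clusters,
                 "mean_cluster_size": e.mean_cluster_size}
                for e in estimates]
    pd.DataFrame(est_rows).to_csv(out / "icc_estimates.csv", index=False)
    summarize_icc_table(estimates).to_csv(out / "icc_table.csv", index=False)
    manifest["stages"]["icc"] = {
        "rows_in": len(cohort), "dropped_censored": n_cens,
        "rows_used": len(cohort) - n_cens,
        "estimates": est_rows}

    # ---- stage 4: permutation test --------------------------------------
    perm_cfg = cfg.get("permutation")
    if perm_cfg:
        res = _icc.permutation_icc_test(
            cohort, estimator=perm_cfg.get("estimator", "anova"),
            n_perm=int(perm_cfg.get("n_perm", 1000)), seed=seed)
        perm_out = {"observed_icc": res.observed_icc, "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                    "estimator": res.estimator,
                    "alternative": res.alternative, "seed": seed}
        with open(out / "permutation.json", "w") as fh:
            json.dump(perm_out, fh, indent=2)
        manifest["stages"]["permutation"] = perm_out

    # ---- stage 5: optional power grid -----------------------------------
    pg_cfg = cfg.get("power_grid")
    if pg_cfg:
        scenarios = [
            _power.TrialScenario(
                n_per_group=int(pg_cfg.get("n_per_group", 100)),
                cluster_size=int(pg_cfg.get("cluster_size", 4)),
                icc=float(icc_val),
                effect_frac=float(pg_cfg.get("effect_frac", 0.0)),
                n_reps=int(pg_cfg.get("n_reps", 1000)),
                seed=seed + i)
            for i, icc_val in enumerate(pg_cfg.get("iccs", [0.0, 0.05, 0.1]))]
        grid = _power.run_power_grid(
            scenarios, methods=tuple(pg_cfg.get("methods", ("LM", "LMM", "GEE"))))
        grid.to_csv(out / "power_results.csv", index=False)
        manifest["stages"]["power_grid"] = {"n_scenarios": len(scenarios)}

    # ---- stage 6: optional sample-size table -----------------------------
    ss_cfg = cfg.get("sample_size")
    if ss_cfg:
        if "strata_csv" in ss_cfg:
            strata = pd.read_csv(ss_cfg["strata_csv"])
        else:
            strata = pd.DataFrame(ss_cfg.get(
                "strata", [{"stratum": "database", "mean": 912.0, "sd": 143.0}]))
        table = _samplesize.sample_size_grid(
            strata,
            icc_list=ss_cfg.get("icc_list", (0.0, 0.01, 0.05, 0.1)),
            k_list=ss_cfg.get("k_list", (4, 6, 8)),
            effect_frac=float(ss_cfg.get("effect_frac", 0.10)),
            alpha=float(ss_cfg.get("alpha", 0.05)),
            power=float(ss_cfg.get("power", 0.80)))
        table.to_csv(out / "sample_size_grid.csv", index=False)
        manifest["stages"]["sample_size"] = {"n_rows": len(table)}

    manifest["elapsed_seconds"] = time.time() - t0
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
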