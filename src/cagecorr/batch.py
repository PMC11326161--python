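"""Pre-analysis batch-effect removal for clustered lifespan cohorts.

Multi-cohort lifespan databases carry additive shifts from the design
factors that batch animals in time (group, cohort, generation).  Before
any intra-cage correlation analysis these shifts are estimated — on data
with far outliers excluded from the fitting subset, conditioning on the
study covariates and a cage random intercept — and subtracted from the raw
outcome.  Batch coefficients are sum-to-zero coded, so the adjustment is a
per-batch constant with zero grand effect: within-batch rank order and the
overall location of the outcome are preserved.

Adjusted lifespans that come out nonpositive are dropped (and counted),
since a nonpositive lifespan is meaningless downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._design import build_design, find_aliased
from .icc import DEFAULT_CLUSTER, DEFAULT_OUTCOME, _cluster_codes, _reml_fit

__all__ = ["BatchModelSpec", "days_to_months", "flag_far_outliers",
           "remove_batch_effects", "DAYS_PER_MONTH"]

#: conversion constant used for murine lifespan databases
DAYS_PER_MONTH = 30.4


def days_to_months(days):
    """Convert lifespan in days to months (days / 30.4)."""
    return np.asarray(days, dtype=float) / DAYS_PER_MONTH if np.ndim(days) \
        else float(days) / DAYS_PER_MONTH


@dataclass(frozen=True)
class BatchModelSpec:
    """Model specification for batch-effect estimation.

    ``fixed_terms`` are the study covariates (sex, diet, strain, ...);
    ``batch_term`` names the batching factor; ``cluster_term`` the cage id
    column carrying the random intercept.
    """

    batch_term: str = "batch"
    fixed_terms: tuple = ()
    cluster_term: str = DEFAULT_CLUSTER
    outcome: str = DEFAULT_OUTCOME

    def __post_init__(self):
        if self.batch_term == self.cluster_term:
            raise ValueError("batch_term and cluster_term must differ")
        if self.batch_term in self.fixed_terms:
            raise ValueError("batch_term must not repeat in fixed_terms")


def flag_far_outliers(values) -> np.ndarray:
    """Boolean mask of values strictly beyond median +/- 3*IQR.

    A deliberately wide fence: only far outliers are excluded from the
    batch-model fitting subset, to avoid over-adjusting for extremes.
    Constant input (IQR = 0, nothing beyond the fence) flags nothing.
    """
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size < 4:
        raise ValueError("need at least 4 finite values to define the fence")
    med = np.median(finite)
    q1, q3 = np.percentile(finite, [25, 75])
    iqr = q3 - q1
    lo, hi = med - 3.0 * iqr, med + 3.0 * iqr
    mask = np.zeros(v.shape, dtype=bool)
    ok = np.isfinite(v)
    mask[ok] = (v[ok] < lo) | (v[ok] > hi)
    return mask


def remove_batch_effects(cohort: pd.DataFrame,
                         spec: BatchModelSpec) -> pd.DataFrame:
    """Subtract estimated batch shifts from the outcome.

    The batch model (outcome ~ fixed_terms + batch + (1|cage), batch
    sum-coded) is fit by REML on the outlier-trimmed subset; every row is
    then adjusted by its batch's centered coefficient.  Rows whose
    adjusted outcome is <= 0 are dropped.  A report with the coefficients
    and per-rule row counts is attached as ``df.attrs["batch_report"]``.

    Single-batch input is returned unchanged (identity adjustment).
    """
    for col in (spec.outcome, spec.batch_term, spec.cluster_term):
        if col not in cohort.columns:
            raise KeyError(f"column {col!r} not in cohort")
    out = cohort.copy()
    levels = pd.unique(out[spec.batch_term])
    if len(levels) < 2:
        out.attrs["batch_report"] = {
            "batch_coefficients": {str(levels[0]): 0.0} if len(levels) else {},
            "n_outliers_trimmed": 0, "n_dropped_nonpositive": 0,
            "n_rows_in": len(out), "n_rows_out": len(out)}
        return out

    y_all = out[spec.outcome].to_numpy(dtype=float)
    trim = flag_far_outliers(y_all)
    fit_df = out.loc[~trim]

    terms = list(spec.fixed_terms)
    X_fix, names_fix, _ = build_design(fit_df, terms)
    X_bat, names_bat, _ = build_design(fit_df, [spec.batch_term], coding="sum")
    X = np.column_stack([X_fix, X_bat[:, 1:]])     # drop duplicate intercept
    names = names_fix + names_bat[1:]
    aliased = find_aliased(X, names)
    if aliased:
        raise ValueError(
            "batch model design is singular (batch confounded with "
            f"covariates); aliased columns: {aliased}")

    codes, m = _cluster_codes(fit_df, spec.cluster_term)
    y = fit_df[spec.outcome].to_numpy(dtype=float)
    lam, s2e, beta, cov, ll, boundary = _reml_fit(y, X, codes, m)

    # reconstruct the per-level batch effect from the sum-coded columns;
    # the implied last-level coefficient is minus the sum of the others
    bat_levels = sorted(pd.unique(out[spec.batch_term]), key=str)
    coef = dict(zip(names, beta))
    eff = {}
    running = 0.0
    for lv in bat_levels[:-1]:
        c = coef[f"{spec.batch_term}[S.{lv}]"]
        eff[lv] = c
        running += c
    eff[bat_levels[-1]] = -running
    # sum-coded effects already average to zero across levels
    center = np.mean(list(eff.values()))
    eff = {lv: float(v - center) for lv, v in eff.items()}

    shift = out[spec.batch_term].map(eff).to_numpy(dtype=float)
    adjusted = y_all - shift
    keep = adjusted > 0
    n_dropped = int((~keep).sum())
    out[spec.outcome] = adjusted
    out = out.loc[keep]
    out.attrs["batch_report"] = {
        "batch_coefficients": {str(k): v for k, v in eff.items()},
        "fixed_effects": {n: float(b) for n, b in zip(names, beta)},
        "sigma2_between": float(lam * s2e),
        "sigma2_within": float(s2e),
        "n_outliers_trimmed": int(trim.sum()),
        "n_dropped_nonpositive": n_dropped,
        "n_rows_in": len(cohort),
        "n_rows_out": len(out),
    }
    return out
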