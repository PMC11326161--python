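"""Intra-cage correlation estimation for clustered murine aging data.

Implements the three complementary routes to the intra-class correlation
(ICC) of co-housed animals and the inference machinery around them:

* one-way ANOVA moment estimator (admits negative values, closed form);
* random-intercept linear mixed model fit by REML with the variance ratio
  profiled in closed form per cluster block (estimate truncated at zero —
  the documented LMM bias under negative ICC);
* exchangeable working-correlation GEE-style moment iteration (marginal,
  admits negative working correlation, robust sandwich covariance);
* parametric-bootstrap and cluster-bootstrap confidence intervals;
* cage-permutation significance test (animals shuffled across cages within
  randomization strata, cage sizes preserved);
* two-level (cage + animal) REML for longitudinal phenotypes with the
  proportion-of-variance ICC;
* joint Wald F tests for fixed effects with and without the cage random
  intercept, to expose anti-conservative inference when co-housing is
  ignored.

Clusters are cages throughout, but nothing restricts the code to mice:
any exchangeably clustered continuous outcome fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar

from ._design import build_design, find_aliased
from .synthetic import icc_lower_bound, substream

__all__ = [
    "VarianceComponents",
    "ICCEstimate",
    "PermutationResult",
    "anova_icc",
    "reml_random_intercept",
    "lmm_icc",
    "parametric_bootstrap_ci",
    "gee_exchangeable",
    "permutation_icc_test",
    "two_level_reml",
    "proportion_of_variance_icc",
    "joint_fixed_effect_test",
]

DEFAULT_OUTCOME = "lifespan_months"
DEFAULT_CLUSTER = "cage_id"


# ---------------------------------------------------------------------------
# result containers


@dataclass
class VarianceComponents:
    """REML variance components and GLS fixed effects.

    ``sigma2_between`` is the cage-level variance (truncated at zero by the
    REML parameterization), ``sigma2_within`` the residual variance, and
    ``sigma2_animal`` the animal-level variance in the two-level model
    (None for single-level fits).  ``reml_loglik`` is the restricted
    log-likelihood including all constants, so it is directly comparable
    to a dense-matrix evaluation.
    """

    sigma2_between: float
    sigma2_within: float
    fixed_effects: pd.Series
    reml_loglik: float
    sigma2_animal: float | None = None
    n_obs: int = 0
    n_clusters: int = 0
    boundary: bool = False
    cov_fixed: np.ndarray | None = field(default=None, repr=False)
    # fit internals kept for bootstrap resimulation / Wald tests
    _y: np.ndarray | None = field(default=None, repr=False)
    _X: np.ndarray | None = field(default=None, repr=False)
    _codes: np.ndarray | None = field(default=None, repr=False)
    _spans: dict | None = field(default=None, repr=False)

    @property
    def icc(self) -> float:
        tot = self.sigma2_between + self.sigma2_within + (self.sigma2_animal or 0.0)
        return self.sigma2_between / tot if tot > 0 else 0.0


@dataclass
class ICCEstimate:
    """Point estimate of the intra-cage correlation with optional CI."""

    method: str
    estimate: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    ci_method: str = "none"
    n_clusters: int = 0
    mean_cluster_size: float = 0.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method in ("lmm_reml", "two_level_lmm") and self.estimate < 0:
            raise ValueError(f"{self.method} ICC cannot be negative")
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if not (self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12):
                raise ValueError("estimate must lie inside its CI")


@dataclass
class PermutationResult:
    """Cage-permutation null for the ICC statistic."""

    observed_icc: float
    null_draws: np.ndarray
    p_value: float
    n_permutations: int
    seed: int | None
    estimator: str = "anova"
    alternative: str = "greater"


# ---------------------------------------------------------------------------
# data plumbing


def _prepare(cohort: pd.DataFrame, outcome: str, cluster: str,
             drop_censored: bool = True) -> pd.DataFrame:
    for col in (outcome, cluster):
        if col not in cohort.columns:
            raise KeyError(f"column {col!r} not in cohort")
    df = cohort
    if drop_censored and "censored" in df.columns:
        df = df.loc[~df["censored"].astype(bool)]
    if df[cluster].isna().any():
        raise ValueError("orphan animals: missing cluster id")
    return df


def _cluster_codes(df: pd.DataFrame, cluster: str):
    codes, uniques = pd.factorize(df[cluster], sort=False)
    return codes.astype(np.intp), len(uniques)


# ---------------------------------------------------------------------------
# ANOVA moment estimator


def anova_icc(cohort: pd.DataFrame, residualize_on: Sequence[str] = (),
              outcome: str = DEFAULT_OUTCOME,
              cluster: str = DEFAULT_CLUSTER) -> ICCEstimate:
    """One-way ANOVA ICC, unbalanced-aware, may be negative.

    Covariates in ``residualize_on`` are regressed out by OLS first; the
    mean squares use the unbalanced cluster-size correction
    k0 = (N - sum(k_i^2)/N) / (m - 1).
    """
    df = _prepare(cohort, outcome, cluster)
    y = df[outcome].to_numpy(dtype=float)
    if residualize_on:
        X, _, _ = build_design(df, residualize_on)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        y = y - X @ beta
    codes, m = _cluster_codes(df, cluster)
    icc, msb, msw, k0 = _anova_icc_from_arrays(y, codes, m)
    k = np.bincount(codes, minlength=m)
    return ICCEstimate(method="anova", estimate=icc, n_clusters=m,
                       mean_cluster_size=float(k.mean()),
                       extras={"msb": msb, "msw": msw, "k0": k0})


def _anova_icc_from_arrays(y: np.ndarray, codes: np.ndarray, m: int):
    N = y.size
    if m < 2:
        raise ValueError("need at least 2 clusters")
    if N - m <= 0:
        raise ValueError("all clusters are singletons: within-cluster mean "
                         "square undefined")
    k = np.bincount(codes, minlength=m).astype(float)
    Sy = np.bincount(codes, weights=y, minlength=m)
    ybar = y.mean()
    means = Sy / k
    ssb = float(np.sum(k * (means - ybar) ** 2))
    ssw = float(y @ y - np.sum(Sy ** 2 / k))
    msb = ssb / (m - 1)
    msw = ssw / (N - m)
    k0 = (N - np.sum(k ** 2) / N) / (m - 1)
    denom = msb + (k0 - 1.0) * msw
    if denom <= 0:
        raise ValueError("degenerate mean squares (no variance in data)")
    return (msb - msw) / denom, msb, msw, float(k0)


# ---------------------------------------------------------------------------
# random-intercept REML (profiled over the variance ratio)


def _reml_profile_factory(y, X, codes, m):
    """Closed-form profiled REML pieces for the random-intercept model.

    For V = sigma2_e * H(lam), H = blockdiag(I + lam*J_k), the inverse and
    log-determinant of each block are available analytically:
    (I + lam J)^-1 = I - c J with c = lam/(1 + k lam), log|I + lam J| =
    log(1 + k lam).  Everything reduces to per-cluster sums, so one
    likelihood evaluation is O(m p^2) after an O(N p) precompute.
    """
    N, p = X.shape
    k = np.bincount(codes, minlength=m).astype(float)
    Sy = np.bincount(codes, weights=y, minlength=m)
    SX = np.empty((m, p))
    for j in range(p):
        SX[:, j] = np.bincount(codes, weights=X[:, j], minlength=m)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def profile(lam: float):
        c = lam / (1.0 + k * lam)
        A = XtX - (SX * c[:, None]).T @ SX
        b = Xty - SX.T @ (c * Sy)
        q = yty - float(np.sum(c * Sy ** 2))
        cf = cho_factor(A, lower=False, check_finite=False)
        beta = cho_solve(cf, b, check_finite=False)
        rHr = q - float(beta @ b)
        if rHr <= 0:
            rHr = np.finfo(float).tiny
        sigma2e = rHr / (N - p)
        logdetA = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ll = -0.5 * ((N - p) * (1.0 + np.log(2.0 * np.pi * sigma2e))
                     + float(np.sum(np.log1p(k * lam))) + logdetA)
        return ll, beta, sigma2e, cf

    return profile


def _reml_fit(y: np.ndarray, X: np.ndarray, codes: np.ndarray, m: int):
    """Maximize the profiled restricted likelihood over lam >= 0.

    Brent search on log(lam) over [1e-8, 1e3], then an explicit comparison
    with the lam = 0 boundary.  Returns (lam, sigma2e, beta, cov_beta,
    loglik, boundary_flag).
    """
    profile = _reml_profile_factory(y, X, codes, m)

    def neg(u):
        return -profile(np.exp(u))[0]

    res = minimize_scalar(neg, bounds=(np.log(1e-8), np.log(1e3)),
                          method="bounded", options={"xatol": 1e-9})
    lam_int = float(np.exp(res.x))
    ll_int = -float(res.fun)
    ll0, beta0, s2e0, cf0 = profile(0.0)
    if ll0 >= ll_int or lam_int <= 2e-8:
        lam, ll, beta, sigma2e, cf = 0.0, ll0, beta0, s2e0, cf0
        boundary = True
    else:
        ll, beta, sigma2e, cf = profile(lam_int)
        lam, boundary = lam_int, False
    p = X.shape[1]
    cov_beta = sigma2e * cho_solve(cf, np.eye(p), check_finite=False)
    return lam, sigma2e, beta, cov_beta, ll, boundary


def reml_random_intercept(cohort: pd.DataFrame,
                          fixed_terms: Sequence[str] = (),
                          outcome: str = DEFAULT_OUTCOME,
                          cluster: str = DEFAULT_CLUSTER) -> VarianceComponents:
    """REML fit of ``outcome ~ fixed_terms + (1 | cluster)``.

    The between-cage variance is constrained nonnegative, so on data with a
    negative intra-cage correlation the fit lands on the boundary
    (``boundary=True``, ICC = 0) — the marginal GEE route is the estimator
    that can see the negative correlation.
    """
    df = _prepare(cohort, outcome, cluster)
    y = df[outcome].to_numpy(dtype=float)
    X, names, spans = build_design(df, fixed_terms)
    aliased = find_aliased(X, names)
    if aliased:
        raise ValueError(f"design is singular; aliased columns: {aliased}")
    codes, m = _cluster_codes(df, cluster)
    lam, s2e, beta, cov, ll, boundary = _reml_fit(y, X, codes, m)
    return VarianceComponents(
        sigma2_between=lam * s2e, sigma2_within=s2e,
        fixed_effects=pd.Series(beta, index=names),
        reml_loglik=ll, n_obs=len(df), n_clusters=m, boundary=boundary,
        cov_fixed=cov, _y=y, _X=X, _codes=codes, _spans=spans)


def lmm_icc(vc: VarianceComponents, B: int = 0, level: float = 0.95,
            seed: int | None = None) -> ICCEstimate:
    """ICC from a random-intercept fit: sigma2_b / (sigma2_b + sigma2_e).

    With ``B`` > 0 a parametric-bootstrap percentile CI is attached
    (B >= 200 required by :func:`parametric_bootstrap_ci`).
    """
    est = vc.sigma2_between / (vc.sigma2_between + vc.sigma2_within)
    k = np.bincount(vc._codes).mean() if vc._codes is not None else 0.0
    if B:
        lo, hi = parametric_bootstrap_ci(vc, B=B, level=level, seed=seed)
        ci_method = "parametric_bootstrap"
    else:
        lo, hi, ci_method = np.nan, np.nan, "none"
    return ICCEstimate(method="lmm_reml", estimate=est, ci_low=lo, ci_high=hi,
                       ci_method=ci_method, n_clusters=vc.n_clusters,
                       mean_cluster_size=float(k),
                       extras={"boundary": vc.boundary,
                               "sigma2_between": vc.sigma2_between,
                               "sigma2_within": vc.sigma2_within})


def parametric_bootstrap_ci(vc: VarianceComponents, B: int = 1000,
                            level: float = 0.95,
                            seed: int | None = None) -> tuple[float, float]:
    """Model-based parametric bootstrap percentile CI for the LMM ICC.

    Simulates B datasets from the fitted model (GLS fixed effects + cage
    intercepts + residual noise) on the original design, refits each by
    REML, and returns the percentile interval of the B ICC estimates.
    """
    if B < 200:
        raise ValueError("B must be >= 200 for a stable percentile interval")
    if vc._X is None or vc._codes is None:
        raise ValueError("fit internals missing; refit with reml_random_intercept")
    rng = substream(seed, "bootstrap")
    X, codes, m = vc._X, vc._codes, vc.n_clusters
    k = np.bincount(codes, minlength=m)
    mu = X @ vc.fixed_effects.to_numpy()
    sd_b = np.sqrt(vc.sigma2_between)
    sd_e = np.sqrt(vc.sigma2_within)
    iccs = np.empty(B)
    failures = 0
    for b in range(B):
        yb = mu + np.repeat(rng.normal(0.0, sd_b, size=m), k) \
             + rng.normal(0.0, sd_e, size=len(mu))
        try:
            lam, s2e, *_ = _reml_fit(yb, X, codes, m)
            iccs[b] = lam / (1.0 + lam)
        except np.linalg.LinAlgError:
            iccs[b] = np.nan
            failures += 1
    if failures > 0.05 * B:
        raise RuntimeError(f"bootstrap refit failure rate {failures/B:.1%} > 5%")
    alpha = 1.0 - level
    lo, hi = np.nanquantile(iccs, [alpha / 2, 1.0 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# exchangeable working-correlation (GEE-style) moment estimator


def _gee_fit(y: np.ndarray, X: np.ndarray, codes: np.ndarray, m: int,
             max_iter: int = 100, tol: float = 1e-10):
    """Gaussian identity-link GEE with exchangeable working correlation.

    Alternates GLS coefficient updates under the current alpha with the
    moment update alpha = sum of within-cluster residual cross-products /
    (phi * number of pairs), phi = RSS/(N-p).  The working alpha is clamped
    inside the PSD band during iteration; the reported alpha is the final
    raw moment value (equal to the clamped one whenever it is interior).
    """
    N, p = X.shape
    k = np.bincount(codes, minlength=m).astype(float)
    kmax = int(k.max())
    n_pairs = float(np.sum(k * (k - 1.0)) / 2.0)
    if n_pairs == 0:
        raise ValueError("no within-cluster pairs: all clusters singleton")
    lo = icc_lower_bound(kmax) + 1e-6
    hi = 1.0 - 1e-6

    SX = np.empty((m, p))
    for j in range(p):
        SX[:, j] = np.bincount(codes, weights=X[:, j], minlength=m)
    XtX = X.T @ X
    Xty = X.T @ y

    def gls(alpha):
        a = 1.0 / (1.0 - alpha)
        c = a * alpha / (1.0 + (k - 1.0) * alpha)
        Sy = np.bincount(codes, weights=y, minlength=m)
        A = a * XtX - (SX * c[:, None]).T @ SX
        b = a * Xty - SX.T @ (c * Sy)
        beta = np.linalg.solve(A, b)
        return beta, A, a, c

    def alpha_moment(e):
        Se = np.bincount(codes, weights=e, minlength=m)
        Se2 = np.bincount(codes, weights=e * e, minlength=m)
        pair_sums = (Se ** 2 - Se2) / 2.0
        phi = float(e @ e) / (N - p)
        return float(np.sum(pair_sums)) / (phi * n_pairs), phi

    alpha_w = 0.0
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    trace = []
    converged = False
    for it in range(max_iter):
        beta_new, A, a, c = gls(alpha_w)
        e = y - X @ beta_new
        alpha_raw, phi = alpha_moment(e)
        alpha_new = float(np.clip(alpha_raw, lo, hi))
        trace.append((alpha_raw, alpha_new))
        db = float(np.max(np.abs(beta_new - beta)) / (1.0 + np.max(np.abs(beta_new))))
        da = abs(alpha_new - alpha_w)
        beta, alpha_w = beta_new, alpha_new
        if da < tol and db < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"GEE did not converge in {max_iter} iterations; alpha trace "
            f"(raw, clamped) tail: {trace[-5:]}")

    # sandwich covariance of beta at the converged working correlation
    beta, A, a, c = gls(alpha_w)
    e = y - X @ beta
    alpha_raw, phi = alpha_moment(e)
    Se = np.bincount(codes, weights=e, minlength=m)
    SXe = np.empty((m, p))
    for j in range(p):
        SXe[:, j] = np.bincount(codes, weights=X[:, j] * e, minlength=m)
    G = a * SXe - c[:, None] * SX * Se[:, None]    # per-cluster score pieces
    Ainv = np.linalg.inv(A)
    cov = Ainv @ (G.T @ G) @ Ainv
    return alpha_raw, alpha_w, beta, phi, cov, len(trace)


def gee_exchangeable(cohort: pd.DataFrame, fixed_terms: Sequence[str] = (),
                     outcome: str = DEFAULT_OUTCOME,
                     cluster: str = DEFAULT_CLUSTER,
                     ci: str | None = "cluster_bootstrap",
                     B: int = 1000, level: float = 0.95,
                     seed: int | None = None) -> ICCEstimate:
    """Marginal ICC via the exchangeable working correlation.

    Unlike the LMM route, the working alpha may be negative, so this is
    the estimator of choice when co-housed animals compete (dispersion
    effects).  CI options: cage-level nonparametric bootstrap percentile
    (default), ``sandwich_delta`` (cluster-linearized large-sample SE), or
    None.
    """
    df = _prepare(cohort, outcome, cluster)
    y = df[outcome].to_numpy(dtype=float)
    X, names, _ = build_design(df, fixed_terms)
    codes, m = _cluster_codes(df, cluster)
    if m < 20:
        warnings.warn(f"only {m} clusters: GEE asymptotics assume many "
                      "clusters; expect inflated type-I error", stacklevel=2)
    alpha_raw, alpha_w, beta, phi, cov, n_iter = _gee_fit(y, X, codes, m)
    k = np.bincount(codes, minlength=m)

    lo_ci, hi_ci, ci_method = np.nan, np.nan, "none"
    if ci == "cluster_bootstrap":
        lo_ci, hi_ci = _gee_cluster_bootstrap_ci(y, X, codes, m, B, level, seed)
        ci_method = "cluster_bootstrap"
    elif ci == "sandwich_delta":
        se = _gee_alpha_delta_se(y, X, codes, m, beta, phi, alpha_raw)
        z = stats.norm.ppf(0.5 + level / 2.0)
        lo_ci, hi_ci = alpha_raw - z * se, alpha_raw + z * se
        ci_method = "sandwich_delta"
    elif ci is not None:
        raise ValueError(f"unknown ci method {ci!r}")
    return ICCEstimate(method="gee_exchangeable", estimate=alpha_raw,
                       ci_low=lo_ci, ci_high=hi_ci, ci_method=ci_method,
                       n_clusters=m, mean_cluster_size=float(k.mean()),
                       extras={"phi": phi, "beta": pd.Series(beta, index=names),
                               "cov_sandwich": cov, "n_iter": n_iter,
                               "alpha_working": alpha_w})


def _gee_cluster_bootstrap_ci(y, X, codes, m, B, level, seed):
    """Percentile CI from resampling whole cages with replacement."""
    rng = substream(seed, "bootstrap")
    order = np.argsort(codes, kind="stable")
    k = np.bincount(codes, minlength=m)
    starts = np.concatenate([[0], np.cumsum(k)])
    rows_by_cage = [order[starts[j]:starts[j + 1]] for j in range(m)]
    alphas = np.empty(B)
    for b in range(B):
        pick = rng.integers(0, m, size=m)
        idx = np.concatenate([rows_by_cage[j] for j in pick])
        codes_b = np.repeat(np.arange(m), k[pick])
        try:
            alphas[b] = _gee_fit(y[idx], X[idx], codes_b, m)[0]
        except (np.linalg.LinAlgError, RuntimeError):
            alphas[b] = np.nan
    alpha = 1.0 - level
    lo, hi = np.nanquantile(alphas, [alpha / 2, 1.0 - alpha / 2])
    return float(lo), float(hi)


def _gee_alpha_delta_se(y, X, codes, m, beta, phi, alpha):
    """Cluster-linearized SE of alpha (phi treated as fixed)."""
    e = y - X @ beta
    k = np.bincount(codes, minlength=m).astype(float)
    Se = np.bincount(codes, weights=e, minlength=m)
    Se2 = np.bincount(codes, weights=e * e, minlength=m)
    pair_sums = (Se ** 2 - Se2) / 2.0
    w = k * (k - 1.0) / 2.0
    u = pair_sums / phi - alpha * w
    return float(np.sqrt(np.sum(u ** 2)) / np.sum(w))


# ---------------------------------------------------------------------------
# cage-permutation significance test


def permutation_icc_test(cohort: pd.DataFrame, estimator: str = "anova",
                         n_perm: int = 1000, seed: int | None = None,
                         strata: Sequence[str] | None = None,
                         outcome: str = DEFAULT_OUTCOME,
                         cluster: str = DEFAULT_CLUSTER,
                         alternative: str = "greater") -> PermutationResult:
    """Permutation null for the ICC: shuffle animals across cages.

    Cages, not animals, are the randomized units, so animals are permuted
    across cages *within* randomization strata (default: the ``arm``
    column when present), preserving every cage's size.  One-sided
    upper-tail p-value with add-one correction by default;
    ``alternative="two-sided"`` compares absolute values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if n_perm < 300:
        warnings.warn("permutation p-values stabilize around n_perm ~ 300; "
                      f"n_perm={n_perm} may be noisy", stacklevel=2)
    if estimator not in ("anova", "gee_exchangeable"):
        raise ValueError("estimator must be 'anova' or 'gee_exchangeable'")
    if strata is None:
        strata = ("arm",) if "arm" in cohort.columns else ()

    df = _prepare(cohort, outcome, cluster).reset_index(drop=True)
    y = df[outcome].to_numpy(dtype=float)
    codes, m = _cluster_codes(df, cluster)
    if strata:
        strat_codes = df.groupby(list(strata), sort=False).ngroup().to_numpy()
    else:
        strat_codes = np.zeros(len(df), dtype=int)
    groups = [np.flatnonzero(strat_codes == s) for s in np.unique(strat_codes)]
    for g in groups:
        if len(np.unique(codes[g])) < 2:
            raise ValueError("each permutation stratum needs >= 2 cages")

    covs = [c for c in strata if c in df.columns]
    if estimator == "anova":
        def statistic(perm_codes):
            yy = y
            if covs:
                X, _, _ = build_design(df, covs)
                beta = np.linalg.lstsq(X, yy, rcond=None)[0]
                yy = yy - X @ beta
            return _anova_icc_from_arrays(yy, perm_codes, m)[0]
    else:
        X, _, _ = build_design(df, covs)

        def statistic(perm_codes):
            return _gee_fit(y, X, perm_codes, m)[0]

    observed = statistic(codes)
    rng = substream(seed, "permutation")
    null = np.empty(n_perm)
    perm_codes = codes.copy()
    for b in range(n_perm):
        for g in groups:
            perm_codes[g] = codes[g][rng.permutation(len(g))]
        null[b] = statistic(perm_codes)
    if alternative == "greater":
        exceed = int(np.sum(null >= observed))
    elif alternative == "two-sided":
        exceed = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    p = (1.0 + exceed) / (1.0 + n_perm)
    return PermutationResult(observed_icc=float(observed), null_draws=null,
                             p_value=p, n_permutations=n_perm, seed=seed,
                             estimator=estimator, alternative=alternative)


# ---------------------------------------------------------------------------
# two-level (cage + animal) REML for longitudinal phenotypes


def two_level_reml(cohort: pd.DataFrame,
                   fixed_terms: Sequence[str] = ("diet", "age"),
                   outcome: str = "value",
                   cage: str = "cage_id",
                   animal: str = "animal_id") -> VarianceComponents:
    """REML for ``value ~ fixed + (1|cage) + (1|animal)`` with nesting.

    Repeated measures cluster twice: observations within animal, animals
    within cage.  The restricted likelihood is profiled over the residual
    variance and fixed effects per (lambda_cage, lambda_animal) and
    maximized by L-BFGS-B with nonnegativity bounds; cage blocks are
    solved densely, batched over cages sharing a block pattern.
    """
    for col in (outcome, cage, animal):
        if col not in cohort.columns:
            raise KeyError(f"column {col!r} not in cohort")
    nest = cohort.groupby(animal)[cage].nunique()
    if (nest > 1).any():
        bad = nest.index[nest > 1][:5].tolist()
        raise ValueError(f"animals in more than one cage (non-nested ids): {bad}")
    obs_per_animal = cohort.groupby(animal).size()
    if obs_per_animal.max() < 2:
        raise ValueError(
            "one observation per animal: sigma2_animal and sigma2_within are "
            "not separately identifiable; collapse to the single-level model "
            "(reml_random_intercept)")

    df = cohort.sort_values([cage, animal], kind="stable").reset_index(drop=True)
    y = df[outcome].to_numpy(dtype=float)
    X, names, spans = build_design(df, fixed_terms)
    aliased = find_aliased(X, names)
    if aliased:
        raise ValueError(f"design is singular; aliased columns: {aliased}")
    N, p = X.shape

    cage_codes, m = _cluster_codes(df, cage)
    # per-cage animal run lengths define the block pattern
    keys = {}
    for j in range(m):
        rows = np.flatnonzero(cage_codes == j)
        a_codes = pd.factorize(df[animal].to_numpy()[rows])[0]
        runs = tuple(np.bincount(a_codes))
        keys.setdefault((len(rows), runs), []).append(rows)

    groups = []
    for (n_j, runs), rowsets in keys.items():
        Z = np.zeros((n_j, len(runs)))
        pos = 0
        for a, r in enumerate(runs):
            Z[pos:pos + r, a] = 1.0
            pos += r
        ZZt = Z @ Z.T
        J = np.ones((n_j, n_j))
        rows = np.array(rowsets)                      # (g, n_j)
        RHS = np.concatenate([X[rows.ravel()].reshape(len(rowsets), n_j, p),
                              y[rows.ravel()].reshape(len(rowsets), n_j, 1)],
                             axis=2)
        groups.append((n_j, ZZt, J, RHS, len(rowsets)))

    XtX_parts = None

    def profile(lam_c: float, lam_a: float):
        A = np.zeros((p, p))
        b = np.zeros(p)
        q = 0.0
        logdetH = 0.0
        for n_j, ZZt, J, RHS, g in groups:
            H = np.eye(n_j) + lam_a * ZZt + lam_c * J
            sign, ld = np.linalg.slogdet(H)
            logdetH += g * ld
            sol = np.linalg.solve(H, RHS)             # (g, n_j, p+1)
            cross = np.einsum("gni,gnj->ij", RHS, sol)
            A += cross[:p, :p]
            b += cross[:p, p]
            q += cross[p, p]
        cf = cho_factor(A, lower=False, check_finite=False)
        beta = cho_solve(cf, b, check_finite=False)
        rHr = q - float(beta @ b)
        if rHr <= 0:
            rHr = np.finfo(float).tiny
        sigma2e = rHr / (N - p)
        logdetA = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ll = -0.5 * ((N - p) * (1.0 + np.log(2.0 * np.pi * sigma2e))
                     + logdetH + logdetA)
        return ll, beta, sigma2e, cf

    def neg(params):
        return -profile(params[0], params[1])[0]

    best = None
    for x0 in ([0.05, 0.5], [0.2, 0.2], [0.0, 1.0]):
        res = minimize(neg, x0=np.asarray(x0), method="L-BFGS-B",
                       bounds=[(0.0, 1e4), (0.0, 1e4)],
                       options={"ftol": 1e-13, "gtol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    lam_c, lam_a = float(best.x[0]), float(best.x[1])
    ll, beta, s2e, cf = profile(lam_c, lam_a)
    cov_beta = s2e * cho_solve(cf, np.eye(p), check_finite=False)
    return VarianceComponents(
        sigma2_between=lam_c * s2e, sigma2_within=s2e,
        sigma2_animal=lam_a * s2e,
        fixed_effects=pd.Series(beta, index=names),
        reml_loglik=ll, n_obs=N, n_clusters=m,
        boundary=(lam_c == 0.0), cov_fixed=cov_beta,
        _y=y, _X=X, _codes=cage_codes, _spans=spans)


def proportion_of_variance_icc(vc: VarianceComponents) -> ICCEstimate:
    """Cage variance share of a two-level fit (bounded below by 0)."""
    if vc.sigma2_animal is None:
        raise ValueError("proportion-of-variance ICC needs a two-level fit")
    tot = vc.sigma2_between + vc.sigma2_animal + vc.sigma2_within
    est = vc.sigma2_between / tot
    return ICCEstimate(method="two_level_lmm", estimate=est,
                       n_clusters=vc.n_clusters,
                       mean_cluster_size=(vc.n_obs / vc.n_clusters
                                          if vc.n_clusters else 0.0),
                       extras={"sigma2_cage": vc.sigma2_between,
                               "sigma2_animal": vc.sigma2_animal,
                               "sigma2_residual": vc.sigma2_within,
                               "boundary": vc.boundary})


# ---------------------------------------------------------------------------
# joint fixed-effect tests with / without the cage random intercept


def joint_fixed_effect_test(cohort: pd.DataFrame,
                            fixed_terms: Sequence[str],
                            term_of_interest: str,
                            with_cage_effect: bool,
                            outcome: str = DEFAULT_OUTCOME,
                            cluster: str = DEFAULT_CLUSTER):
    """Wald F test of a (possibly multi-level) fixed term.

    With the cage random intercept the coefficient covariance comes from
    the REML GLS fit and the denominator df is the between-cluster count
    m - rank(cage-level design); without it, OLS with residual df.  On
    positively correlated data the OLS route understates p-values — the
    anti-conservative artifact of ignoring co-housing.

    Returns ``(F, (df_num, df_den), p_value)``.
    """
    if term_of_interest not in fixed_terms:
        raise ValueError("term_of_interest must be among fixed_terms")
    df = _prepare(cohort, outcome, cluster)
    y = df[outcome].to_numpy(dtype=float)
    X, names, spans = build_design(df, fixed_terms)
    aliased = find_aliased(X, names)
    if aliased:
        raise ValueError(f"design is singular; aliased columns: {aliased}")
    sl = spans[term_of_interest]
    q = sl.stop - sl.start
    if q < 1:
        raise ValueError(f"term {term_of_interest!r} has < 2 levels")
    codes, m = _cluster_codes(df, cluster)

    if with_cage_effect:
        lam, s2e, beta, cov, ll, boundary = _reml_fit(y, X, codes, m)
        # rank of the cage-level (between-cluster) design
        k = np.bincount(codes, minlength=m).astype(float)
        Xbar = np.empty((m, X.shape[1]))
        for j in range(X.shape[1]):
            Xbar[:, j] = np.bincount(codes, weights=X[:, j], minlength=m) / k
        r = np.linalg.matrix_rank(Xbar)
        df_den = m - r
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = float(resid @ resid) / (len(y) - X.shape[1])
        cov = s2 * np.linalg.inv(X.T @ X)
        df_den = len(y) - X.shape[1]
    if df_den < 1:
        raise ValueError("nonpositive denominator degrees of freedom")
    bL = beta[sl]
    covL = cov[sl][:, sl]
    F = float(bL @ np.linalg.solve(covL, bL)) / q
    p = float(stats.f.sf(F, q, df_den))
    return F, (q, int(df_den)), p
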