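# Methods

This note records the statistical models the package implements, the
numerical choices behind them, what the synthetic generator does and does
not emulate, and the design decisions taken where more than one reasonable
option existed.

## Models

### Exchangeable clustered outcomes

A cohort is a set of cages j = 1..m with sizes k_j, each cage assigned to
one treatment arm. The Gaussian model for lifespan y_ij is

    y_ij = μ + x_j'β + ε_ij,   Cov(ε_ij, ε_i'j) = σ² [ 1{i=i'} + ρ 1{i≠i'} ],

i.e. an exchangeable within-cage correlation ρ (the ICC) with common
marginal variance σ². Exchangeability requires ρ ≥ −1/(k−1) for the
largest cage (otherwise the covariance is not positive semidefinite); ρ
may be negative, as when cage mates compete.

### The three ICC estimators

**ANOVA (moments).** After regressing out covariates by OLS, the one-way
mean squares give

    ICĈ = (MSB − MSW) / (MSB + (k₀ − 1) MSW),
    k₀ = (N − Σk_j²/N) / (m − 1)   (unbalanced correction).

Range [−1/(k_max−1), 1]; unbiased to first order; closed form.

**Random-intercept REML (LMM).** y = Xβ + Zb + e with b_j ~ N(0, σ²_b),
e ~ N(0, σ²_e). The restricted likelihood is profiled analytically: for
λ = σ²_b/σ²_e, each cage block of H(λ) = I + λJ has inverse I − cJ with
c = λ/(1+k_jλ) and log-determinant log(1+k_jλ), so β(λ), σ̂²_e(λ) and the
restricted log-likelihood reduce to per-cage sums (one evaluation is
O(m p²) after an O(N p) precompute). λ is maximized by bounded Brent
search on log λ over [1e-8, 1e3], followed by an explicit comparison with
the λ = 0 boundary; `boundary=True` marks fits truncated at σ²_b = 0.
The reported restricted log-likelihood includes all constants and equals a
dense-matrix evaluation to ~1e-12 (asserted to 1e-6 in tests), and the fit
is cross-checked against statsmodels MixedLM. ICĈ = σ̂²_b/(σ̂²_b+σ̂²_e) ∈
[0, 1): **the LMM cannot report negative ICC** — on anticorrelated data it
returns a flagged boundary fit, the documented bias of variance-components
models.

**Exchangeable working-correlation (GEE).** Identity-link Gaussian
estimating equations alternating (i) GLS coefficient updates under the
current working α, using the same exchangeable block-inverse identities,
and (ii) the moment update

    α̂ = Σ_j Σ_{i<i'} e_ij e_i'j / ( φ · Σ_j k_j(k_j−1)/2 ),
    φ = RSS/(N − p),

with α clamped to the open PSD band during iteration; the reported value
is the final raw moment (equal to the clamped iterate whenever interior,
hence free to be negative). Coefficient covariance is the robust sandwich
B⁻¹MB⁻¹ over cage-level score contributions. On balanced intercept-only
data α̂ equals the brute-force average pairwise residual correlation
exactly (asserted to 1e-6). statsmodels' GEE differs by subtracting p from
the pair-count denominator — an O(p/Σpairs) difference used as a
cross-check tolerance, not adopted.

### Confidence intervals

- LMM: model-based **parametric bootstrap** (default B as configured,
  minimum 200): resimulate from the fitted (β̂, σ̂²_b, σ̂²_e) on the original
  design, refit, percentile interval. Truncation piles bootstrap mass at
  zero, so a zero lower limit is expected whenever σ̂²_b is small.
- GEE: **cage-level nonparametric bootstrap** percentile interval (default
  B=1000), chosen over the delta method for robustness near the PSD
  boundary; a cluster-linearized `sandwich_delta` SE (φ treated as fixed)
  is available as an option.

### Permutation test

Cages, not animals, are the randomized units, so significance of the
observed ICC is assessed by shuffling animals across cages *within
randomization strata* (default: the arm column), preserving every cage's
size, and recomputing the statistic (ANOVA by default; GEE optional).
One-sided upper-tail p with add-one correction,
p = (1 + #{null ≥ obs})/(1 + B); a two-sided variant compares absolute
values. Default B = 1000; p-values are stable from roughly B ≈ 300, and a
warning is raised below that. The upper-tail default means strongly
*negative* observed ICCs yield p near 1 by construction.

### Two-level model for longitudinal phenotypes

Repeated measures cluster twice: observations within animal, animals
within cage. The model is value ~ fixed effects + (1|cage) + (1|animal) +
noise, fit by REML over (λ_cage, λ_animal) with σ²_e and β profiled per
evaluation; cage blocks H = I + λ_a ZZ' + λ_c J are solved densely,
batched over cages sharing a block pattern, so a 24,000-row balanced fit
takes ~1.5 s. Optimization is L-BFGS-B with nonnegativity bounds from
three starts. The cage-level ICC is reported as the **proportion of
variance** σ²_cage/(σ²_cage+σ²_animal+σ²_e), bounded below by 0. Animals
appearing in two cages are rejected (non-nested design), and a single
observation per animal is rejected as unidentifiable (collapse to the
single-level model instead).

### Joint fixed-effect tests

Wald F for a (possibly multi-level) term, either from the REML GLS
coefficient covariance with **between-cluster denominator df** m − rank of
the cage-level design (a deliberate approximation; Satterthwaite-type df
are out of scope), or from OLS with residual df. Comparing the two on the
same data exposes the understated p-values of cluster-naive analysis under
positive ICC.

### Trial simulation

Two-arm cage-randomized replicates are generated from the exchangeable
model (partial last cage allowed) and analyzed by LM (OLS t), LMM (REML
Wald t with m−2 df), GEE (sandwich Wald z) and LOGRANK (two-group log-rank
computed in-package and cross-checked against lifelines). Replicate r
draws from an independent substream of the scenario seed, so results are
independent of execution order. Rates come with mc_se = √(r(1−r)/n_reps);
scenarios with fewer than 20 cages per arm are flagged (GEE asymptotics
assume many clusters). P-value-uniformity diagnostics report the KS
distance from U(0,1), the mean−0.5 skew direction, and decile counts.

### Sample size

Base two-sample per-group n from the normal approximation
n₀ = 2(z_{1−α/2}+z_{power})² sd²/(es·mean)², inflated by DE = 1+(k−1)ICC,
with the **ceiling applied once, after inflation**. With mean 912 days,
SD 143, es 10%, power 0.8, k=4 this yields 39/40/45/51 at ICC
0/0.01/0.05/0.1. z-quantiles are the default because they reproduce that
sequence exactly; a t-quantile fixed-point variant (`use_t=True`) is
provided and is never smaller. Grids are full factorials over user-supplied
stratum (mean, sd) rows × ICC × cage size; only the (912, 143) example is
shipped, since stratum-specific inputs are the user's data.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical* structure of murine aging
cohorts: hundreds to thousands of cages of 3–8 animals, cage-level arm
assignment, exchangeable within-cage correlation of magnitude roughly
−0.05…+0.10, additive cage-level batch shifts, and <4% right-censoring
(default 0; censoring times drawn uniformly on (0, event time), and
lifespan analyses drop censored rows). Defaults are a marginal lifespan of
30 months (912 days at 30.4 days/month) with SD 4.7 months (143 days).

Positive ICC uses the shared-cage-intercept construction; negative ICC
(which no shared intercept can produce) uses the exact eigenstructure
factorization of the exchangeable covariance — the two coincide in
distribution for ρ ≥ 0. The `gaussian-copula-weibull` family pushes latent
exchangeable normal scores through the probability integral transform onto
a Weibull matched to the requested mean/SD; its ground-truth ICC is
defined on the **latent scale** (`df.attrs["icc_scale"]`), and the induced
outcome-scale correlation is attenuated, so calibration experiments use
the Gaussian family. The two-level longitudinal generator takes
`residual_sd` as the noise SD and sets total variance to
residual_sd²/(1−icc_cage−icc_animal) so the variance shares are exactly
the requested ones; the default age slope is 0 (a trend adds nothing to
the variance-share questions and can be switched on).

Not emulated: within-cage biology (frailty dynamics, barbering, dominance),
informative censoring, cage reassignments over time, heteroscedastic
strains. Passing tests therefore demonstrate correctness of the estimators
under the exchangeable model, not robustness to those violations.

One global integer seed expands to fixed per-operation substreams
(SeedSequence spawn keys), so re-ordering pipeline stages does not perturb
draws; identical config + seed gives byte-identical outputs.

## Batch adjustment choices

"Far outliers" are values strictly beyond median ± 3·IQR — a deliberately
wide fence excluded only from the *fitting* subset (all rows are
adjusted). Batch coefficients are sum-to-zero coded so the adjustment
subtracts a per-batch constant with zero grand effect, preserving
within-batch rank order; adjusted outcomes ≤ 0 are dropped and counted.
Aliased designs (batch confounded with a covariate) raise an error naming
the dependent columns via QR column pivoting.

## Numerical details and degenerate inputs

- REML ratio λ searched on [1e-8, 1e3] (log scale, xatol 1e-9) with an
  explicit λ=0 boundary comparison; rHr is floored at tiny to survive
  zero-noise degenerate data.
- GEE iterations: convergence at 1e-10 on α and relative β; 100-iteration
  cap raises with the (raw, clamped) α trace. Singleton-only cohorts (no
  within-cage pairs) are rejected.
- ANOVA requires ≥2 cages and at least one cage with ≥2 animals.
- Bootstrap refit failures above 5% abort; per-replicate trial failures
  above 2% abort the scenario.
- All estimators drop rows flagged `censored` before fitting (log-rank
  keeps them and uses the censoring indicator).

## Simulation sizes used by the shipped checks

The acceptance-style tests run: estimator calibration at 1000 cages × 4
over 200 replicates per truth; type-I-error scenarios at 50 cages per arm
× 2000 replicates; permutation calibration over 200 null cohorts × 300
permutations; bootstrap coverage at 1000 cages, B=500, 200 outer
replicates; two-level recovery at 500 cages × 8 animals × 6 ages. These
sizes give Monte Carlo SEs small enough for the asserted 3-SE bands while
keeping the full suite around five minutes on one core.

## Known limitations

- One clustering level for lifespan analyses (GEE and permutation); the
  two-level machinery is specific to the longitudinal REML.
- Mixed-model Wald tests use between-cluster denominator df, slightly
  conservative in small samples relative to Satterthwaite-type choices.
- No shared-frailty (correlated survival) models; the censored-data arm of
  the simulator is the cluster-naive log-rank only.
- The LMM boundary behavior means its parametric-bootstrap CI is one-sided
  near zero truth; coverage there is maintained by the zero pile-up, not
  by interval symmetry.
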