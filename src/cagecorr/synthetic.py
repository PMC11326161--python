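"""Synthetic clustered cohorts with known ground-truth intra-cage correlation.

Murine aging studies randomize whole housing units (cages) to treatment
arms, so lifespans and longitudinal phenotypes of co-housed animals share
an exchangeable within-cage correlation (the intra-class correlation, ICC).
This module generates cohorts with that structure under experimenter
control: many cages of 3-8 animals, cage-level arm assignment, optional
batch shifts, light right-censoring, and an ICC that may be positive, zero,
or negative down to the exchangeability bound -1/(k-1).

Two marginal families are provided:

* ``gaussian`` — outcomes are exchangeable multivariate normal within each
  cage.  For icc >= 0 this is realized as a shared cage intercept plus
  independent noise; for icc < 0 (where no shared-intercept construction
  exists) the exchangeable covariance is factorized directly through its
  known eigenstructure.
* ``gaussian-copula-weibull`` — latent exchangeable normal scores are
  pushed through the probability integral transform onto a Weibull with
  the requested mean and SD.  The ground-truth ICC then lives on the
  latent normal scale (recorded in the output's metadata); the induced
  outcome-scale correlation is slightly attenuated.

Cohorts are plain :class:`pandas.DataFrame` objects with the canonical
columns ``animal_id, cage_id, arm, batch, lifespan_months, censored``
(longitudinal: ``animal_id, cage_id, diet, age, trait, value``), matching
the CSV layout used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CageStructure",
    "GeneratorConfig",
    "make_cage_structure",
    "sample_exchangeable_outcomes",
    "apply_censoring",
    "sample_longitudinal",
    "icc_lower_bound",
    "substream",
]

#: canonical lifespan-cohort columns, in CSV order
COHORT_COLUMNS = ["animal_id", "cage_id", "arm", "sex", "strain", "batch",
                  "lifespan_months", "censored"]
#: canonical longitudinal-cohort columns, in CSV order
LONGITUDINAL_COLUMNS = ["animal_id", "cage_id", "diet", "age", "trait", "value"]

# Fixed substream ids: one global seed expands to independent per-operation
# streams via SeedSequence spawn keys, so stages can be reordered without
# perturbing each other's draws.
_STREAMS = {
    "structure": 0,
    "outcomes": 1,
    "censoring": 2,
    "longitudinal": 3,
    "permutation": 4,
    "bootstrap": 5,
    "trial": 6,
}


def substream(seed: int | None, stream: str, *key: int) -> np.random.Generator:
    """Return a Generator for a named substream of the global ``seed``."""
    if stream not in _STREAMS:
        raise KeyError(f"unknown stream {stream!r}; one of {sorted(_STREAMS)}")
    entropy = 0 if seed is None else int(seed)
    ss = np.random.SeedSequence(entropy, spawn_key=(_STREAMS[stream], *key))
    return np.random.Generator(np.random.PCG64(ss))


def icc_lower_bound(max_cluster_size: int) -> float:
    """Exchangeability (positive semidefiniteness) bound -1/(k-1)."""
    k = int(max_cluster_size)
    if k < 2:
        return 0.0
    return -1.0 / (k - 1)


@dataclass(frozen=True)
class CageStructure:
    """Cage-level frame of a cluster-randomized design.

    Treatment arms are a property of the cage, not the animal: every animal
    in a cage shares its cage's arm label.
    """

    cage_ids: tuple
    sizes: tuple
    arms: tuple

    def __post_init__(self):
        if not (len(self.cage_ids) == len(self.sizes) == len(self.arms)):
            raise ValueError("cage_ids, sizes and arms must be equally long")
        if len(set(self.cage_ids)) != len(self.cage_ids):
            raise ValueError("cage_ids must be unique")
        if any(int(s) < 1 for s in self.sizes):
            raise ValueError("all cage sizes must be >= 1")

    @property
    def n_cages(self) -> int:
        return len(self.cage_ids)

    @property
    def n_animals(self) -> int:
        return int(sum(self.sizes))

    @property
    def max_size(self) -> int:
        return int(max(self.sizes))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic lifespan cohort.

    Defaults mirror a typical murine aging cohort: lifespan ~30 months
    (912 days / 30.4) with SD ~4.7 months (143 days), under 4% censoring.
    """

    icc: float = 0.05
    marginal_mean: float = 30.0
    marginal_sd: float = 4.7
    effect: float = 0.0
    marginal_family: str = "gaussian"
    censor_rate: float = 0.0
    batch_labels: Sequence[str] | None = None
    batch_shifts: Sequence[float] | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.marginal_sd <= 0:
            raise ValueError("marginal_sd must be positive")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must be in [0, 1)")
        if self.marginal_family not in ("gaussian", "gaussian-copula-weibull"):
            raise ValueError(f"unknown marginal_family {self.marginal_family!r}")
        if (self.batch_labels is None) != (self.batch_shifts is None):
            raise ValueError("batch_labels and batch_shifts go together")
        if self.batch_labels is not None and len(self.batch_labels) != len(self.batch_shifts):
            raise ValueError("batch_labels and batch_shifts must be equally long")


def make_cage_structure(n_cages_per_arm: int,
                        cluster_size: int | Sequence[int],
                        n_arms: int = 2,
                        seed: int | None = None,
                        arm_labels: Sequence[str] | None = None) -> CageStructure:
    """Build a cage frame with arms assigned to whole cages, balanced by arm.

    ``cluster_size`` is either one size for all cages or a per-cage list of
    length ``n_cages_per_arm * n_arms``.  Cage-to-arm assignment is a
    seeded permutation (block-balanced), deterministic for a fixed seed.
    """
    if n_cages_per_arm < 1 or n_arms < 1:
        raise ValueError("n_cages_per_arm and n_arms must be positive")
    m = n_cages_per_arm * n_arms
    if np.isscalar(cluster_size):
        sizes = [int(cluster_size)] * m
    else:
        sizes = [int(s) for s in cluster_size]
        if len(sizes) != m:
            raise ValueError(f"need {m} cage sizes, got {len(sizes)}")
    if any(s < 1 for s in sizes):
        raise ValueError("cluster sizes must be >= 1")
    if arm_labels is None:
        arm_labels = (["control", "treatment"] if n_arms == 2
                      else [f"arm{a}" for a in range(n_arms)])
    if len(arm_labels) != n_arms:
        raise ValueError("need one label per arm")
    rng = substream(seed, "structure")
    order = rng.permutation(m)
    arms = [None] * m
    for rank, cage in enumerate(order):
        arms[cage] = arm_labels[rank % n_arms]
    cage_ids = tuple(f"C{j:05d}" for j in range(m))
    return CageStructure(cage_ids=cage_ids, sizes=tuple(sizes), arms=tuple(arms))


def _exchangeable_normal(rng: np.random.Generator, sizes: np.ndarray,
                         icc: float) -> np.ndarray:
    """Standardized exchangeable normal scores, stacked cage by cage.

    The exchangeable correlation matrix (1-rho) I + rho J has eigenvalue
    1+(k-1)rho on the equi-angular direction and 1-rho on its complement;
    scaling those two subspaces of an iid draw yields the exact factorized
    covariance, valid for any rho >= -1/(k-1) including negative values.
    """
    out = np.empty(int(sizes.sum()))
    pos = 0
    for k in sizes:
        z = rng.standard_normal(k)
        zbar = z.mean()
        mean_scale = np.sqrt(max(1.0 + (k - 1) * icc, 0.0) / k)
        resid_scale = np.sqrt(max(1.0 - icc, 0.0))
        out[pos:pos + k] = resid_scale * (z - zbar) + mean_scale * np.sqrt(k) * zbar
        pos += k
    return out


def _shared_intercept_normal(rng: np.random.Generator, sizes: np.ndarray,
                             icc: float) -> np.ndarray:
    """Standardized scores from the cage-intercept construction (icc >= 0)."""
    b = rng.standard_normal(len(sizes)) * np.sqrt(icc)
    e = rng.standard_normal(int(sizes.sum())) * np.sqrt(1.0 - icc)
    return np.repeat(b, sizes) + e


def _weibull_params(mean: float, sd: float) -> tuple[float, float]:
    """Shape and scale of the Weibull matching a given mean and SD."""
    from scipy.optimize import brentq
    from scipy.special import gammaln

    cv2 = (sd / mean) ** 2

    def f(log_c):
        c = np.exp(log_c)
        r = np.exp(gammaln(1 + 2 / c) - 2 * gammaln(1 + 1 / c))
        return r - 1 - cv2

    log_c = brentq(f, np.log(0.05), np.log(200.0), xtol=1e-12)
    c = float(np.exp(log_c))
    scale = mean / np.exp(gammaln(1 + 1 / c))
    return c, scale


def sample_exchangeable_outcomes(structure: CageStructure,
                                 config: GeneratorConfig) -> pd.DataFrame:
    """Draw one lifespan cohort from the configured exchangeable model.

    Outcome for cage j is marginal_mean + arm effect (+ batch shift) plus
    an exchangeable draw with common SD ``marginal_sd`` and pairwise
    correlation ``config.icc``.  For the Weibull copula family the ICC is
    imposed on the latent normal scale; ``df.attrs["icc_scale"]`` records
    which scale the ground truth refers to.
    """
    from scipy import stats

    sizes = np.asarray(structure.sizes, dtype=int)
    bound = icc_lower_bound(structure.max_size)
    if not (bound - 1e-12 <= config.icc < 1.0):
        raise ValueError(
            f"icc={config.icc} outside [{bound:.4f}, 1) for max cage size "
            f"{structure.max_size} (exchangeable covariance not PSD)")

    rng = substream(config.seed, "outcomes")
    if config.icc >= 0:
        z = _shared_intercept_normal(rng, sizes, config.icc)
    else:
        z = _exchangeable_normal(rng, sizes, config.icc)

    arm_labels = list(dict.fromkeys(structure.arms))
    # additive shift on every non-reference arm; scalar effect
    shift_by_arm = {a: (config.effect if i > 0 else 0.0)
                    for i, a in enumerate(arm_labels)}
    arm_per_cage = np.asarray(structure.arms, dtype=object)
    cage_shift = np.array([shift_by_arm[a] for a in arm_per_cage])

    if config.batch_labels is not None:
        batch_idx = rng.integers(0, len(config.batch_labels), size=structure.n_cages)
        batch_per_cage = np.asarray(config.batch_labels, dtype=object)[batch_idx]
        cage_shift = cage_shift + np.asarray(config.batch_shifts)[batch_idx]
    else:
        batch_per_cage = np.array(["B0"] * structure.n_cages, dtype=object)

    if config.marginal_family == "gaussian":
        y = config.marginal_mean + np.repeat(cage_shift, sizes) \
            + config.marginal_sd * z
        icc_scale = "outcome"
    else:
        u = stats.norm.cdf(z)
        mean_per_row = config.marginal_mean + np.repeat(cage_shift, sizes)
        y = np.empty_like(u)
        for mu in np.unique(mean_per_row):
            c, scale = _weibull_params(mu, config.marginal_sd)
            sel = mean_per_row == mu
            y[sel] = stats.weibull_min.ppf(u[sel], c, scale=scale)
        icc_scale = "latent"

    df = pd.DataFrame({
        "animal_id": [f"A{i:06d}" for i in range(structure.n_animals)],
        "cage_id": np.repeat(np.asarray(structure.cage_ids, dtype=object), sizes),
        "arm": np.repeat(arm_per_cage, sizes),
        "sex": "F",
        "strain": "synthetic",
        "batch": np.repeat(batch_per_cage, sizes),
        "lifespan_months": y,
        "censored": False,
    })
    df.attrs["icc_truth"] = config.icc
    df.attrs["icc_scale"] = icc_scale
    df.attrs["marginal_family"] = config.marginal_family
    if config.censor_rate > 0:
        df = apply_censoring(df, config.censor_rate, seed=config.seed)
    return df


def apply_censoring(cohort: pd.DataFrame, censor_rate: float,
                    seed: int | None = None,
                    outcome: str = "lifespan_months") -> pd.DataFrame:
    """Flag a random ``censor_rate`` fraction as right-censored.

    Flagged animals get an independently drawn censoring time uniform on
    (0, event time); their recorded outcome becomes that censoring time.
    Downstream lifespan ICC analyses drop these rows.
    """
    if not (0.0 <= censor_rate < 1.0):
        raise ValueError("censor_rate must be in [0, 1)")
    out = cohort.copy()
    out.attrs = dict(cohort.attrs)
    if censor_rate == 0.0:
        return out
    rng = substream(seed, "censoring")
    flag = rng.random(len(out)) < censor_rate
    times = out[outcome].to_numpy(dtype=float, copy=True)
    times[flag] = rng.uniform(0.0, times[flag])
    out[outcome] = times
    out["censored"] = flag
    return out


def sample_longitudinal(structure: CageStructure,
                        icc_cage: float,
                        icc_animal: float,
                        ages: Sequence[float],
                        diet_effects: dict[str, float] | None = None,
                        residual_sd: float = 1.0,
                        age_slope: float = 0.0,
                        trait: str = "trait",
                        seed: int | None = None) -> pd.DataFrame:
    """Draw a two-level longitudinal phenotype table.

    value = diet effect + age_slope*age + cage intercept + animal intercept
    + noise, with the three random components holding variance shares
    icc_cage, icc_animal and 1-icc_cage-icc_animal of the total.
    ``residual_sd`` is the SD of the observation-level noise, so the total
    variance is residual_sd**2 / (1 - icc_cage - icc_animal).
    """
    if icc_cage < 0 or icc_animal < 0 or icc_cage + icc_animal >= 1:
        raise ValueError("variance shares must satisfy icc_cage, icc_animal >= 0 "
                         "and icc_cage + icc_animal < 1")
    if residual_sd <= 0:
        raise ValueError("residual_sd must be positive")
    ages = np.asarray(list(ages), dtype=float)
    if ages.size == 0:
        raise ValueError("need at least one age")

    sizes = np.asarray(structure.sizes, dtype=int)
    n_animals = structure.n_animals
    total_var = residual_sd ** 2 / (1.0 - icc_cage - icc_animal)
    sd_cage = np.sqrt(icc_cage * total_var)
    sd_animal = np.sqrt(icc_animal * total_var)

    rng = substream(seed, "longitudinal")
    cage_int = rng.normal(0.0, sd_cage, size=structure.n_cages)
    animal_int = rng.normal(0.0, sd_animal, size=n_animals)

    animal_ids = np.array([f"A{i:06d}" for i in range(n_animals)], dtype=object)
    cage_of_animal = np.repeat(np.asarray(structure.cage_ids, dtype=object), sizes)
    arm_of_animal = np.repeat(np.asarray(structure.arms, dtype=object), sizes)
    cage_int_of_animal = np.repeat(cage_int, sizes)

    T = ages.size
    n_rows = n_animals * T
    noise = rng.normal(0.0, residual_sd, size=n_rows)
    diet_effects = diet_effects or {}
    diet_shift = np.array([diet_effects.get(a, 0.0) for a in arm_of_animal])

    value = (np.repeat(diet_shift, T)
             + age_slope * np.tile(ages, n_animals)
             + np.repeat(cage_int_of_animal, T)
             + np.repeat(animal_int, T)
             + noise)
    df = pd.DataFrame({
        "animal_id": np.repeat(animal_ids, T),
        "cage_id": np.repeat(cage_of_animal, T),
        "diet": np.repeat(arm_of_animal, T),
        "age": np.tile(ages, n_animals),
        "trait": trait,
        "value": value,
    })
    df.attrs["icc_cage_truth"] = icc_cage
    df.attrs["icc_animal_truth"] = icc_animal
    return df
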