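"""The dilution model of pooled sequencing.

A heterozygous allele carried by one of N pooled individuals is diluted to an
expected allele fraction of 1/(2N) — 1/32 for the 16-sample pools the design
targets.  This module holds the arithmetic around that quantization: expected
allele fractions, the "relative coverage" scale (observed AF in multiples of
1/(2N)), maximum-likelihood estimation of the carrier-allele count c from read
counts, empirical concordance bands with outlier flagging, exact detection
power, pool-size design, and the pooled-vs-individual cost model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .models import DepthModel
from ._rng import rng_for

__all__ = [
    "DilutionParams",
    "ConcordanceBands",
    "Concordance",
    "CostInputs",
    "PoolDesign",
    "expected_af",
    "relative_coverage",
    "check_concordance",
    "estimate_carrier_count",
    "detection_power",
    "design_pool_size",
    "cost_fold_reduction",
]


@dataclass(frozen=True)
class DilutionParams:
    """Pool size N, carrier-allele count c, site depth D and error rate."""

    n: int
    c: int
    depth: int
    error_rate: float = 0.002

    def __post_init__(self) -> None:
        if not 0 <= self.c <= 2 * self.n:
            raise ValueError(f"carrier count {self.c} outside [0, {2 * self.n}]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


def expected_af(c: int, n: int) -> float:
    """Expected allele fraction of c carrier alleles diluted in a pool of n.

    c/(2n): 1/32 for a single het in a 16-sample pool, 2/32 for one hom or
    two hets.
    """
    if n < 1:
        raise ValueError("pool size must be >= 1")
    if not 0 <= c <= 2 * n:
        raise ValueError(f"carrier allele count {c} outside [0, {2 * n}]")
    return c / (2 * n)


def relative_coverage(alt_reads: int, depth: int, n: int) -> float:
    """Observed alt fraction on the relative-coverage scale (units of 1/(2n)).

    A single het in a 16-sample pool is expected at 1.0 on this scale
    ("1/32"); one hom or two hets at 2.0.
    """
    if depth <= 0:
        raise ValueError("relative coverage undefined at zero depth")
    return 2 * n * alt_reads / depth


class Concordance(str, Enum):
    CONSISTENT = "consistent"
    OUTLIER_HIGH = "outlier_high"
    OUTLIER_LOW = "outlier_low"


#: follow-up attached to any outlier verdict: sequence the whole pool
#: individually to test for additional carrier alleles.
OUTLIER_ACTION = "sequence_whole_pool"


@dataclass(frozen=True)
class ConcordanceBands:
    """Empirical relative-coverage bands for 1- and 2-allele pool variants.

    Defaults are the observed ranges for validated variants: hets fell in
    [0.56, 1.54]/32 and two-allele variants in [1.5, 2.3]/32; values outside
    are flagged as outliers and trigger whole-pool re-sequencing.
    """

    one_allele_band: tuple[float, float] = (0.56, 1.54)
    two_allele_band: tuple[float, float] = (1.5, 2.3)

    def __post_init__(self) -> None:
        for lo, hi in (self.one_allele_band, self.two_allele_band):
            if not lo < hi:
                raise ValueError("band lower bound must be below upper bound")

    def band(self, known_alleles: int) -> tuple[float, float]:
        if known_alleles == 1:
            return self.one_allele_band
        if known_alleles == 2:
            return self.two_allele_band
        raise ValueError(f"no band defined for {known_alleles} alleles")


def check_concordance(
    obs_rel_cov: float,
    known_alleles: int,
    bands: ConcordanceBands | None = None,
) -> Concordance:
    """Classify an observed relative coverage against the band for the known
    allele count; outliers carry the ``sequence_whole_pool`` follow-up."""
    bands = bands or ConcordanceBands()
    lo, hi = bands.band(known_alleles)
    if obs_rel_cov < lo:
        return Concordance.OUTLIER_LOW
    if obs_rel_cov > hi:
        return Concordance.OUTLIER_HIGH
    return Concordance.CONSISTENT


def _q_of_c(c: np.ndarray | int, n: int, error_rate: float) -> np.ndarray:
    """Expected alt-read probability for c carrier alleles with symmetric
    substitution error: q = f(1-e) + (1-f)e, f = c/(2n)."""
    f = np.asarray(c, dtype=float) / (2 * n)
    return f * (1.0 - error_rate) + (1.0 - f) * error_rate


def estimate_carrier_count(
    alt_reads: int,
    depth: int,
    n: int,
    error_rate: float = 0.002,
) -> tuple[int, np.ndarray]:
    """Maximum-likelihood carrier-allele count on the integer lattice 0..2n.

    The pooled alt count is modeled Binomial(depth, q(c)); the estimate is
    the argmax of the likelihood over c in {0..2n}, with ties broken toward
    smaller c (fewer carriers).  Returns (c_hat, per-c log-likelihoods) so
    callers can report near-ties.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= alt_reads <= depth:
        raise ValueError("alt_reads outside [0, depth]")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error rate must be in [0, 0.5)")
    c_grid = np.arange(2 * n + 1)
    q = _q_of_c(c_grid, n, error_rate)
    with np.errstate(divide="ignore"):
        loglik = stats.binom.logpmf(alt_reads, depth, q)
    c_hat = int(np.argmax(loglik))  # argmax returns the first (smallest) c on ties
    return c_hat, loglik


def _critical_alt_reads(depth: int, error_rate: float, alpha: float, min_alt_reads: int) -> int:
    """Smallest alt count whose one-sided binomial tail is <= alpha."""
    # sf(k-1) = P(X >= k); isf gives the smallest k with sf(k) <= alpha
    k = int(stats.binom.isf(alpha, depth, error_rate)) + 1
    # guard against isf edge rounding
    while k > 0 and stats.binom.sf(k - 2, depth, error_rate) <= alpha:
        k -= 1
    while stats.binom.sf(k - 1, depth, error_rate) > alpha:
        k += 1
    return max(k, min_alt_reads)


def _power_at_depth(
    depth: int, n: int, c: int, error_rate: float, alpha: float, min_depth: int, min_alt_reads: int
) -> float:
    if depth < min_depth or depth <= 0:
        return 0.0
    k = _critical_alt_reads(depth, error_rate, alpha, min_alt_reads)
    q = float(_q_of_c(c, n, error_rate))
    return float(stats.binom.sf(k - 1, depth, q))


def detection_power(
    n: int,
    c: int,
    depth_model: DepthModel | int,
    error_rate: float = 0.002,
    alpha: float = 1e-5,
    min_depth: int = 30,
    min_alt_reads: int = 3,
    n_monte_carlo: int = 2000,
    seed: int = 0,
) -> float:
    """Probability that a site with c carrier alleles in a pool of n passes
    both the depth floor and the level-alpha binomial test.

    ``depth_model`` may be a fixed pool depth (exact binomial tail sums) or a
    :class:`DepthModel` (power averaged over the lognormal per-amplicon depth
    distribution by seeded Monte Carlo).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 <= c <= 2 * n:
        raise ValueError(f"carrier count {c} outside [0, {2 * n}]")
    if isinstance(depth_model, (int, np.integer)):
        return _power_at_depth(int(depth_model), n, c, error_rate, alpha, min_depth, min_alt_reads)
    if depth_model.dispersion == 0:
        d = int(round(depth_model.mean_pool_depth(n)))
        return _power_at_depth(d, n, c, error_rate, alpha, min_depth, min_alt_reads)
    rng = rng_for(seed, "detection_power", f"N={n}", f"c={c}")
    mu = depth_model.mean_pool_depth(n)
    sigma = depth_model.dispersion
    depths = rng.lognormal(math.log(mu) - sigma**2 / 2.0, sigma, size=n_monte_carlo)
    vals = [
        _power_at_depth(int(round(d)), n, c, error_rate, alpha, min_depth, min_alt_reads)
        for d in depths
    ]
    return float(np.mean(vals))


@dataclass
class PoolDesign:
    """Result of a pool-size sweep: the recommendation (None when no pool size
    reaches the target power) and the full (N, power) table."""

    recommended_n: int | None
    table: pd.DataFrame  # columns: N, c, power


def design_pool_size(
    max_pool: int,
    target_power: float = 0.99,
    depth_model: DepthModel | None = None,
    error_rate: float = 0.002,
    alpha: float = 1e-5,
    hrm_batch_limit: int = 16,
    min_depth: int = 30,
    c: int = 1,
    seed: int = 0,
) -> PoolDesign:
    """Largest pool size N <= min(max_pool, hrm_batch_limit) whose single-
    allele detection power meets the target.

    The HRM batch limit reflects the downstream genotyping step: each pool is
    deconvoluted on one melt plate, so N cannot exceed the samples one assay
    batch can resolve (16 in the reference design).
    """
    if max_pool < 1:
        raise ValueError("max_pool must be >= 1")
    depth_model = depth_model or DepthModel()
    rows = []
    for n in range(1, min(max_pool, hrm_batch_limit) + 1):
        p = detection_power(
            n, c, depth_model, error_rate=error_rate, alpha=alpha, min_depth=min_depth, seed=seed
        )
        rows.append({"N": n, "c": c, "power": p})
    table = pd.DataFrame(rows)
    ok = table[table["power"] >= target_power]
    recommended = int(ok["N"].max()) if len(ok) else None
    return PoolDesign(recommended_n=recommended, table=table)


@dataclass
class CostInputs:
    """Per-patient cost components of the individual vs pooled workflows.

    The published prices behind the headline fold-reductions are not part of
    the toolkit; these defaults are placeholders meant to be overridden from a
    YAML config.
    """

    library_prep_cost_per_library: float = 250.0
    sequencing_cost_per_library: float = 550.0
    genotyping_cost_per_assay: float = 5.0
    assays_per_patient: float = 3.0
    fixed_cost_per_patient: float = 0.0

    def __post_init__(self) -> None:
        vals = (
            self.library_prep_cost_per_library,
            self.sequencing_cost_per_library,
            self.genotyping_cost_per_assay,
            self.assays_per_patient,
            self.fixed_cost_per_patient,
        )
        if any(v < 0 for v in vals):
            raise ValueError("cost inputs must be non-negative")


def cost_fold_reduction(costs: CostInputs, n: int) -> tuple[float, float]:
    """(sequencing_fold, overall_fold) of pooled over individual workflows.

    One library serves N patients in the pooled arm, so the per-patient
    library+sequencing share is divided by N; the overall fold additionally
    charges the pooled arm for the deconvolution genotyping assays and any
    fixed per-patient cost.
    """
    if n < 1:
        raise ValueError("pool size must be >= 1")
    lib_seq = costs.library_prep_cost_per_library + costs.sequencing_cost_per_library
    pooled_seq_share = lib_seq / n
    if pooled_seq_share <= 0:
        raise ValueError("pooled sequencing cost is zero; fold undefined")
    sequencing_fold = lib_seq / pooled_seq_share
    individual_total = lib_seq + costs.fixed_cost_per_patient
    pooled_total = (
        pooled_seq_share
        + costs.genotyping_cost_per_assay * costs.assays_per_patient
        + costs.fixed_cost_per_patient
    )
    overall_fold = individual_total / pooled_total
    return float(sequencing_fold), float(overall_fold)
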