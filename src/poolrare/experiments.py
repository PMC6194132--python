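"""Replicas of the two control spike-in sensitivity experiments.

Experiment 1 (pool-size titration): a nested series of pools of 4, 8 and 16
samples built from one set of control carriers — the 4-pool is a subset of
the 8-pool, which is a subset of the 16-pool — each sequenced and called
independently.

Experiment 2 (production design): 7 pools of 16 samples drawn from a
112-sample cohort in which 16 control samples carry 21 distinct rare
variants, at least 2 controls per pool.  Redetecting all 21 spiked variants
corresponds to 100% sensitivity.

Both run entirely on synthetic data at the study conditions (per-sample
depth 196, substitution error 0.002, equimolarity bias sigma 0.2) and
return per-pool detection detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .caller import CallerParams, call_pool
from .models import DepthModel, NoiseModel, PoolManifest, VariantKey
from .synthdata import build_pools, generate_cohort, generate_panel, simulate_pool_reads
from ._rng import subseed

__all__ = ["SpikeDetectionResult", "control_redetection_experiment", "nested_pool_experiment"]


@dataclass
class SpikeDetectionResult:
    """Spiked-variant redetection outcome of one experiment replica."""

    n_spiked: int  # spiked variant-in-pool instances evaluated
    n_detected: int  # instances with a PASS call in the carrier's pool
    per_pool: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def sensitivity_pct(self) -> float:
        return 100.0 * self.n_detected / self.n_spiked if self.n_spiked else 0.0


def _detect_in_pools(pools, cohort, panel, depth_model, noise, params, seed):
    per_pool: dict[str, tuple[int, int]] = {}
    n_spiked = n_detected = 0
    for pool in pools:
        counts = simulate_pool_reads(
            pool, cohort, panel, depth_model, noise, seed=subseed(seed, "reads", pool.pool_id)
        )
        calls = {
            VariantKey(c.chrom, c.pos, c.ref, c.alt): c
            for c in call_pool(counts, pool.n, params)
        }
        spiked_here = [
            k for k in cohort.variants if cohort.pool_allele_count(k, pool.members) > 0
        ]
        detected_here = sum(calls[k].passed for k in spiked_here)
        per_pool[pool.pool_id] = (len(spiked_here), detected_here)
        n_spiked += len(spiked_here)
        n_detected += detected_here
    return SpikeDetectionResult(n_spiked=n_spiked, n_detected=n_detected, per_pool=per_pool)


def control_redetection_experiment(
    seed: int,
    n_pools: int = 7,
    pool_size: int = 16,
    n_variants: int = 21,
    n_carrier_samples: int = 16,
    n_samples: int = 112,
    controls_per_pool: int = 2,
    depth_model: DepthModel | None = None,
    noise: NoiseModel | None = None,
    params: CallerParams | None = None,
    panel_genes: int = 24,
    amplicons_per_gene: int = 6,
) -> SpikeDetectionResult:
    """Production-design replica: 7 pools x 16 samples, 21 spiked variants."""
    depth_model = depth_model or DepthModel()
    noise = noise or NoiseModel()
    params = params or CallerParams(error_rate=noise.error_rate)
    panel = generate_panel(panel_genes, amplicons_per_gene, seed=subseed(seed, "panel"))
    genes = panel.genes
    spike = [(genes[i % len(genes)], "het", 1) for i in range(n_variants)]
    candidates = [f"S{i + 1:04d}" for i in range(n_carrier_samples)]
    cohort = generate_cohort(
        panel, n_samples, spike, seed=subseed(seed, "cohort"), carrier_candidates=candidates
    )
    pools = build_pools(cohort, pool_size, controls_per_pool, seed=subseed(seed, "pools"))
    assert len(pools) == n_pools
    return _detect_in_pools(pools, cohort, panel, depth_model, noise, params, seed)


def nested_pool_experiment(
    seed: int,
    pool_sizes: tuple[int, ...] = (4, 8, 16),
    n_controls: int = 13,
    depth_model: DepthModel | None = None,
    noise: NoiseModel | None = None,
    params: CallerParams | None = None,
    panel_genes: int = 16,
    amplicons_per_gene: int = 4,
) -> SpikeDetectionResult:
    """Pool-size titration replica: nested 4/8/16 pools over 13 control
    carriers, each carrying one previously validated variant."""
    depth_model = depth_model or DepthModel()
    noise = noise or NoiseModel()
    params = params or CallerParams(error_rate=noise.error_rate)
    panel = generate_panel(panel_genes, amplicons_per_gene, seed=subseed(seed, "panel"))
    genes = panel.genes
    n_samples = max(pool_sizes)
    spike = [(genes[i % len(genes)], "het", 1) for i in range(n_controls)]
    candidates = [f"S{i + 1:04d}" for i in range(n_controls)]
    cohort = generate_cohort(
        panel, n_samples, spike, seed=subseed(seed, "cohort"), carrier_candidates=candidates
    )
    pools = [
        PoolManifest(
            pool_id=f"nest{size:02d}",
            members=cohort.samples[:size],
            controls=[s for s in cohort.samples[:size] if s in set(cohort.carrier_samples())],
        )
        for size in pool_sizes
    ]
    return _detect_in_pools(pools, cohort, panel, depth_model, noise, params, seed)
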