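"""Synthetic data generation: panels, cohorts, pool manifests, pooled reads.

This module produces every input the rest of the toolkit consumes, emulating
the reference study design: targeted amplicon panels (~142 bp amplicons),
cohorts with spiked rare variants, pools of 4/8/16 samples with >=2 control
carriers each, and pooled read counts at ~196X per pooled sample with a
symmetric substitution error rate and lognormal equimolarity bias.

All operations are deterministic for a fixed seed; sub-streams are keyed by
pool and site identifiers so evaluation order never matters.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .models import (
    CohortGenotypes,
    DepthModel,
    Inheritance,
    NoiseModel,
    Panel,
    PanelRegion,
    PoolManifest,
    SiteReadCounts,
    VariantKey,
)
from ._rng import rng_for

__all__ = [
    "generate_panel",
    "generate_cohort",
    "build_pools",
    "simulate_pool_reads",
]

_CHROMS = [f"chr{i}" for i in range(1, 23)] + ["chrX"]


def generate_panel(
    n_genes: int,
    amplicons_per_gene: int,
    inheritance_mix: dict[Inheritance, float] | None = None,
    seed: int = 0,
    amplicon_length_range: tuple[int, int] = (100, 200),
) -> Panel:
    """Generate a toy amplicon panel of ``n_genes`` x ``amplicons_per_gene``.

    Genes are laid out on chr1..chrX with non-overlapping footprints;
    amplicons tile each gene with short random overlaps, lengths drawn
    uniformly from ``amplicon_length_range`` (reference design: ~142 bp
    mean, 316 genes over 7222 amplicons).  ``inheritance_mix`` gives the
    proportion of dominant/recessive/X-linked genes (default 25/65/10%,
    X-linked genes are placed on chrX).
    """
    if n_genes < 1 or amplicons_per_gene < 1:
        raise ValueError("n_genes and amplicons_per_gene must be >= 1")
    lo, hi = amplicon_length_range
    if not 0 < lo <= hi:
        raise ValueError("invalid amplicon length range")
    mix = inheritance_mix or {
        Inheritance.DOMINANT: 0.25,
        Inheritance.RECESSIVE: 0.65,
        Inheritance.X_LINKED: 0.10,
    }
    modes = list(mix)
    probs = np.asarray([mix[m] for m in modes], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("inheritance_mix proportions must sum to a positive value")
    probs = probs / probs.sum()

    rng = rng_for(seed, "generate_panel")
    regions: list[PanelRegion] = []
    # running cursor per chromosome keeps gene footprints disjoint
    cursor = {c: 10_000 for c in _CHROMS}
    autosomes = [c for c in _CHROMS if c != "chrX"]
    for g in range(n_genes):
        mode = modes[int(rng.choice(len(modes), p=probs))]
        chrom = "chrX" if mode == Inheritance.X_LINKED else autosomes[g % len(autosomes)]
        gene_id = f"GENE{g + 1:04d}"
        start = cursor[chrom]
        pos = start
        for _ in range(amplicons_per_gene):
            length = int(rng.integers(lo, hi + 1))
            regions.append(PanelRegion(gene_id, chrom, pos, pos + length, mode))
            # tile with a small overlap so adjacent amplicons share breakpoints
            overlap = int(rng.integers(0, min(30, length)))
            pos += length - overlap if amplicons_per_gene > 1 else length
        end = max(r.end for r in regions if r.gene_id == gene_id)
        cursor[chrom] = end + int(rng.integers(5_000, 20_000))
    return Panel(regions=regions)


def generate_cohort(
    panel: Panel,
    n_samples: int,
    spike_spec: Sequence[tuple[str, str, int]] = (),
    seed: int = 0,
    carrier_candidates: Sequence[str] | None = None,
) -> CohortGenotypes:
    """Generate a cohort of ``n_samples`` with spiked variants.

    ``spike_spec`` is a list of (gene, zygosity, n_carriers) requests; each
    request creates one distinct variant at a position inside the gene and
    assigns it to ``n_carriers`` samples at the requested zygosity ("het" or
    "hom").  Carriers cycle through a shuffled candidate list (all samples
    unless ``carrier_candidates`` restricts them, as when a fixed set of
    control samples carries every spike), so carriers are reused evenly when
    there are more spikes than candidates.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = rng_for(seed, "generate_cohort")
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    sex = {s: ("male" if rng.random() < 0.5 else "female") for s in samples}
    cohort = CohortGenotypes(samples=samples, sex=sex)

    candidates = list(carrier_candidates) if carrier_candidates is not None else list(samples)
    unknown = set(candidates) - set(samples)
    if unknown:
        raise ValueError(f"carrier candidates not in cohort: {sorted(unknown)}")
    order = list(rng.permutation(candidates))
    cursor = 0

    bases = np.array(["A", "C", "G", "T"])
    used_pos: set[tuple[str, int]] = set()
    for i, (gene, zygosity, n_carriers) in enumerate(spike_spec):
        if gene not in panel.genes:
            raise ValueError(f"spiked gene {gene!r} not in panel")
        if zygosity not in ("het", "hom"):
            raise ValueError(f"unknown zygosity {zygosity!r}")
        if n_carriers > len(candidates):
            raise ValueError(
                f"spike {i}: {n_carriers} carriers requested but only "
                f"{len(candidates)} candidate samples"
            )
        srng = rng_for(seed, "generate_cohort", f"spike{i}", gene)
        regs = panel.gene_regions(gene)
        reg = regs[int(srng.integers(0, len(regs)))]
        # draw a fresh 1-based position within the amplicon
        for _ in range(1000):
            pos1 = int(srng.integers(reg.start + 1, reg.end + 1))
            if (reg.chrom, pos1) not in used_pos:
                break
        used_pos.add((reg.chrom, pos1))
        ref, alt = srng.choice(bases, size=2, replace=False)
        key = VariantKey(reg.chrom, pos1, str(ref), str(alt))
        count = 1 if zygosity == "het" else 2
        calls: dict[str, int] = {}
        for _ in range(n_carriers):
            s = order[cursor % len(order)]
            cursor += 1
            c = count
            if reg.inheritance == Inheritance.X_LINKED and sex[s] == "male":
                c = min(c, 1)
            calls[s] = c
        cohort.genotypes[key] = calls
    return cohort


def build_pools(
    cohort: CohortGenotypes,
    pool_size: int,
    controls_per_pool: int = 2,
    seed: int = 0,
) -> list[PoolManifest]:
    """Partition the cohort into pools of ``pool_size``.

    Carrier (control) samples are dealt round-robin so every pool receives at
    least ``controls_per_pool`` controls when enough exist; remaining samples
    fill pools in shuffled order.  A final short pool is allowed when the
    cohort size is not a multiple of ``pool_size`` (reference design: 112
    samples -> 7 pools of 16, each with >=2 controls).
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if controls_per_pool > pool_size:
        raise ValueError("controls_per_pool cannot exceed pool_size")
    rng = rng_for(seed, "build_pools")
    controls = cohort.carrier_samples()
    others = [s for s in cohort.samples if s not in set(controls)]
    n_pools = math.ceil(len(cohort.samples) / pool_size)
    controls = list(rng.permutation(controls))
    others = list(rng.permutation(others))

    members: list[list[str]] = [[] for _ in range(n_pools)]
    ctl: list[list[str]] = [[] for _ in range(n_pools)]
    for i, s in enumerate(controls):
        p = i % n_pools
        if len(members[p]) < pool_size:
            members[p].append(s)
            ctl[p].append(s)
        else:
            others.append(s)
    for p in range(n_pools):
        while len(members[p]) < pool_size and others:
            members[p].append(others.pop())
    # any leftovers go into the last (short) pool slots
    for s in others:
        members[-1].append(s)
    return [
        PoolManifest(pool_id=f"pool{p + 1:02d}", members=members[p], controls=ctl[p])
        for p in range(n_pools)
        if members[p]
    ]


def simulate_pool_reads(
    pool: PoolManifest,
    cohort: CohortGenotypes,
    panel: Panel,
    depth_model: DepthModel | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> list[SiteReadCounts]:
    """Simulate pooled read counts at every cohort variant site.

    Each pool member contributes a lognormal DNA weight (renormalized to sum
    to 1) shared across all sites — imperfect equimolar pooling.  At a site
    with weighted carrier-allele fraction f, alt reads are Binomial(D, q)
    with q = f(1-e) + (1-f)e; sites with no carriers in this pool emit
    error-only counts.  Depth D is drawn per site from the depth model
    (mean 196 x N under the per-sample rule).
    """
    depth_model = depth_model or DepthModel()
    noise = noise or NoiseModel()
    missing = set(pool.members) - set(cohort.samples)
    if missing:
        raise ValueError(f"pool members not in cohort: {sorted(missing)}")

    n = pool.n
    wrng = rng_for(seed, "simulate_pool_reads", pool.pool_id, "weights")
    if noise.equimolar_bias_sigma > 0:
        sigma = noise.equimolar_bias_sigma
        w = wrng.lognormal(-(sigma**2) / 2.0, sigma, size=n)
    else:
        w = np.ones(n)
    w = w / w.sum()
    weight = dict(zip(pool.members, w))

    mu_depth = depth_model.mean_pool_depth(n)
    eps = noise.error_rate
    out: list[SiteReadCounts] = []
    for key in cohort.variants:
        srng = rng_for(seed, "simulate_pool_reads", pool.pool_id, str(key))
        if depth_model.dispersion > 0:
            d = int(
                round(
                    srng.lognormal(
                        math.log(mu_depth) - depth_model.dispersion**2 / 2.0,
                        depth_model.dispersion,
                    )
                )
            )
        else:
            d = int(round(mu_depth))
        d = max(d, 0)
        calls = cohort.genotypes.get(key, {})
        f = sum(weight[s] * calls.get(s, 0) for s in pool.members) / 2.0
        q = f * (1.0 - eps) + (1.0 - f) * eps
        alt = int(srng.binomial(d, q)) if d > 0 else 0
        out.append(
            SiteReadCounts(
                pool_id=pool.pool_id,
                chrom=key.chrom,
                pos=key.pos,
                ref=key.ref,
                alt=key.alt,
                depth=d,
                alt_reads=alt,
            )
        )
    return out
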