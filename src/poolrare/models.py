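"""Core domain types shared across the toolkit.

Coordinates are 0-based half-open internally (``PanelRegion.start``/``end``);
variant positions (``VariantKey.pos``) and every TSV/VCF emission are 1-based,
matching VCF convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping


class Inheritance(str, Enum):
    """Mendelian inheritance mode of a gene."""

    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    X_LINKED = "x_linked"


@dataclass(frozen=True, order=True)
class VariantKey:
    """A variant site identified by (chrom, 1-based pos, ref, alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class PanelRegion:
    """One amplicon of the targeted panel (0-based half-open interval)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    inheritance: Inheritance = Inheritance.RECESSIVE

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty region for {self.gene_id}: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos1: int) -> bool:
        """Whether a 1-based position falls inside this amplicon."""
        return chrom == self.chrom and self.start < pos1 <= self.end


@dataclass
class Panel:
    """An amplicon panel: a list of regions with per-gene inheritance labels."""

    regions: list[PanelRegion]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.gene_id, None)
        return list(seen)

    def gene_inheritance(self, gene_id: str) -> Inheritance:
        for r in self.regions:
            if r.gene_id == gene_id:
                return r.inheritance
        raise KeyError(gene_id)

    def gene_span(self, gene_id: str) -> tuple[str, int, int]:
        """(chrom, start, end) footprint of a gene's amplicons, 0-based half-open."""
        regs = [r for r in self.regions if r.gene_id == gene_id]
        if not regs:
            raise KeyError(gene_id)
        chrom = regs[0].chrom
        return chrom, min(r.start for r in regs), max(r.end for r in regs)

    def gene_regions(self, gene_id: str) -> list[PanelRegion]:
        return [r for r in self.regions if r.gene_id == gene_id]

    def region_at(self, chrom: str, pos1: int) -> PanelRegion | None:
        """First amplicon containing a 1-based position, or None."""
        for r in self.regions:
            if r.contains(chrom, pos1):
                return r
        return None

    def gene_at(self, chrom: str, pos1: int) -> str | None:
        r = self.region_at(chrom, pos1)
        return None if r is None else r.gene_id


@dataclass
class CohortGenotypes:
    """Per-sample allele counts for every variant segregating in a cohort.

    ``genotypes`` is sparse: a missing (variant, sample) cell means allele
    count 0.  Allele counts are in {0, 1, 2}; males carry at most 1 allele of
    an X-linked variant.
    """

    samples: list[str]
    genotypes: dict[VariantKey, dict[str, int]] = field(default_factory=dict)
    sex: dict[str, str] = field(default_factory=dict)  # sample -> "male"/"female"

    @property
    def variants(self) -> list[VariantKey]:
        return sorted(self.genotypes)

    def allele_count(self, sample: str, key: VariantKey) -> int:
        return self.genotypes.get(key, {}).get(sample, 0)

    def carriers(self, key: VariantKey) -> dict[str, int]:
        return {s: c for s, c in self.genotypes.get(key, {}).items() if c > 0}

    def carrier_samples(self) -> list[str]:
        """Samples carrying at least one non-reference allele, in cohort order."""
        hit = {s for calls in self.genotypes.values() for s, c in calls.items() if c > 0}
        return [s for s in self.samples if s in hit]

    def pool_allele_count(self, key: VariantKey, members: Iterable[str]) -> int:
        calls = self.genotypes.get(key, {})
        return sum(calls.get(s, 0) for s in members)


@dataclass
class PoolManifest:
    """Membership of one sequencing pool."""

    pool_id: str
    members: list[str]
    controls: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate samples in pool {self.pool_id}")
        if not set(self.controls) <= set(self.members):
            raise ValueError(f"controls not a subset of members in pool {self.pool_id}")

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SiteReadCounts:
    """Observed pooled read counts at one site."""

    pool_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_reads: int

    def __post_init__(self) -> None:
        if not 0 <= self.alt_reads <= self.depth:
            raise ValueError(
                f"alt_reads {self.alt_reads} outside [0, depth={self.depth}] at "
                f"{self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class DepthModel:
    """Per-amplicon sequencing-depth model.

    ``per_sample_mean_depth`` is the mean depth contributed per pooled
    individual (default 196 reads); under the ``per_sample_times_N`` rule a
    pool of N samples is sequenced to ~196*N at each amplicon.  Depth varies
    between amplicons as a lognormal with sigma ``dispersion`` around that
    mean.  The ``fixed_pool_depth`` rule instead sequences every pool to the
    same total depth regardless of N.
    """

    per_sample_mean_depth: float = 196.0
    dispersion: float = 0.35
    pool_depth_rule: str = "per_sample_times_N"  # or "fixed_pool_depth"
    fixed_pool_depth: float = 196.0

    def __post_init__(self) -> None:
        if self.per_sample_mean_depth <= 0:
            raise ValueError("mean depth must be positive")
        if self.pool_depth_rule not in ("per_sample_times_N", "fixed_pool_depth"):
            raise ValueError(f"unknown pool_depth_rule {self.pool_depth_rule!r}")

    def mean_pool_depth(self, n: int) -> float:
        if self.pool_depth_rule == "per_sample_times_N":
            return self.per_sample_mean_depth * n
        return self.fixed_pool_depth


@dataclass
class NoiseModel:
    """Sequencing-noise model for pooled read counts.

    ``error_rate`` is the per-base probability of reading the specific alt
    allele at a reference position.  ``equimolar_bias_sigma`` is the lognormal
    sigma of each sample's DNA contribution to the pool (weights renormalized
    to sum to 1), emulating imperfect equimolar pooling.
    """

    error_rate: float = 0.002
    equimolar_bias_sigma: float = 0.20

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.equimolar_bias_sigma < 0:
            raise ValueError("equimolar_bias_sigma must be >= 0")
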