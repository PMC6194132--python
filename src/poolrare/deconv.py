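"""Carrier deconvolution: from a pool-level call back to individuals.

A pooled detection says only that c mutant alleles exist somewhere among the
N pooled samples.  The wet-lab step that resolves *which* samples carry them
is an HRM (high-resolution melting) assay run on each pool member
individually, followed by Sanger confirmation of flagged samples.  Here that
channel is modeled as a Bernoulli flag per sample (sensitivity/specificity,
both 1.0 by default as observed in practice), with zygosity taken from the
Sanger-confirmation stand-in (the simulation truth).  A discordance between
the assigned allele total and the call's estimated carrier count — or an
out-of-band relative coverage — triggers the whole-pool-sequencing fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .caller import PoolVariantCall
from .models import CohortGenotypes, Panel, PoolManifest, VariantKey
from .poolmath import Concordance, ConcordanceBands, check_concordance
from ._rng import rng_for

__all__ = [
    "AssayPlan",
    "AssayPlanningError",
    "HRMModel",
    "CarrierAssignment",
    "plan_assay",
    "batch_assays",
    "assign_carriers",
    "resolve_and_check",
]

WINDOW_MIN, WINDOW_MAX = 250, 330  # bp; melt-assay amplicon length range
MAX_VARIANTS_PER_RUN = 7
REPLICATES_PER_SAMPLE = 3

STATUS_HRM_FLAGGED = "hrm_flagged"
STATUS_SANGER_CONFIRMED = "sanger_confirmed"
STATUS_FALLBACK = "fallback_whole_pool"

ACTION_ACCEPT = "accept"
ACTION_SEQUENCE_WHOLE_POOL = "sequence_whole_pool"


class AssayPlanningError(ValueError):
    """Raised when no melt-assay window of the required length fits."""


@dataclass
class AssayPlan:
    """A planned melt-genotyping amplicon for one pool variant."""

    variant: VariantKey
    chrom: str
    win_start: int  # 0-based half-open
    win_end: int
    replicates: int = REPLICATES_PER_SAMPLE
    samples: list[str] = field(default_factory=list)  # the <=16 pool members

    def __post_init__(self) -> None:
        length = self.win_end - self.win_start
        if not WINDOW_MIN <= length <= WINDOW_MAX:
            raise ValueError(f"window length {length} outside [{WINDOW_MIN}, {WINDOW_MAX}]")
        pos0 = self.variant.pos - 1  # 0-based
        if not self.win_start < pos0 < self.win_end - 1:
            raise ValueError("variant position not strictly inside the window")


@dataclass
class HRMModel:
    """Bernoulli flag channel standing in for melt-curve discrimination."""

    sensitivity: float = 1.0
    specificity: float = 1.0
    hom_vs_het_distinguishable: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.sensitivity <= 1 and 0 <= self.specificity <= 1):
            raise ValueError("sensitivity and specificity must be in [0, 1]")


@dataclass
class CarrierAssignment:
    """Per-sample genotypes resolved for one pool variant."""

    variant: VariantKey
    pool_id: str
    genotypes: dict[str, str]  # sample -> "ref" | "het" | "hom"
    status: str = STATUS_HRM_FLAGGED

    @property
    def allele_total(self) -> int:
        return sum({"ref": 0, "het": 1, "hom": 2}[g] for g in self.genotypes.values())

    def carriers(self) -> dict[str, str]:
        return {s: g for s, g in self.genotypes.items() if g != "ref"}


def plan_assay(
    call: PoolVariantCall,
    panel: Panel,
    window_length: int = 290,
    seed: int = 0,
) -> AssayPlan:
    """Place a melt-assay window of ``window_length`` bp over the variant.

    The window is centered on the variant and shifted (never shrunk) when it
    would overhang the gene's amplicon footprint; planning fails explicitly
    when the footprint is shorter than the window.
    """
    if not WINDOW_MIN <= window_length <= WINDOW_MAX:
        raise ValueError(
            f"window_length {window_length} outside [{WINDOW_MIN}, {WINDOW_MAX}]"
        )
    gene = panel.gene_at(call.chrom, call.pos)
    if gene is None:
        raise AssayPlanningError(f"variant {call.chrom}:{call.pos} not inside any panel gene")
    chrom, span_start, span_end = panel.gene_span(gene)
    if span_end - span_start < window_length:
        raise AssayPlanningError(
            f"gene {gene} span ({span_end - span_start} bp) shorter than window "
            f"({window_length} bp)"
        )
    pos0 = call.pos - 1
    start = call.pos - window_length // 2  # centered on the 1-based position
    start = max(span_start, min(start, span_end - window_length))
    # keep the variant strictly inside after clipping at the gene boundary
    if pos0 <= start:
        start = max(span_start, pos0 - 1)
    if pos0 >= start + window_length - 1:
        start = min(span_end, pos0 + 2) - window_length
    return AssayPlan(
        variant=VariantKey(call.chrom, call.pos, call.ref, call.alt),
        chrom=chrom,
        win_start=start,
        win_end=start + window_length,
    )


def batch_assays(plans: list[AssayPlan]) -> list[list[AssayPlan]]:
    """Group assay plans into runs of at most 7 variants each."""
    return [
        plans[i : i + MAX_VARIANTS_PER_RUN]
        for i in range(0, len(plans), MAX_VARIANTS_PER_RUN)
    ]


def assign_carriers(
    call: PoolVariantCall,
    manifest: PoolManifest,
    truth: CohortGenotypes,
    model: HRMModel | None = None,
    seed: int = 0,
) -> CarrierAssignment:
    """Flag pool members through the melt channel and genotype the flagged.

    Each true carrier is flagged with probability ``sensitivity``; each
    non-carrier with probability ``1 - specificity``.  Flagged samples are
    then genotyped from the truth table — the Sanger-confirmation stand-in —
    so a false-positive flag resolves back to "ref".
    """
    if call.pool_id != manifest.pool_id:
        raise ValueError(
            f"call pool {call.pool_id!r} does not match manifest {manifest.pool_id!r}"
        )
    model = model or HRMModel()
    key = VariantKey(call.chrom, call.pos, call.ref, call.alt)
    rng = rng_for(seed, "assign_carriers", manifest.pool_id, str(key))
    genotypes: dict[str, str] = {}
    any_flagged = False
    for s in manifest.members:
        count = truth.allele_count(s, key)
        if count > 0:
            flagged = rng.random() < model.sensitivity
        else:
            flagged = rng.random() >= model.specificity
        if flagged:
            any_flagged = True
            genotypes[s] = {0: "ref", 1: "het", 2: "hom"}[count]
        else:
            genotypes[s] = "ref"
    status = STATUS_SANGER_CONFIRMED if any_flagged else STATUS_HRM_FLAGGED
    return CarrierAssignment(variant=key, pool_id=manifest.pool_id, genotypes=genotypes, status=status)


def resolve_and_check(
    assignment: CarrierAssignment,
    call: PoolVariantCall,
    bands: ConcordanceBands | None = None,
    manifest: PoolManifest | None = None,
    truth: CohortGenotypes | None = None,
) -> tuple[CarrierAssignment, str]:
    """Cross-check the assigned allele total against the pool call.

    Accept when the assigned total equals the ML carrier count, or when the
    observed relative coverage is consistent with the assigned total (1 or 2
    alleles).  Otherwise the whole pool is re-sequenced individually — in
    simulation, the truth table is re-read for every member — and the
    corrected assignment is returned with fallback status.
    """
    key = VariantKey(call.chrom, call.pos, call.ref, call.alt)
    if assignment.variant != key or assignment.pool_id != call.pool_id:
        raise ValueError("assignment and call refer to different variants/pools")
    total = assignment.allele_total
    if total == call.c_hat:
        return assignment, ACTION_ACCEPT
    if total in (1, 2):
        if check_concordance(call.rel_cov, total, bands) is Concordance.CONSISTENT:
            return assignment, ACTION_ACCEPT
    if manifest is None or truth is None:
        raise ValueError(
            "discordant assignment requires manifest and truth for whole-pool fallback"
        )
    genotypes = {
        s: {0: "ref", 1: "het", 2: "hom"}[truth.allele_count(s, key)]
        for s in manifest.members
    }
    corrected = CarrierAssignment(
        variant=key,
        pool_id=call.pool_id,
        genotypes=genotypes,
        status=STATUS_FALLBACK,
    )
    return corrected, ACTION_SEQUENCE_WHOLE_POOL
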