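"""Variant prioritization and inheritance-aware case resolution.

Candidate variants are retained when they satisfy any of five pre-established
criteria — previously reported pathogenic; novel loss-of-function; novel
splicing; reported missense with in-silico support; novel missense predicted
damaging by at least five predictors — AND pass the population filters:
gnomAD MAF < 0.001 and absence from the national variant server (CSVS) for
dominant genes, MAF < 0.003 and never-homozygous in CSVS for recessive genes.

Case resolution then applies the inheritance-specific allele quota: a
recessive gene needs two pathogenic alleles (a homozygote or a compound
heterozygote), a dominant gene one allele with confirmed family segregation,
an X-linked male one hemizygous allele.  Failed segregation or an
unresolvable digenic combination caps the verdict at VUS; everything else
with an unmet quota is UNSOLVED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .models import Inheritance

__all__ = [
    "VariantAnnotation",
    "PatientVariant",
    "PatientVariants",
    "CaseResolution",
    "classify_variant",
    "insilico_consensus",
    "resolve_case",
    "detection_rate",
    "novel_fraction",
]

# retention tiers, mirroring the five selection criteria
TIER_KNOWN_PATHOGENIC = "known_pathogenic"
TIER_LOF_NOVEL = "lof_novel"
TIER_SPLICE_NOVEL = "splice_novel"
TIER_MISSENSE_REPORTED = "missense_reported"
TIER_MISSENSE_NOVEL_PREDICTED = "missense_novel_predicted"
TIER_REJECTED = "rejected"

LOF_CONSEQUENCES = {"nonsense", "frameshift"}
CONSEQUENCES = {
    "nonsense",
    "frameshift",
    "splice_site",
    "missense",
    "inframe_indel",
    "synonymous",
    "intronic",
    "other",
}

MAF_DOMINANT = 0.001
MAF_RECESSIVE = 0.003

SOLVED, VUS, UNSOLVED = "SOLVED", "VUS", "UNSOLVED"


@dataclass
class VariantAnnotation:
    """Annotation consumed by the prioritization rules.

    Predictor verdicts are precomputed externally (SIFT, PolyPhen-2,
    PROVEAN, GVGD, MutationTaster class tools); a missing MAF means the
    variant is absent from the aggregation database and is treated as 0.
    """

    variant_id: str
    gene: str
    inheritance: Inheritance
    consequence: str
    known_pathogenic: bool = False
    gnomad_maf: float | None = None
    csvs_status: str = "absent"  # absent | het_only | hom_observed
    predictor_verdicts: Sequence[str] = ()  # "damaging" / "tolerated"
    novel: bool = False

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.csvs_status not in ("absent", "het_only", "hom_observed"):
            raise ValueError(f"unknown csvs_status {self.csvs_status!r}")
        if self.gnomad_maf is not None and not 0 <= self.gnomad_maf <= 1:
            raise ValueError("gnomad_maf must be in [0, 1]")
        if len(self.predictor_verdicts) > 5:
            raise ValueError("at most 5 predictor verdicts supported")

    @property
    def maf(self) -> float:
        return 0.0 if self.gnomad_maf is None else self.gnomad_maf


def insilico_consensus(verdicts: Iterable[str], k_required: int = 5) -> bool:
    """True when at least ``k_required`` predictors call the variant damaging.

    The default of 5 requires unanimity across the five predictors used.
    """
    if k_required < 1:
        raise ValueError("k_required must be >= 1")
    return sum(1 for v in verdicts if v == "damaging") >= k_required


def _population_filters_pass(ann: VariantAnnotation) -> bool:
    if ann.inheritance == Inheritance.DOMINANT:
        return ann.csvs_status == "absent" and ann.maf < MAF_DOMINANT
    if ann.inheritance in (Inheritance.RECESSIVE, Inheritance.X_LINKED):
        return ann.maf < MAF_RECESSIVE and ann.csvs_status != "hom_observed"
    raise ValueError(f"unknown inheritance {ann.inheritance!r}")


def classify_variant(ann: VariantAnnotation, k_required: int = 5) -> tuple[bool, str]:
    """(retained, tier) for one annotated variant.

    A variant is retained when any selection criterion holds and the
    population-frequency filters for its gene's inheritance mode pass.
    """
    if not isinstance(ann.inheritance, Inheritance):
        raise ValueError(f"unknown inheritance label {ann.inheritance!r}")
    if not _population_filters_pass(ann):
        return False, TIER_REJECTED
    if ann.known_pathogenic:
        return True, TIER_KNOWN_PATHOGENIC
    if ann.novel and ann.consequence in LOF_CONSEQUENCES:
        return True, TIER_LOF_NOVEL
    if ann.novel and ann.consequence == "splice_site":
        return True, TIER_SPLICE_NOVEL
    if ann.consequence == "missense":
        if not ann.novel and insilico_consensus(ann.predictor_verdicts, k_required=1):
            return True, TIER_MISSENSE_REPORTED
        if ann.novel and insilico_consensus(ann.predictor_verdicts, k_required=k_required):
            return True, TIER_MISSENSE_NOVEL_PREDICTED
    return False, TIER_REJECTED


@dataclass
class PatientVariant:
    """One variant observed in a patient, with zygosity and annotation."""

    annotation: VariantAnnotation
    zygosity: str  # het | hom | hemizygous

    def __post_init__(self) -> None:
        if self.zygosity not in ("het", "hom", "hemizygous"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")

    @property
    def allele_count(self) -> int:
        return {"het": 1, "hom": 2, "hemizygous": 1}[self.zygosity]


@dataclass
class PatientVariants:
    """A patient's candidate variants plus the family-segregation outcome."""

    patient_id: str
    sex: str  # male | female
    variants: list[PatientVariant]
    segregation: str = "not_available"  # yes | no | not_available

    def __post_init__(self) -> None:
        if self.segregation not in ("yes", "no", "not_available"):
            raise ValueError(f"unknown segregation {self.segregation!r}")


@dataclass
class CaseResolution:
    """Per-patient verdict with the retained variants and a rationale code."""

    patient_id: str
    verdict: str
    retained: list[PatientVariant] = field(default_factory=list)
    rationale: str = ""


def resolve_case(
    pv: PatientVariants,
    k_required: int = 5,
    digenic_pairs: set[frozenset[str]] | None = None,
) -> CaseResolution:
    """Resolve one patient to SOLVED / VUS / UNSOLVED.

    Allele quota per gene: recessive >= 2 (hom or compound het), dominant
    >= 1 with segregation confirmed, X-linked male >= 1 hemizygous.
    Segregation "no" on a quota-meeting gene caps at VUS; a whitelisted cross-gene
    (digenic) het pair also caps at VUS.  Compound hets without segregation
    data are provisionally SOLVED with rationale "phase_unconfirmed".
    """
    retained: list[PatientVariant] = []
    for v in pv.variants:
        keep, _tier = classify_variant(v.annotation, k_required=k_required)
        if keep:
            retained.append(v)
    if not retained:
        return CaseResolution(pv.patient_id, UNSOLVED, [], "no_retained_variants")

    by_gene: dict[str, list[PatientVariant]] = {}
    for v in retained:
        by_gene.setdefault(v.annotation.gene, []).append(v)

    candidates: list[CaseResolution] = []
    for gene in sorted(by_gene):
        vs = by_gene[gene]
        inh = vs[0].annotation.inheritance
        alleles = sum(v.allele_count for v in vs)
        if inh == Inheritance.RECESSIVE:
            if alleles >= 2:
                if pv.segregation == "no":
                    candidates.append(
                        CaseResolution(pv.patient_id, VUS, vs, "segregation_failed")
                    )
                else:
                    compound = len(vs) >= 2
                    rationale = (
                        "recessive_biallelic_phase_unconfirmed"
                        if compound and pv.segregation == "not_available"
                        else "recessive_biallelic"
                    )
                    candidates.append(CaseResolution(pv.patient_id, SOLVED, vs, rationale))
        elif inh == Inheritance.DOMINANT:
            if alleles >= 1:
                if pv.segregation == "yes":
                    candidates.append(
                        CaseResolution(pv.patient_id, SOLVED, vs, "dominant_segregating")
                    )
                else:
                    rationale = (
                        "segregation_failed"
                        if pv.segregation == "no"
                        else "segregation_unavailable"
                    )
                    candidates.append(CaseResolution(pv.patient_id, VUS, vs, rationale))
        elif inh == Inheritance.X_LINKED:
            quota = 1 if pv.sex == "male" else 2
            if alleles >= quota:
                if pv.segregation == "no":
                    candidates.append(
                        CaseResolution(pv.patient_id, VUS, vs, "segregation_failed")
                    )
                else:
                    candidates.append(
                        CaseResolution(pv.patient_id, SOLVED, vs, "x_linked_hemizygous")
                    )
    for verdict in (SOLVED, VUS):
        for cand in candidates:
            if cand.verdict == verdict:
                return cand

    # no single gene meets its quota: consider whitelisted digenic pairs
    if digenic_pairs:
        genes = set(by_gene)
        for pair in digenic_pairs:
            if pair <= genes:
                vs = [v for g in sorted(pair) for v in by_gene[g]]
                return CaseResolution(pv.patient_id, VUS, vs, "digenic_candidate")

    return CaseResolution(pv.patient_id, UNSOLVED, retained, "allele_quota_not_met")


def detection_rate(resolutions: Iterable[CaseResolution], cohort_size: int) -> float:
    """Diagnostic yield: 100 x SOLVED / cohort size, to one decimal.

    36 solved of 115 probands gives the headline 31.3%.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    solved = sum(1 for r in resolutions if r.verdict == SOLVED)
    if solved > cohort_size:
        raise ValueError("more solved cases than cohort members")
    return round(100.0 * solved / cohort_size, 1)


def novel_fraction(
    resolutions: Iterable[CaseResolution] | None = None,
    n_causative: int | None = None,
    n_novel: int | None = None,
) -> tuple[int, int, float]:
    """(n_causative, n_novel, percentage) of first-described mutations among
    the causative mutations of solved patients.

    Counts distinct (gene, variant) mutations across SOLVED resolutions when
    given resolutions; explicit counts may be supplied instead when the
    counting convention is fixed externally (e.g. 49 causative / 14 novel
    -> 28.6%).
    """
    if resolutions is not None:
        causative: set[tuple[str, str]] = set()
        novel: set[tuple[str, str]] = set()
        for r in resolutions:
            if r.verdict != SOLVED:
                continue
            for v in r.retained:
                key = (v.annotation.gene, v.annotation.variant_id)
                causative.add(key)
                if v.annotation.novel:
                    novel.add(key)
        n_causative, n_novel = len(causative), len(novel)
    if n_causative is None or n_novel is None:
        raise ValueError("either resolutions or explicit counts are required")
    pct = 0.0 if n_causative == 0 else round(100.0 * n_novel / n_causative, 1)
    return n_causative, n_novel, pct
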