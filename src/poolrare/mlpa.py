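"""Exon-level CNV calling from MLPA peak tables.

MLPA (multiplex ligation-dependent probe amplification) measures the copy
number of individual exons via probe peak heights.  Each sample's peaks are
normalized to its own control probes, then divided by the median of the same
ratio across reference samples, giving a dosage quotient (DQ) of ~1.0 at two
copies, ~0.5 for a heterozygous deletion and ~1.5 for a duplication.
Contiguous non-normal exons are merged into spans — e.g. a heterozygous
deletion of PRPF31 exons 9-13 appears as five ~0.5 DQ probes merged into one
"exons 9-13" deletion span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import rng_for

__all__ = [
    "MlpaPeakTable",
    "DosageCall",
    "CnvSpan",
    "normalize_dosage",
    "call_cnv",
    "merge_spans",
    "synthetic_peak_table",
]

DEL_THRESHOLD = 0.65
DUP_THRESHOLD = 1.35


@dataclass
class MlpaPeakTable:
    """Peak heights of one sample over a probemix.

    ``probes`` columns: probe_id, gene, exon (nullable Int64), is_control,
    height.  At least two control probes are required and all heights must
    be positive.
    """

    sample_id: str
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "gene", "exon", "is_control", "height"}
        missing = required - set(self.probes.columns)
        if missing:
            raise ValueError(f"peak table missing columns: {sorted(missing)}")
        if (self.probes["height"] <= 0).any():
            raise ValueError("peak heights must be positive")
        if int(self.probes["is_control"].sum()) < 2:
            raise ValueError("at least 2 control probes required")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.probes["probe_id"])

    def control_mean(self) -> float:
        return float(self.probes.loc[self.probes["is_control"], "height"].mean())


@dataclass(frozen=True)
class DosageCall:
    """Dosage-quotient verdict for one exon probe."""

    probe_id: str
    gene: str
    exon: int
    dq: float
    status: str  # normal | deletion | duplication
    low_confidence: bool = False  # single-probe aberrations are flagged downstream


@dataclass(frozen=True)
class CnvSpan:
    """A maximal run of equal-status aberrant exons (endpoints inclusive)."""

    gene: str
    first_exon: int
    last_exon: int
    status: str

    @property
    def n_exons(self) -> int:
        return self.last_exon - self.first_exon + 1


def normalize_dosage(
    test: MlpaPeakTable, references: list[MlpaPeakTable]
) -> pd.Series:
    """Per-probe dosage quotient of a test sample against references.

    DQ(probe) = (test height / mean test control height) divided by the
    median across references of (ref height / mean ref control height).
    Control probes come out at ~1 by construction; the whole statistic is
    invariant to rescaling any sample's heights.
    """
    if not references:
        raise ValueError("at least one reference sample required")
    probe_ids = test.probe_ids
    for ref in references:
        if ref.probe_ids != probe_ids:
            raise ValueError(
                f"probe set of reference {ref.sample_id!r} does not match test sample"
            )
    t = test.probes.set_index("probe_id")["height"] / test.control_mean()
    ref_ratios = pd.DataFrame(
        {
            ref.sample_id: ref.probes.set_index("probe_id")["height"] / ref.control_mean()
            for ref in references
        }
    )
    dq = t / ref_ratios.median(axis=1)
    dq.name = "DQ"
    return dq


def call_cnv(
    dq: pd.Series,
    probes: pd.DataFrame,
    del_threshold: float = DEL_THRESHOLD,
    dup_threshold: float = DUP_THRESHOLD,
) -> list[DosageCall]:
    """Per-probe CNV status from dosage quotients.

    Thresholds default to common MLPA practice (deletion below 0.65,
    duplication above 1.35).  Control probes are excluded from CNV status.
    """
    if not 0 < del_threshold < 1 < dup_threshold:
        raise ValueError("thresholds must satisfy 0 < del < 1 < dup")
    meta = probes.set_index("probe_id")
    calls: list[DosageCall] = []
    for probe_id, value in dq.items():
        row = meta.loc[probe_id]
        if bool(row["is_control"]):
            continue
        if value < del_threshold:
            status = "deletion"
        elif value > dup_threshold:
            status = "duplication"
        else:
            status = "normal"
        calls.append(
            DosageCall(
                probe_id=str(probe_id),
                gene=str(row["gene"]),
                exon=int(row["exon"]),
                dq=float(value),
                status=status,
            )
        )
    # a single isolated aberrant probe is reported but flagged low-confidence
    flagged: list[DosageCall] = []
    by_gene: dict[str, list[DosageCall]] = {}
    for c in calls:
        by_gene.setdefault(c.gene, []).append(c)
    for gene_calls in by_gene.values():
        gene_calls.sort(key=lambda c: c.exon)
        for i, c in enumerate(gene_calls):
            if c.status == "normal":
                flagged.append(c)
                continue
            prev_same = i > 0 and gene_calls[i - 1].status == c.status and gene_calls[i - 1].exon == c.exon - 1
            next_same = (
                i + 1 < len(gene_calls)
                and gene_calls[i + 1].status == c.status
                and gene_calls[i + 1].exon == c.exon + 1
            )
            if not (prev_same or next_same):
                c = DosageCall(c.probe_id, c.gene, c.exon, c.dq, c.status, low_confidence=True)
            flagged.append(c)
    flagged.sort(key=lambda c: (c.gene, c.exon))
    return flagged


def merge_spans(calls: list[DosageCall]) -> list[CnvSpan]:
    """Merge maximal runs of consecutive equal-status aberrant exons."""
    spans: list[CnvSpan] = []
    by_gene: dict[str, list[DosageCall]] = {}
    for c in calls:
        by_gene.setdefault(c.gene, []).append(c)
    for gene in sorted(by_gene):
        run: list[DosageCall] = []
        for c in sorted(by_gene[gene], key=lambda c: c.exon):
            if c.status == "normal":
                if run:
                    spans.append(CnvSpan(gene, run[0].exon, run[-1].exon, run[0].status))
                    run = []
                continue
            if run and (c.status != run[-1].status or c.exon != run[-1].exon + 1):
                spans.append(CnvSpan(gene, run[0].exon, run[-1].exon, run[0].status))
                run = []
            run.append(c)
        if run:
            spans.append(CnvSpan(gene, run[0].exon, run[-1].exon, run[0].status))
    return spans


def synthetic_peak_table(
    probes: pd.DataFrame,
    sample_id: str,
    deletions: dict[str, tuple[int, int]] | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
    base_height: float = 1000.0,
) -> MlpaPeakTable:
    """Simulate a peak table over a probemix definition.

    ``deletions`` maps gene -> (first_exon, last_exon) heterozygous deletion
    (heights halved on those probes); multiplicative lognormal noise with
    coefficient of variation ``noise_cv`` emulates capillary run variation.
    """
    deletions = deletions or {}
    rng = rng_for(seed, "synthetic_peak_table", sample_id)
    heights = []
    for _, row in probes.iterrows():
        h = base_height
        gene = row["gene"]
        if not row["is_control"] and gene in deletions:
            lo, hi = deletions[gene]
            if lo <= int(row["exon"]) <= hi:
                h *= 0.5
        if noise_cv > 0:
            sigma = float(np.sqrt(np.log1p(noise_cv**2)))
            h *= rng.lognormal(-(sigma**2) / 2.0, sigma)
        heights.append(h)
    out = probes.copy()
    out["height"] = heights
    return MlpaPeakTable(sample_id=sample_id, probes=out)
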