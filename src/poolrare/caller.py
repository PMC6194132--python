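"""Pool-aware low-allele-fraction variant calling.

A variant carried by one allele in a 16-sample pool sits at an expected
fraction of 1/32 — far below a diploid het — so pooled calls are made in
"somatic" style: each site is tested against the sequencing-error null with
a one-sided exact binomial tail, P(X >= alt_reads | depth, error_rate).
Calls are annotated with the ML carrier-allele count, relative coverage and
QC flags (depth floor 30X, minimum alt reads, optional Bonferroni control
over the targeted bases), then emitted as VCF 4.2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .models import SiteReadCounts
from .poolmath import (
    Concordance,
    ConcordanceBands,
    check_concordance,
    estimate_carrier_count,
    relative_coverage,
)

__all__ = [
    "CallerParams",
    "PoolVariantCall",
    "test_site",
    "log_test_site",
    "call_pool",
    "coverage_qc",
    "emit_pool_vcf",
    "read_pool_vcf",
]

FILTER_PASS = "PASS"
FILTER_LOW_DEPTH = "LOW_DEPTH"
FILTER_FAIL_TEST = "FAIL_TEST"
FILTER_AF_OUTLIER = "AF_OUTLIER"  # informational; does not block PASS


@dataclass
class CallerParams:
    """Knobs of the pool-aware binomial caller.

    ``min_depth`` is the 30X per-pool coverage floor below which a site is
    not callable; ``min_alt_reads`` guards against singleton errors at
    extreme depth; ``alpha`` is the per-site level of the one-sided binomial
    test; ``multiple_testing='bonferroni_by_targeted_bases'`` divides alpha
    by ``targeted_bases`` for panel-wide FWER control.
    """

    error_rate: float = 0.002
    alpha: float = 1e-5
    min_depth: int = 30
    min_alt_reads: int = 3
    multiple_testing: str = "none"  # or "bonferroni_by_targeted_bases"
    targeted_bases: int = 1_000_000

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.multiple_testing not in ("none", "bonferroni_by_targeted_bases"):
            raise ValueError(f"unknown multiple_testing {self.multiple_testing!r}")

    @property
    def log_alpha_adjusted(self) -> float:
        if self.multiple_testing == "bonferroni_by_targeted_bases":
            return math.log(self.alpha) - math.log(self.targeted_bases)
        return math.log(self.alpha)


@dataclass
class PoolVariantCall:
    """A pool-level detection with QC annotations."""

    pool_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_reads: int
    af_hat: float
    rel_cov: float  # units of 1/(2N)
    c_hat: int
    p_value: float
    log10_p: float
    filters: set[str] = field(default_factory=set)

    @property
    def passed(self) -> bool:
        return FILTER_PASS in self.filters


def log_test_site(alt_reads: int, depth: int, error_rate: float) -> float:
    """Natural-log one-sided binomial tail ln P(X >= alt_reads | depth, e).

    Computed by log-space summation of pmf terms when the tail underflows
    double precision (p below ~1e-300), so extreme detections keep a finite,
    comparable statistic.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= alt_reads <= depth:
        raise ValueError("alt_reads outside [0, depth]")
    if alt_reads == 0:
        return 0.0  # P(X >= 0) = 1
    if error_rate <= 0:
        # boundary: any alt read is impossible under a zero-error null
        return -math.inf
    sf = float(stats.binom.sf(alt_reads - 1, depth, error_rate))
    if sf > 1e-300:
        return math.log(sf)
    # tail terms decay geometrically; 2000 terms is far past convergence
    upper = min(depth, alt_reads + 2000)
    ks = np.arange(alt_reads, upper + 1)
    return float(logsumexp(stats.binom.logpmf(ks, depth, error_rate)))


def test_site(alt_reads: int, depth: int, error_rate: float) -> float:
    """One-sided exact binomial tail P(X >= alt_reads | depth, error_rate).

    Returns 0.0 when the tail underflows double precision; use
    :func:`log_test_site` for the log-space value in that regime.
    """
    lp = log_test_site(alt_reads, depth, error_rate)
    return math.exp(lp) if lp > -745 else 0.0


def call_pool(
    counts: list[SiteReadCounts],
    n: int,
    params: CallerParams | None = None,
    bands: ConcordanceBands | None = None,
) -> list[PoolVariantCall]:
    """Annotate every site of one pool with p-value, ML carrier count,
    relative coverage and filter flags.

    PASS requires depth >= min_depth, alt_reads >= min_alt_reads and
    p <= adjusted alpha.  AF_OUTLIER is an additional, non-blocking flag set
    when the observed relative coverage falls outside the empirical band for
    the estimated allele count (1 or 2).
    """
    params = params or CallerParams()
    pools = {c.pool_id for c in counts}
    if len(pools) > 1:
        raise ValueError(f"counts from mixed pools: {sorted(pools)}")
    calls: list[PoolVariantCall] = []
    for site in counts:
        filters: set[str] = set()
        af = site.alt_reads / site.depth if site.depth > 0 else 0.0
        if site.depth > 0:
            rel = relative_coverage(site.alt_reads, site.depth, n)
            lp = log_test_site(site.alt_reads, site.depth, params.error_rate) if site.depth >= 1 else 0.0
            c_hat, _ = estimate_carrier_count(site.alt_reads, site.depth, n, params.error_rate)
        else:
            rel, lp, c_hat = 0.0, 0.0, 0
        if site.depth < params.min_depth:
            filters.add(FILTER_LOW_DEPTH)
        if lp > params.log_alpha_adjusted or site.alt_reads < params.min_alt_reads:
            filters.add(FILTER_FAIL_TEST)
        if not filters:
            filters.add(FILTER_PASS)
        if c_hat in (1, 2) and site.depth > 0:
            if check_concordance(rel, c_hat, bands) is not Concordance.CONSISTENT:
                filters.add(FILTER_AF_OUTLIER)
        calls.append(
            PoolVariantCall(
                pool_id=site.pool_id,
                chrom=site.chrom,
                pos=site.pos,
                ref=site.ref,
                alt=site.alt,
                depth=site.depth,
                alt_reads=site.alt_reads,
                af_hat=af,
                rel_cov=rel,
                c_hat=c_hat,
                p_value=math.exp(lp) if lp > -745 else 0.0,
                log10_p=lp / math.log(10),
                filters=filters,
            )
        )
    return calls


def coverage_qc(
    depths: list[tuple[str, int]],
    cutoff: int = 30,
) -> tuple[float, list[tuple[str, int]]]:
    """Fraction of targeted regions below the coverage cutoff, plus the
    failing regions (region label, depth).

    The reference run kept this under 3.4% of regions below 30X per pool.
    """
    if not depths:
        raise ValueError("empty depth list")
    failing = [(region, d) for region, d in depths if d < cutoff]
    return len(failing) / len(depths), failing


_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Pool read depth">',
    '##INFO=<ID=AO,Number=1,Type=Integer,Description="Alt-supporting reads">',
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Observed alt allele fraction">',
    '##INFO=<ID=CHAT,Number=1,Type=Integer,Description="ML carrier-allele count in the pool">',
    '##INFO=<ID=RELCOV,Number=1,Type=Float,Description="Relative coverage in units of 1/(2N)">',
    '##INFO=<ID=POOL,Number=1,Type=String,Description="Pool identifier">',
    '##FILTER=<ID=LOW_DEPTH,Description="Depth below the per-pool coverage floor">',
    '##FILTER=<ID=FAIL_TEST,Description="Binomial test not significant or too few alt reads">',
    '##FILTER=<ID=AF_OUTLIER,Description="Relative coverage outside the empirical band">',
]


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (0, f"{int(c):03d}") if c.isdigit() else (1, c)


def emit_pool_vcf(calls: list[PoolVariantCall], n: int, out: str | Path) -> Path:
    """Write pool-level calls as VCF 4.2 with DP/AO/AF/CHAT/RELCOV INFO
    fields; the FILTER column mirrors the call's flags."""
    out = Path(out)
    ordered = sorted(calls, key=lambda c: (_chrom_sort_key(c.chrom), c.pos, c.ref, c.alt))
    chroms: dict[str, None] = {}
    for c in ordered:
        chroms.setdefault(c.chrom, None)
    with out.open("w") as fh:
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        fh.write(f"##poolrare_pool_size={n}\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in ordered:
            flt = (
                FILTER_PASS
                if c.passed and c.filters == {FILTER_PASS}
                else ";".join(sorted(c.filters))
            )
            qual = f"{-10.0 * c.log10_p:.2f}" if math.isfinite(c.log10_p) else "9999"
            info = (
                f"DP={c.depth};AO={c.alt_reads};AF={c.af_hat!r};CHAT={c.c_hat};"
                f"RELCOV={c.rel_cov!r};POOL={c.pool_id}"
            )
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t{qual}\t{flt}\t{info}\n"
            )
    return out


def read_pool_vcf(
    path: str | Path, n: int | None = None, error_rate: float = 0.002
) -> list[PoolVariantCall]:
    """Read back a VCF written by :func:`emit_pool_vcf`.

    Derived floats (AF, RELCOV, p-value) are recomputed from the integer
    DP/AO fields and the pool size stored in the header, so a write-read
    round trip reproduces every field value exactly.
    """
    from cyvcf2 import VCF

    calls: list[PoolVariantCall] = []
    vcf = VCF(str(path))
    pool_n = n
    for raw in vcf.raw_header.splitlines():
        if raw.startswith("##poolrare_pool_size="):
            pool_n = int(raw.split("=", 1)[1])
    if pool_n is None:
        raise ValueError("pool size missing from header and not supplied")
    for rec in vcf:
        filters = set((rec.FILTER or FILTER_PASS).split(";"))
        depth = int(rec.INFO["DP"])
        alt_reads = int(rec.INFO["AO"])
        lp = log_test_site(alt_reads, depth, error_rate) if depth >= 1 else 0.0
        calls.append(
            PoolVariantCall(
                pool_id=str(rec.INFO["POOL"]),
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                depth=depth,
                alt_reads=alt_reads,
                af_hat=alt_reads / depth if depth > 0 else 0.0,
                rel_cov=relative_coverage(alt_reads, depth, pool_n) if depth > 0 else 0.0,
                c_hat=int(rec.INFO["CHAT"]),
                p_value=math.exp(lp) if lp > -745 else 0.0,
                log10_p=lp / math.log(10),
                filters=filters,
            )
        )
    vcf.close()
    return calls
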