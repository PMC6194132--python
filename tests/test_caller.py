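"""Pool-aware binomial caller: p-values, flags, sensitivity/specificity, VCF."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from poolrare import (
    CallerParams,
    DepthModel,
    NoiseModel,
    call_pool,
    coverage_qc,
    emit_pool_vcf,
    read_pool_vcf,
    simulate_pool_reads,
)
from poolrare import test_site as site_pvalue
from poolrare.caller import (
    FILTER_FAIL_TEST,
    FILTER_LOW_DEPTH,
    FILTER_PASS,
    PoolVariantCall,
    log_test_site,
)
from poolrare.models import PoolManifest, SiteReadCounts
from poolrare.synthdata import generate_cohort


def _exact_tail(alt, depth, eps):
    """Exact rational binomial tail P(X >= alt), summed with Fractions."""
    e = Fraction(eps).limit_denominator(10**9)
    total = Fraction(0)
    for k in range(alt, depth + 1):
        total += math.comb(depth, k) * e**k * (1 - e) ** (depth - k)
    return float(total)


class TestSiteTest:
    def test_zero_alt_reads_is_one(self):
        assert site_pvalue(0, 100, 0.002) == 1.0

    def test_saturated_site_needs_log_space(self):
        # p = eps^100 ~ 1e-270: still representable
        assert site_pvalue(100, 100, 0.002) == pytest.approx(0.002**100, rel=1e-9)
        # deeper site underflows doubles; the log value stays finite
        lp = log_test_site(200, 200, 0.002)
        assert lp == pytest.approx(200 * math.log(0.002), rel=1e-9)
        assert site_pvalue(200, 200, 0.002) == 0.0

    def test_exact_tail_value(self):
        assert site_pvalue(6, 192, 0.002) == pytest.approx(_exact_tail(6, 192, 0.002), rel=1e-9)

    @pytest.mark.parametrize("depth", [5, 10, 20])
    def test_matches_exact_enumeration_at_small_depth(self, depth):
        for alt in range(depth + 1):
            got = site_pvalue(alt, depth, 0.01)
            want = _exact_tail(alt, depth, 0.01)
            assert got == pytest.approx(want, abs=1e-9)

    def test_zero_error_rate_boundary(self):
        assert log_test_site(3, 100, 0.0) == -math.inf
        assert log_test_site(0, 100, 0.0) == 0.0

    @given(depth=st.integers(10, 500), eps=st.floats(1e-4, 0.05))
    def test_monotone_nonincreasing_in_alt_reads(self, depth, eps):
        lps = [log_test_site(alt, depth, eps) for alt in range(0, depth + 1, max(1, depth // 7))]
        assert all(a >= b for a, b in zip(lps, lps[1:]))

    @given(alt=st.integers(1, 30), depth=st.integers(30, 300))
    def test_monotone_nondecreasing_in_error_rate(self, alt, depth):
        alt = min(alt, depth)
        p1 = log_test_site(alt, depth, 0.001)
        p2 = log_test_site(alt, depth, 0.01)
        assert p2 >= p1


class TestCallPool:
    def test_spiked_het_passes_with_chat_1(self, small_panel):
        cohort = generate_cohort(small_panel, 16, [(small_panel.genes[0], "het", 1)], seed=3)
        pool = PoolManifest("pool01", members=list(cohort.samples))
        counts = simulate_pool_reads(
            pool, cohort, small_panel, DepthModel(dispersion=0.0),
            NoiseModel(equimolar_bias_sigma=0.0), seed=8,
        )
        (call,) = call_pool(counts, 16)
        assert call.passed and call.c_hat == 1

    def test_low_depth_site_never_passes(self):
        site = SiteReadCounts("p1", "chr1", 100, "A", "T", depth=29, alt_reads=10)
        (call,) = call_pool([site], 16)
        assert FILTER_LOW_DEPTH in call.filters and not call.passed

    def test_min_alt_reads_guard(self):
        site = SiteReadCounts("p1", "chr1", 100, "A", "T", depth=1000, alt_reads=2)
        (call,) = call_pool([site], 16, CallerParams(error_rate=1e-6))
        assert FILTER_FAIL_TEST in call.filters

    def test_mixed_pools_rejected(self):
        sites = [
            SiteReadCounts("p1", "chr1", 100, "A", "T", 100, 0),
            SiteReadCounts("p2", "chr1", 100, "A", "T", 100, 0),
        ]
        with pytest.raises(ValueError):
            call_pool(sites, 16)

    def test_all_reference_pool_yields_no_pass_calls(self, small_panel):
        """Per-site false-positive rate stays below alpha: over 100 seeded
        null replicates of 21 error-only sites, essentially no PASS calls."""
        genes = small_panel.genes
        cohort = generate_cohort(
            small_panel, 16, [(genes[i % len(genes)], "het", 1) for i in range(21)], seed=5
        )
        for key in list(cohort.genotypes):
            cohort.genotypes[key] = {}  # keep sites, drop all carriers
        pool = PoolManifest("pool01", members=list(cohort.samples))
        n_sites = n_fp = 0
        for seed in range(100):
            counts = simulate_pool_reads(pool, cohort, small_panel, seed=seed)
            calls = call_pool(counts, 16)
            n_sites += len(calls)
            n_fp += sum(c.passed for c in calls)
        # 2100 null sites at alpha=1e-5: P(>=3 false positives) < 1e-6
        assert n_fp <= 2
        assert n_sites == 2100


class TestCoverageQc:
    def test_all_covered(self):
        frac, failing = coverage_qc([("r1", 100), ("r2", 31)], cutoff=30)
        assert frac == 0.0 and failing == []

    def test_quarter_below(self):
        depths = [("r1", 29), ("r2", 100), ("r3", 100), ("r4", 100)]
        frac, failing = coverage_qc(depths, cutoff=30)
        assert frac == 0.25 and failing == [("r1", 29)]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            coverage_qc([])

    def test_default_simulation_close_to_reference_fraction(self, small_panel, spiked_cohort):
        """At per-sample depth 196 and dispersion 0.35, the fraction of
        regions under 30X per 16-pool is tiny (reference context: <=3.4%)."""
        pool = PoolManifest("pool01", members=spiked_cohort.samples[:16])
        counts = simulate_pool_reads(pool, spiked_cohort, small_panel, seed=1)
        frac, _ = coverage_qc([(f"{c.chrom}:{c.pos}", c.depth) for c in counts], cutoff=30)
        assert frac <= 0.034


class TestVcfRoundTrip:
    def test_empty_call_list_writes_header_only(self, tmp_path):
        path = emit_pool_vcf([], 16, tmp_path / "empty.vcf")
        lines = path.read_text().splitlines()
        assert lines[0] == "##fileformat=VCFv4.2"
        assert all(ln.startswith("#") for ln in lines)

    def test_single_pass_record(self, tmp_path):
        site = SiteReadCounts("p1", "chr2", 500, "G", "C", depth=3200, alt_reads=110)
        (call,) = call_pool([site], 16)
        assert call.passed
        path = emit_pool_vcf([call], 16, tmp_path / "one.vcf")
        body = [ln for ln in path.read_text().splitlines() if not ln.startswith("#")]
        assert len(body) == 1 and body[0].split("\t")[6] == FILTER_PASS

    def test_fifty_random_calls_round_trip_identically(self, tmp_path):
        rng = np.random.default_rng(42)
        sites = []
        for i in range(50):
            depth = int(rng.integers(20, 4000))
            alt = int(rng.integers(0, depth + 1))
            sites.append(
                SiteReadCounts(
                    "pool01", f"chr{int(rng.integers(1, 23))}", int(rng.integers(1, 10**6)),
                    "A", "T", depth, alt,
                )
            )
        # de-duplicate coordinates to keep record identity unambiguous
        calls = call_pool(sites, 16)
        path = emit_pool_vcf(calls, 16, tmp_path / "fifty.vcf")
        back = read_pool_vcf(path)
        key = lambda c: (c.chrom, c.pos, c.ref, c.alt)
        assert sorted(map(key, back)) == sorted(map(key, calls))
        orig = {key(c): c for c in calls}
        for c in back:
            o = orig[key(c)]
            assert (c.depth, c.alt_reads, c.c_hat, c.filters) == (
                o.depth, o.alt_reads, o.c_hat, o.filters
            )
            assert c.af_hat == o.af_hat
            assert c.rel_cov == o.rel_cov
            assert c.log10_p == o.log10_p
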