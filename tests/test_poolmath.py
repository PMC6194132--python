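"""Dilution arithmetic, carrier-count estimation, power and cost model."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from poolrare import (
    Concordance,
    ConcordanceBands,
    CostInputs,
    DepthModel,
    check_concordance,
    cost_fold_reduction,
    design_pool_size,
    detection_power,
    estimate_carrier_count,
    expected_af,
    relative_coverage,
)


class TestExpectedAf:
    @pytest.mark.parametrize(
        "c,n,want",
        [(1, 16, 0.03125), (2, 16, 0.0625), (0, 16, 0.0), (32, 16, 1.0)],
    )
    def test_quantized_fractions(self, c, n, want):
        assert expected_af(c, n) == want

    def test_out_of_range_carrier_count(self):
        with pytest.raises(ValueError):
            expected_af(33, 16)
        with pytest.raises(ValueError):
            expected_af(-1, 16)

    @given(n=st.integers(1, 64), c=st.integers(0, 128))
    def test_linear_in_c_and_saturates_at_one(self, n, c):
        c = min(c, 2 * n)
        assert expected_af(c, n) == pytest.approx(c * expected_af(1, n))
        assert expected_af(2 * n, n) == 1.0


class TestRelativeCoverage:
    @pytest.mark.parametrize(
        "alt,depth,n,want",
        [(100, 3200, 16, 1.0), (6, 64, 16, 3.0), (0, 500, 16, 0.0)],
    )
    def test_examples(self, alt, depth, n, want):
        assert relative_coverage(alt, depth, n) == pytest.approx(want)

    def test_zero_depth_undefined(self):
        with pytest.raises(ValueError):
            relative_coverage(0, 0, 16)


class TestConcordanceBands:
    @pytest.mark.parametrize(
        "rel,alleles,want",
        [
            (1.54, 1, Concordance.CONSISTENT),
            (0.56, 1, Concordance.CONSISTENT),
            (1.75, 1, Concordance.OUTLIER_HIGH),
            (2.98, 2, Concordance.OUTLIER_HIGH),
            (1.25, 2, Concordance.OUTLIER_LOW),
            (2.3, 2, Concordance.CONSISTENT),
            (1.5, 2, Concordance.CONSISTENT),
        ],
    )
    def test_band_classification(self, rel, alleles, want):
        assert check_concordance(rel, alleles) is want

    def test_unsupported_allele_count(self):
        with pytest.raises(ValueError):
            check_concordance(1.0, 3)

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            ConcordanceBands(one_allele_band=(1.5, 0.5))

    @given(
        alt=st.integers(1, 200),
        depth=st.integers(200, 4000),
        scale=st.integers(2, 10),
        alleles=st.sampled_from([1, 2]),
    )
    def test_invariant_to_rescaling_counts_at_fixed_ratio(self, alt, depth, scale, alleles):
        alt = min(alt, depth)
        r1 = relative_coverage(alt, depth, 16)
        r2 = relative_coverage(alt * scale, depth * scale, 16)
        assert r1 == pytest.approx(r2)
        assert check_concordance(r1, alleles) is check_concordance(r2, alleles)


def _brute_force_chat(alt, depth, n, eps):
    """Independent likelihood scan using log pmf built from math.comb."""
    best_c, best_ll = None, -math.inf
    for c in range(2 * n + 1):
        q = (c / (2 * n)) * (1 - eps) + (1 - c / (2 * n)) * eps
        if q == 0.0:
            ll = 0.0 if alt == 0 else -math.inf
        elif q == 1.0:
            ll = 0.0 if alt == depth else -math.inf
        else:
            ll = (
                math.lgamma(depth + 1)
                - math.lgamma(alt + 1)
                - math.lgamma(depth - alt + 1)
                + alt * math.log(q)
                + (depth - alt) * math.log(1 - q)
            )
        if ll > best_ll:  # strict: ties stay with the smaller c
            best_c, best_ll = c, ll
    return best_c


class TestCarrierCountEstimate:
    @pytest.mark.parametrize(
        "alt,depth,want",
        [(98, 3136, 1), (196, 3136, 2), (0, 3136, 0)],
    )
    def test_exact_lattice_points(self, alt, depth, want):
        c_hat, support = estimate_carrier_count(alt, depth, 16, 0.0)
        assert c_hat == want
        assert len(support) == 33

    @pytest.mark.parametrize("alt", [0, 49, 98, 147, 196, 300, 1500, 3136])
    def test_matches_brute_force_likelihood_scan(self, alt):
        c_hat, _ = estimate_carrier_count(alt, 3136, 16, 0.002)
        assert c_hat == _brute_force_chat(alt, 3136, 16, 0.002)

    @given(alt=st.integers(0, 400), depth=st.integers(50, 400), n=st.sampled_from([4, 8, 16]))
    def test_matches_oracle_across_lattice(self, alt, depth, n):
        alt = min(alt, depth)
        c_hat, _ = estimate_carrier_count(alt, depth, n, 0.002)
        assert c_hat == _brute_force_chat(alt, depth, n, 0.002)

    def test_invalid_error_rate(self):
        with pytest.raises(ValueError):
            estimate_carrier_count(10, 100, 16, 0.7)

    def test_recovers_true_count_on_simulated_sites(self):
        """ML estimate recovers true c in >=99% of sites at pool depth 196*16."""
        rng = np.random.default_rng(7)
        n, depth, eps = 16, 196 * 16, 0.002
        hits = total = 0
        for c_true in (1, 2, 3):
            q = (c_true / 32) * (1 - eps) + (1 - c_true / 32) * eps
            alts = rng.binomial(depth, q, size=1000)
            for alt in alts:
                c_hat, _ = estimate_carrier_count(int(alt), depth, n, eps)
                hits += c_hat == c_true
                total += 1
        assert hits / total >= 0.99


def _power_oracle(depth, n, c, eps, alpha, min_depth, min_alt=3):
    """Exact enumeration: smallest significant alt count, then the tail mass
    of the alternative — all tails summed directly from the pmf."""
    if depth < min_depth:
        return 0.0
    pmf_null = [float(stats.binom.pmf(k, depth, eps)) for k in range(depth + 1)]
    k_crit = None
    for k in range(depth + 1):
        if sum(pmf_null[k:]) <= alpha:
            k_crit = k
            break
    if k_crit is None:
        return 0.0
    k_crit = max(k_crit, min_alt)
    q = (c / (2 * n)) * (1 - eps) + (1 - c / (2 * n)) * eps
    return sum(float(stats.binom.pmf(k, depth, q)) for k in range(k_crit, depth + 1))


class TestDetectionPower:
    def test_single_het_at_full_pool_depth_is_detected(self):
        p = detection_power(16, 1, 3136, error_rate=0.002, alpha=1e-5, min_depth=30)
        assert p >= 0.999

    def test_zero_depth_has_zero_power(self):
        assert detection_power(16, 1, 0) == 0.0

    def test_null_power_bounded_by_alpha(self):
        p = detection_power(16, 0, 3136, error_rate=0.002, alpha=1e-5, min_depth=30)
        assert p <= 1e-5

    @pytest.mark.parametrize("depth", [30, 40, 50])
    @pytest.mark.parametrize("c", [0, 1, 2])
    def test_agrees_with_exact_enumeration_at_small_depth(self, depth, c):
        got = detection_power(16, c, depth, error_rate=0.01, alpha=1e-3, min_depth=30)
        want = _power_oracle(depth, 16, c, 0.01, 1e-3, 30)
        assert got == pytest.approx(want, abs=1e-9)

    def test_monte_carlo_close_to_fixed_depth_at_low_dispersion(self):
        dm = DepthModel(per_sample_mean_depth=196, dispersion=0.05)
        p_mc = detection_power(16, 1, dm, seed=1)
        p_fixed = detection_power(16, 1, 3136)
        assert p_mc == pytest.approx(p_fixed, abs=0.01)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            detection_power(16, 1, 3136, alpha=0.0)


class TestDesignPoolSize:
    def test_reference_design_recommends_16(self):
        res = design_pool_size(max_pool=32, target_power=0.99, hrm_batch_limit=16)
        assert res.recommended_n == 16
        assert set(res.table.columns) == {"N", "c", "power"}

    def test_unreachable_target_returns_no_solution(self):
        res = design_pool_size(max_pool=8, target_power=1.01)
        assert res.recommended_n is None
        assert len(res.table) == 8

    def test_power_monotone_nonincreasing_at_fixed_pool_depth(self):
        dm = DepthModel(pool_depth_rule="fixed_pool_depth", fixed_pool_depth=800, dispersion=0.0)
        res = design_pool_size(max_pool=16, target_power=0.5, depth_model=dm)
        powers = list(res.table["power"])
        oracle = [_power_oracle(800, n, 1, 0.002, 1e-5, 30) for n in range(1, 17)]
        assert powers == pytest.approx(oracle, abs=1e-9)
        assert all(a >= b - 1e-12 for a, b in zip(powers, powers[1:]))


class TestCostModel:
    def test_identity_at_pool_of_one(self):
        costs = CostInputs(genotyping_cost_per_assay=0.0, assays_per_patient=0.0)
        assert cost_fold_reduction(costs, 1) == (1.0, 1.0)

    def test_analytic_fold_at_16_without_genotyping(self):
        costs = CostInputs(genotyping_cost_per_assay=0.0, assays_per_patient=0.0,
                           fixed_cost_per_patient=0.0)
        assert cost_fold_reduction(costs, 16) == (16.0, 16.0)

    @given(
        lib=st.floats(1, 1000),
        seq=st.floats(1, 1000),
        geno=st.floats(0.01, 100),
        assays=st.floats(0.1, 10),
        fixed=st.floats(0, 100),
        n=st.integers(1, 32),
    )
    def test_overall_fold_never_exceeds_sequencing_fold(self, lib, seq, geno, assays, fixed, n):
        costs = CostInputs(lib, seq, geno, assays, fixed)
        seq_fold, overall = cost_fold_reduction(costs, n)
        assert overall <= seq_fold + 1e-9

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            CostInputs(library_prep_cost_per_library=-1)
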