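"""Summary statistics against hand calculations and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popdemog.errors import PopdemogError
from popdemog.sumstats import (
    dxy,
    fay_wu_h,
    haplotype_count,
    harmonic_number,
    largest_nonrecombining_block,
    locus_summary,
    min_recombination_rm,
    pairwise_diversity,
    population_summary,
    segregating_sites,
    tajimas_d,
    watterson_theta,
    _incompatible_pairs,
)

from conftest import make_matrix, random_segregating_matrix


class TestBasicStatistics:
    def test_segregating_sites_counts_columns(self):
        assert segregating_sites(make_matrix(["000", "011", "110", "101"])) == 3

    def test_pairwise_diversity_hand_enumeration(self):
        # pairs of {000,001,011,111}: 1+2+3+1+2+1 = 10 over 6 pairs
        m = make_matrix(["000", "001", "011", "111"])
        pi_total, pi_site = pairwise_diversity(m)
        assert pi_total == pytest.approx(10 / 6)
        assert pi_site == pytest.approx(10 / 6 / 100)

    def test_two_haplotypes_one_difference(self):
        m = make_matrix(["0", "1"], L=100)
        assert pairwise_diversity(m) == (1.0, 0.01)

    @pytest.mark.parametrize(
        "S,n,L,expected",
        [(3, 2, 100, 0.03), (0, 5, 100, 0.0), (11, 4, 100, 11 / ((1 + 0.5 + 1 / 3) * 100))],
    )
    def test_watterson_theta(self, S, n, L, expected):
        assert watterson_theta(S, n, L) == pytest.approx(expected)

    def test_haplotype_count_distinct_rows(self):
        assert haplotype_count(make_matrix(["000", "001", "001", "111"])) == 3
        assert haplotype_count(make_matrix(["", ""], L=10)) == 1


class TestTajimasD:
    def test_undefined_for_monomorphic_data(self):
        assert math.isnan(tajimas_d(make_matrix(["", "", ""], L=50)))

    def test_direct_evaluation_of_published_constants(self):
        # independent spreadsheet-style evaluation for the 6x4 matrix below:
        # pi_total = 32/15, S = 4, n = 6
        m = make_matrix(["0000", "0011", "0101", "1110", "1010", "0000"])
        n, S = 6, 4
        pi_total = pairwise_diversity(m)[0]
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        expected = (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert tajimas_d(m) == pytest.approx(expected, rel=1e-12)

    def test_sign_matches_pi_minus_watterson(self, rng):
        for _ in range(25):
            m = random_segregating_matrix(rng, n=6, S_target=int(rng.integers(1, 9)))
            d = tajimas_d(m)
            diff = pairwise_diversity(m)[0] - m.S / harmonic_number(m.n)
            if diff != 0 and not math.isnan(d):
                assert math.copysign(1, d) == math.copysign(1, diff)


class TestFayWuH:
    def test_hand_evaluation_singleton_and_high_frequency(self):
        assert fay_wu_h(make_matrix(["1", "0", "0", "0"])) == pytest.approx(1 / 3)
        assert fay_wu_h(make_matrix(["1", "1", "1", "0"])) == pytest.approx(-1.0)

    def test_zero_without_segregating_sites(self):
        assert fay_wu_h(make_matrix(["", "", ""], L=10)) == 0.0

    def test_undefined_without_polarized_columns(self):
        m = make_matrix(["10", "01"], polarized=False)
        m.col_polarized[:] = False
        assert math.isnan(fay_wu_h(m))

    def test_column_relabeling_changes_theta_h_not_pi(self):
        m = make_matrix(["110", "100", "001", "010"])
        flipped = make_matrix(["001", "011", "110", "101"])
        assert pairwise_diversity(m)[0] == pairwise_diversity(flipped)[0]
        assert fay_wu_h(m) != fay_wu_h(flipped)
        assert tajimas_d(m) == pytest.approx(tajimas_d(flipped))


def brute_force_rm(pairs):
    """Exhaustive search over every selection of pairwise-disjoint intervals."""
    ivs = sorted(pairs, key=lambda p: p[1])
    best = 0

    def rec(idx, last_end, count):
        nonlocal best
        best = max(best, count)
        for k in range(idx, len(ivs)):
            i, j = ivs[k]
            if i >= last_end:
                rec(k + 1, j, count + 1)

    rec(0, -1, 0)
    return best


class TestRecombination:
    def test_no_violation_means_zero(self):
        m = make_matrix(["00", "01", "11"])
        assert min_recombination_rm(m)[0] == 0

    def test_single_four_gamete_pair(self):
        m = make_matrix(["00", "01", "10", "11"])
        rm, pairs = min_recombination_rm(m)
        assert rm == 1 and pairs == [(0, 1)]

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(120):
            n = int(rng.integers(4, 9))
            S = int(rng.integers(2, 13))
            m = random_segregating_matrix(rng, n=n, S_target=S)
            rm, pairs = min_recombination_rm(m)
            assert rm == brute_force_rm(pairs)

    def test_block_full_length_iff_no_violation(self):
        m = make_matrix(["00", "01", "11"])
        assert largest_nonrecombining_block(m, 339) == 339.0
        empty = make_matrix(["", ""], L=339)
        assert largest_nonrecombining_block(empty, 339) == 339.0

    def test_block_splits_at_conflicting_pair(self):
        # columns at 10 and 20 conflict: blocks are [0,15) and [15,100)
        m = make_matrix(["00", "01", "10", "11"], positions=[10.0, 20.0])
        assert largest_nonrecombining_block(m, 100) == pytest.approx(85.0)

    def test_block_with_three_sites_and_one_conflict(self):
        # conflict only between columns 0 and 1 (positions 10, 50); column 90
        # is compatible with both, so the right block spans [30, 100)
        rows = ["000", "011", "101", "110"]
        m = make_matrix(rows, positions=[10.0, 50.0, 90.0])
        incompat = _incompatible_pairs(m)
        assert (0, 1) in incompat
        expected = 100 - 30 if (1, 2) not in incompat else None
        if expected:
            assert largest_nonrecombining_block(m, 100) == pytest.approx(expected)


class TestDxy:
    def test_known_divergence(self):
        m = make_matrix(["00", "00", "11"], L=100)
        assert dxy(m, [0, 1], [2]) == pytest.approx(0.02)

    def test_symmetry_and_overlap_error(self, rng):
        m = random_segregating_matrix(rng, n=6, S_target=5)
        assert dxy(m, [0, 1, 2], [3, 4, 5]) == pytest.approx(dxy(m, [3, 4, 5], [0, 1, 2]))
        with pytest.raises(PopdemogError):
            dxy(m, [0, 1], [1, 2])

    def test_two_v_two_enumeration(self):
        # between pairs: (r0,r2)=1, (r0,r3)=2, (r1,r2)=2, (r1,r3)=1 -> mean 1.5
        m = make_matrix(["00", "01", "10", "11"], L=10)
        assert dxy(m, [0, 1], [2, 3]) == pytest.approx(1.5 / 10)


class TestPopulationSummary:
    def test_monomorphic_population(self):
        mats = [make_matrix(["", "", ""], L=300) for _ in range(3)]
        p = population_summary(mats, "pop")
        assert p.pi_site == 0 and p.theta_w_site == 0 and math.isnan(p.tajima_d)

    def test_concatenation_equals_single_locus_when_split(self):
        # splitting one locus into two halves must not change pooled values
        whole = make_matrix(["0011", "0101", "1110", "0000"], L=200)
        left = make_matrix(["00", "01", "11", "00"], L=100)
        right = make_matrix(["11", "01", "10", "00"], L=100)
        a = population_summary([whole], "x")
        b = population_summary([left, right], "x")
        assert a.pi_site == pytest.approx(b.pi_site)
        assert a.theta_w_site == pytest.approx(b.theta_w_site)
        assert a.tajima_d == pytest.approx(b.tajima_d)


class TestInvariantProperties:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_row_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        m = random_segregating_matrix(rng, n=6, S_target=6)
        perm = rng.permutation(6)
        mp = make_matrix(
            ["".join(str(int(x)) for x in m.matrix[i]) for i in perm], L=m.L
        )
        assert pairwise_diversity(m)[0] == pytest.approx(pairwise_diversity(mp)[0])
        assert haplotype_count(m) == haplotype_count(mp)
        assert min_recombination_rm(m)[0] == min_recombination_rm(mp)[0]
        assert fay_wu_h(m) == pytest.approx(fay_wu_h(mp))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounds(self, seed):
        rng = np.random.default_rng(seed)
        S = int(rng.integers(1, 10))
        m = random_segregating_matrix(rng, n=5, S_target=S)
        v = locus_summary(m, alignment_length=m.L)
        assert v.pi_total <= v.S
        assert v.rm <= max(0, v.S - 1)
        assert 1 <= v.h <= v.n
        assert 0 < v.block_bp <= m.L
        assert (v.block_bp == m.L) == (len(_incompatible_pairs(m)) == 0)
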