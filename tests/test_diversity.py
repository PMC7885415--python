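import itertools
import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplopop.diversity import (
    ewens_sprime,
    fu_fs,
    haplotype_diversity,
    mean_pairwise_differences,
    nucleotide_diversity,
    population_stats,
    stirling_first_unsigned,
)


def _partitions(n, largest=None):
    """All multisets of positive integers summing to n (descending)."""
    largest = n if largest is None else largest
    if n == 0:
        yield ()
        return
    for first in range(min(n, largest), 0, -1):
        for rest in _partitions(n - first, first):
            yield (first,) + rest


def _spectrum_seqs(counts, distances_from_first, L=1175):
    """Haplotype sequences placed at given distances from haplotype 0,
    mutating disjoint site blocks so pairwise distances are additive."""
    base = "".join(random.Random(0).choice("ACGT") for _ in range(L))
    seqs = {"hap0": base}
    pos = 0
    for i, d in enumerate(distances_from_first, start=1):
        s = list(base)
        for _ in range(d):
            s[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
            pos += 1
        seqs[f"hap{i}"] = "".join(s)
    hap_counts = {f"hap{i}": c for i, c in enumerate(counts)}
    return hap_counts, seqs


class TestStirling:
    def test_small_values_match_cycle_count_enumeration(self):
        # brute force: count permutations by number of cycles
        def cycles(perm):
            seen, n = set(), 0
            for start in perm:
                if start in seen:
                    continue
                n += 1
                j = start
                while j not in seen:
                    seen.add(j)
                    j = perm[j]
            return n

        for n in range(1, 7):
            counts = {}
            for p in itertools.permutations(range(n)):
                counts[cycles(p)] = counts.get(cycles(p), 0) + 1
            for k in range(1, n + 1):
                assert stirling_first_unsigned(n, k) == counts.get(k, 0)

    def test_row_sums_are_factorials(self):
        for n in range(1, 13):
            assert sum(
                stirling_first_unsigned(n, k) for k in range(n + 1)
            ) == math.factorial(n)

    def test_out_of_range_is_zero(self):
        assert stirling_first_unsigned(5, 0) == 0
        assert stirling_first_unsigned(5, 6) == 0
        assert stirling_first_unsigned(4, 1) == 6


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "counts,expected",
        [((3, 1, 1), 0.7), ((2, 1, 1, 1), 0.9), ((6, 2), 0.429), ((5, 4), 0.556)],
    )
    def test_printed_table_values(self, counts, expected):
        assert round(haplotype_diversity(counts), 3) == expected

    def test_monomorphic_sample_has_zero_diversity(self):
        assert haplotype_diversity([24]) == 0.0

    def test_singleton_sample_is_undefined(self):
        assert math.isnan(haplotype_diversity([1]))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            haplotype_diversity([])
        with pytest.raises(ValueError):
            haplotype_diversity([3, 0])

    def test_matches_unlike_pair_probability_for_all_small_spectra(self):
        # independent oracle: fraction of ordered without-replacement pairs
        # of individuals that carry different haplotypes
        for n in range(2, 11):
            for spectrum in _partitions(n):
                inds = [h for h, c in enumerate(spectrum) for _ in range(c)]
                unlike = sum(
                    1
                    for a, b in itertools.permutations(range(len(inds)), 2)
                    if inds[a] != inds[b]
                )
                oracle = unlike / (n * (n - 1))
                assert haplotype_diversity(spectrum) == pytest.approx(oracle)

    def test_zero_iff_single_haplotype(self):
        for spectrum in _partitions(6):
            hd = haplotype_diversity(spectrum)
            assert 0.0 <= hd <= 1.0
            assert (hd == 0.0) == (len(spectrum) == 1)


class TestNucleotideDiversity:
    def test_two_individuals_two_sites_apart(self):
        counts, seqs = _spectrum_seqs((1, 1), [2])
        assert round(nucleotide_diversity(counts, seqs), 4) == 0.0017

    def test_identical_individuals_have_zero_pi(self):
        counts, seqs = _spectrum_seqs((5,), [])
        assert nucleotide_diversity(counts, seqs) == 0.0

    def test_serbia_like_spectrum(self):
        counts, seqs = _spectrum_seqs((5, 4), [2])
        pi = nucleotide_diversity(counts, seqs)
        assert pi == pytest.approx((5 * 4 * 2) / (36 * 1175))
        assert round(pi, 5) == 0.00095

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            nucleotide_diversity({"a": 1, "b": 1}, {"a": "ACGT", "b": "ACG"})

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.lists(st.integers(min_value=1, max_value=4), min_size=1, max_size=4),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_count_weighted_form_equals_individual_pair_loop(self, counts, seed):
        rng = random.Random(seed)
        L = 40
        seqs = {
            f"h{i}": "".join(rng.choice("ACGT") for _ in range(L))
            for i in range(len(counts))
        }
        hap_counts = {f"h{i}": c for i, c in enumerate(counts)}
        n = sum(counts)
        if n < 2:
            return
        inds = [h for h, c in hap_counts.items() for _ in range(c)]
        total = sum(
            sum(x != y for x, y in zip(seqs[inds[a]], seqs[inds[b]]))
            for a in range(n)
            for b in range(a + 1, n)
        )
        oracle = total / (n * (n - 1) / 2) / L
        assert nucleotide_diversity(hap_counts, seqs, L) == pytest.approx(oracle)


class TestFuFs:
    def test_printed_table_values(self):
        fs, s = fu_fs(9, 2, 40 / 36)
        assert fs == pytest.approx(2.302, abs=0.01)
        assert 0 < s < 1
        fs, _ = fu_fs(15, 3, 142 / 105)
        assert fs == pytest.approx(1.626, abs=0.01)
        fs, _ = fu_fs(15, 4, 254 / 105)
        assert fs == pytest.approx(1.84, abs=0.01)

    def test_monomorphic_conventions(self):
        assert fu_fs(11, 1, 0.0) == (0.0, 1.0)
        fs, s = fu_fs(10, 1, 1.0)
        assert fs == 0.0 and s == 1.0  # Pr(K >= 1) is exactly 1

    def test_fs_stays_finite_when_sprime_rounds_to_one(self):
        # S' is numerically 1 here; the complementary log-sum keeps the
        # statistic finite and large instead of overflowing
        fs, s = fu_fs(50, 2, 1e12)
        assert s == pytest.approx(1.0)
        assert math.isfinite(fs) and fs > 100

    def test_sprime_matches_chinese_restaurant_simulation(self):
        # CRP: the number of occupied tables is a sum of independent
        # Bernoulli(theta / (theta + i)) indicators, i = 0..n-1
        rng = np.random.default_rng(12345)
        reps = 200_000
        for n, theta in [(5, 0.5), (10, 2.0), (25, 5.0)]:
            p_new = theta / (theta + np.arange(n))
            k = (rng.random((reps, n)) < p_new).sum(axis=1)
            for k_obs in (2, max(2, int(np.mean(k)))):
                emp = float(np.mean(k >= k_obs))
                se = math.sqrt(max(emp * (1 - emp), 1e-12) / reps)
                assert abs(ewens_sprime(n, k_obs, theta) - emp) <= 3 * se + 1e-9

    def test_sprime_bounds_and_monotonicity_in_k(self):
        vals = [ewens_sprime(20, k, 2.0) for k in range(1, 21)]
        assert vals[0] == 1.0
        assert all(0 <= b <= a for a, b in zip(vals, vals[1:]))


class TestPopulationStats:
    def test_serbia_like_row(self):
        counts, seqs = _spectrum_seqs((5, 4), [2])
        members = {"Senta": ["hap0"] * 5 + ["hap1"] * 4}
        st_ = population_stats(members, seqs, 1175)[0]
        assert (st_.n, st_.k) == (9, 2)
        assert round(st_.hd, 3) == 0.556
        assert round(st_.pi, 5) == 0.00095
        assert st_.fs == pytest.approx(2.302, abs=0.01)

    def test_singleton_population_reports_nan(self):
        counts, seqs = _spectrum_seqs((1,), [])
        st_ = population_stats({"Gifu": ["hap0"]}, seqs, 1175)[0]
        assert math.isnan(st_.hd) and math.isnan(st_.pi)
        assert st_.rounded()["Hd"] == "NA"

    def test_pooled_monomorphic_populations_have_zero_diversity(self):
        counts, seqs = _spectrum_seqs((4,), [])
        members = {"pool": ["hap0"] * 8}
        st_ = population_stats(members, seqs, 1175)[0]
        assert st_.hd == 0.0 and st_.pi == 0.0 and st_.fs == 0.0

    def test_country_stats_equal_pooled_region_stats(self):
        counts, seqs = _spectrum_seqs((6, 3, 2), [2, 5])
        region_a = ["hap0"] * 4 + ["hap1"] * 1
        region_b = ["hap0"] * 2 + ["hap1"] * 2 + ["hap2"] * 2
        pooled = population_stats({"country": region_a + region_b}, seqs, 1175)[0]
        direct = population_stats({"country": region_b + region_a}, seqs, 1175)[0]
        assert pooled.hd == pytest.approx(direct.hd)
        assert pooled.pi == pytest.approx(direct.pi)
        assert pooled.fs == pytest.approx(direct.fs)

    def test_theta_is_pi_times_length(self):
        counts, seqs = _spectrum_seqs((5, 4), [2])
        st_ = population_stats({"p": ["hap0"] * 5 + ["hap1"] * 4}, seqs, 1175)[0]
        assert st_.theta_pi == pytest.approx(st_.pi * 1175)
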