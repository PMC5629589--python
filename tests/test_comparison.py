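from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from markovcmp import (
    CoverageProfile,
    chi2_statistic,
    coverage_profile_from_reads,
    count_words_sequence,
    degrees_of_freedom,
    loglik_ratio,
    p_value,
    scaling_d,
    simulate_sequence,
)
from markovcmp.comparison import ComparisonResult, chi2_from_counts, chi2_log_tail
from markovcmp.ngs_sim import ReadSet, sample_reads_homogeneous
from markovcmp.word_counts import WordCountTable

from conftest import batch_records, record


def make_table(counts, k=1, kind="sequence"):
    counts = np.asarray(counts, dtype=np.int64)
    return WordCountTable(k, "ACGT", counts, kind, int(counts.sum()))


def chi2_k1_via_general_form(n1, n2, t1, t2):
    """Exact-rational evaluation of the pooled chi-square with N_{w-} = L_s."""
    total = Fraction(0)
    pool_pre = Fraction(t1 + t2)
    for a, b in zip(n1, n2):
        pool = Fraction(int(a) + int(b))
        if pool == 0:
            continue
        for n, t in ((int(a), t1), (int(b), t2)):
            expected = Fraction(t) * pool / pool_pre
            total += (n - expected) ** 2 / expected
    return total


def chi2_k1_frequency_form(n1, n2, t1, t2):
    """Exact-rational evaluation of the frequency-difference form of S_1."""
    total = Fraction(0)
    for a, b in zip(n1, n2):
        if a + b == 0:
            continue
        p1 = Fraction(int(a), t1)
        p2 = Fraction(int(b), t2)
        total += Fraction(t1 * t2) * (p1 - p2) ** 2 / (t1 * p1 + t2 * p2)
    return total


class TestChiSquareStatistic:
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_identical_tables_give_zero(self, table1, k):
        t = count_words_sequence(simulate_sequence(table1, 2_000, 1), k)
        assert chi2_statistic(t, t).statistic == 0.0
        assert chi2_statistic(t, t).p_value == 1.0

    def test_hand_worked_single_letter_value(self):
        a = count_words_sequence(record("AACC"), 1)
        b = count_words_sequence(record("GGTT"), 1)
        # each of the four symbols contributes 16*0.25/2 = 2
        assert chi2_statistic(a, b).statistic == pytest.approx(8.0)

    def test_frequency_form_equals_pooled_form_at_k1(self):
        """The two printed forms of the single-letter statistic are one
        algebraic identity, checked exactly on 100 random count tables."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            n1 = rng.integers(0, 40, size=4)
            n2 = rng.integers(0, 40, size=4)
            t1, t2 = int(n1.sum()), int(n2.sum())
            if t1 == 0 or t2 == 0:
                continue
            lhs = chi2_k1_frequency_form(n1, n2, t1, t2)
            rhs = chi2_k1_via_general_form(n1, n2, t1, t2)
            assert lhs == rhs
            got = chi2_from_counts(n1, n2, t1, t2, 1, 4)
            assert got == pytest.approx(float(lhs), rel=1e-12)

    def test_symmetry(self, table1):
        a = count_words_sequence(simulate_sequence(table1, 3_000, 5), 3)
        b = count_words_sequence(simulate_sequence(table1, 4_000, 6), 3)
        assert chi2_statistic(a, b).statistic == pytest.approx(
            chi2_statistic(b, a).statistic
        )

    def test_mismatched_tables_rejected(self):
        a = make_table([1, 2, 3, 4], k=1)
        b = count_words_sequence(record("AACC"), 2)
        with pytest.raises(ValueError):
            chi2_statistic(a, b)

    def test_null_calibration_mean_matches_df(self, table1):
        """Under the null, the word-length-2 statistic between two long
        first-order sequences has mean df = 12 (chi-square limit)."""
        from markovcmp import ExperimentConfig, null_distribution

        cfg = ExperimentConfig(table1, table1, table1, L=20_000, reps_null=2_000, seed=77)
        sample = null_distribution(cfg, 2)
        tol = 3 * np.sqrt(2 * 12 / 2_000)
        assert abs(sample.mean() - 12) < tol


class TestLogLikelihoodRatio:
    def test_identical_tables_give_zero(self, table1):
        t = count_words_sequence(simulate_sequence(table1, 2_000, 8), 2)
        assert loglik_ratio(t, t) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative(self, table1):
        a = count_words_sequence(simulate_sequence(table1, 1_000, 1), 2)
        b = count_words_sequence(simulate_sequence(table1, 1_500, 2), 2)
        assert loglik_ratio(a, b) >= 0

    def test_read_tables_rejected(self, table1):
        seq = simulate_sequence(table1, 1_000, 3)
        reads = sample_reads_homogeneous(seq, 10, 100, 4)
        from markovcmp import count_words_reads

        t = count_words_reads(reads, 2)
        with pytest.raises(ValueError):
            loglik_ratio(t, t)

    def test_twice_loglik_close_to_chi2_under_null(self, table1):
        """2 log(P1/P0) and the chi-square statistic share their asymptotic
        law; on 20 kb null pairs they agree within 5% on average."""
        rel = []
        recs = batch_records(table1, 20_000, 100, 3_000)
        for i in range(0, 100, 2):
            a = count_words_sequence(recs[i], 2)
            b = count_words_sequence(recs[i + 1], 2)
            s = chi2_statistic(a, b).statistic
            rel.append(abs(2 * loglik_ratio(a, b) - s) / s)
        assert np.mean(rel) < 0.05


class TestDegreesOfFreedom:
    @pytest.mark.parametrize("C,k,expected", [(4, 3, 48), (4, 1, 3), (2, 5, 16), (4, 2, 12)])
    def test_values(self, C, k, expected):
        assert degrees_of_freedom(C, k) == expected

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            degrees_of_freedom(1, 2)
        with pytest.raises(ValueError):
            degrees_of_freedom(4, 0)


class TestCoverageScaling:
    def test_two_level_profile(self):
        d = scaling_d(CoverageProfile([1, 3], [0.5, 0.5]))
        assert d == pytest.approx(2.5)

    def test_poisson_profile_gives_one_plus_lambda(self):
        assert scaling_d(CoverageProfile.poisson(2.0)) == pytest.approx(3.0, abs=1e-6)

    def test_constant_coverage_collapses_to_level(self):
        assert scaling_d(CoverageProfile([5], [1.0])) == pytest.approx(5.0)

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            scaling_d(CoverageProfile([0], [1.0]))

    def test_profile_from_single_read(self):
        reads = ReadSet.from_strings(["A" * 50], starts=np.array([0]), source_length=100)
        prof = coverage_profile_from_reads(reads)
        assert prof.levels.tolist() == [0, 1]
        assert prof.fractions.tolist() == [0.5, 0.5]

    def test_profile_from_duplicate_reads(self):
        reads = ReadSet.from_strings(
            ["A" * 50, "A" * 50], starts=np.array([10, 10]), source_length=100
        )
        prof = coverage_profile_from_reads(reads)
        assert dict(zip(prof.levels, prof.fractions))[2.0] == pytest.approx(0.5)

    def test_homogeneous_layout_d_near_one_plus_lambda(self, table1):
        """Uniform read starts give Poisson-like coverage, so the empirical
        scaling is close to 1 + lambda = 3."""
        seq = simulate_sequence(table1, 20_000, 17)
        ds = []
        for seed in range(20):
            reads = sample_reads_homogeneous(seq, 200, 200, 500 + seed)
            ds.append(scaling_d(coverage_profile_from_reads(reads)))
        assert abs(np.mean(ds) - 3.0) / 3.0 < 0.10


class TestPValues:
    def test_zero_statistic(self):
        res = ComparisonResult(2, 0.0, 12)
        assert p_value(res) == 1.0

    def test_extreme_statistic_has_finite_log_tail(self):
        res = ComparisonResult(3, 48e6, 48)
        assert p_value(res) == 0.0
        assert np.isfinite(res.log_p_value) and res.log_p_value < -1e6

    def test_log_tail_matches_scipy_where_finite(self):
        for x, df in ((0.5, 3), (30, 12), (200, 48), (700, 9)):
            assert chi2_log_tail(x, df) == pytest.approx(stats.chi2.logsf(x, df), rel=1e-9)

    def test_scaled_statistic_drives_p_value(self):
        res = ComparisonResult(3, 144.0, 48, d=3.0)
        assert res.scaled_statistic == pytest.approx(48.0)
        assert res.p_value == pytest.approx(stats.chi2.sf(48, 48))
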