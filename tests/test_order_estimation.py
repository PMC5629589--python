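import numpy as np
import pytest

from markovcmp import (
    SequenceRecord,
    aic_bic_scan,
    count_words_sequence,
    estimate_order,
    expected_counts,
    p_scan,
    peres_shields_scan,
    t_scan,
    z_scan,
)
from markovcmp.alphabet import decode
from markovcmp.markov_model import simulate_sequences
from markovcmp.ngs_sim import sample_reads_homogeneous
from markovcmp.order_estimation import (
    aic_bic_from_counts,
    counts_for_lengths,
    criteria_from_counts,
    _ratio_scan,
)

from conftest import batch_records, naive_word_counts, record


def all_estimates(source, k_max=4):
    """All six order estimates of one source from a single count pass."""
    C = len(source.alphabet)
    cbl = counts_for_lengths(source, range(1, k_max + 2))
    crit = criteria_from_counts(cbl, C, k_max)
    out = {
        "ps": _ratio_scan(crit["delta"], k_max, "max"),
        "t": _ratio_scan(crit["t"], k_max, "min"),
        "p": _ratio_scan(crit["logp"], k_max, "min"),
        "z": _ratio_scan(crit["zmax"], k_max, "min"),
    }
    if not hasattr(source, "kappa"):
        aic, bic = aic_bic_from_counts(cbl, C, source.length, k_max)
        ks = sorted(aic)
        out["aic"] = ks[int(np.argmin([aic[k] for k in ks]))]
        out["bic"] = ks[int(np.argmin([bic[k] for k in ks]))]
    return out


class TestExpectedCounts:
    def test_small_example_against_marginal_oracle(self):
        # windows of AACC at k=2: AA, AC, CC; prefix A appears 2x, suffix C 2x
        t = count_words_sequence(record("AACC"), 2)
        E = expected_counts(t)
        ew = dict(zip([t.word(i) for i in range(16)], E))
        assert ew["AC"] == pytest.approx(2 * 2 / 3)
        assert ew["AA"] == pytest.approx(2 * 1 / 3)
        # brute-force marginals over the 3 windows
        pre = {"A": 2, "C": 1}
        suf = {"A": 1, "C": 2}
        for w, e in ew.items():
            expected = pre.get(w[0], 0) * suf.get(w[1], 0) / 3
            assert e == pytest.approx(expected)

    def test_single_repeated_word_collapses(self):
        t = count_words_sequence(record("AAAA"), 2)
        E = expected_counts(t)
        assert E[0] == pytest.approx(t.counts[0])  # E_AA = N_AA when one word dominates

    def test_expected_counts_conserve_total(self, table1):
        from markovcmp import simulate_sequence

        t = count_words_sequence(simulate_sequence(table1, 30_000, 4), 3)
        assert expected_counts(t).sum() == pytest.approx(t.total_windows, abs=1e-6)

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            expected_counts(count_words_sequence(record("ACGT"), 1))


class TestLongSequenceOracles:
    """Simulation oracles: each estimator must recover the true order of the
    generating chain on long sequences, for the bulk of replicate seeds."""

    def test_iid_sequence_estimated_as_order_zero(self, iid_uniform):
        hits = 0
        for rec in batch_records(iid_uniform, 30_000, 100, 50):
            hits += all_estimates(rec)["bic"] == 0
        assert hits >= 95

    def test_first_order_sequence(self, table1):
        counts = {m: 0 for m in ("aic", "bic", "ps", "t", "p", "z")}
        for rec in batch_records(table1, 30_000, 100, 51):
            est = all_estimates(rec)
            for m in counts:
                counts[m] += est[m] == 1
        assert counts["bic"] >= 95
        assert counts["p"] >= 95
        assert counts["ps"] >= 90

    def test_second_order_sequence(self, table2_second):
        counts = {"bic": 0, "p": 0}
        for rec in batch_records(table2_second, 30_000, 100, 52):
            est = all_estimates(rec)
            for m in counts:
                counts[m] += est[m] == 2
        assert counts["bic"] >= 90
        assert counts["p"] >= 90

    def test_accuracy_nondecreasing_in_length(self, table1):
        """Estimator consistency: the fraction of correct estimates grows with
        sequence length (one small Monte Carlo inversion tolerated)."""
        fractions = {"bic": [], "p": []}
        for j, L in enumerate((5_000, 10_000, 20_000, 30_000)):
            hits = {"bic": 0, "p": 0}
            for rec in batch_records(table1, L, 100, 60 + j):
                est = all_estimates(rec)
                for m in hits:
                    hits[m] += est[m] == 1
            for m in fractions:
                fractions[m].append(hits[m] / 100)
        for m, fr in fractions.items():
            diffs = np.diff(fr)
            assert np.all(diffs >= -0.02), (m, fr)
            assert np.sum(diffs < 0) <= 1, (m, fr)


class TestReadOracles:
    def test_peres_shields_on_reads_recovers_first_order(self, table1):
        seqs = simulate_sequences(table1, 20_000, 100, 70)
        rng = np.random.default_rng(71)
        hits_ps = hits_p = 0
        for arr in seqs:
            rec = SequenceRecord("s", decode(arr))
            reads = sample_reads_homogeneous(rec, 200, 200, rng)
            est = all_estimates(reads)
            hits_ps += est["ps"] == 1
            hits_p += est["p"] == 1
        assert hits_ps > 50
        assert hits_p > 50


class TestScanMechanics:
    def test_periodic_sequence_is_deterministic(self):
        rec = record("ACGT" * 5_000)
        first = peres_shields_scan(rec, 4)
        second = peres_shields_scan(rec, 4)
        assert first.estimate == second.estimate
        assert first.values == second.values

    def test_log_p_values_are_finite_and_nonpositive(self, table1):
        from markovcmp import simulate_sequence

        scan = p_scan(simulate_sequence(table1, 10_000, 9), 4)
        for v in scan.values.values():
            assert np.isfinite(v) and v <= 0

    def test_dispatch_matches_direct_scans(self, table1):
        from markovcmp import simulate_sequence

        rec = simulate_sequence(table1, 10_000, 21)
        assert estimate_order(rec, "p", 4).estimate == p_scan(rec, 4).estimate
        assert estimate_order(rec, "T", 4).estimate == t_scan(rec, 4).estimate
        assert estimate_order(rec, "z", 4).estimate == z_scan(rec, 4).estimate

    def test_aic_bic_rejected_on_reads(self, table1):
        from markovcmp import simulate_sequence

        seq = simulate_sequence(table1, 2_000, 2)
        reads = sample_reads_homogeneous(seq, 10, 100, 3)
        with pytest.raises(ValueError):
            aic_bic_scan(reads, 4)
        with pytest.raises(ValueError):
            estimate_order(reads, "aic", 4)

    def test_unknown_method_rejected(self, table1):
        from markovcmp import simulate_sequence

        with pytest.raises(ValueError):
            estimate_order(simulate_sequence(table1, 1_000, 2), "nope", 4)

    def test_alphabet_relabeling_leaves_estimates_unchanged(self, table1):
        """The ratio estimators depend on counts only, so permuting symbol
        labels cannot change them."""
        from markovcmp import simulate_sequence

        rec = simulate_sequence(table1, 5_000, 33)
        base = all_estimates(rec)
        rng = np.random.default_rng(34)
        for _ in range(5):
            perm = rng.permutation(list("ACGT"))
            mapping = dict(zip("ACGT", perm))
            relabeled = SequenceRecord("perm", "".join(mapping[c] for c in rec.symbols))
            est = all_estimates(relabeled)
            for m in ("ps", "t", "p", "z"):
                assert est[m] == base[m]

    def test_degenerate_all_zero_deviations_rejected(self):
        with pytest.raises(ValueError):
            peres_shields_scan(record("A" * 100), 3)
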