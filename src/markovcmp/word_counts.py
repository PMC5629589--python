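"""Overlapping word (k-mer) counting for long sequences and read sets.

Counts are dense over all ``C**k`` words in lexicographic order, because the
word-count statistics iterate over every word including zero cells, and the
word lengths used by the comparison method are small by design (``k <= 12``
is enforced).  Counting is on the forward strand only; any window containing
an ambiguous symbol is dropped from both the counts and the window total, so
the marginal identities stay exact on the retained windows.  Words are never
counted across read boundaries or across FASTA record boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import index_to_word

MAX_K = 12


@dataclass
class WordCountTable:
    """Dense counts of all length-``k`` words from one source.

    Attributes
    ----------
    k : word length.
    alphabet : ordered symbols (size ``C``).
    counts : int64 array of length ``C**k`` in lexicographic word order.
    source_kind : ``"sequence"`` or ``"reads"``.
    total_windows : number of counted windows (equals ``counts.sum()``).
    """

    k: int
    alphabet: str
    counts: np.ndarray
    source_kind: str
    total_windows: int

    def __post_init__(self) -> None:
        C = len(self.alphabet)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (C**self.k,):
            raise ValueError(f"counts must have length {C**self.k}")
        if self.source_kind not in ("sequence", "reads"):
            raise ValueError("source_kind must be 'sequence' or 'reads'")
        if int(self.counts.sum()) != self.total_windows:
            raise ValueError("total_windows must equal the sum of counts")

    def word(self, index: int) -> str:
        return index_to_word(index, self.k, self.alphabet)

    def as_dict(self, include_zeros: bool = False) -> dict[str, int]:
        if include_zeros:
            return {self.word(i): int(c) for i, c in enumerate(self.counts)}
        return {self.word(i): int(c) for i, c in enumerate(self.counts) if c}

    def to_tsv(self, path, include_zeros: bool = True) -> None:
        with open(path, "w") as fh:
            fh.write("word\tcount\n")
            for i, c in enumerate(self.counts):
                if include_zeros or c:
                    fh.write(f"{self.word(i)}\t{int(c)}\n")


def _check_k(k: int, C: int) -> None:
    if k < 1:
        raise ValueError("word length k must be >= 1")
    if k > MAX_K:
        raise ValueError(f"word length k={k} exceeds the dense-table guard ({MAX_K})")


def count_encoded_sequence(arr: np.ndarray, k: int, C: int) -> tuple[np.ndarray, int]:
    """Counts and window total for one encoded sequence (ambiguous = -1)."""
    L = arr.shape[0]
    n_win = L - k + 1
    valid = arr >= 0
    vals = np.where(valid, arr, 0).astype(np.int64)
    codes = np.zeros(n_win, dtype=np.int64)
    for j in range(k):
        codes = codes * C + vals[j : j + n_win]
    if valid.all():
        keep = codes
    else:
        bad = np.concatenate([[0], np.cumsum(~valid)])
        keep = codes[bad[k:] - bad[:-k] == 0]
    counts = np.bincount(keep, minlength=C**k)
    return counts, int(keep.shape[0])


def count_encoded_reads(arr2d: np.ndarray, k: int, C: int) -> tuple[np.ndarray, int]:
    """Counts and window total for an ``(M, kappa)`` encoded read array."""
    M, kappa = arr2d.shape
    n_win = kappa - k + 1
    valid = arr2d >= 0
    vals = np.where(valid, arr2d, 0).astype(np.int64)
    codes = np.zeros((M, n_win), dtype=np.int64)
    for j in range(k):
        codes = codes * C + vals[:, j : j + n_win]
    if valid.all():
        keep = codes.ravel()
    else:
        bad = np.concatenate(
            [np.zeros((M, 1), dtype=np.int64), np.cumsum(~valid, axis=1)], axis=1
        )
        keep = codes[(bad[:, k:] - bad[:, :-k]) == 0]
    counts = np.bincount(keep, minlength=C**k)
    return counts, int(keep.shape[0])


def count_words_sequence(seq, k: int) -> WordCountTable:
    """Count the ``L - k + 1`` overlapping length-``k`` windows of a sequence.

    Windows containing an ambiguous symbol are skipped and ``total_windows``
    reduced accordingly.
    """
    C = len(seq.alphabet)
    _check_k(k, C)
    if k > seq.length:
        raise ValueError(f"k={k} exceeds sequence length {seq.length}")
    counts, total = count_encoded_sequence(seq.encoded(), k, C)
    return WordCountTable(k, seq.alphabet, counts, "sequence", total)


def count_words_reads(reads, k: int) -> WordCountTable:
    """Count length-``k`` windows per read, summed over a read set.

    Each read of length ``kappa`` contributes its ``kappa - k + 1`` windows;
    words never span read boundaries.
    """
    C = len(reads.alphabet)
    _check_k(k, C)
    if k > reads.kappa:
        raise ValueError(f"k={k} exceeds read length {reads.kappa}")
    counts, total = count_encoded_reads(reads.encoded, k, C)
    return WordCountTable(k, reads.alphabet, counts, "reads", total)


def count_words_fasta(path, k: int) -> WordCountTable:
    """Count words in a (possibly multi-record) FASTA file.

    Records are counted separately and summed; junction windows between
    records are never formed.
    """
    from .io import read_fasta

    records = read_fasta(path)
    if not records:
        raise ValueError(f"no sequences in {path}")
    C = len(records[0].alphabet)
    _check_k(k, C)
    counts = np.zeros(C**k, dtype=np.int64)
    total = 0
    for rec in records:
        if rec.length >= k:
            c, t = count_encoded_sequence(rec.encoded(), k, C)
            counts += c
            total += t
    return WordCountTable(k, records[0].alphabet, counts, "sequence", total)


def prefix_marginal(counts: np.ndarray, C: int) -> np.ndarray:
    """``N_{w-}[u] = sum_a counts[u a]`` (last letter summed out)."""
    return counts.reshape(-1, C).sum(axis=1)


def suffix_marginal(counts: np.ndarray, C: int) -> np.ndarray:
    """``N_{-w}[u] = sum_a counts[a u]`` (first letter summed out)."""
    return counts.reshape(C, -1).sum(axis=0)


def both_marginal(counts: np.ndarray, C: int) -> np.ndarray:
    """``N_{-w-}[v] = sum_{a,b} counts[a v b]`` (both end letters summed out)."""
    return counts.reshape(C, -1, C).sum(axis=(0, 2))


def marginals(table: WordCountTable) -> tuple[WordCountTable, WordCountTable, WordCountTable]:
    """Prefix, suffix, and both-trimmed marginal tables of a k-table.

    Requires ``k >= 2``; for ``k == 2`` the both-trimmed table is over the
    single empty word and holds ``total_windows``.
    """
    if table.k < 2:
        raise ValueError("marginals require k >= 2")
    C = len(table.alphabet)
    pre = prefix_marginal(table.counts, C)
    suf = suffix_marginal(table.counts, C)
    mid = both_marginal(table.counts, C)
    mk = lambda k, c: WordCountTable(k, table.alphabet, c, table.source_kind, table.total_windows)
    return mk(table.k - 1, pre), mk(table.k - 1, suf), mk(table.k - 2, mid)
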