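"""Two-sample word-count statistics for testing equality of Markov models.

Given length-``k`` word counts ``N_w`` from two sources, the null hypothesis
is that both sources follow the same order-``(k-1)`` Markov chain.  The
log-likelihood ratio for that test is

    log(P1/P0) = sum_s sum_w N^(s)_w log( N^(s)_w N^(-)_{w-} /
                                          (N^(s)_{w-} N^(-)_w) ),

where ``w-`` drops the last letter and ``N^(-)`` pools the two sources.
Twice the log-likelihood ratio shares its asymptotic law with the
chi-square-type statistic

    S_k = sum_s sum_{w-} sum_{w_k}
          (N^(s)_w - N^(s)_{w-} N^(-)_w / N^(-)_{w-})^2
          / (N^(s)_{w-} N^(-)_w / N^(-)_{w-}),

which depends only on word counts and therefore also applies to sequencing
reads (the likelihood itself does not, because overlapping reads are
dependent).  For ``k = 1`` the statistic compares symbol frequencies
directly with ``N_{w-}`` replaced by the window totals.

Under the null, ``S_k`` (long sequences) and ``S_k^R / d`` (reads, with the
coverage scaling ``d``) are approximately chi-square with
``df = (C-1) C**(k-1)`` degrees of freedom.  Under Poisson (Lander-Waterman)
coverage at mean depth ``lambda = M*kappa/L``, ``d = 1 + lambda``; in general
``d = sum_i r_i^2 f_i / sum_j r_j f_j`` over the coverage-level histogram.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .word_counts import WordCountTable, prefix_marginal


def chi2_log_tail(x: float, df: float) -> float:
    """Natural-log upper-tail chi-square probability, finite for any x.

    ``scipy.stats.chi2.logsf`` underflows to -inf once the tail drops below
    the smallest double (log p < ~-745); beyond that point the asymptotic
    expansion of the upper incomplete gamma function,

        sf(x; df) ~ s^(a-1) e^(-s) / Gamma(a) * (1 + (a-1)/s + ...),

    with ``a = df/2`` and ``s = x/2``, is used instead.  The criterion scans
    that ratio log tails rely on this staying finite.
    """
    v = float(stats.chi2.logsf(x, df))
    if np.isfinite(v):
        return v
    a, s = df / 2.0, x / 2.0
    base = -s + (a - 1.0) * np.log(s) - gammaln(a)
    corr, term = 1.0, 1.0
    for i in range(1, 12):
        term *= (a - i) / s
        if term <= 0 or abs(term) < 1e-18:
            break
        corr += term
    return float(base + np.log(corr))


@dataclass
class ComparisonResult:
    """Outcome of a two-source word-count comparison."""

    k: int
    statistic: float
    df: int
    d: float = 1.0
    loglik_ratio: float | None = None

    @property
    def scaled_statistic(self) -> float:
        return self.statistic / self.d

    @property
    def p_value(self) -> float:
        return float(stats.chi2.sf(self.scaled_statistic, self.df))

    @property
    def log_p_value(self) -> float:
        """Natural-log upper-tail probability (finite even when p underflows)."""
        return chi2_log_tail(self.scaled_statistic, self.df)


@dataclass
class CoverageProfile:
    """Histogram of per-base coverage levels of a read layout.

    ``levels[i]`` is a distinct coverage value and ``fractions[i]`` the
    fraction of bases covered exactly that many times (the zero level is
    allowed and contributes nothing to the scaling).  ``lam`` is the mean
    coverage ``M*kappa/L`` when known.
    """

    levels: np.ndarray
    fractions: np.ndarray
    lam: float | None = None

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.levels.shape != self.fractions.shape:
            raise ValueError("levels and fractions must have the same shape")
        if np.any(self.fractions < 0):
            raise ValueError("fractions must be nonnegative")

    @classmethod
    def poisson(cls, lam: float, tol: float = 1e-12) -> "CoverageProfile":
        """Poisson(lam) coverage histogram truncated where the mass drops below tol."""
        if lam <= 0:
            raise ValueError("lam must be positive")
        upper = int(stats.poisson.isf(tol, lam)) + 1
        levels = np.arange(upper + 1)
        return cls(levels, stats.poisson.pmf(levels, lam), lam)


def degrees_of_freedom(C: int, k: int) -> int:
    """``(C - 1) * C**(k - 1)`` -- the chi-square df of S_k on a C-letter alphabet."""
    if C < 2:
        raise ValueError("alphabet size C must be >= 2")
    if k < 1:
        raise ValueError("word length k must be >= 1")
    return (C - 1) * C ** (k - 1)


def chi2_from_counts(n1: np.ndarray, n2: np.ndarray, t1: int, t2: int, k: int, C: int) -> float:
    """S_k from two dense count vectors and their window totals.

    Terms whose denominator vanishes are skipped (they are 0/0 limits of the
    summand).  Summation is in lexicographic word order for bit-for-bit
    reproducibility.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if k == 1:
        pool = n1 + n2
        mask = pool > 0
        p1 = n1 / t1
        p2 = n2 / t2
        num = t1 * t2 * (p1 - p2) ** 2
        return float(np.sum(num[mask] / pool[mask]))
    pre1 = n1.reshape(-1, C).sum(axis=1)
    pre2 = n2.reshape(-1, C).sum(axis=1)
    pool = (n1 + n2).reshape(-1, C)
    pool_pre = pre1 + pre2
    total = 0.0
    for ns, pres in ((n1.reshape(-1, C), pre1), (n2.reshape(-1, C), pre2)):
        mask = (pres[:, None] > 0) & (pool > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            expected = (pres[:, None] * pool / pool_pre[:, None])[mask]
        total += float(np.sum((ns[mask] - expected) ** 2 / expected))
    return total


def _check_pair(tableA: WordCountTable, tableB: WordCountTable) -> None:
    if tableA.k != tableB.k:
        raise ValueError("tables have different word lengths")
    if tableA.alphabet != tableB.alphabet:
        raise ValueError("tables have different alphabets")
    if tableA.total_windows == 0 and tableB.total_windows == 0:
        raise ValueError("both tables are empty")


def chi2_statistic(tableA: WordCountTable, tableB: WordCountTable, d=1.0) -> ComparisonResult:
    """The chi-square statistic S_k (or S_k^R) for two word-count tables.

    ``d`` is the coverage scaling: 1 for long sequences; for reads pass a
    :class:`CoverageProfile`, or ``1 + lambda`` under homogeneous (Poisson)
    coverage.  The statistic itself is unscaled; ``scaled_statistic`` and the
    p-value divide by ``d``.
    """
    _check_pair(tableA, tableB)
    if isinstance(d, CoverageProfile):
        d = scaling_d(d)
    if d <= 0:
        raise ValueError("scaling d must be positive")
    C = len(tableA.alphabet)
    stat = chi2_from_counts(
        tableA.counts, tableB.counts, tableA.total_windows, tableB.total_windows, tableA.k, C
    )
    return ComparisonResult(tableA.k, stat, degrees_of_freedom(C, tableA.k), float(d))


def loglik_ratio(tableA: WordCountTable, tableB: WordCountTable) -> float:
    """log(P1/P0) for two long-sequence word-count tables.

    Read-derived tables are rejected: overlapping reads are dependent, so the
    product-form likelihood does not hold for them.  Terms with
    ``N^(s)_w = 0`` contribute 0.
    """
    _check_pair(tableA, tableB)
    if tableA.source_kind == "reads" or tableB.source_kind == "reads":
        raise ValueError("the likelihood ratio is defined for long sequences, not reads")
    C = len(tableA.alphabet)
    n1 = tableA.counts.astype(float)
    n2 = tableB.counts.astype(float)
    if tableA.k == 1:
        pre1 = np.full(1, float(tableA.total_windows))
        pre2 = np.full(1, float(tableB.total_windows))
        shape = (1, C)
    else:
        pre1 = prefix_marginal(tableA.counts, C).astype(float)
        pre2 = prefix_marginal(tableB.counts, C).astype(float)
        shape = (-1, C)
    pool = (n1 + n2).reshape(shape)
    pool_pre = pre1 + pre2
    total = 0.0
    for ns, pres in ((n1.reshape(shape), pre1), (n2.reshape(shape), pre2)):
        mask = ns > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = ns * pool_pre[:, None] / (pres[:, None] * pool)
        total += float(np.sum(np.log(ratio[mask]) * ns[mask]))
    return total


def scaling_d(profile: CoverageProfile) -> float:
    """``d = sum_i r_i^2 f_i / sum_j r_j f_j`` over the coverage histogram."""
    num = float(np.sum(profile.levels**2 * profile.fractions))
    den = float(np.sum(profile.levels * profile.fractions))
    if den <= 0:
        raise ValueError("coverage is zero everywhere")
    return num / den


def coverage_profile_from_reads(reads, L: int | None = None) -> CoverageProfile:
    """Per-base coverage histogram of a read layout with known start positions."""
    if reads.starts is None:
        raise ValueError("read set has no recorded start positions")
    if L is None:
        L = reads.source_length
    if L is None:
        raise ValueError("source length unknown")
    starts = np.asarray(reads.starts, dtype=np.int64)
    if np.any(starts < 0) or np.any(starts + reads.kappa > L):
        raise ValueError("a read extends past the source boundaries")
    diff = np.zeros(L + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, starts + reads.kappa, -1)
    cov = np.cumsum(diff[:-1])
    levels, counts = np.unique(cov, return_counts=True)
    return CoverageProfile(levels, counts / L, reads.M * reads.kappa / L)


def p_value(result: ComparisonResult) -> float:
    """Upper-tail chi-square probability of ``statistic / d`` at ``df``."""
    if result.df < 1 or result.d <= 0:
        raise ValueError("need df >= 1 and d > 0")
    return float(stats.chi2.sf(result.statistic / result.d, result.df))
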