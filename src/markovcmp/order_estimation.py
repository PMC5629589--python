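"""Markov-order estimation from word counts.

Six estimators of the order ``r`` of a Markov source are provided, all of
which scan candidate word lengths and locate the point where an order-(k-2)
fit starts explaining the length-k word counts:

* ``aic`` / ``bic`` -- penalized-likelihood criteria minimized over k
  (long sequences only; the read likelihood is intractable because
  overlapping reads are dependent);
* ``ps`` (Peres-Shields) -- the maximal cell deviation
  ``Delta^k = max_w |N_w - E_w|`` with ``E_w = N_{-w} N_{w-} / N_{-w-}``;
  the estimate is ``argmax_k Delta^k / Delta^{k+1} - 1``;
* ``t`` -- the goodness-of-fit sum ``T_k = sum_w (N_w - E_w)^2 / E_w``,
  approximately chi-square with ``(C-1)^2 C^(k-2)`` df once ``k >= r + 2``
  and the table is dense (when cells with zero expectation are excluded,
  the df is reduced proportionally);
  the estimate is ``argmin_k T_{k+1}/T_k - 1``;
* ``p`` -- the same scan on the log tail probabilities ``log p_k`` of
  ``T_k`` (evaluated directly in log space: for ``k <= r + 1`` the tail
  underflows double precision, which would destroy the ratio);
* ``z`` -- the maximal standardized cell deviation
  ``Z_max(k) = max_w |N_w - E_w| / sigma_w`` with
  ``sigma_w^2 = E_w (1 - N_{-w}/N_{-w-}) (1 - N_{w-}/N_{-w-})``.

The count-based estimators (``ps``, ``t``, ``p``, ``z``) accept either a
long sequence or a read set; only the word counts enter.

Scan convention: criterion values are computed for word lengths
``k = 1 .. k_max + 1`` and the ratio scans search ``k = 1 .. k_max``, so
estimable orders are ``0 .. k_max - 1``.  The general ``E_w`` needs
length-(k-2) marginals and is undefined at ``k = 1``; there the uniform
baseline ``E_w = total/C`` (with both marginals replaced by ``total/C`` in
``sigma_w``) is used as the natural degenerate extension, which is what
makes order 0 estimable.  Ties always break toward the smallest k, and a
criterion ratio with an exactly zero denominator (a perfect fit at that
level) is treated as +infinity.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .comparison import chi2_log_tail
from .word_counts import (
    WordCountTable,
    both_marginal,
    count_encoded_reads,
    count_encoded_sequence,
    prefix_marginal,
    suffix_marginal,
)

METHODS = ("aic", "bic", "ps", "t", "p", "z")
DEFAULT_K_MAX = 6


@dataclass
class OrderScan:
    """Per-k criterion values and the resulting order estimate for one method."""

    method: str
    k_range: tuple[int, int]
    values: dict[int, float]
    estimate: int


def _is_reads(source) -> bool:
    return hasattr(source, "kappa")


def _encoded(source):
    return source.encoded if _is_reads(source) else source.encoded()


def counts_for_lengths(source, lengths) -> dict[int, tuple[np.ndarray, int]]:
    """Dense word counts (and window totals) of one source for several word lengths."""
    C = len(source.alphabet)
    arr = _encoded(source)
    out = {}
    for k in lengths:
        if _is_reads(source):
            out[k] = count_encoded_reads(arr, k, C)
        else:
            out[k] = count_encoded_sequence(arr, k, C)
    return out


def expected_counts(table: WordCountTable) -> np.ndarray:
    """``E_w = N_{-w} N_{w-} / N_{-w-}`` for every word of a k-table (k >= 2).

    ``E_w`` is 0 wherever the trimmed marginal ``N_{-w-}`` is 0.
    """
    if table.k < 2:
        raise ValueError("expected counts require k >= 2")
    C = len(table.alphabet)
    return _expected_from_counts(table.counts, table.k, C)[0].ravel()


def _expected_from_counts(counts: np.ndarray, k: int, C: int):
    """E_w and sigma_w^2 in (C, C**(k-2), C) layout; also the masks of valid cells."""
    c3 = counts.reshape(C, C ** (k - 2), C).astype(float)
    pre = prefix_marginal(counts, C).astype(float).reshape(C, C ** (k - 2))
    suf = suffix_marginal(counts, C).astype(float).reshape(C ** (k - 2), C)
    mid = both_marginal(counts, C).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        E = pre[:, :, None] * suf[None, :, :] / mid[None, :, None]
        sigma2 = E * (1 - suf[None, :, :] / mid[None, :, None]) * (
            1 - pre[:, :, None] / mid[None, :, None]
        )
    E = np.where(mid[None, :, None] > 0, E, 0.0)
    sigma2 = np.where(mid[None, :, None] > 0, sigma2, 0.0)
    return E, sigma2, c3


def _criteria_one_k(counts: np.ndarray, total: int, k: int, C: int):
    """(Delta^k, T_k, log p_k, Z_max(k)) for one word length."""
    if k == 1:
        E = total / C
        diff = counts.astype(float) - E
        delta = float(np.max(np.abs(diff))) if total else 0.0
        T = float(np.sum(diff**2) / E) if total else 0.0
        df = (C - 1) ** 2 / C
        sigma2 = E * (1 - 1 / C) ** 2
        zmax = float(np.max(np.abs(diff)) / np.sqrt(sigma2)) if total else 0.0
    else:
        E, sigma2, c3 = _expected_from_counts(counts, k, C)
        diff = c3 - E
        ok = E > 0
        delta = float(np.max(np.abs(diff[ok]))) if ok.any() else 0.0
        T = float(np.sum(diff[ok] ** 2 / E[ok])) if ok.any() else 0.0
        # T_k is a sum of per-stratum independence statistics: for each
        # middle word m, the (first letter) x (last letter) contingency
        # table contributes (r_m - 1)(c_m - 1) df over its observed support.
        # This equals the dense-table value (C-1)^2 C^(k-2) when every cell
        # is populated; on sparse tables it stops p_k from saturating at 1
        # (tiny strata are fitted exactly and contribute neither to T nor
        # to the df), which would break the log-p ratio scan.
        pre_pos = (c3.sum(axis=2) > 0).sum(axis=0)  # r_m: observed first letters
        suf_pos = (c3.sum(axis=0) > 0).sum(axis=1)  # c_m: observed last letters
        df = max(float(np.sum(np.maximum(pre_pos - 1, 0) * np.maximum(suf_pos - 1, 0))), 1.0)
        okz = sigma2 > 0
        zmax = float(np.max(np.abs(diff[okz]) / np.sqrt(sigma2[okz]))) if okz.any() else 0.0
    logp = chi2_log_tail(T, df)
    return delta, T, logp, zmax


def criteria_from_counts(
    counts_by_len: Mapping[int, tuple[np.ndarray, int]], C: int, k_max: int
) -> dict[str, dict[int, float]]:
    """Delta, T, log p, and Z_max for word lengths 1 .. k_max + 1."""
    out = {"delta": {}, "t": {}, "logp": {}, "zmax": {}}
    for k in range(1, k_max + 2):
        counts, total = counts_by_len[k]
        delta, T, logp, zmax = _criteria_one_k(counts, total, k, C)
        out["delta"][k] = delta
        out["t"][k] = T
        out["logp"][k] = logp
        out["zmax"][k] = zmax
    return out


def _ratio_scan(values: dict[int, float], k_max: int, mode: str) -> int:
    """argmin/argmax over k = 1..k_max of values[k+1]/values[k]-style ratios, minus 1.

    For the Peres-Shields scan (``mode='max'``) the ratio is
    ``values[k] / values[k+1]``; for the others ``values[k+1] / values[k]``.
    A zero denominator yields +inf; ties break toward the smallest k.
    """
    ratios = np.empty(k_max)
    for i, k in enumerate(range(1, k_max + 1)):
        num, den = (values[k], values[k + 1]) if mode == "max" else (values[k + 1], values[k])
        ratios[i] = np.inf if den == 0 else num / den
    idx = int(np.argmax(ratios)) if mode == "max" else int(np.argmin(ratios))
    return idx  # (idx + 1) - 1: ks start at 1 and the estimate subtracts 1


def _count_scan(source, method: str, k_max: int) -> OrderScan:
    C = len(source.alphabet)
    counts_by_len = counts_for_lengths(source, range(1, k_max + 2))
    crit = criteria_from_counts(counts_by_len, C, k_max)
    key = {"ps": "delta", "t": "t", "p": "logp", "z": "zmax"}[method]
    values = crit[key]
    if method == "ps" and all(crit["delta"][k] == 0 for k in range(2, k_max + 2)):
        raise ValueError("degenerate source: all Delta^k are zero")
    mode = "max" if method == "ps" else "min"
    estimate = _ratio_scan(values, k_max, mode)
    return OrderScan(method, (1, k_max + 1), values, estimate)


def peres_shields_scan(source, k_max: int = DEFAULT_K_MAX) -> OrderScan:
    """Order estimate from the maximal-deviation ratio scan (sequence or reads)."""
    return _count_scan(source, "ps", k_max)


def t_scan(source, k_max: int = DEFAULT_K_MAX) -> OrderScan:
    """Order estimate from the goodness-of-fit ratio ``T_{k+1}/T_k``."""
    return _count_scan(source, "t", k_max)


def p_scan(source, k_max: int = DEFAULT_K_MAX) -> OrderScan:
    """Order estimate from the log tail-probability ratio ``log p_{k+1} / log p_k``."""
    return _count_scan(source, "p", k_max)


def z_scan(source, k_max: int = DEFAULT_K_MAX) -> OrderScan:
    """Order estimate from the standardized-deviation ratio ``Z_max(k+1)/Z_max(k)``."""
    return _count_scan(source, "z", k_max)


def loglik_terms(counts_by_len: Mapping[int, tuple[np.ndarray, int]], C: int, k_max: int) -> dict[int, float]:
    """``sum_w N_w log(N_w / N_{w-})`` over (k+1)-words, for k = 0 .. k_max."""
    out = {}
    for k in range(0, k_max + 1):
        counts, total = counts_by_len[k + 1]
        n = counts.astype(float)
        if k == 0:
            pre = np.full(1, float(total))
        else:
            pre = prefix_marginal(counts, C).astype(float)
        n2 = n.reshape(-1, C)
        mask = n2 > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = n2 / pre[:, None]
        out[k] = float(np.sum(n2[mask] * np.log(ratio[mask])))
    return out


def aic_bic_from_counts(
    counts_by_len: Mapping[int, tuple[np.ndarray, int]], C: int, L: int, k_max: int
) -> tuple[dict[int, float], dict[int, float]]:
    """AIC(k) and BIC(k) maps for k = 0 .. k_max from precomputed counts."""
    ll = loglik_terms(counts_by_len, C, k_max)
    aic = {k: -2 * ll[k] + 2 * (C - 1) * C**k for k in ll}
    bic = {k: -2 * ll[k] + (C - 1) * C**k * np.log(L - k + 1) for k in ll}
    return aic, bic


def aic_bic_scan(seq, k_max: int = DEFAULT_K_MAX) -> tuple[OrderScan, OrderScan]:
    """AIC and BIC order scans of a long sequence (read sets are rejected)."""
    if _is_reads(seq):
        raise ValueError("AIC/BIC need the sequence likelihood and cannot be used on reads")
    C = len(seq.alphabet)
    counts_by_len = counts_for_lengths(seq, range(1, k_max + 2))
    aic, bic = aic_bic_from_counts(counts_by_len, C, seq.length, k_max)
    ks = sorted(aic)
    est_aic = ks[int(np.argmin([aic[k] for k in ks]))]
    est_bic = ks[int(np.argmin([bic[k] for k in ks]))]
    return (
        OrderScan("aic", (0, k_max), aic, est_aic),
        OrderScan("bic", (0, k_max), bic, est_bic),
    )


def estimate_order(source, method: str, k_max: int = DEFAULT_K_MAX) -> OrderScan:
    """Dispatch to one of the six order estimators by name.

    ``method`` is one of ``aic, bic, ps, t, p, z`` (case-insensitive).
    AIC and BIC reject read sets.
    """
    m = method.lower()
    if m not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if m in ("aic", "bic"):
        scans = aic_bic_scan(source, k_max)
        return scans[0] if m == "aic" else scans[1]
    return _count_scan(source, m, k_max)
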