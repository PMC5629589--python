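"""Null/alternative simulation protocol: thresholds, power curves, power loss.

The protocol estimates the power of the word-count statistic at a word
length ``k`` by Monte Carlo:

1. simulate many replicate pairs of sequences from the *null* model (both
   sources share one transition law), optionally turn each sequence into a
   shotgun read set with errors, and compute ``S_k`` (or ``S_k^R``) per
   replicate;
2. take an empirical percentile of the null sample as the rejection
   threshold (the default nominal type-I error is 0.05, i.e. the 95th
   percentile);
3. simulate replicate pairs under the *alternative* (two different models)
   and report the fraction of statistics above the threshold.

Because the threshold is an empirical quantile of the same statistic, the
coverage scaling ``d`` cancels and the raw statistic is used throughout.
``power_loss_experiment`` additionally estimates the Markov orders of both
simulated sources per replicate, scores the statistic at
``k_hat = max(r_hat_1, r_hat_2) + 1`` against the matching threshold, and
reports the power difference relative to the optimal word length
``k_opt = max(r_1, r_2) + 1`` known from the generating models.

Sequence simulation is batched across replicates; read sampling and
sequencing errors use an independent child seed per replicate index.  Every
experiment is deterministic given ``ExperimentConfig.seed``.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import takewhile
from typing import Sequence

import numpy as np

from .comparison import chi2_from_counts
from .markov_model import MarkovModel, effective_order, simulate_sequences
from .ngs_sim import (
    DEFAULT_BLOCKS,
    DEFAULT_GAMMA_SCALE,
    DEFAULT_GAMMA_SHAPE,
    apply_errors_array,
    gather_reads,
    sample_starts_heterogeneous,
    sample_starts_homogeneous,
)
from .order_estimation import (
    DEFAULT_K_MAX,
    METHODS,
    aic_bic_from_counts,
    criteria_from_counts,
    _ratio_scan,
)
from .word_counts import count_encoded_reads, count_encoded_sequence

READ_MODES = ("none", "hom", "het")


@dataclass
class ExperimentConfig:
    """Everything one power experiment needs, including its base seed."""

    model_null: MarkovModel
    model_alt_a: MarkovModel
    model_alt_b: MarkovModel
    L: int
    k_values: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    reps_null: int = 2000
    reps_alt: int = 500
    level: float = 0.05
    read_mode: str = "none"
    M: int = 200
    kappa: int = 200
    error_rate: float = 0.0
    het_blocks: int = DEFAULT_BLOCKS
    het_shape: float = DEFAULT_GAMMA_SHAPE
    het_scale: float = DEFAULT_GAMMA_SCALE
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("level must lie in (0, 1)")
        if self.reps_null < 1 or self.reps_alt < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.read_mode not in READ_MODES:
            raise ValueError(f"read_mode must be one of {READ_MODES}")
        for m in (self.model_null, self.model_alt_a, self.model_alt_b):
            if m.alphabet != self.model_null.alphabet:
                raise ValueError("all models must share one alphabet")


@dataclass
class PowerResult:
    """Empirical threshold and power at one word length."""

    k: int
    threshold: float
    power: float
    reps: int
    power_loss: float | None = None
    method: str | None = None


def _replicate_stats(
    model_a: MarkovModel,
    model_b: MarkovModel,
    cfg: ExperimentConfig,
    ks: Sequence[int],
    reps: int,
    seed_seq: np.random.SeedSequence,
    order_methods: Sequence[str] | None = None,
    k_max: int = DEFAULT_K_MAX,
):
    """Per-replicate statistics (and order-based word lengths) for one model pair."""
    C = model_a.n_symbols
    need = set(ks)
    if order_methods:
        bad = set(order_methods) - set(METHODS)
        if bad:
            raise ValueError(f"unknown order methods: {sorted(bad)}")
        if cfg.read_mode != "none" and ({"aic", "bic"} & set(order_methods)):
            raise ValueError("AIC/BIC cannot estimate the order from reads")
        need |= set(range(1, k_max + 2))
    need = sorted(need)
    ss_a, ss_b, ss_rep = seed_seq.spawn(3)
    seqs_a = simulate_sequences(model_a, cfg.L, reps, np.random.default_rng(ss_a))
    seqs_b = simulate_sequences(model_b, cfg.L, reps, np.random.default_rng(ss_b))
    rep_seeds = ss_rep.spawn(reps) if cfg.read_mode != "none" else [None] * reps

    stats_out = np.empty((reps, len(ks)))
    khat = {m: np.empty(reps, dtype=np.int64) for m in (order_methods or [])}
    ratio_methods = [m for m in (order_methods or []) if m not in ("aic", "bic")]
    ll_methods = [m for m in (order_methods or []) if m in ("aic", "bic")]

    for i in range(reps):
        sources = []
        rep_rngs = (
            [np.random.default_rng(s) for s in rep_seeds[i].spawn(2)]
            if cfg.read_mode != "none"
            else (None, None)
        )
        for arr, which in ((seqs_a[i], 0), (seqs_b[i], 1)):
            if cfg.read_mode == "none":
                counts = {k: count_encoded_sequence(arr, k, C) for k in need}
            else:
                rng = rep_rngs[which]
                if cfg.read_mode == "hom":
                    starts = sample_starts_homogeneous(rng, cfg.L, cfg.kappa, cfg.M)
                else:
                    starts = sample_starts_heterogeneous(
                        rng, cfg.L, cfg.kappa, cfg.M,
                        cfg.het_blocks, cfg.het_shape, cfg.het_scale,
                    )
                reads = gather_reads(arr, starts, cfg.kappa)
                if cfg.error_rate > 0:
                    reads = apply_errors_array(rng, reads, cfg.error_rate, C)
                counts = {k: count_encoded_reads(reads, k, C) for k in need}
            sources.append(counts)
        ca, cb = sources
        for j, k in enumerate(ks):
            stats_out[i, j] = chi2_from_counts(ca[k][0], cb[k][0], ca[k][1], cb[k][1], k, C)
        if order_methods:
            ests = {m: [] for m in order_methods}
            for counts in sources:
                if ratio_methods:
                    crit = criteria_from_counts(counts, C, k_max)
                    key = {"ps": "delta", "t": "t", "p": "logp", "z": "zmax"}
                    for m in ratio_methods:
                        mode = "max" if m == "ps" else "min"
                        ests[m].append(_ratio_scan(crit[key[m]], k_max, mode))
                if ll_methods:
                    aic, bic = aic_bic_from_counts(counts, C, cfg.L, k_max)
                    ks_ll = sorted(aic)
                    if "aic" in ll_methods:
                        ests["aic"].append(ks_ll[int(np.argmin([aic[k] for k in ks_ll]))])
                    if "bic" in ll_methods:
                        ests["bic"].append(ks_ll[int(np.argmin([bic[k] for k in ks_ll]))])
            for m in order_methods:
                khat[m][i] = int(np.clip(max(ests[m]) + 1, 1, k_max))
    return stats_out, khat


def null_distribution(cfg: ExperimentConfig, k: int) -> np.ndarray:
    """Replicate sample of the statistic at word length ``k`` under the null."""
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(0,))
    stats, _ = _replicate_stats(cfg.model_null, cfg.model_null, cfg, [k], cfg.reps_null, ss)
    return stats[:, 0]


def empirical_threshold(sample, level: float) -> float:
    """Order-statistic percentile (type-7 linear interpolation) of a sample."""
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise ValueError("empty sample")
    return float(np.quantile(sample, level, method="linear"))


def estimate_power(cfg: ExperimentConfig, k: int, threshold: float) -> PowerResult:
    """Fraction of alternative replicates whose statistic exceeds the threshold."""
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(1,))
    stats, _ = _replicate_stats(cfg.model_alt_a, cfg.model_alt_b, cfg, [k], cfg.reps_alt, ss)
    return PowerResult(k, threshold, float(np.mean(stats[:, 0] > threshold)), cfg.reps_alt)


def power_curve(cfg: ExperimentConfig, k_values: Sequence[int] | None = None) -> list[PowerResult]:
    """Empirical thresholds and powers over a range of word lengths.

    Null replicates (and alternative replicates) are shared across word
    lengths: each simulated pair is scored at every ``k``, matching the
    single-threshold protocol and reducing Monte Carlo variance.
    """
    ks = list(k_values if k_values is not None else cfg.k_values)
    ss_null = np.random.SeedSequence(cfg.seed, spawn_key=(0,))
    ss_alt = np.random.SeedSequence(cfg.seed, spawn_key=(1,))
    null_stats, _ = _replicate_stats(cfg.model_null, cfg.model_null, cfg, ks, cfg.reps_null, ss_null)
    alt_stats, _ = _replicate_stats(cfg.model_alt_a, cfg.model_alt_b, cfg, ks, cfg.reps_alt, ss_alt)
    out = []
    for j, k in enumerate(ks):
        thr = empirical_threshold(null_stats[:, j], 1 - cfg.level)
        out.append(PowerResult(k, thr, float(np.mean(alt_stats[:, j] > thr)), cfg.reps_alt))
    return out


def power_loss_experiment(
    cfg: ExperimentConfig,
    order_method: str | Sequence[str],
    k_max: int = DEFAULT_K_MAX,
):
    """Power achieved when the word length comes from estimated Markov orders.

    Per alternative replicate the orders of both simulated sources are
    estimated, the statistic is scored at ``k_hat = max + 1`` against the
    threshold for that word length, and the resulting power is compared with
    the power at the optimal word length implied by the generating models.
    Returns one :class:`PowerResult` (with ``power_loss`` filled) per method;
    a single method name yields a single result.
    """
    single = isinstance(order_method, str)
    methods = [order_method] if single else list(order_method)
    k_opt = max(effective_order(cfg.model_alt_a), effective_order(cfg.model_alt_b)) + 1
    if k_opt > k_max:
        raise ValueError("k_max too small for the models' true orders")
    ks = list(range(1, k_max + 1))
    ss_null = np.random.SeedSequence(cfg.seed, spawn_key=(0,))
    ss_alt = np.random.SeedSequence(cfg.seed, spawn_key=(1,))
    null_stats, _ = _replicate_stats(cfg.model_null, cfg.model_null, cfg, ks, cfg.reps_null, ss_null)
    thr = np.array([empirical_threshold(null_stats[:, j], 1 - cfg.level) for j in range(len(ks))])
    alt_stats, khat = _replicate_stats(
        cfg.model_alt_a, cfg.model_alt_b, cfg, ks, cfg.reps_alt, ss_alt,
        order_methods=methods, k_max=k_max,
    )
    power_opt = float(np.mean(alt_stats[:, k_opt - 1] > thr[k_opt - 1]))
    rows = np.arange(cfg.reps_alt)
    results = {}
    for m in methods:
        kh = khat[m]
        power_m = float(np.mean(alt_stats[rows, kh - 1] > thr[kh - 1]))
        results[m] = PowerResult(
            k=k_opt,
            threshold=float(thr[k_opt - 1]),
            power=power_m,
            reps=cfg.reps_alt,
            power_loss=power_opt - power_m,
            method=m,
        )
    return results[order_method] if single else results


def selectivity_sensitivity(ranked_labels: Sequence[bool], top_n: int = 20) -> tuple[int, int]:
    """Ranking quality of a dissimilarity search against known relatedness.

    ``ranked_labels`` flags, in ascending order of dissimilarity, whether
    each retrieved item is truly related to the query.  *Selectivity* is the
    length of the initial all-related run (consecutive correct
    classifications); *sensitivity* is the number of related items among the
    first ``top_n``.
    """
    labels = list(ranked_labels)
    if not labels:
        raise ValueError("empty ranking")
    if top_n > len(labels):
        raise ValueError("top_n exceeds the ranking length")
    selectivity = sum(1 for _ in takewhile(bool, labels))
    sensitivity = int(sum(bool(x) for x in labels[:top_n]))
    return selectivity, sensitivity
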