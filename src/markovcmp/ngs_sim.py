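"""Shotgun-read simulation from a long sequence.

Reads have a fixed length ``kappa`` and are sampled independently with
replacement from the forward strand, with start positions restricted to
``{0, ..., L - kappa}`` (no wrap-around and no truncated tail reads).  Two
sampling schemes are supported:

* homogeneous -- starts uniform over the valid range, the standard
  Lander-Waterman setting where per-base coverage is approximately
  Poisson with mean ``lambda = M * kappa / L``;
* heterogeneous -- the sequence is cut into equal blocks, each block
  receives an independent Gamma(shape, scale) intensity, and start
  positions are drawn proportionally to their block's intensity (a crude
  model of library-preparation coverage bias).  The normalization makes
  the law invariant to the scale parameter; defaults are 100 blocks with
  Gamma(1, 20), i.e. exponential weights.

Sequencing errors are substitution-only: each base is independently
miscalled with the given rate, uniformly over the other ``C - 1`` symbols.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import DNA, as_rng, decode

DEFAULT_BLOCKS = 100
DEFAULT_GAMMA_SHAPE = 1.0
DEFAULT_GAMMA_SCALE = 20.0


@dataclass
class ErrorModel:
    """Substitution-only sequencing error model (uniform over the other bases)."""

    per_base_rate: float = 0.005

    def __post_init__(self) -> None:
        if not 0 <= self.per_base_rate < 1:
            raise ValueError("per_base_rate must lie in [0, 1)")


@dataclass
class ReadSet:
    """``M`` fixed-length reads, optionally with their source start positions.

    ``encoded`` is an ``(M, kappa)`` int8 array of symbol codes.  ``starts``
    (when known) allows the per-base coverage profile of the layout to be
    recomputed; reads parsed from a plain FASTA/FASTQ file have no layout.
    """

    encoded: np.ndarray
    alphabet: str = DNA
    starts: np.ndarray | None = None
    source_length: int | None = None
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.encoded = np.asarray(self.encoded, dtype=np.int8)
        if self.encoded.ndim != 2:
            raise ValueError("encoded reads must form an (M, kappa) array")
        if self.starts is not None:
            self.starts = np.asarray(self.starts, dtype=np.int64)
            if self.starts.shape != (self.M,):
                raise ValueError("starts must have one entry per read")
            if np.any(self.starts < 0):
                raise ValueError("read start positions must be nonnegative")
            if self.source_length is not None and np.any(
                self.starts + self.kappa > self.source_length
            ):
                raise ValueError("a read extends past the end of the source sequence")

    @property
    def M(self) -> int:
        return self.encoded.shape[0]

    @property
    def kappa(self) -> int:
        return self.encoded.shape[1]

    @property
    def reads(self) -> list[str]:
        return [decode(row, self.alphabet) for row in self.encoded]

    @classmethod
    def from_strings(cls, reads, alphabet: str = DNA, starts=None, source_length=None, ids=None):
        from .alphabet import encode

        if not reads:
            raise ValueError("empty read list")
        lengths = {len(r) for r in reads}
        if len(lengths) != 1:
            raise ValueError("all reads must have the same length")
        arr = np.stack([encode(r, alphabet) for r in reads])
        return cls(arr, alphabet, starts, source_length, ids)


def gather_reads(seq_arr: np.ndarray, starts: np.ndarray, kappa: int) -> np.ndarray:
    """Slice fixed-length reads out of an encoded sequence at the given starts."""
    return seq_arr[starts[:, None] + np.arange(kappa)]


def sample_starts_homogeneous(rng, L: int, kappa: int, M: int) -> np.ndarray:
    return rng.integers(0, L - kappa + 1, size=M)


def sample_starts_heterogeneous(
    rng,
    L: int,
    kappa: int,
    M: int,
    n_blocks: int = DEFAULT_BLOCKS,
    gamma_shape: float = DEFAULT_GAMMA_SHAPE,
    gamma_scale: float = DEFAULT_GAMMA_SCALE,
) -> np.ndarray:
    """Start positions weighted by per-block gamma intensities.

    Each valid start inherits the intensity of the block containing it
    (block membership is decided by the start coordinate).
    """
    n_starts = L - kappa + 1
    if n_blocks > n_starts:
        raise ValueError("more blocks than valid start positions")
    weights = rng.gamma(gamma_shape, gamma_scale, size=n_blocks)
    while not np.any(weights > 0):  # resample guard; zero draws have measure zero
        weights = rng.gamma(gamma_shape, gamma_scale, size=n_blocks)
    block_of = (np.arange(n_starts, dtype=np.int64) * n_blocks) // L
    p = weights[block_of]
    p = p / p.sum()
    return rng.choice(n_starts, size=M, p=p)


def _sample(seq, M: int, kappa: int, starts_fn, rng) -> ReadSet:
    if kappa > seq.length:
        raise ValueError(f"read length {kappa} exceeds sequence length {seq.length}")
    if M < 1:
        raise ValueError("need at least one read")
    starts = starts_fn(rng, seq.length, kappa, M)
    return ReadSet(
        gather_reads(seq.encoded(), starts, kappa),
        seq.alphabet,
        starts,
        seq.length,
    )


def sample_reads_homogeneous(seq, M: int, kappa: int, seed) -> ReadSet:
    """Sample ``M`` reads with uniform start positions (Lander-Waterman layout)."""
    return _sample(seq, M, kappa, sample_starts_homogeneous, as_rng(seed))


def sample_reads_heterogeneous(
    seq,
    M: int,
    kappa: int,
    n_blocks: int = DEFAULT_BLOCKS,
    gamma_shape: float = DEFAULT_GAMMA_SHAPE,
    gamma_scale: float = DEFAULT_GAMMA_SCALE,
    seed=None,
) -> ReadSet:
    """Sample ``M`` reads under the gamma-weighted block coverage model."""

    def starts_fn(rng, L, kappa_, M_):
        return sample_starts_heterogeneous(rng, L, kappa_, M_, n_blocks, gamma_shape, gamma_scale)

    return _sample(seq, M, kappa, starts_fn, as_rng(seed))


def apply_errors_array(rng, encoded: np.ndarray, rate: float, C: int) -> np.ndarray:
    """Substitution errors on an encoded read array (ambiguous cells untouched)."""
    if rate == 0:
        return encoded.copy()
    out = encoded.copy()
    hit = (rng.random(out.shape) < rate) & (out >= 0)
    shift = rng.integers(1, C, size=out.shape)
    out[hit] = (out[hit] + shift[hit]) % C
    return out


def apply_errors(reads: ReadSet, model: ErrorModel | float, seed) -> ReadSet:
    """Independently miscall each base with the model's rate; starts unchanged."""
    rate = model.per_base_rate if isinstance(model, ErrorModel) else float(model)
    if not 0 <= rate <= 1:
        raise ValueError("error rate must lie in [0, 1]")
    rng = as_rng(seed)
    C = len(reads.alphabet)
    if rate == 1.0:  # forced substitution everywhere
        shift = rng.integers(1, C, size=reads.encoded.shape)
        out = np.where(reads.encoded >= 0, (reads.encoded + shift) % C, reads.encoded)
    else:
        out = apply_errors_array(rng, reads.encoded, rate, C)
    return ReadSet(out.astype(np.int8), reads.alphabet, reads.starts, reads.source_length, reads.ids)
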