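"""Finite-alphabet Markov chain models: construction, validation, simulation.

An order-``r`` Markov chain over an alphabet of ``C`` symbols is specified by
a row-stochastic transition table with one row per length-``r`` context and
one column per next symbol, plus an initial law over contexts (the stationary
law by default).  Order 0 is the i.i.d. special case with a single row.

Two built-in model families on ``{A,C,G,T}`` support simulation studies:

* :func:`table1_model` -- a first-order chain whose doubly stochastic
  transition matrix has the uniform stationary law;
* :func:`table2_model` -- a second-order family obtained by shifting the
  first-order rows with context-dependent offsets ``(+p1, -p1, +p2, -p2)``,
  where the pair ``(p1, p2)`` depends on the first context symbol.  When all
  four offset pairs coincide the family collapses back to a first-order
  chain, which makes it convenient for order-estimation benchmarks.

Simulation is vectorized across replicate chains (`simulate_sequences`), so
thousands of multi-kilobase sequences can be drawn in seconds.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import DNA, AMBIGUOUS, as_rng, decode, encode, index_to_word

_ROW_TOL = 1e-12
_STATIONARY_TOL = 1e-10


@dataclass
class SequenceRecord:
    """A named symbol sequence over an alphabet plus the ambiguity marker."""

    id: str
    symbols: str
    alphabet: str = DNA

    def __post_init__(self) -> None:
        allowed = set(self.alphabet) | {AMBIGUOUS}
        extra = set(self.symbols) - allowed
        if extra:
            raise ValueError(
                f"sequence {self.id!r} contains symbols outside "
                f"{self.alphabet + AMBIGUOUS!r}: {sorted(extra)}"
            )
        self._encoded: np.ndarray | None = None

    @property
    def length(self) -> int:
        return len(self.symbols)

    def encoded(self) -> np.ndarray:
        """int8 codes, ambiguous symbols as -1 (cached)."""
        if self._encoded is None:
            self._encoded = encode(self.symbols, self.alphabet)
        return self._encoded


@dataclass
class MarkovModel:
    """An order-``r`` Markov chain over a finite alphabet.

    Parameters
    ----------
    alphabet
        Ordered symbols; its length is the alphabet size ``C``.
    order
        Memory length ``r >= 0``.
    transitions
        Array of shape ``(C**r, C)``; row ``i`` is the next-symbol law for
        the context with lexicographic index ``i``.  A flat length-``C``
        vector is accepted for order 0.
    initial
        Optional law over the ``C**r`` contexts used for the first ``r``
        symbols; defaults to the stationary law.
    """

    alphabet: str
    order: int
    transitions: np.ndarray
    initial: np.ndarray | None = None
    _stationary: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        C = len(self.alphabet)
        if C < 2 or len(set(self.alphabet)) != C:
            raise ValueError("alphabet must have at least 2 distinct symbols")
        if self.order < 0:
            raise ValueError("order must be >= 0")
        t = np.asarray(self.transitions, dtype=float)
        S = C**self.order
        if self.order == 0 and t.shape == (C,):
            t = t.reshape(1, C)
        if t.shape != (S, C):
            raise ValueError(f"transitions must have shape ({S}, {C}), got {t.shape}")
        if np.any(t < -_ROW_TOL) or np.any(t > 1 + _ROW_TOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if np.max(np.abs(t.sum(axis=1) - 1.0)) > _ROW_TOL:
            raise ValueError("every transition row must sum to 1")
        self.transitions = t
        if self.initial is not None:
            init = np.asarray(self.initial, dtype=float)
            if init.shape != (S,):
                raise ValueError(f"initial law must have length {S}")
            if np.any(init < 0) or abs(init.sum() - 1.0) > 1e-9:
                raise ValueError("initial law must be a probability vector")
            self.initial = init

    @property
    def n_symbols(self) -> int:
        return len(self.alphabet)

    @property
    def n_contexts(self) -> int:
        return self.n_symbols**self.order

    def contexts(self) -> list[str]:
        """All length-``r`` contexts in lexicographic (row) order."""
        return [index_to_word(i, self.order, self.alphabet) for i in range(self.n_contexts)]

    def transition(self, context: str) -> np.ndarray:
        """Next-symbol law for a context string (empty string for order 0)."""
        if len(context) != self.order:
            raise ValueError(f"context must have length {self.order}")
        idx = 0
        for ch in context:
            idx = idx * self.n_symbols + self.alphabet.index(ch)
        return self.transitions[idx]

    def initial_distribution(self) -> np.ndarray:
        """The explicit initial law, or the stationary law if none was given."""
        if self.initial is not None:
            return self.initial
        if self._stationary is None:
            self._stationary = stationary_distribution(self)
        return self._stationary


@dataclass(frozen=True)
class Table2Params:
    """Offsets controlling the built-in second-order transition family.

    The row for context ``XY`` is the first-order row for ``Y`` shifted by
    ``(+p1, -p1, +p2, -p2)`` with ``(p1, p2)`` equal to ``(alpha1, alpha2)``,
    ``(beta1, beta2)``, ``(gamma1, gamma2)`` or ``(delta1, delta2)`` according
    to ``X`` = A, C, G or T.  Equal pairs across all four groups reduce the
    chain to first order.
    """

    alpha1: float = 0.0
    alpha2: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    delta1: float = 0.0
    delta2: float = 0.0

    def pairs(self) -> tuple[tuple[float, float], ...]:
        return (
            (self.alpha1, self.alpha2),
            (self.beta1, self.beta2),
            (self.gamma1, self.gamma2),
            (self.delta1, self.delta2),
        )

    def scaled(self, c: float) -> "Table2Params":
        """All offsets multiplied by ``c`` (effect-size sweeps)."""
        return Table2Params(*(c * v for v in (
            self.alpha1, self.alpha2, self.beta1, self.beta2,
            self.gamma1, self.gamma2, self.delta1, self.delta2)))


_TABLE1 = np.array(
    [
        [0.1, 0.2, 0.3, 0.4],
        [0.2, 0.3, 0.4, 0.1],
        [0.3, 0.4, 0.1, 0.2],
        [0.4, 0.1, 0.2, 0.3],
    ]
)

#: Offsets giving a *first-order* chain distinct from the base chain
#: (all four context groups share the same pair).
PERTURB_FIRST_ORDER = Table2Params(0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05)

#: Offsets giving a genuinely *second-order* chain (pairs differ by group).
PERTURB_SECOND_ORDER = Table2Params(0.05, 0.05, -0.05, -0.05, 0.03, 0.03, -0.03, -0.03)


def table1_model() -> MarkovModel:
    """The built-in first-order benchmark chain on {A,C,G,T}.

    Its transition matrix is doubly stochastic, so the stationary
    mononucleotide law is uniform.
    """
    return MarkovModel(DNA, 1, _TABLE1.copy())


def table2_model(params: Table2Params = Table2Params()) -> MarkovModel:
    """The built-in second-order family on {A,C,G,T} (see :class:`Table2Params`).

    Raises ``ValueError`` if any offset pushes a probability outside [0, 1].
    """
    trans = np.empty((16, 4))
    for x, (p1, p2) in enumerate(params.pairs()):
        shift = np.array([p1, -p1, p2, -p2])
        for y in range(4):
            trans[x * 4 + y] = _TABLE1[y] + shift
    if np.any(trans < 0) or np.any(trans > 1):
        raise ValueError("offsets push a transition probability outside [0, 1]")
    return MarkovModel(DNA, 2, trans)


def lifted_transition_matrix(model: MarkovModel) -> np.ndarray:
    """One-step transition matrix of the chain lifted to ``C**r`` context states."""
    C, r = model.n_symbols, model.order
    S = C**r
    P = np.zeros((S, S))
    rows = np.repeat(np.arange(S), C)
    cols = ((np.arange(S)[:, None] * C + np.arange(C)) % S).ravel()
    np.add.at(P, (rows, cols), model.transitions.ravel())
    return P


def effective_order(model: MarkovModel) -> int:
    """Minimal memory length that reproduces the model's transition law.

    A structurally order-``r`` model whose rows depend only on the last
    ``j < r`` context symbols is statistically an order-``j`` chain (e.g.
    the second-order family with all offset pairs equal collapses to first
    order).  Returns the smallest such ``j``.
    """
    C, r = model.n_symbols, model.order
    for j in range(r + 1):
        rows = model.transitions.reshape(C ** (r - j), C**j * C)
        if np.allclose(rows, rows[0], atol=1e-12):
            return j
    return r


def stationary_distribution(model: MarkovModel) -> np.ndarray:
    """Stationary law over length-``r`` contexts.

    Solves ``v P = v`` on the lifted context chain with the sum-to-one
    constraint (least squares on the stacked system).  Raises ``ValueError``
    when the chain has no unique stationary law (reducible/periodic input).
    """
    if model.order == 0:
        return model.transitions[0].copy()
    P = lifted_transition_matrix(model)
    S = P.shape[0]
    if np.linalg.matrix_rank(P.T - np.eye(S)) < S - 1:
        raise ValueError("chain has no unique stationary law (reducible)")
    A = np.vstack([P.T - np.eye(S), np.ones(S)])
    b = np.zeros(S + 1)
    b[-1] = 1.0
    v, *_ = np.linalg.lstsq(A, b, rcond=None)
    if (
        np.any(v < -1e-9)
        or abs(v.sum() - 1.0) > 1e-9
        or np.max(np.abs(v @ P - v)) > _STATIONARY_TOL
    ):
        raise ValueError("chain has no unique stationary law (reducible or periodic)")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def simulate_sequences(model: MarkovModel, length: int, n: int, seed) -> np.ndarray:
    """Simulate ``n`` independent chains of the given length.

    Returns an ``(n, length)`` int8 array of symbol codes.  The first ``r``
    symbols of each chain are drawn from the model's initial context law
    (stationary by default); every later symbol from the transition row of
    the preceding ``r`` symbols.  The per-position loop is vectorized across
    chains, which is what makes large replicate studies affordable.
    """
    rng = as_rng(seed)
    C, r = model.n_symbols, model.order
    S = C**r
    if length < r:
        raise ValueError(f"length {length} shorter than model order {r}")
    if n < 1:
        raise ValueError("need n >= 1 chains")
    out = np.empty((n, length), dtype=np.int8)
    if r > 0:
        init = model.initial_distribution()
        states = rng.choice(S, size=n, p=init).astype(np.int64)
        for j in range(r):
            out[:, j] = (states // C ** (r - 1 - j)) % C
    else:
        states = np.zeros(n, dtype=np.int64)
    cum = np.cumsum(model.transitions, axis=1)
    cum[:, -1] = 1.0  # guard against float round-off in the last column
    for i in range(r, length):
        u = rng.random((n, 1))
        sym = (u > cum[states]).sum(axis=1)
        out[:, i] = sym
        if r > 0:
            states = (states * C + sym) % S
    return out


def simulate_sequence(model: MarkovModel, length: int, seed, record_id: str = "sim") -> SequenceRecord:
    """Simulate one sequence; deterministic for a given integer seed."""
    arr = simulate_sequences(model, length, 1, seed)[0]
    return SequenceRecord(record_id, decode(arr, model.alphabet), model.alphabet)


def write_model_tsv(model: MarkovModel, path) -> None:
    """Write a model as a tab-separated matrix: context column + one column per symbol."""
    with open(path, "w") as fh:
        fh.write("context\t" + "\t".join(model.alphabet) + "\n")
        for ctx, row in zip(model.contexts(), model.transitions):
            cells = "\t".join(f"{p:.12g}" for p in row)
            fh.write(f"{ctx or '-'}\t{cells}\n")


def read_model_tsv(path) -> MarkovModel:
    """Read a model written by :func:`write_model_tsv` (order inferred from contexts)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"context": str})
    alphabet = "".join(df.columns[1:])
    contexts = ["" if c == "-" else c for c in df["context"]]
    order = len(contexts[0])
    C = len(alphabet)
    if len(contexts) != C**order or any(len(c) != order for c in contexts):
        raise ValueError("context column does not enumerate all C**r contexts")
    trans = np.empty((C**order, C))
    for ctx, row in zip(contexts, df.iloc[:, 1:].to_numpy(dtype=float)):
        idx = 0
        for ch in ctx:
            idx = idx * C + alphabet.index(ch)
        trans[idx] = row
    return MarkovModel(alphabet, order, trans)
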