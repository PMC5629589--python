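"""Symbol/integer encoding for fixed finite alphabets.

Sequences are held internally as ``int8`` arrays with values ``0..C-1`` in
alphabet order and ``-1`` marking an ambiguous symbol (``N`` for DNA).
Length-k words are addressed by their lexicographic index
``sum_j code(w_j) * C**(k-1-j)``.
"""
from __future__ import annotations

import numpy as np

DNA = "ACGT"
AMBIGUOUS = "N"


def _lookup(alphabet: str) -> np.ndarray:
    table = np.full(256, -1, dtype=np.int8)
    for i, ch in enumerate(alphabet):
        table[ord(ch)] = i
        table[ord(ch.lower())] = i
    return table


def encode(symbols: str, alphabet: str = DNA) -> np.ndarray:
    """Encode a symbol string to an int8 array (-1 for ambiguous symbols)."""
    raw = np.frombuffer(symbols.encode("ascii"), dtype=np.uint8)
    return _lookup(alphabet)[raw]


def decode(codes: np.ndarray, alphabet: str = DNA) -> str:
    """Decode an int8 code array back to a symbol string (-1 becomes 'N')."""
    chars = np.array(list(alphabet + AMBIGUOUS), dtype="U1")
    return "".join(chars[np.asarray(codes, dtype=np.int64)])


def index_to_word(index: int, k: int, alphabet: str = DNA) -> str:
    """The length-k word with the given lexicographic index."""
    C = len(alphabet)
    out = []
    for j in range(k):
        out.append(alphabet[(index // C ** (k - 1 - j)) % C])
    return "".join(out)


def word_to_index(word: str, alphabet: str = DNA) -> int:
    """Lexicographic index of a word (inverse of :func:`index_to_word`)."""
    C = len(alphabet)
    idx = 0
    for ch in word:
        pos = alphabet.find(ch)
        if pos < 0:
            raise ValueError(f"symbol {ch!r} not in alphabet {alphabet!r}")
        idx = idx * C + pos
    return idx


def as_rng(seed) -> np.random.Generator:
    """Coerce an integer seed, SeedSequence, or Generator to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
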