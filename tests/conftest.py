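from collections import Counter

import numpy as np
import pytest

from markovcmp import (
    PERTURB_FIRST_ORDER,
    PERTURB_SECOND_ORDER,
    SequenceRecord,
    table1_model,
    table2_model,
)
from markovcmp.alphabet import decode
from markovcmp.markov_model import MarkovModel, simulate_sequences


@pytest.fixture(scope="session")
def table1():
    return table1_model()


@pytest.fixture(scope="session")
def table2_first():
    """Second-order parameterization that collapses to a first-order chain."""
    return table2_model(PERTURB_FIRST_ORDER)


@pytest.fixture(scope="session")
def table2_second():
    """Genuinely second-order chain."""
    return table2_model(PERTURB_SECOND_ORDER)


@pytest.fixture(scope="session")
def iid_uniform():
    return MarkovModel("ACGT", 0, np.full(4, 0.25))


def record(symbols: str, rid: str = "s") -> SequenceRecord:
    return SequenceRecord(rid, symbols)


def batch_records(model, length, n, seed):
    """n simulated SequenceRecords drawn with the vectorized batch engine."""
    arrs = simulate_sequences(model, length, n, seed)
    return [SequenceRecord(f"s{i}", decode(a, model.alphabet)) for i, a in enumerate(arrs)]


def naive_word_counts(s: str, k: int) -> Counter:
    """Brute-force overlapping window scan; windows containing N are skipped."""
    c = Counter()
    for i in range(len(s) - k + 1):
        w = s[i : i + k]
        if "N" not in w:
            c[w] += 1
    return c
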