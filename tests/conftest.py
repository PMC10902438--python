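from __future__ import annotations

import numpy as np
import pytest

from protostrain.seqio import SequenceRecord

BASES = np.array(list("ACGT"))
AAS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_dna(rng):
    def make(length: int, id: str = "g") -> SequenceRecord:
        return SequenceRecord(id=id, seq="".join(rng.choice(BASES, size=length)))

    return make


@pytest.fixture
def random_protein(rng):
    def make(length: int, id: str = "p") -> SequenceRecord:
        return SequenceRecord(
            id=id, seq="".join(rng.choice(AAS, size=length)), moltype="protein"
        )

    return make


def mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def mutate_protein(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in rng.choice(len(out), size=min(n_subs, len(out)), replace=False):
        out[i] = rng.choice([a for a in AAS if a != out[i]])
    return "".join(out)
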