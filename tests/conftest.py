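import numpy as np
import pytest

from mycobarcode.io import SequenceRecord

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Substitute exactly n_subs distinct positions to a different base."""
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = rng.choice(choices)
    return "".join(arr)


def record(seq_id: str, residues: str, species: str = "") -> SequenceRecord:
    return SequenceRecord(id=seq_id, residues=residues, species=species)


@pytest.fixture
def rng():
    return np.random.default_rng(20110922)
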