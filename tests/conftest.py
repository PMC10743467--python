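import numpy as np
import pytest

from skimtax import LabeledAlignment, LabeledSequence


def make_alignment(rows, species=None):
    """Build a LabeledAlignment from residue strings.

    ``rows`` is a list of residue strings or (sample_id, species, residues)
    tuples; bare strings get ids s1, s2, ... and species ``species`` or
    one species per sequence.
    """
    seqs = []
    for i, row in enumerate(rows):
        if isinstance(row, tuple):
            seqs.append(LabeledSequence(*row))
        else:
            sp = species if species is not None else f"sp{i + 1}"
            seqs.append(LabeledSequence(f"s{i + 1}", sp, row))
    return LabeledAlignment(seqs)


def random_alignment(rng, n_seqs=10, n_cols=50, alphabet="ACGT-N"):
    """Random alignment over the given alphabet (seeded)."""
    letters = np.array(list(alphabet))
    rows = [
        "".join(rng.choice(letters, size=n_cols)) for _ in range(n_seqs)
    ]
    return make_alignment(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
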