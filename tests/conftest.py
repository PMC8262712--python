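import numpy as np
import pytest

from isopoint.charge import PKaSet, registry
from isopoint.seqio import PolypeptideSequence


@pytest.fixture(scope="session")
def toy_acid_base_set() -> PKaSet:
    """One basic (N-term, pKa 9) and one acidic (C-term, pKa 2) group only."""
    return PKaSet(name="toy", n_term=9.0, c_term=2.0, side_chain={})


@pytest.fixture(scope="session")
def all_sets() -> dict[str, PKaSet]:
    return registry()


@pytest.fixture()
def random_peptides():
    """Deterministic random peptides over the 20 standard residues."""

    def make(n: int, min_len: int = 3, max_len: int = 30, seed: int = 0):
        rng = np.random.default_rng(seed)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        out = []
        for i in range(n):
            length = rng.integers(min_len, max_len + 1)
            out.append(
                PolypeptideSequence(f"r{i}", "".join(rng.choice(letters, size=length)))
            )
        return out

    return make
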