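import numpy as np
import pytest

from mutfold import get_model, make_fixture_sequences, validate_sequence
from mutfold.energy import is_canonical, structure_energy
from mutfold.fold import enumerate_structures


@pytest.fixture(scope="session")
def uniform():
    return get_model("toy-uniform")


@pytest.fixture(scope="session")
def pairtype():
    return get_model("toy-pairtype")


@pytest.fixture(scope="session")
def stacking():
    return get_model("stacking")


@pytest.fixture(scope="session")
def all_models(uniform, pairtype, stacking):
    return (uniform, pairtype, stacking)


@pytest.fixture
def gaaac():
    return validate_sequence("GAAAC")


@pytest.fixture
def ggaaacc():
    return validate_sequence("GGAAACC")


@pytest.fixture(scope="session")
def oracle_sequences():
    """200 seeded random sequences with n in [8, 15] and a planted stem."""
    rng = np.random.default_rng(42)
    return [
        make_fixture_sequences(1000 + k, 1, int(rng.integers(8, 16)))[0]
        for k in range(200)
    ]


def relent_bruteforce(wt, mut, model):
    """Independent relative-entropy oracle: enumerate both ensembles,
    restrict to the common structure space, renormalize, sum q*ln(q/p)."""
    structures = enumerate_structures(wt, model)
    common = [
        s
        for s in structures
        if all(
            is_canonical(mut.residues[i - 1], mut.residues[j - 1])
            for (i, j) in s.pairs
        )
    ]
    w_wt_all = np.array(
        [np.exp(-structure_energy(wt, s, model) / model.RT) for s in structures]
    )
    w_wt = np.array(
        [np.exp(-structure_energy(wt, s, model) / model.RT) for s in common]
    )
    w_mut = np.array(
        [np.exp(-structure_energy(mut, s, model) / model.RT) for s in common]
    )
    q = w_wt / w_wt.sum()
    p = w_mut / w_mut.sum()
    d = float(np.sum(q * np.log(q / p)))
    coverage_wt = float(w_wt.sum() / w_wt_all.sum())
    return d, coverage_wt
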