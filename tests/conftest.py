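import numpy as np
import pytest

from ssbond.core import AnnotationTrack, DisulfidePattern, LabeledDataset, Protein
from ssbond.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def acca():
    """Minimal two-cysteine protein."""
    return Protein(id="p1", sequence="ACCA")


@pytest.fixture
def four_cys_protein():
    """Length-100 protein with cysteines at 0-based positions 4, 19, 29, 49."""
    sequence = ["A"] * 100
    for pos in (4, 19, 29, 49):
        sequence[pos] = "C"
    return Protein(id="p4", sequence="".join(sequence))


@pytest.fixture
def protein_with_tracks(four_cys_protein):
    rng = np.random.default_rng(42)
    L = four_cys_protein.length
    pssm = rng.uniform(0, 1, size=(L, 20))
    four_cys_protein.attach(
        AnnotationTrack("PSSM", [f"a{i}" for i in range(20)], pssm)
    )
    ss3 = rng.dirichlet(np.ones(3), size=L)
    four_cys_protein.attach(AnnotationTrack("SS3", ["H", "E", "C"], ss3))
    return four_cys_protein


@pytest.fixture(scope="session")
def small_dataset():
    """60 fully-bonded 4-cys/2-bridge proteins at full signal."""
    return generate_dataset(SyntheticConfig(n_proteins=60, seed=17))


@pytest.fixture(scope="session")
def hetero_dataset():
    """Mixed strata: bridge-free, partially bonded and fully bonded proteins."""
    return generate_dataset(
        SyntheticConfig(
            n_proteins=90, frac_bridge_free=0.3, frac_partial=0.2, seed=23
        )
    )


@pytest.fixture
def toy_labeled_dataset():
    proteins = [
        Protein(id="a", sequence="ACCACCA"),
        Protein(id="b", sequence="CCCC"),
    ]
    patterns = {
        "a": DisulfidePattern([(0, 1), (2, 3)]),
        "b": DisulfidePattern([(0, 2), (1, 3)]),
    }
    return LabeledDataset(proteins, patterns)
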