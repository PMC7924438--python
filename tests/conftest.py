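import numpy as np
import pytest

from clusmote.synthetic import (SyntheticSpec, ToyStructureSpec,
                                make_grouped, make_imbalanced,
                                make_toy_structure)


@pytest.fixture(scope="session")
def default_ds():
    """Default 10:1 imbalanced dataset (50 positives, 500 negatives)."""
    return make_imbalanced(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def grouped_ds():
    return make_grouped(SyntheticSpec(seed=2), n_groups=5)


@pytest.fixture(scope="session")
def separated_ds():
    """Well-separated majority blobs, zero class overlap (cluster recovery)."""
    return make_imbalanced(SyntheticSpec(cluster_separation=10.0,
                                         overlap=0.0, seed=7))


@pytest.fixture(scope="session")
def helix():
    rt, text = make_toy_structure(ToyStructureSpec(n_residues=20,
                                                   geometry="helix", seed=3))
    return rt, text


@pytest.fixture(scope="session")
def sphere():
    rt, text = make_toy_structure(
        ToyStructureSpec(n_residues=40, geometry="sphere_surface", seed=4))
    return rt, text
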