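import numpy as np
import pytest

from histac.io import HistoneProtein
from histac.synthetic import load_bundled_histones, make_synthetic_nucleosome


@pytest.fixture(scope="session")
def human_histones():
    return load_bundled_histones("human", filter="strict")


@pytest.fixture(scope="session")
def arabidopsis_histones():
    return load_bundled_histones("arabidopsis", filter="none")


@pytest.fixture(scope="session")
def synthetic_structure(tmp_path_factory, human_histones):
    """Synthetic nucleosome-scale PDB over the bundled human histones."""
    path = tmp_path_factory.mktemp("structure") / "nucleosome.synthetic.pdb"
    geometry = make_synthetic_nucleosome(human_histones, path, seed=1)
    return path, geometry


@pytest.fixture()
def toy_protein():
    return HistoneProtein(
        id="toy",
        species="synthetic",
        family="SYN",
        variant="toy",
        sequence="AAAKAAAKAAAAAAKAAA",
        labels={4: "P", 8: "P", 15: "N"},
    )


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    d = rng.uniform(0.05, 1.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d
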