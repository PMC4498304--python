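import numpy as np
import pytest

from pocketdyn import CoordinateSet, Structure


def make_coordset(coords, prefix="s"):
    coords = np.asarray(coords, dtype=float)
    labels = tuple((prefix, "A", i + 1, "", "CA") for i in range(len(coords)))
    return CoordinateSet(labels, coords)


def point_ligand(position=(0.0, 0.0, 0.0)):
    """Single-carbon ligand Structure at a position."""
    return Structure(
        chain_id=np.array(["L"]),
        res_id=np.array([1]),
        ins_code=np.array([""]),
        res_name=np.array(["LIG"]),
        atom_name=np.array(["C1"]),
        element=np.array(["C"]),
        coords=np.array([position], dtype=float),
        hetero=np.array([True]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def random_pair(rng):
    """Two paired 10-point CoordinateSets related by a rigid motion + noise."""
    coords = rng.normal(scale=4.0, size=(10, 3))
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=5).as_matrix()
    moved = coords @ R.T + np.array([3.0, -1.0, 2.0]) + rng.normal(
        scale=0.3, size=(10, 3)
    )
    return make_coordset(coords), make_coordset(moved)
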