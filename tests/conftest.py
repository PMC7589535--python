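import numpy as np
import pytest
import biotite.structure as struc

from fretassist.structure_io import Conformer, Ensemble
from fretassist.synthetic_fixtures import (
    HingeToySpec,
    make_benchmark_case,
    make_hinge_conformer,
    make_hinge_ensemble,
)


def toy_conformer(coords, atom_names=None, res_ids=None, elements=None,
                  chain="A", label="toy"):
    """Build a minimal conformer from raw coordinates (one atom per entry)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    atoms = struc.AtomArray(n)
    atoms.coord = coords
    atoms.chain_id = np.full(n, chain)
    atoms.res_id = np.asarray(res_ids if res_ids is not None else range(1, n + 1))
    atoms.res_name = np.full(n, "ALA")
    atoms.atom_name = np.asarray(
        atom_names if atom_names is not None else ["CA"] * n
    )
    atoms.element = np.asarray(elements if elements is not None else ["C"] * n)
    atoms.hetero = np.zeros(n, dtype=bool)
    return Conformer(atoms, label)


@pytest.fixture
def hinge_spec():
    return HingeToySpec()


@pytest.fixture
def hinge_ensemble(hinge_spec):
    return make_hinge_ensemble(hinge_spec, [0.0, 15.0, 30.0, 45.0, 60.0])


@pytest.fixture(scope="session")
def benchmark_case():
    """Noise-free benchmark: target bent at 90 deg, seeds straddling it."""
    spec = HingeToySpec()
    return spec, make_benchmark_case(
        spec, target_theta=90.0,
        seed_thetas=[50.0, 65.0, 80.0, 100.0, 110.0, 120.0],
        seed=1,
    )


def random_rigid_motion(rng):
    """A random rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    t = rng.normal(scale=20.0, size=3)
    return R.as_matrix(), t
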