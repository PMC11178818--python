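import numpy as np
import pytest

import bcdirect as bd
from bcdirect import fem


@pytest.fixture(scope="session")
def frame():
    return bd.STIMULATION_FRAME


@pytest.fixture()
def rng():
    return np.random.default_rng(20240614)


@pytest.fixture(scope="session")
def rw_fixture():
    """Canonical 48-node ring + 218-quad membrane disc."""
    return bd.make_rw_fixture(seed=0)


@pytest.fixture(scope="session")
def toy_model():
    """Toy temporal-bone model with its window frame and assembled operators."""
    model, rw_frame = bd.make_toy_bone(seed=0)
    ops = fem.assemble(model)
    return model, rw_frame, ops


def make_rod(n_z: int = 20, L_mm: float = 20.0, E: float = 1e9, rho: float = 1000.0,
             nu: float = 0.0, eta: float = 0.0) -> fem.FEModel:
    """Fixed-free prismatic rod along z, unit 1 mm² cross-section, force at tip."""
    nodes, elems, _ = fem.box_mesh((1, 1, n_z), (1.0, 1.0, L_mm))
    fixed = np.nonzero(np.isclose(nodes[:, 2], 0.0))[0]
    tip = np.nonzero(np.isclose(nodes[:, 2], L_mm * 1e-3))[0]
    return fem.FEModel(
        nodes=nodes, elements=elems,
        material_ids=np.zeros(len(elems), dtype=int),
        materials={0: fem.Material(E=E, nu=nu, rho=rho, eta=eta)},
        fixed_nodes=fixed, attachment_mass_kg=0.0, attachment_nodes=tip,
    )
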