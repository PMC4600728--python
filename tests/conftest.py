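import numpy as np
import pytest

from rockdyn.lattice import LatticeSpec, SymmetryOp, build_reference_lattice
from rockdyn.synthetic import make_helical_template

P212121_OPS = [
    SymmetryOp(np.diag([1.0, 1.0, 1.0]), np.array([0.0, 0.0, 0.0])),
    SymmetryOp(np.diag([-1.0, -1.0, 1.0]), np.array([0.5, 0.0, 0.5])),
    SymmetryOp(np.diag([-1.0, 1.0, -1.0]), np.array([0.0, 0.5, 0.5])),
    SymmetryOp(np.diag([1.0, -1.0, -1.0]), np.array([0.5, 0.5, 0.0])),
]

ORTHO_CELL = (34.0, 36.0, 30.0, 90.0, 90.0, 90.0)


@pytest.fixture(scope="session")
def template():
    xyz, atoms = make_helical_template(8)
    return xyz, atoms


@pytest.fixture(scope="session")
def small_lattice(template):
    xyz, atoms = template
    spec = LatticeSpec(ORTHO_CELL, P212121_OPS, xyz, atoms)
    return build_reference_lattice(spec)
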