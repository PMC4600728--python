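"""Crystal lattice construction from symmetry operators.

Builds a static multi-copy reference frame by applying space-group symmetry
operators (rotation + translation in fractional coordinates) and unit-cell
replication to one or more template chains, keeping the exact rigid
transform that generated each copy so that downstream analysis can map any
molecule back into the template frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import AtomTable

__all__ = ["SymmetryOp", "LatticeSpec", "ReferenceLattice", "build_reference_lattice",
           "orthogonalization_matrix", "cell_volume"]


class InvalidSpecError(ValueError):
    """Raised when a lattice specification is inconsistent."""


def orthogonalization_matrix(cell) -> np.ndarray:
    """3x3 matrix A mapping fractional to Cartesian coordinates (Angstrom).

    cell = (a, b, c, alpha, beta, gamma) with angles in degrees; standard
    PDB convention (a along x, b in the xy plane).
    """
    a, b, c, alpha, beta, gamma = cell
    al, be, ga = np.deg2rad([alpha, beta, gamma])
    cosal, cosbe, cosga, singa = np.cos(al), np.cos(be), np.cos(ga), np.sin(ga)
    v = np.sqrt(1 - cosal ** 2 - cosbe ** 2 - cosga ** 2 + 2 * cosal * cosbe * cosga)
    return np.array([
        [a, b * cosga, c * cosbe],
        [0.0, b * singa, c * (cosal - cosbe * cosga) / singa],
        [0.0, 0.0, c * v / singa],
    ])


def cell_volume(cell) -> float:
    """Unit-cell volume in A^3 (general triclinic formula)."""
    a, b, c = cell[:3]
    al, be, ga = np.deg2rad(cell[3:])
    cosal, cosbe, cosga = np.cos(al), np.cos(be), np.cos(ga)
    return a * b * c * np.sqrt(
        1 - cosal ** 2 - cosbe ** 2 - cosga ** 2 + 2 * cosal * cosbe * cosga)


@dataclass
class SymmetryOp:
    """Symmetry operator in fractional coordinates: x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)

    @classmethod
    def identity(cls) -> "SymmetryOp":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class RigidTransform:
    """Cartesian rigid-body transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class LatticeSpec:
    """Specification of a crystal lattice built from template chains.

    template_coords has shape (n_chains_asu, n_atoms, 3); every chain shares
    one atom table.  replication is the number of unit-cell copies along
    each cell axis.
    """

    unit_cell: tuple  # (a, b, c, alpha, beta, gamma)
    symmetry_ops: list[SymmetryOp]
    template_coords: np.ndarray
    atoms: AtomTable
    replication: tuple = (1, 1, 1)

    def __post_init__(self):
        self.template_coords = np.asarray(self.template_coords, dtype=float)
        if self.template_coords.ndim == 2:
            self.template_coords = self.template_coords[None]
        if self.template_coords.size == 0:
            raise InvalidSpecError("empty chain template")
        if self.template_coords.shape[1] != len(self.atoms):
            raise InvalidSpecError("template does not match atom table")

    @property
    def n_chains_asu(self) -> int:
        return self.template_coords.shape[0]

    @property
    def n_molecules(self) -> int:
        return (self.n_chains_asu * len(self.symmetry_ops)
                * int(np.prod(self.replication)))


@dataclass
class ReferenceLattice:
    """One static frame of the expanded lattice plus per-molecule provenance."""

    coordinates: np.ndarray  # (n_molecules, n_atoms, 3)
    transforms: list[RigidTransform]  # Cartesian, template -> copy
    template_chain: np.ndarray  # ASU chain index per molecule
    atoms: AtomTable = field(repr=False, default=None)

    @property
    def n_molecules(self) -> int:
        return self.coordinates.shape[0]

    def map_to_template(self, molecule: int, xyz: np.ndarray) -> np.ndarray:
        """Express a molecule copy's coordinates in the template frame."""
        return self.transforms[molecule].inverse().apply(xyz)


def build_reference_lattice(spec: LatticeSpec, orthonormal_tol: float = 1e-6
                            ) -> ReferenceLattice:
    """Expand the asymmetric unit by symmetry and unit-cell replication.

    Each symmetry operator's rotation part must be a proper rigid rotation
    in the Cartesian frame (orthonormal, det +1); improper or distorting
    operators raise :class:`InvalidSpecError`.
    """
    A = orthogonalization_matrix(spec.unit_cell)
    Ainv = np.linalg.inv(A)

    cart_ops = []
    for op in spec.symmetry_ops:
        R = A @ op.rotation @ Ainv
        if (np.abs(R @ R.T - np.eye(3)).max() > orthonormal_tol
                or np.linalg.det(R) < 0):
            raise InvalidSpecError(
                "symmetry operator is not a proper rigid rotation in the "
                "Cartesian frame")
        cart_ops.append(RigidTransform(R, A @ op.translation))

    nx, ny, nz = spec.replication
    coords, transforms, chain_of = [], [], []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                shift = A @ np.array([i, j, k], dtype=float)
                for op in cart_ops:
                    for ci in range(spec.n_chains_asu):
                        t = RigidTransform(op.rotation, op.translation + shift)
                        coords.append(t.apply(spec.template_coords[ci]))
                        transforms.append(t)
                        chain_of.append(ci)
    return ReferenceLattice(
        coordinates=np.stack(coords),
        transforms=transforms,
        template_chain=np.array(chain_of, dtype=int),
        atoms=spec.atoms,
    )
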