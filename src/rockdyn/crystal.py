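"""Crystal packing metrics.

The Matthews coefficient V_m = V_cell / (Z * M) (cell volume per Dalton of
protein in the cell) and the derived fractional solvent content
V_s = 1 - 1.23 / V_m, with 1.23 the conventional constant combining the
protein partial specific volume (~0.74 cm^3/g) with unit conversion.
Lower solvent content means denser packing, which correlates with less
rigid-body rocking freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .lattice import cell_volume

__all__ = ["UnitCellContents", "matthews_solvent", "MATTHEWS_CONSTANT"]

MATTHEWS_CONSTANT = 1.23  # A^3/Da per (cm^3/g of protein), conventional


@dataclass
class UnitCellContents:
    """Unit-cell dimensions plus protein content.

    z_asu_per_cell is the space-group multiplicity (asymmetric units per
    cell, supplied explicitly); chain_mass in Da.
    """

    cell: tuple  # (a, b, c, alpha, beta, gamma), Angstrom / degrees
    z_asu_per_cell: int
    chains_per_asu: int
    chain_mass: float

    def __post_init__(self):
        if self.chain_mass <= 0 or self.z_asu_per_cell < 1 or self.chains_per_asu < 1:
            raise ValueError("masses and counts must be positive")
        if cell_volume(self.cell) <= 0:
            raise ValueError("degenerate unit cell")


def matthews_solvent(contents: UnitCellContents) -> tuple[float, float]:
    """(V_m in A^3/Da, fractional solvent content V_s).

    V_s is clipped at 0 (with a warning) for implausibly dense contents.
    """
    v_cell = cell_volume(contents.cell)
    mass = contents.z_asu_per_cell * contents.chains_per_asu * contents.chain_mass
    v_m = v_cell / mass
    v_s = 1.0 - MATTHEWS_CONSTANT / v_m
    if v_s < 0:
        warnings.warn("V_m at or below the protein-only limit; solvent "
                      "content clipped to 0", stacklevel=2)
        v_s = 0.0
    return float(v_m), float(v_s)
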