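"""Reference data for the three ubiquitin crystal forms.

Published inputs used throughout the examples and validation: unit cells
and space-group multiplicities of the deposited structures, the
experimentally measured 'base' 15N R1rho rates (the per-residue floor,
attributed to overall rocking plus a residual), and the spectrometer
conditions of the relaxation measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

from .conditions import SpectrometerConditions
from .crystal import UnitCellContents

__all__ = ["CrystalForm", "CRYSTAL_FORMS", "UBIQUITIN_CHAIN_MASS",
           "MEASUREMENT_CONDITIONS"]

UBIQUITIN_CHAIN_MASS = 8565.0  # Da, human ubiquitin 1-76, average mass


@dataclass(frozen=True)
class CrystalForm:
    name: str
    pdb_id: str
    space_group: str
    cell: tuple  # a, b, c (A), alpha, beta, gamma (deg)
    z_asu_per_cell: int  # space-group multiplicity
    chains_per_asu: int
    base_r1rho: float | None  # s^-1, measured 'base' rate (None if not measured)

    def contents(self, chain_mass: float = UBIQUITIN_CHAIN_MASS) -> UnitCellContents:
        return UnitCellContents(self.cell, self.z_asu_per_cell,
                                self.chains_per_asu, chain_mass)


CRYSTAL_FORMS = {
    "cubic-PEG-ub": CrystalForm(
        name="cubic-PEG-ub", pdb_id="4XOL", space_group="P 43 3 2",
        cell=(104.95, 104.95, 104.95, 90.0, 90.0, 90.0),
        z_asu_per_cell=24, chains_per_asu=2, base_r1rho=12.0),
    "rod-PEG-ub": CrystalForm(
        name="rod-PEG-ub", pdb_id="4XOK", space_group="P 21 21 21",
        cell=(43.72, 50.36, 93.46, 90.0, 90.0, 90.0),
        z_asu_per_cell=4, chains_per_asu=3, base_r1rho=None),
    "MPD-ub": CrystalForm(
        name="MPD-ub", pdb_id="3ONS", space_group="P 32 2 1",
        cell=(48.43, 48.43, 62.04, 90.0, 90.0, 120.0),
        z_asu_per_cell=6, chains_per_asu=1, base_r1rho=3.5),
}

# 600 MHz 1H, 39.5 kHz MAS, 15 kHz 15N spin-lock: the R1rho measurement
MEASUREMENT_CONDITIONS = SpectrometerConditions(
    proton_larmor=600e6, mas_rate=39.5e3, spinlock=15e3)
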