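"""Spectrometer and interaction parameters fixing relaxation computations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import constants

__all__ = ["SpectrometerConditions", "RotaryResonanceWarning"]


class RotaryResonanceWarning(UserWarning):
    """Spin-lock field at (or within 1 Hz of) the n = 1 or 2 rotary
    resonance condition, where the simple relaxation expressions fail."""


@dataclass
class SpectrometerConditions:
    """Static field (as 1H Larmor frequency), MAS rate, spin-lock field and
    NH interaction constants.

    proton_larmor and the rf fields are in Hz; r_nh in Angstrom; the 15N
    CSA (delta_sigma_n) in ppm, axially symmetric and collinear with the
    NH bond by assumption.
    """

    proton_larmor: float = 600e6  # Hz
    mas_rate: float = 39.5e3  # Hz
    spinlock: float = 15e3  # Hz
    r_nh: float = 1.02  # Angstrom
    delta_sigma_n: float = -170.0  # ppm

    def __post_init__(self):
        if self.proton_larmor <= 0 or self.mas_rate <= 0 or self.spinlock <= 0:
            raise ValueError("all frequencies must be positive")
        for n in (1, 2):
            if abs(self.spinlock - n * self.mas_rate) < 1.0:
                warnings.warn(
                    f"spin-lock at the n={n} rotary resonance "
                    f"(nu_1 = {self.spinlock:.0f} Hz, nu_r = {self.mas_rate:.0f} Hz)",
                    RotaryResonanceWarning, stacklevel=3)

    # angular frequencies, rad/s
    @property
    def omega_h(self) -> float:
        return 2 * np.pi * self.proton_larmor

    @property
    def omega_n(self) -> float:
        return self.omega_h * abs(constants.GAMMA_N) / constants.GAMMA_H

    @property
    def omega_1(self) -> float:
        return 2 * np.pi * self.spinlock

    @property
    def omega_r(self) -> float:
        return 2 * np.pi * self.mas_rate

    @property
    def d_nh(self) -> float:
        """Rigid-limit NH dipolar coupling, rad/s."""
        return constants.dipolar_coupling_constant(self.r_nh)

    @property
    def c_csa(self) -> float:
        """CSA interaction constant c = delta_sigma * omega_N / sqrt(3), rad/s."""
        return abs(self.delta_sigma_n) * 1e-6 * self.omega_n / np.sqrt(3.0)
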