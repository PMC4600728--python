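"""Model-free motion descriptions and spectral densities.

Correlation functions here are P2-normalized to 1 at tau = 0 and written as

    C(tau) = S^2 + sum_i c_i exp(-tau / tau_i),

so the spectral density of the time-modulated part is

    J(omega) = (2/5) sum_i c_i tau_i / (1 + (omega tau_i)^2)

with the conventional 2/5 carried inside J (the same convention in which
15N R1 = (d^2/4)[J(wH-wN) + 3 J(wN) + 6 J(wH+wN)] + c^2 J(wN)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModelFreeMotion", "MultiExpFit", "spectral_density"]


@dataclass
class ModelFreeMotion:
    """Order parameter plus exponential components of the modulated part."""

    s2: float
    components: list = field(default_factory=list)  # [(c_i, tau_i s), ...]

    def __post_init__(self):
        if not 0.0 <= self.s2 <= 1.0:
            raise ValueError("S^2 must lie in [0, 1]")
        for c, tau in self.components:
            if c < 0 or tau < 0:
                raise ValueError("component amplitudes and times must be >= 0")

    @classmethod
    def single(cls, s2: float, tau: float) -> "ModelFreeMotion":
        """One-component motion: C(tau) = S^2 + (1-S^2) exp(-tau/tau)."""
        return cls(s2=s2, components=[(1.0 - s2, tau)])


@dataclass
class MultiExpFit:
    """Multi-exponential + constant fit of a correlation function."""

    amplitudes: np.ndarray  # a_i >= 0
    taus: np.ndarray  # s
    constant: float  # a_0
    residual_norm: float

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.taus = np.asarray(self.taus, dtype=float)

    def evaluate(self, tau) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        return self.constant + np.sum(
            self.amplitudes[:, None] * np.exp(-tau[None, :] / self.taus[:, None]),
            axis=0)

    @property
    def components(self):
        return [(float(a), float(t)) for a, t in zip(self.amplitudes, self.taus)
                if a > 0]


def _components_of(motion) -> list:
    if isinstance(motion, (ModelFreeMotion, MultiExpFit)):
        return motion.components
    return list(motion)


def spectral_density(motion, omega) -> np.ndarray:
    """J(omega) in s/rad for the time-modulated part of the motion.

    ``motion`` may be a ModelFreeMotion, a MultiExpFit (its constant term
    does not contribute), or a bare list of (c_i, tau_i) pairs.
    """
    comps = _components_of(motion)
    omega = np.asarray(omega, dtype=float)
    J = np.zeros_like(omega)
    for c, tau in comps:
        if tau < 0:
            raise ValueError("negative correlation time")
        J = J + 0.4 * c * tau / (1.0 + (omega * tau) ** 2)
    return J
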