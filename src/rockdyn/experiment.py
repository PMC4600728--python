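"""Fitting of experimental relaxation decays and REDOR dephasing curves.

Relaxation rate constants come from single-exponential fits with
Monte-Carlo error estimates.  HN dipolar couplings come from REDOR
dephasing curves fitted by chi-square over a grid of coupling strengths,
with the radio-frequency field inhomogeneity across the sample modelled as
a weighted mixture of B1 scale factors; couplings convert to squared order
parameters against the rigid-limit coupling.

The REDOR element is simulated for an isolated 15N-1H pair with ideal
delta-function pulses every half rotor period (finite pulse widths are out
of scope); the B1 scale enters as the flip angle of the recoupling pulses.
In the ideal-pulse, nominal-B1 limit the powder-averaged curve reproduces
the analytic universal REDOR curve

    dS/S0(t) = 1 - (sqrt(2) pi / 4) J_{1/4}(sqrt(2) D t) J_{-1/4}(sqrt(2) D t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import jv

from . import constants

__all__ = [
    "DecayCurve", "RedorCurve", "RfInhomogeneity", "MonoExpFit",
    "RedorFit", "fit_monoexponential_mc", "redor_dephasing",
    "redor_universal_curve", "redor_fit_chi2", "coupling_to_s2",
]


class InvalidParameterError(ValueError):
    pass


class FitFailureError(RuntimeError):
    pass


@dataclass
class DecayCurve:
    """Intensity decay: times (s, strictly increasing, >= 3 points) with a
    known noise standard deviation in intensity units."""

    times: np.ndarray
    intensities: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.size < 3:
            raise InvalidParameterError("a decay curve needs >= 3 points")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")

    @classmethod
    def read(cls, path) -> "DecayCurve":
        """Two/three-column text: time, intensity[, error]."""
        data = np.loadtxt(path)
        noise = float(np.mean(data[:, 2])) if data.shape[1] > 2 else 0.0
        return cls(data[:, 0], data[:, 1], noise_sd=noise)


@dataclass
class RedorCurve:
    """REDOR dephasing dS/S0 versus recoupling time."""

    recoupling_times: np.ndarray  # s, >= 0
    dephasing: np.ndarray  # dS/S0, dimensionless
    noise_sd: float = 0.0

    def __post_init__(self):
        self.recoupling_times = np.asarray(self.recoupling_times, dtype=float)
        self.dephasing = np.asarray(self.dephasing, dtype=float)
        if np.any(self.recoupling_times < 0):
            raise InvalidParameterError("recoupling times must be >= 0")
        if np.any(self.dephasing < -0.1) or np.any(self.dephasing > 1.2):
            raise InvalidParameterError(
                "dephasing outside [-0.1, 1.2]: not a plausible dS/S0 curve")


@dataclass
class RfInhomogeneity:
    """B1 field distribution across the sample: relative scale factors with
    normalized weights."""

    scales: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.scales = np.asarray(self.scales, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.scales <= 0):
            raise InvalidParameterError("B1 scales must be positive")
        total = self.weights.sum()
        if total <= 0:
            raise InvalidParameterError("weights must sum to a positive value")
        self.weights = self.weights / total

    @classmethod
    def ideal(cls) -> "RfInhomogeneity":
        return cls(np.array([1.0]), np.array([1.0]))

    @classmethod
    def gaussian(cls, n: int = 7, mean: float = 1.0, sd: float = 0.05
                 ) -> "RfInhomogeneity":
        """Discretized Gaussian B1 profile (default 7 points, 5% width)."""
        x = np.linspace(-2.5, 2.5, n)
        w = np.exp(-0.5 * x * x)
        return cls(mean + sd * x, w)


# ------------------------------------------------------------- decay fitting

@dataclass
class MonoExpFit:
    rate: float  # s^-1
    rate_error: float  # Monte-Carlo sd
    amplitude: float


def _fit_single_exp(t, y):
    a0 = max(y[0], np.abs(y).max(), 1e-12)
    r0 = max(1.0 / (t[-1] - t[0]), 1e-9)
    if y[0] > 0 and y[-1] > 0 and y[-1] < y[0]:
        r0 = np.log(y[0] / y[-1]) / (t[-1] - t[0])
    popt, _ = curve_fit(lambda tt, a, r: a * np.exp(-r * tt), t, y,
                        p0=[a0, r0], maxfev=10000)
    return popt  # (amplitude, rate)


def fit_monoexponential_mc(curve: DecayCurve, n_mc: int = 500,
                           seed: int = 0) -> MonoExpFit:
    """Least-squares A exp(-R t) fit; the error is the standard deviation
    of rates refit on noise-resampled replicas (curve.noise_sd)."""
    if n_mc < 50:
        raise InvalidParameterError("n_mc must be >= 50")
    if np.all(curve.intensities <= 0):
        raise FitFailureError("no positive intensities to fit")
    t, y = curve.times, curve.intensities
    amp, rate = _fit_single_exp(t, y)
    if curve.noise_sd == 0:
        return MonoExpFit(float(rate), 0.0, float(amp))
    rng = np.random.default_rng(seed)
    model = amp * np.exp(-rate * t)
    rates = []
    for _ in range(n_mc):
        try:
            _, r = _fit_single_exp(t, model + rng.normal(0, curve.noise_sd, t.shape))
            rates.append(r)
        except RuntimeError:
            continue
    if len(rates) < n_mc // 2:
        raise FitFailureError("Monte-Carlo refits mostly failed")
    return MonoExpFit(float(rate), float(np.std(rates)), float(amp))


# ----------------------------------------------------------------- REDOR

def redor_universal_curve(d_eff_hz, t):
    """Analytic powder REDOR dephasing for ideal pulses,
    dS/S0 = 1 - (sqrt(2) pi/4) J_{1/4}(sqrt2 lam) J_{-1/4}(sqrt2 lam),
    lam = D t."""
    lam = np.asarray(d_eff_hz * np.asarray(t, dtype=float))
    x = np.sqrt(2.0) * np.where(lam == 0, 1.0, lam)  # dummy at 0, masked below
    out = 1.0 - (np.sqrt(2.0) * np.pi / 4.0) * jv(0.25, x) * jv(-0.25, x)
    return np.where(lam == 0, 0.0, out)


def _redor_half_phases(d_rad, beta, gamma, mas_rate):
    """Dipolar phases accumulated by S over the two halves of a rotor
    period (analytic integral of the MAS-modulated dipolar offset):
    phi_1 = -sqrt(2) d sin(2 beta) sin(gamma) / omega_r and phi_2 = -phi_1;
    the REDOR phase per period is phi_1 - phi_2."""
    base = np.sqrt(2.0) * d_rad * np.sin(2 * beta) * np.sin(gamma) / (
        2 * np.pi * mas_rate)
    return -base, base


def redor_dephasing(d_eff_hz: float, recoupling_times, rf: RfInhomogeneity | None = None,
                    mas_rate: float = 37.0e3, n_beta: int = 64, n_gamma: int = 32
                    ) -> RedorCurve:
    """Powder-averaged two-spin REDOR dephasing curve (noise-free).

    Ideal delta pulses; a B1 scale s turns each recoupling pi pulse into an
    s*pi rotation of the proton, attenuating the dephasing.  Recoupling
    times are interpreted as whole numbers of rotor periods (rounded).
    """
    if d_eff_hz < 0:
        raise InvalidParameterError("coupling must be >= 0")
    times = np.asarray(recoupling_times, dtype=float)
    if times.size == 0:
        raise InvalidParameterError("empty recoupling time list")
    if rf is None:
        rf = RfInhomogeneity.ideal()

    period = 1.0 / mas_rate
    n_periods = np.round(times / period).astype(int)
    d_rad = 2 * np.pi * d_eff_hz

    # powder: Gauss-Legendre in cos(beta), uniform gamma
    x, wq = np.polynomial.legendre.leggauss(n_beta)
    beta = np.arccos(x)
    gamma = (np.arange(n_gamma) + 0.5) * (2 * np.pi / n_gamma)
    B, G = np.meshgrid(beta, gamma, indexing="ij")
    Wgt = np.repeat(wq[:, None], n_gamma, axis=1) / (2.0 * n_gamma)
    phi1, phi2 = _redor_half_phases(d_rad, B.ravel(), G.ravel(), mas_rate)

    signal = np.zeros(times.size)
    for scale, weight in zip(rf.scales, rf.weights):
        s_curve = _redor_signal_flip((phi1, phi2), Wgt, n_periods, scale)
        signal += weight * s_curve
    dephasing = 1.0 - signal
    dephasing[n_periods == 0] = 0.0
    return RedorCurve(times, np.clip(dephasing, -0.1, 1.2))


def _redor_signal_flip(half_phases, wgt, n_periods_arr, scale):
    """S(t)/S0 for recoupling pi pulses of flip angle scale*pi.

    Exact delta-pulse two-spin result.  Because the dipolar Hamiltonian
    commutes with both Iz and Sz between pulses, the S+ coherence evolves
    with a conditional proton-space propagator V+- = ... P D(+-phi2) P
    D(+-phi1) per rotor period, where D(phi) = exp(-i Iz phi) collects the
    half-period dipolar phase phi and P rotates the proton by scale*pi
    about x.  The observed signal with the proton at thermal equilibrium is
    (1/2) Re Tr[V+ V-^dagger]; for scale = 1 this collapses to the
    classical cos(N * delta_phi) REDOR dephasing.
    """
    phi1, phi2 = half_phases  # (n_cryst,) each
    theta = np.pi * scale
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    P = np.array([[c, -1j * s], [-1j * s, c]])

    def dmat(phi):
        z = np.zeros_like(phi)
        return np.stack([
            np.stack([np.exp(-1j * phi / 2.0), z], axis=-1),
            np.stack([z, np.exp(+1j * phi / 2.0)], axis=-1),
        ], axis=-2)

    Tp = P @ dmat(phi2) @ P @ dmat(phi1)
    Tm = P @ dmat(-phi2) @ P @ dmat(-phi1)
    flat_w = wgt.ravel()
    nmax = int(n_periods_arr.max())
    want = {int(n) for n in n_periods_arr}
    signals = {0: 1.0}
    Vp = np.broadcast_to(np.eye(2, dtype=complex), Tp.shape).copy()
    Vm = Vp.copy()
    for n in range(1, nmax + 1):
        Vp = Tp @ Vp
        Vm = Tm @ Vm
        if n in want:
            W = Vp @ np.conj(np.swapaxes(Vm, -1, -2))
            tr = 0.5 * np.einsum("...ii->...", W).real
            signals[n] = float(np.sum(flat_w * tr.ravel()))
    return np.array([signals[int(n)] for n in n_periods_arr])


@dataclass
class RedorFit:
    coupling: float  # Hz
    coupling_error: float  # Monte-Carlo sd, Hz
    chi2_grid: np.ndarray
    coupling_grid: np.ndarray
    at_edge: bool
    diagnostics: dict = field(default_factory=dict)


def redor_fit_chi2(observed: RedorCurve, coupling_grid, rf: RfInhomogeneity | None = None,
                   mas_rate: float = 37.0e3, n_mc: int = 100, seed: int = 0,
                   noise_inflation: float = 3.0) -> RedorFit:
    """Grid chi-square fit of the dipolar coupling to a REDOR curve.

    Simulates the dephasing curve for every grid coupling (with the given
    B1 inhomogeneity), computes chi^2 with uniform weights, refines the
    minimum parabolically, and estimates the error by Monte-Carlo
    resampling with noise at ``noise_inflation`` times the curve's noise
    level (default 3x, the conservative convention for spectral noise).
    """
    grid = np.asarray(coupling_grid, dtype=float)
    if grid.size < 3:
        raise InvalidParameterError("coupling grid needs >= 3 points")
    sims = np.stack([
        redor_dephasing(D, observed.recoupling_times, rf, mas_rate=mas_rate).dephasing
        for D in grid])
    chi2 = np.sum((sims - observed.dephasing[None, :]) ** 2, axis=1)
    imin = int(np.argmin(chi2))
    at_edge = imin in (0, grid.size - 1)
    if at_edge:
        warnings.warn("chi^2 minimum at the edge of the coupling grid; "
                      "no parabolic refinement", stacklevel=2)
        best = float(grid[imin])
    else:
        best = _parabolic_min(grid[imin - 1:imin + 2], chi2[imin - 1:imin + 2])

    err = 0.0
    if observed.noise_sd > 0 and n_mc > 0:
        rng = np.random.default_rng(seed)
        sd = noise_inflation * observed.noise_sd
        bests = []
        for _ in range(n_mc):
            pert = observed.dephasing + rng.normal(0, sd, observed.dephasing.shape)
            c2 = np.sum((sims - pert[None, :]) ** 2, axis=1)
            j = int(np.argmin(c2))
            if 0 < j < grid.size - 1:
                bests.append(_parabolic_min(grid[j - 1:j + 2], c2[j - 1:j + 2]))
            else:
                bests.append(float(grid[j]))
        err = float(np.std(bests))
    return RedorFit(best, err, chi2, grid, at_edge,
                    diagnostics={"n_mc": n_mc, "noise_inflation": noise_inflation})


def _parabolic_min(x3, y3) -> float:
    denom = (x3[0] - x3[1]) * (x3[0] - x3[2]) * (x3[1] - x3[2])
    a = (x3[2] * (y3[1] - y3[0]) + x3[1] * (y3[0] - y3[2])
         + x3[0] * (y3[2] - y3[1])) / denom
    b = (x3[2] ** 2 * (y3[0] - y3[1]) + x3[1] ** 2 * (y3[2] - y3[0])
         + x3[0] ** 2 * (y3[1] - y3[2])) / denom
    if a <= 0:
        return float(x3[int(np.argmin(y3))])
    return float(-b / (2 * a))


# ------------------------------------------------------------ order parameter

def rigid_limit_coupling(r_nh: float = 1.02) -> float:
    """Rigid-limit NH dipolar coupling in Hz at the given bond length."""
    return constants.dipolar_coupling_constant(r_nh) / (2 * np.pi)


def coupling_to_s2(d_fit_hz: float, r_nh: float = 1.02) -> float:
    """S^2 = (D_fit / D_rigid)^2; couplings above the rigid limit clip to 1."""
    if d_fit_hz < 0:
        raise InvalidParameterError("coupling must be >= 0")
    d_rigid = rigid_limit_coupling(r_nh)
    if d_fit_hz > d_rigid:
        warnings.warn("fitted coupling exceeds the rigid limit; S^2 clipped to 1",
                      stacklevel=2)
        return 1.0
    return float((d_fit_hz / d_rigid) ** 2)
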