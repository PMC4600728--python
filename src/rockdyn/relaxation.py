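"""15N R1rho under magic-angle spinning with an on-resonance spin-lock.

Redfield-theory rates
---------------------
For stochastic motion with P2-normalized correlation function
C(tau) = S^2 + sum_i c_i exp(-tau/tau_i) and spectral density
J(w) = (2/5) sum_i c_i tau_i / (1 + (w tau_i)^2), second-order theory for
an NH pair (dipolar coupling d) plus an axially symmetric 15N CSA
(constant c = dsigma wN / sqrt(3), tensor collinear with the bond) gives,
under MAS at omega_r with an on-resonance spin-lock omega_1,

  R1rho^DD  = (d^2/8) [ (4/3) J(w1 - wr) + (4/3) J(w1 + wr)
                      + (2/3) J(w1 - 2 wr) + (2/3) J(w1 + 2 wr)
                      + J(wH - wN) + 3 J(wN) + 6 J(wH) + 6 J(wH + wN) ]
  R1rho^CSA = (c^2/6) [ (4/3) J(w1 - wr) + (4/3) J(w1 + wr)
                      + (2/3) J(w1 - 2 wr) + (2/3) J(w1 + 2 wr) + 3 J(wN) ]

i.e. the static secular J(0) term is redistributed over the MAS sidebands
of the spin-lock frequency with the magic-angle weights
|d2_0,+-1|^2 = 1/3 and |d2_0,+-2|^2 = 1/6, while the high-frequency
non-secular terms keep their solution-state form.  These expressions are
pinned against an independent numerical two-site-jump propagation (below)
rather than trusted on transcription alone.

Numerical two-site jump
-----------------------
``r1rho_numeric_jump`` propagates the spin-locked 15N magnetization
classically under the time-dependent dipolar + CSA frequency offset of a
crystallite spinning at the magic angle, with orientational two-site
exchange treated by an exchange superoperator (stochastic-Liouville in
the fast-fluctuation-free sense): a 6-dimensional ODE per crystallite and
proton spin state, powder averaged.  It stays valid outside the Redfield
regime, where the perturbative expressions above fail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq, minimize_scalar

from .conditions import SpectrometerConditions
from .modelfree import ModelFreeMotion, spectral_density, _components_of
from .rocking import BiExpBaseFit, sphere_vectors

__all__ = [
    "JumpModel", "SimControls", "RateSurface", "TauBranches",
    "r1rho_redfield", "rocking_r1rho", "rate_surface", "solve_tau_branches",
    "r1rho_numeric_jump", "RedfieldValidityWarning",
]


class RedfieldValidityWarning(UserWarning):
    """Motion slower than the inverse of the smallest sampled frequency gap:
    the perturbative rate is no longer guaranteed accurate."""


# ----------------------------------------------------------------- Redfield

def _sideband_sum(J, w1, wr):
    return ((4.0 / 3.0) * (J(w1 - wr) + J(w1 + wr))
            + (2.0 / 3.0) * (J(w1 - 2 * wr) + J(w1 + 2 * wr)))


def r1rho_redfield(motion, cond: SpectrometerConditions,
                   include_dipolar: bool = True, include_csa: bool = True,
                   validity_warning: bool = True) -> float:
    """Redfield-theory on-resonance 15N R1rho for the supplied motion only.

    ``motion`` is a ModelFreeMotion, MultiExpFit or list of (c_i, tau_i).
    Emits :class:`RedfieldValidityWarning` when the longest correlation
    time exceeds the inverse of the smallest spin-lock/MAS frequency gap.
    """
    comps = _components_of(motion)
    w1, wr = cond.omega_1, cond.omega_r
    wh, wn = cond.omega_h, cond.omega_n
    if validity_warning and comps:
        gap = min(abs(w1 - wr), abs(w1 + wr), abs(w1 - 2 * wr), abs(w1 + 2 * wr))
        tau_max = max(t for _, t in comps)
        if tau_max > 1.0 / gap:
            warnings.warn(
                f"tau = {tau_max:.3g} s exceeds 1/(smallest sampled frequency) "
                f"= {1.0 / gap:.3g} s; Redfield treatment is approximate here",
                RedfieldValidityWarning, stacklevel=2)
    J = lambda w: spectral_density(comps, np.array([abs(w)]))[0]
    rate = 0.0
    if include_dipolar:
        d2 = cond.d_nh ** 2
        rate += d2 / 8.0 * (_sideband_sum(J, w1, wr)
                            + J(wh - wn) + 3 * J(wn) + 6 * J(wh) + 6 * J(wh + wn))
    if include_csa:
        rate += cond.c_csa ** 2 / 6.0 * (_sideband_sum(J, w1, wr) + 3 * J(wn))
    return float(rate)


def rocking_r1rho(fit: BiExpBaseFit, cond: SpectrometerConditions,
                  include_fast: bool = False, fast_cutoff: float = 1e-8,
                  **kw) -> float:
    """R1rho contribution of fitted rocking motion.

    Maps the slow component of the bi-exponential fit onto a model-free
    motion via 1 - S^2 = c_s and tau = tau_s (components merged through
    :meth:`BiExpBaseFit.slow_component`).  The fast ~ns component is
    excluded by default since its contribution is negligible at these
    spin-lock/MAS frequencies; ``include_fast`` adds it back.
    """
    c_s, tau_s = fit.slow_component(fast_cutoff=fast_cutoff)
    comps = []
    if c_s > 0:
        comps.append((c_s, tau_s))
    if include_fast:
        comps += [(c, t) for c, t in ((fit.c_f, fit.tau_f), (fit.c_s, fit.tau_s))
                  if t < fast_cutoff and c > 0]
    if not comps:
        return 0.0
    return r1rho_redfield(comps, cond, **kw)


# ------------------------------------------------------------- rate surface

@dataclass
class TauBranches:
    """Two-branch solution of R1rho(tau) = target at fixed S^2."""

    tau_fast: float | None
    tau_slow: float | None
    tau_max: float
    rate_max: float
    target: float

    @property
    def solvable(self) -> bool:
        return self.tau_fast is not None


def _rate_of_tau(s2, cond, **kw):
    def f(tau):
        return r1rho_redfield(ModelFreeMotion.single(s2, tau), cond,
                              validity_warning=False, **kw)
    return f


def solve_tau_branches(target_rate: float, s2: float,
                       cond: SpectrometerConditions,
                       tau_range=(1e-12, 1e-1), **kw) -> TauBranches:
    """Both correlation-time roots of the iso-rate equation at fixed S^2.

    Locates the tau maximizing R1rho (the rate is unimodal in tau), then
    bisects on each side.  When the target exceeds the maximum, returns an
    explicit no-solution result rather than raising.
    """
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    rate = _rate_of_tau(s2, cond, **kw)
    lo, hi = np.log(tau_range[0]), np.log(tau_range[1])
    res = minimize_scalar(lambda lt: -rate(np.exp(lt)), bounds=(lo, hi),
                          method="bounded",
                          options={"xatol": 1e-10})
    lt_max = res.x
    r_max = -res.fun
    tau_max = float(np.exp(lt_max))
    if target_rate > r_max:
        return TauBranches(None, None, tau_max, float(r_max), target_rate)
    g = lambda lt: rate(np.exp(lt)) - target_rate
    if abs(g(lt_max)) < 1e-9 * target_rate:
        return TauBranches(tau_max, tau_max, tau_max, float(r_max), target_rate)
    t_fast = np.exp(brentq(g, lo, lt_max, xtol=1e-14)) if g(lo) < 0 else np.exp(lo)
    t_slow = np.exp(brentq(g, lt_max, hi, xtol=1e-14)) if g(hi) < 0 else np.exp(hi)
    return TauBranches(float(t_fast), float(t_slow), tau_max, float(r_max),
                       target_rate)


@dataclass
class RateSurface:
    """R1rho over an (S^2, tau) grid at fixed spectrometer conditions."""

    s2_grid: np.ndarray
    tau_grid: np.ndarray
    rates: np.ndarray  # (n_s2, n_tau)
    conditions: SpectrometerConditions

    def contour(self, target_rate: float, **kw):
        """Iso-rate polylines: rows (s2, tau_fast, tau_slow); rows where the
        target exceeds the row maximum are dropped (empty contour possible)."""
        pts = []
        for s2 in self.s2_grid:
            if s2 >= 1.0:
                continue
            br = solve_tau_branches(target_rate, float(s2), self.conditions,
                                    tau_range=(self.tau_grid[0], self.tau_grid[-1]),
                                    **kw)
            if br.solvable:
                pts.append((float(s2), br.tau_fast, br.tau_slow))
        if not pts and target_rate > 0:
            warnings.warn(f"requested contour {target_rate} s^-1 is above the "
                          "surface maximum everywhere", stacklevel=2)
        return np.array(pts).reshape(-1, 3)


def rate_surface(s2_grid, tau_grid, cond: SpectrometerConditions, **kw
                 ) -> RateSurface:
    """Evaluate the Redfield R1rho surface over monotone S^2 and tau grids."""
    s2_grid = np.asarray(s2_grid, dtype=float)
    tau_grid = np.asarray(tau_grid, dtype=float)
    if np.any(np.diff(s2_grid) <= 0) or np.any(np.diff(tau_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    rates = np.empty((s2_grid.size, tau_grid.size))
    for i, s2 in enumerate(s2_grid):
        f = _rate_of_tau(float(s2), cond, **kw)
        for j, tau in enumerate(tau_grid):
            rates[i, j] = f(float(tau))
    return RateSurface(s2_grid, tau_grid, rates, cond)


# ------------------------------------------------------- numerical two-site

@dataclass
class JumpModel:
    """Two-site orientational exchange of the NH vector.

    ``phi_deg`` is the angle between the two site orientations of the
    vector; equal populations, per-site escape rate ``k_ex`` so the
    model-free correlation time is 1/(2 k_ex) and the plateau order
    parameter is S^2 = (1 + 3 cos^2 Phi)/4.
    """

    phi_deg: float
    k_ex: float  # s^-1

    def __post_init__(self):
        if self.k_ex < 0:
            raise ValueError("k_ex must be non-negative")

    @property
    def s2(self) -> float:
        c = np.cos(np.deg2rad(self.phi_deg))
        return (1.0 + 3.0 * c * c) / 4.0

    @property
    def tau(self) -> float:
        return np.inf if self.k_ex == 0 else 1.0 / (2.0 * self.k_ex)


@dataclass
class SimControls:
    """Discretization of the numerical spin-lock propagation."""

    n_directions: int = 48  # crystallite director orientations (spiral)
    n_azimuths: int = 3  # rotations of the jump plane about the director
    steps_per_period: int = 100
    t_max: float = 50e-3  # s, spin-lock period over which the decay is fitted
    mode: str = "superoperator"  # or "stochastic"
    n_stochastic: int = 200  # trajectories per crystallite (stochastic mode)
    seed: int = 0
    include_csa: bool = True
    include_dipolar: bool = True

    def __post_init__(self):
        if self.n_directions < 1 or self.steps_per_period < 4:
            raise ValueError("non-positive powder grid or too few rotor steps")


@dataclass
class NumericRate:
    rate: float  # s^-1
    r_squared: float
    exponential: bool
    curve: np.ndarray = field(repr=False, default=None)
    times: np.ndarray = field(repr=False, default=None)


def _mas_offset_coeffs(u_rotor):
    """Fourier coefficients of W(t) = (3 cos^2 theta(t) - 1)/2 for a vector
    with rotor-frame direction u: W = A1 cos(wr t + g) + A2 cos(2 wr t + 2g).
    Returns (A1, A2, g)."""
    x, y, z = u_rotor
    beta = np.arccos(np.clip(z, -1.0, 1.0))
    gamma = np.arctan2(y, x)
    A1 = (np.sqrt(2.0) / 2.0) * np.sin(2 * beta)
    A2 = 0.5 * np.sin(beta) ** 2
    return A1, A2, gamma


def _cross_matrix(w1, dw):
    return np.array([[0.0, -dw, 0.0],
                     [dw, 0.0, -w1],
                     [0.0, w1, 0.0]])


def r1rho_numeric_jump(model: JumpModel, cond: SpectrometerConditions,
                       controls: SimControls | None = None) -> NumericRate:
    """Powder-averaged spin-lock decay rate of a two-site jump, by direct
    propagation of the classical magnetization with exchange.

    For every crystallite the two NH site orientations are placed at
    +-Phi/2 from the crystallite director; the instantaneous frequency
    offset of 15N (dipolar, for each proton spin state, plus CSA) follows
    the MAS rotation analytically.  Exchange enters as a symmetric
    superoperator coupling the two sites' magnetization vectors.  The
    powder- and proton-state-averaged Mx decay is fitted log-linearly; a
    decay with log-fit R^2 below 0.98 is flagged non-exponential.
    """
    if controls is None:
        controls = SimControls()
    if controls.mode == "stochastic":
        return _numeric_jump_stochastic(model, cond, controls)

    w1, wr = cond.omega_1, cond.omega_r
    period = 2 * np.pi / wr
    n_steps = controls.steps_per_period
    dt = period / n_steps
    n_periods = max(int(controls.t_max / period), 8)
    k = model.k_ex

    half = np.deg2rad(model.phi_deg) / 2.0
    d = cond.d_nh if controls.include_dipolar else 0.0
    csa_scale = ((2.0 / 3.0) * cond.delta_sigma_n * 1e-6 * cond.omega_n
                 if controls.include_csa else 0.0)

    dirs = sphere_vectors(controls.n_directions)
    azimuths = np.linspace(0, np.pi, controls.n_azimuths, endpoint=False)
    t_grid = (np.arange(n_steps) + 0.5) * dt

    # site offsets W_site(t) for every crystallite (director x azimuth)
    W_sites = []  # (n_cryst, 2, n_steps)
    for n_dir in dirs:
        a = np.array([0.0, 0.0, 1.0]) if abs(n_dir[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(n_dir, a)
        e1 /= np.linalg.norm(e1)
        for az in azimuths:
            e = np.cos(az) * e1 + np.sin(az) * np.cross(n_dir, e1)
            u_sites = [np.cos(half) * n_dir + np.sin(half) * e,
                       np.cos(half) * n_dir - np.sin(half) * e]
            coeffs = [_mas_offset_coeffs(u) for u in u_sites]
            W_sites.append([A1 * np.cos(wr * t_grid + g)
                            + A2 * np.cos(2 * (wr * t_grid + g))
                            for (A1, A2, g) in coeffs])
    W_sites = np.asarray(W_sites)

    # ensemble over (crystallite, proton state); dipolar offset per proton
    # state is +-(d/2)(3cos^2 th - 1) = +-d W, CSA adds (2/3) dsigma wN W
    dws = np.concatenate([(mI * d + csa_scale) * W_sites for mI in (+1.0, -1.0)])
    K = dws.shape[0]
    dw1, dw2 = dws[:, 0, :], dws[:, 1, :]  # (K, n_steps) per site
    L = np.zeros((K, n_steps, 6, 6))
    L[..., 0, 1] = -dw1
    L[..., 1, 0] = dw1
    L[..., 3, 4] = -dw2
    L[..., 4, 3] = dw2
    L[..., 1, 2] = -w1
    L[..., 2, 1] = w1
    L[..., 4, 5] = -w1
    L[..., 5, 4] = w1
    idx = np.arange(3)
    L[..., idx, idx] -= k
    L[..., idx + 3, idx + 3] -= k
    L[..., idx, idx + 3] += k
    L[..., idx + 3, idx] += k
    steps = expm(L * dt)  # batched matrix exponentials
    U = steps[:, 0]
    for s in range(1, n_steps):
        U = np.einsum("kij,kjl->kil", steps[:, s], U)

    m = np.tile([0.5, 0.0, 0.0, 0.5, 0.0, 0.0], (K, 1))
    mx = np.empty(n_periods + 1)
    mx[0] = 1.0
    for p in range(1, n_periods + 1):
        m = np.einsum("kij,kj->ki", U, m)
        mx[p] = (m[:, 0] + m[:, 3]).mean()
    times = np.arange(n_periods + 1) * period
    return _fit_decay_rate(times, mx)


def _fit_decay_rate(times, mx) -> NumericRate:
    good = mx > 0.05 * mx[0]
    t, y = times[good], np.log(mx[good] / mx[0])
    if t.size < 4:
        t, y = times[:4], np.log(np.clip(mx[:4], 1e-12, None) / mx[0])
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = np.sum((y - pred) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return NumericRate(rate=float(-slope), r_squared=float(r2),
                       exponential=bool(r2 >= 0.98), curve=mx, times=times)


def _rodrigues_step(m, w1, dw, dt):
    """Rotate magnetization rows m (N, 3) about axes (w1, 0, dw_i) by
    |omega| dt (exact piecewise-constant Bloch step, no relaxation)."""
    wmag = np.sqrt(w1 * w1 + dw * dw)
    ax = np.empty((dw.size, 3))
    ax[:, 0] = w1 / wmag
    ax[:, 1] = 0.0
    ax[:, 2] = dw / wmag
    ang = wmag * dt
    cosa, sina = np.cos(ang)[:, None], np.sin(ang)[:, None]
    dot = np.sum(ax * m, axis=1, keepdims=True)
    return m * cosa + np.cross(ax, m) * sina + ax * dot * (1.0 - cosa)


def _numeric_jump_stochastic(model, cond, controls) -> NumericRate:
    """Monte-Carlo telegraph-trajectory cross-check of the superoperator
    mode: explicit random two-site jumps, vectorized over all trajectories."""
    from .synthetic import _telegraph_states

    rng = np.random.default_rng(controls.seed)
    w1, wr = cond.omega_1, cond.omega_r
    period = 2 * np.pi / wr
    n_steps = controls.steps_per_period
    dt = period / n_steps
    n_periods = max(int(controls.t_max / period), 8)
    half = np.deg2rad(model.phi_deg) / 2.0
    d = cond.d_nh if controls.include_dipolar else 0.0
    csa_scale = ((2.0 / 3.0) * cond.delta_sigma_n * 1e-6 * cond.omega_n
                 if controls.include_csa else 0.0)
    dirs = sphere_vectors(controls.n_directions)
    t_grid = (np.arange(n_steps * n_periods) + 0.5) * dt
    per_dir = max(controls.n_stochastic // controls.n_directions, 1)

    # per-crystallite site offsets W_site(t) for both sites
    Wall = []
    for n_dir in dirs:
        a = np.array([0.0, 0.0, 1.0]) if abs(n_dir[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(n_dir, a)
        e1 /= np.linalg.norm(e1)
        u_sites = [np.cos(half) * n_dir + np.sin(half) * e1,
                   np.cos(half) * n_dir - np.sin(half) * e1]
        coeffs = [_mas_offset_coeffs(u) for u in u_sites]
        Wall.append([A1 * np.cos(wr * t_grid + g) + A2 * np.cos(2 * (wr * t_grid + g))
                     for (A1, A2, g) in coeffs])

    # build ensemble: (crystallite, replica, proton state) flattened
    dw_series = []
    for ci in range(len(dirs)):
        W0, W1 = Wall[ci]
        for _ in range(per_dir):
            states = _telegraph_states(rng, t_grid.size, dt, model.k_ex)
            Wt = np.where(states == 0, W0, W1)
            for mI in (+1.0, -1.0):
                dw_series.append((mI * d + csa_scale) * Wt)
    dw_series = np.array(dw_series)  # (N, n_steps*n_periods)
    N = dw_series.shape[0]
    m = np.tile([1.0, 0.0, 0.0], (N, 1))
    mx = np.empty(n_periods + 1)
    mx[0] = 1.0
    idx = 0
    for p in range(1, n_periods + 1):
        for _s in range(n_steps):
            m = _rodrigues_step(m, w1, dw_series[:, idx], dt)
            idx += 1
        mx[p] = m[:, 0].mean()
    times = np.arange(n_periods + 1) * period
    return _fit_decay_rate(times, mx)
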