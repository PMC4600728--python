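"""Rigid-body rocking analysis of crystal trajectories.

From a multi-copy trajectory, extract per-molecule rotation-matrix series
Xi(t) (least-squares fit of a Calpha selection against reference
coordinates), apply them to a quasi-uniform unit-vector set to build the
isotropic rocking correlation function

    g_rock(tau) = < P2( (Xi(t) u) . (Xi(t+tau) u) ) >_{u, t, molecules}

with P2(x) = (3 x^2 - 1)/2, classify molecules whose curve deviates wildly
from the rest as outliers, and fit the mean curve with a bi-exponential
plus a flat base whose plateau is reported as the rocking order parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .trajectory import Trajectory
from .lattice import ReferenceLattice

__all__ = [
    "CorrelationFunction", "RotationSeries", "BiExpBaseFit",
    "fit_rotation", "rotation_series", "sphere_vectors",
    "rocking_correlation", "aggregate_and_flag", "fit_biexp_base",
    "log_lag_grid",
]


class DegenerateFitError(ValueError):
    """Selection too small or collinear for a rigid-body fit."""


class FitFailureError(RuntimeError):
    pass


# ------------------------------------------------------------------- fitting

def fit_rotation(mobile: np.ndarray, reference: np.ndarray,
                 selection: np.ndarray | None = None):
    """Proper rotation minimizing RMSD of mobile onto reference (Kabsch).

    Centroids are removed first; the optimal reflection case is forced to a
    proper rotation (det +1).  Returns ``(R, rmsd)`` with
    ``R @ (reference - centroid)`` best matching ``mobile - centroid``.
    """
    if selection is not None:
        mobile = mobile[selection]
        reference = reference[selection]
    R, rmsd = _kabsch_batch(mobile[None], reference)
    return R[0], float(rmsd[0])


def _kabsch_batch(mobile: np.ndarray, reference: np.ndarray):
    """Batched Kabsch: mobile (F, N, 3) onto one reference (N, 3).

    Returns rotations (F, 3, 3) with det +1 mapping reference -> mobile
    (both centered), and per-frame RMSD.
    """
    n = reference.shape[0]
    if n < 3:
        raise DegenerateFitError("need >= 3 atoms for a rigid-body fit")
    ref_c = reference - reference.mean(axis=0)
    span = np.linalg.svd(ref_c, compute_uv=False)
    if span[1] < 1e-8 * max(span[0], 1.0):
        raise DegenerateFitError("selected atoms are (nearly) collinear")
    mob_c = mobile - mobile.mean(axis=1, keepdims=True)
    # covariance H = ref^T mob per frame
    H = np.einsum("na,fnb->fab", ref_c, mob_c)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("fab,fbc->fac", U, Vt)))
    # flip the smallest singular direction when the optimum is a reflection
    Vt_f = Vt.copy()
    Vt_f[:, 2, :] *= d[:, None]
    R = np.transpose(U @ Vt_f, (0, 2, 1))  # R = V' U^T, maps ref -> mob
    fitted = np.einsum("fab,nb->fna", R, ref_c)
    rmsd = np.sqrt(np.mean(np.sum((fitted - mob_c) ** 2, axis=2), axis=1))
    return R, rmsd


@dataclass
class RotationSeries:
    """Per-frame proper rotations Xi(t) of one molecule relative to its
    reference coordinates, with the per-frame fit RMSD in Angstrom."""

    matrices: np.ndarray  # (n_frames, 3, 3)
    molecule_id: str
    fit_rmsd: np.ndarray
    time_step: float

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=float)
        err = np.abs(np.einsum("fab,fcb->fac", self.matrices, self.matrices)
                     - np.eye(3)).max()
        if err > 1e-8:
            raise ValueError(f"rotation matrices not orthonormal (max dev {err:.2e})")

    @property
    def n_frames(self) -> int:
        return self.matrices.shape[0]

    def max_angle(self) -> float:
        """Largest rotation angle (rad) in the series."""
        tr = np.trace(self.matrices, axis1=1, axis2=2)
        return float(np.max(np.arccos(np.clip((tr - 1) / 2, -1, 1))))


def rotation_series(traj: Trajectory, reference: ReferenceLattice,
                    selection: np.ndarray | None = None) -> list[RotationSeries]:
    """Extract Xi(t) for every molecule of a trajectory.

    Each molecule is first mapped into the template frame using the stored
    lattice transform, then fitted (selection atoms only, default CA) to
    the corresponding template-chain coordinates.
    """
    if selection is None:
        selection = traj.atoms.mask(atom_names=["CA"])
    if traj.n_molecules != reference.n_molecules:
        raise ValueError("trajectory and reference disagree on molecule count")
    out = []
    for mi in range(traj.n_molecules):
        xyz = traj.coordinates[:, mi]
        if not np.isfinite(xyz).all():
            bad = np.argwhere(~np.isfinite(xyz))[0]
            raise ValueError(
                f"non-finite coordinates in molecule {mi}, frame {bad[0]}")
        inv = reference.transforms[mi].inverse()
        mapped = xyz[:, selection] @ inv.rotation.T + inv.translation
        template = inv.apply(reference.coordinates[mi])[selection]
        R, rmsd = _kabsch_batch(mapped, template)
        out.append(RotationSeries(R, traj.molecule_labels[mi], rmsd,
                                  traj.time_step))
    return out


# ------------------------------------------------------------------- vectors

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def sphere_vectors(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (generalized spiral).

    Seed-free; n = 1 returns (0, 0, 1) by convention.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    phi = i * _GOLDEN_ANGLE
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


# -------------------------------------------------------- correlation curves

@dataclass
class CorrelationFunction:
    """Orientational correlation curve on a (possibly non-linear) lag grid."""

    lags: np.ndarray  # s, strictly increasing, starts at 0
    values: np.ndarray
    n_origins: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_origins = np.asarray(self.n_origins, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lags, "value": self.values,
                             "n_origins": self.n_origins})


def log_lag_grid(time_step: float, total_time: float,
                 per_decade: int = 25, max_fraction: float = 0.2) -> np.ndarray:
    """Integer frame lags, log-spaced at ~per_decade points per decade from
    one frame up to max_fraction of the trajectory, plus lag zero."""
    max_lag = max(int(total_time / time_step * max_fraction), 1)
    n_dec = np.log10(max_lag) if max_lag > 1 else 0
    n_pts = max(int(np.ceil(n_dec * per_decade)), 1) + 1
    lags = np.unique(np.round(np.logspace(0, np.log10(max_lag), n_pts)).astype(int))
    return np.concatenate([[0], lags])


def _vector_fourth_moment(vectors: np.ndarray) -> np.ndarray:
    u = np.asarray(vectors, dtype=float)
    return np.einsum("ka,kb,kc,kd->abcd", u, u, u, u) / u.shape[0]


def rocking_correlation(series: RotationSeries, vectors: np.ndarray,
                        lag_frames: np.ndarray, origin_stride: int = 1
                        ) -> CorrelationFunction:
    """Isotropic rocking correlation function of one molecule.

    Averages P2((Xi(t) u).(Xi(t+tau) u)) over the supplied vector set and
    all time origins (stride configurable for long inputs).  The vector
    average is evaluated exactly through the fourth-moment tensor of the
    vector set, which is algebraically identical to looping over vectors.
    """
    lag_frames = np.asarray(lag_frames, dtype=int)
    if lag_frames.size == 0:
        raise ValueError("empty lag grid")
    F = series.n_frames
    if lag_frames.max() >= F:
        raise ValueError("lag grid exceeds trajectory length")
    T4 = _vector_fourth_moment(vectors)
    mats = series.matrices
    values = np.empty(lag_frames.size)
    counts = np.empty(lag_frames.size, dtype=int)
    for li, L in enumerate(lag_frames):
        a = mats[:F - L:origin_stride]
        b = mats[L:F:origin_stride][: a.shape[0]]
        M = np.einsum("fba,fbc->fac", a, b)  # Xi(t)^T Xi(t+L)
        e2 = np.einsum("fab,fcd,abcd->f", M, M, T4)
        values[li] = np.mean(1.5 * e2 - 0.5)
        counts[li] = a.shape[0]
    return CorrelationFunction(lag_frames * series.time_step, values, counts,
                               label=series.molecule_id)


def aggregate_and_flag(curves: list[CorrelationFunction], k_mad: float = 3.0):
    """Mean correlation curve over molecules with outlier rejection.

    A curve is an outlier when its RMS deviation from the pointwise median
    curve exceeds ``k_mad`` times the median of all curves' RMS deviations.
    Returns ``(mean_curve, outlier_flags)``.
    """
    if len(curves) < 2:
        raise ValueError("need >= 2 curves to aggregate")
    lags = curves[0].lags
    for c in curves[1:]:
        if c.lags.shape != lags.shape or not np.allclose(c.lags, lags):
            raise ValueError("curves are not on a common lag grid")
    vals = np.stack([c.values for c in curves])
    median = np.median(vals, axis=0)
    rmsd = np.sqrt(np.mean((vals - median) ** 2, axis=1))
    flags = rmsd > k_mad * np.median(rmsd)
    kept = vals[~flags] if (~flags).any() else vals
    mean = kept.mean(axis=0)
    counts = curves[0].n_origins * kept.shape[0]
    return CorrelationFunction(lags, mean, counts, label="mean"), flags


# ---------------------------------------------------------------- biexp fit

@dataclass
class BiExpBaseFit:
    """Bi-exponential-with-flat-base fit of a rocking correlation function:
    g(tau) = plateau + c_f exp(-tau/tau_f) + c_s exp(-tau/tau_s)."""

    c_f: float
    c_s: float
    tau_f: float  # s
    tau_s: float  # s
    plateau: float
    residual_norm: float
    diagnostics: dict = field(default_factory=dict)

    def slow_component(self, fast_cutoff: float = 1e-8):
        """(amplitude, tau) of the slow rocking component.

        Components faster than ``fast_cutoff`` (default 10 ns, i.e. the
        ~1 ns libration scale with margin) are excluded; if both fitted
        exponentials are slow they are merged amplitude-weighted, which
        preserves sum(c_i tau_i), the quantity that controls the
        spin-lock relaxation contribution for omega*tau << 1.  This makes
        the (1 - S^2, tau_s) read-out robust when the underlying decay is
        effectively mono-exponential and the two fitted time constants are
        degenerate.  Returns (0.0, 0.0) for a flat curve.
        """
        comps = [(c, t) for c, t in ((self.c_f, self.tau_f), (self.c_s, self.tau_s))
                 if t >= fast_cutoff and c > 0]
        c_tot = sum(c for c, _ in comps)
        if c_tot <= 0:
            return 0.0, 0.0
        tau_eff = sum(c * t for c, t in comps) / c_tot
        return float(c_tot), float(tau_eff)


def _biexp(tau, p, cf, cs, tf, ts):
    return p + cf * np.exp(-tau / tf) + cs * np.exp(-tau / ts)


def fit_biexp_base(curve: CorrelationFunction, n_starts: int = 4) -> BiExpBaseFit:
    """Least-squares bi-exponential + flat base fit with multi-start over a
    log-spaced tau initialization grid; amplitudes bounded non-negative and
    both taus restricted to (time_step, total span]."""
    tau = curve.lags
    y = curve.values
    if tau.size < 7:
        raise ValueError("need >= 7 lag points")
    if not np.isfinite(y).all():
        raise ValueError("correlation values must be finite")
    dt = tau[1] - tau[0] if tau[0] == 0 else tau[0]
    t_max = tau[-1]
    lo = np.log(max(dt, 1e-15))
    hi = np.log(t_max)
    grid = np.exp(np.linspace(lo, hi, n_starts + 2))[1:-1]

    def resid(p):
        pl, cf, cs, ltf, lts = p
        return _biexp(tau, pl, cf, cs, np.exp(ltf), np.exp(lts)) - y

    best = None
    amp0 = max(y[0] - y[-1], 1e-4)
    for tf0 in grid:
        for ts0 in grid:
            if ts0 <= tf0:
                continue
            x0 = [y[-1], 0.2 * amp0, 0.8 * amp0, np.log(tf0), np.log(ts0)]
            try:
                sol = least_squares(
                    resid, x0,
                    bounds=([0.0, 0.0, 0.0, lo, lo], [1.5, 1.0, 1.0, hi, hi]),
                    method="trf", xtol=1e-12, ftol=1e-12)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise FitFailureError("no bi-exponential start converged")
    pl, cf, cs, ltf, lts = best.x
    tf, ts = np.exp(ltf), np.exp(lts)
    if tf > ts:  # enforce tau_f <= tau_s labelling
        tf, ts = ts, tf
        cf, cs = cs, cf
    return BiExpBaseFit(
        c_f=float(cf), c_s=float(cs), tau_f=float(tf), tau_s=float(ts),
        plateau=float(pl), residual_norm=float(np.sqrt(2 * best.cost)),
        diagnostics={"n_points": int(tau.size), "success": bool(best.success)})
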