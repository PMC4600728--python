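"""Site-specific internal dynamics from crystal trajectories.

Maps every molecule copy into the template frame with the stored crystal
symmetry transforms, extracts NH bond unit vectors, and computes the
observables used to compare internal dynamics between crystal forms:
per-residue order parameters (Bruschweiler-Wright second-moment formula),
NH orientational correlation functions on a non-linear lag grid,
multi-exponential + constant fits, spectral densities and 15N R1 rates,
and the global scaling factor aligning two S^2 profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, nnls

from .conditions import SpectrometerConditions
from .lattice import ReferenceLattice
from .modelfree import ModelFreeMotion, MultiExpFit, spectral_density
from .rocking import CorrelationFunction, FitFailureError
from .trajectory import Trajectory

__all__ = [
    "VectorSeries", "symmetry_superpose", "nh_vector_series",
    "s2_bruschweiler_wright", "vector_correlation", "fit_multiexp",
    "r1_nitrogen", "global_s2_scaling",
]


def symmetry_superpose(traj: Trajectory, reference: ReferenceLattice) -> Trajectory:
    """Express every molecule copy in the template frame.

    Applies the inverse of each molecule's stored lattice transform, so all
    copies become directly comparable (the per-residue series can then be
    concatenated across molecules into one long array).
    """
    if traj.n_molecules != reference.n_molecules:
        raise ValueError("trajectory and reference disagree on molecule count")
    out = np.empty_like(traj.coordinates)
    for mi in range(traj.n_molecules):
        inv = reference.transforms[mi].inverse()
        out[:, mi] = traj.coordinates[:, mi] @ inv.rotation.T + inv.translation
    return Trajectory(out, traj.time_step, traj.atoms,
                      molecule_labels=list(traj.molecule_labels),
                      metadata=dict(traj.metadata, superposed=True))


@dataclass
class VectorSeries:
    """Unit NH vectors per molecule / frame / residue."""

    vectors: np.ndarray  # (n_molecules, n_frames, n_residues, 3), unit norm
    residue_ids: np.ndarray
    time_step: float

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        norms = np.linalg.norm(self.vectors, axis=-1)
        if np.abs(norms - 1.0).max() > 1e-9:
            raise ValueError("vectors must be unit length")

    @property
    def n_molecules(self) -> int:
        return self.vectors.shape[0]

    def concatenated(self) -> np.ndarray:
        """Long array per residue: molecules stacked along the sample axis,
        shape (n_molecules * n_frames, n_residues, 3)."""
        m, f, r, _ = self.vectors.shape
        return self.vectors.reshape(m * f, r, 3)


def nh_vector_series(traj: Trajectory, reference: ReferenceLattice | None = None
                     ) -> VectorSeries:
    """Extract unit N->H vectors, optionally after symmetry superposition."""
    if reference is not None:
        traj = symmetry_superpose(traj, reference)
    atoms = traj.atoms
    n_idx, h_idx, resids = [], [], []
    h_by_resid = {atoms.resids[i]: i for i, n in enumerate(atoms.names) if n == "H"}
    for i, name in enumerate(atoms.names):
        if name == "N" and atoms.resids[i] in h_by_resid:
            n_idx.append(i)
            h_idx.append(h_by_resid[atoms.resids[i]])
            resids.append(atoms.resids[i])
    if not n_idx:
        raise ValueError("no N/H atom pairs found")
    nh = (traj.coordinates[:, :, h_idx] - traj.coordinates[:, :, n_idx])
    norm = np.linalg.norm(nh, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("zero-length NH vector encountered")
    vectors = np.swapaxes(nh / norm, 0, 1)  # -> (mol, frame, residue, 3)
    return VectorSeries(vectors, np.array(resids), traj.time_step)


# ----------------------------------------------------------- order parameters

def s2_bruschweiler_wright(vectors: np.ndarray) -> np.ndarray:
    """Order parameters from Cartesian second moments of unit vectors.

    For each residue, with Q_ab = <e_a e_b> over all samples,
    S^2 = (3 sum_ab Q_ab^2 - 1)/2, which is bounded to [0, 1].
    ``vectors`` has shape (n_samples, 3) or (n_samples, n_residues, 3).
    """
    v = np.asarray(vectors, dtype=float)
    squeeze = v.ndim == 2
    if squeeze:
        v = v[:, None, :]
    if v.shape[0] < 2:
        raise ValueError("need >= 2 samples per residue")
    norms = np.linalg.norm(v, axis=-1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length vectors")
    v = v / norms[..., None]
    Q = np.einsum("sra,srb->rab", v, v) / v.shape[0]
    s2 = 0.5 * (3.0 * np.einsum("rab,rab->r", Q, Q) - 1.0)
    return float(s2[0]) if squeeze else s2


# ------------------------------------------------------- correlation functions

def vector_correlation(series: VectorSeries, lag_frames: np.ndarray,
                       origin_stride: int = 1) -> list[CorrelationFunction]:
    """Per-residue P2 autocorrelation of NH vectors on a non-linear grid.

    Correlations are computed within each molecule (never across the
    concatenation boundary) and averaged over the equivalent molecules.
    """
    lag_frames = np.asarray(lag_frames, dtype=int)
    if lag_frames.size == 0:
        raise ValueError("empty lag grid")
    m, F, n_res, _ = series.vectors.shape
    if lag_frames.max() >= F:
        raise ValueError("lag grid exceeds trajectory length")
    values = np.empty((lag_frames.size, n_res))
    counts = np.empty(lag_frames.size, dtype=int)
    for li, L in enumerate(lag_frames):
        a = series.vectors[:, :F - L:origin_stride]
        b = series.vectors[:, L:F:origin_stride][:, : a.shape[1]]
        dots = np.einsum("mfrx,mfrx->mfr", a, b)
        values[li] = np.mean(1.5 * dots ** 2 - 0.5, axis=(0, 1))
        counts[li] = m * a.shape[1]
    lags = lag_frames * series.time_step
    return [CorrelationFunction(lags, values[:, r], counts,
                                label=str(series.residue_ids[r]))
            for r in range(n_res)]


# ----------------------------------------------------------------- multi-exp

def fit_multiexp(curve: CorrelationFunction, max_terms: int = 6,
                 tau_cap: float | None = None, dictionary_size: int = 40
                 ) -> MultiExpFit:
    """Fit C(tau) = a0 + sum a_i exp(-tau/tau_i), a_i >= 0, tau_i <= tau_cap.

    Non-negative least squares over a log-spaced tau dictionary picks the
    active components; the largest ``max_terms`` are then locally refined
    (amplitudes and times jointly, times capped at ``tau_cap``, which
    defaults to the curve's total span -- the trajectory-length bound).
    """
    tau = curve.lags
    y = curve.values
    if tau.size < 2 * max_terms:
        raise ValueError(f"need >= {2 * max_terms} lag points")
    if np.allclose(y, 0.0):
        raise FitFailureError("all-zero correlation curve")
    if tau_cap is None:
        tau_cap = tau[-1]
    dt = tau[1] - tau[0] if tau[0] == 0 else tau[0]
    taus_dict = np.logspace(np.log10(dt), np.log10(tau_cap), dictionary_size)
    basis = np.exp(-tau[:, None] / taus_dict[None, :])
    A = np.column_stack([basis, np.ones_like(tau)])
    coef, _ = nnls(A, y)
    amps, const = coef[:-1], coef[-1]

    order = np.argsort(amps)[::-1]
    active = [i for i in order[:max_terms] if amps[i] > 0]
    if not active:
        return MultiExpFit(np.zeros(1), np.array([tau_cap]), float(const),
                           float(np.linalg.norm(A @ coef - y)))
    a0 = amps[active]
    t0 = taus_dict[active]
    k = len(active)

    def resid(p):
        a, lt, c = p[:k], p[k:2 * k], p[-1]
        model = c + np.sum(a[:, None] * np.exp(-tau[None, :] / np.exp(lt)[:, None]),
                           axis=0)
        return model - y

    lo_t, hi_t = np.log(dt * 1e-2), np.log(tau_cap)
    x0 = np.concatenate([a0, np.clip(np.log(t0), lo_t, hi_t), [const]])
    sol = least_squares(
        resid, x0,
        bounds=(np.concatenate([np.zeros(k), np.full(k, lo_t), [0.0]]),
                np.concatenate([np.full(k, np.inf), np.full(k, hi_t), [np.inf]])),
        xtol=1e-14, ftol=1e-14)
    a, lt, c = sol.x[:k], sol.x[k:2 * k], sol.x[-1]
    order = np.argsort(np.exp(lt))
    return MultiExpFit(a[order], np.exp(lt)[order], float(c),
                       float(np.linalg.norm(sol.fun)))


# ---------------------------------------------------------------- relaxation

def r1_nitrogen(motion, cond: SpectrometerConditions) -> float:
    """Longitudinal 15N relaxation rate from NH dipolar + 15N CSA.

    R1 = (d^2/4)[J(wH-wN) + 3 J(wN) + 6 J(wH+wN)] + c^2 J(wN),
    with d the rigid-limit NH dipolar coupling and c = dsigma*wN/sqrt(3);
    only the time-modulated part of the motion contributes.
    """
    wh, wn = cond.omega_h, cond.omega_n
    J = lambda w: spectral_density(motion, np.array([w]))[0]
    d2 = cond.d_nh ** 2
    return float(d2 / 4.0 * (J(wh - wn) + 3 * J(wn) + 6 * J(wh + wn))
                 + cond.c_csa ** 2 * J(wn))


# ------------------------------------------------------------------ profiles

def global_s2_scaling(profile_a: dict, profile_b: dict):
    """Least-squares scalar alpha aligning two per-residue S^2 profiles.

    alpha = argmin sum_r (S2_a[r] - alpha S2_b[r])^2 over residues shared
    by both profiles (dict residue -> S^2).  Returns (alpha, rms_before,
    rms_after).
    """
    shared = sorted(set(profile_a) & set(profile_b))
    if len(shared) < 5:
        raise ValueError("need >= 5 shared residues")
    a = np.array([profile_a[r] for r in shared])
    b = np.array([profile_b[r] for r in shared])
    alpha = float(np.dot(a, b) / np.dot(b, b))
    rms_before = float(np.sqrt(np.mean((a - b) ** 2)))
    rms_after = float(np.sqrt(np.mean((a - alpha * b) ** 2)))
    return alpha, rms_before, rms_after
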