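"""Synthetic crystal trajectories with known rigid-body rocking.

The generators here produce ground truth for the whole analysis chain:
multi-copy lattices whose molecules undergo prescribed rigid-body
orientational fluctuations ("rocking") about their lattice sites, optional
per-residue NH wobble, and synthetic experimental curves (exponential
decays) with controlled noise.

Two rocking processes are provided; both are stand-ins for whatever
microscopic process drives rocking in a real crystal (which no generative
model is claimed for here):

* ``two_site_jump`` — exchange between two orientations separated by a
  rotation of angle Phi about a fixed axis, with exponentially distributed
  dwell times (symmetric exchange; correlation time 1/(2 k_ex)).
* ``restrained_diffusion`` — independent Ornstein-Uhlenbeck processes on
  the three components of a rotation vector, composed through the
  exponential map each frame.  A good small-angle model for sigma up to
  roughly 0.3 rad.

Order-parameter conventions.  A *single vector* jumping between two
orientations separated by angle Phi has the textbook plateau
``S^2 = (1 + 3 cos^2 Phi)/4``.  A *rigid body* rotated by Phi moves
different vectors by different angles, so the plateau of an isotropically
averaged vector set differs:  ``(2 + 2 cos^2 Phi + cos Phi)/5``.  Both
closed forms are exposed because the first is what the relaxation jump
model uses per NH vector, while the second is what the isotropic rocking
correlation function of a rigid-body process converges to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .experiment import DecayCurve, InvalidParameterError
from .lattice import ReferenceLattice
from .trajectory import AtomTable, Trajectory

__all__ = [
    "RockingProcess", "InternalMotion", "DecayCurve",
    "simulate_rocking_series", "assemble_trajectory", "synth_decay_curve",
    "two_site_vector_s2", "rigid_body_plateau", "diffusion_plateau",
    "sigma_for_plateau", "make_helical_template",
]


# --------------------------------------------------------------- closed forms

def two_site_vector_s2(phi_deg: float) -> float:
    """Plateau S^2 of a single vector jumping by angle Phi between two
    equally populated orientations: (1 + 3 cos^2 Phi)/4."""
    c = np.cos(np.deg2rad(phi_deg))
    return (1.0 + 3.0 * c * c) / 4.0


def _iso_p2_of_rotation(cos_chi):
    """Isotropic vector average of P2(u . R u) for a rotation by angle chi.

    <P2(u.Ru)>_u = (4 cos^2 chi + 2 cos chi - 1)/5.
    """
    c = np.asarray(cos_chi, dtype=float)
    return (4.0 * c * c + 2.0 * c - 1.0) / 5.0


def rigid_body_plateau(phi_deg: float) -> float:
    """Isotropic-vector-set plateau for a rigid body jumping by angle Phi.

    Equal populations: (1 + <P2(u.R_Phi u)>)/2 = (2 + 2 cos^2 Phi + cos Phi)/5.
    """
    c = np.cos(np.deg2rad(phi_deg))
    return (2.0 + 2.0 * c * c + c) / 5.0


def diffusion_plateau(sigma: float, n_samples: int = 200_000,
                      seed: int = 20_1509) -> float:
    """Plateau order parameter of the stationary restrained-diffusion process.

    Monte-Carlo estimate over independent pairs of stationary orientations
    (Gaussian rotation vectors, per-axis std ``sigma``); deterministic for
    fixed seed.  For sigma = 0 returns exactly 1.
    """
    if sigma < 0:
        raise InvalidParameterError("sigma must be non-negative")
    if sigma == 0.0:
        return 1.0
    rng = np.random.default_rng(seed)
    v1 = rng.normal(0.0, sigma, size=(n_samples, 3))
    v2 = rng.normal(0.0, sigma, size=(n_samples, 3))
    q = (Rotation.from_rotvec(v1).inv() * Rotation.from_rotvec(v2)).as_matrix()
    cos_chi = 0.5 * (np.trace(q, axis1=1, axis2=2) - 1.0)
    return float(np.mean(_iso_p2_of_rotation(cos_chi)))


def sigma_for_plateau(s2: float) -> float:
    """Invert :func:`diffusion_plateau`: per-axis rotation-vector std giving
    a target isotropic plateau order parameter."""
    if not 0.4 < s2 <= 1.0:
        raise InvalidParameterError("target plateau must be in (0.4, 1]")
    if s2 == 1.0:
        return 0.0
    return brentq(lambda s: diffusion_plateau(s) - s2, 1e-4, 0.8, xtol=1e-6)


# ------------------------------------------------------------------ processes

@dataclass
class RockingProcess:
    """Rigid-body orientational fluctuation model for one lattice site."""

    kind: str  # "two_site_jump" or "restrained_diffusion"
    jump_angle_phi: float = 0.0  # degrees, angle between the two orientations
    exchange_rate: float = 0.0  # s^-1, per-site escape rate (two-site)
    jump_axis: tuple = (1.0, 0.0, 0.0)
    angular_stddev: float = 0.0  # rad per rotation-vector axis (diffusion)
    relaxation_time: float = 0.0  # s (diffusion)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("two_site_jump", "restrained_diffusion"):
            raise InvalidParameterError(f"unknown rocking kind {self.kind!r}")
        if self.exchange_rate < 0 or self.angular_stddev < 0:
            raise InvalidParameterError("rates and stddevs must be non-negative")
        if self.kind == "restrained_diffusion" and self.angular_stddev > 0 \
                and self.relaxation_time <= 0:
            raise InvalidParameterError("diffusion needs a positive relaxation_time")

    @property
    def correlation_time(self) -> float:
        """Model-free correlation time: 1/(2 k_ex) for symmetric two-site
        exchange, the OU relaxation time for restrained diffusion."""
        if self.kind == "two_site_jump":
            return np.inf if self.exchange_rate == 0 else 1.0 / (2.0 * self.exchange_rate)
        return self.relaxation_time

    @property
    def plateau_s2(self) -> float:
        """Isotropic-vector-set plateau of the process (ground truth for
        the rocking correlation function)."""
        if self.kind == "two_site_jump":
            return rigid_body_plateau(self.jump_angle_phi)
        return diffusion_plateau(self.angular_stddev)


@dataclass
class InternalMotion:
    """Per-residue NH wobble: Gaussian axial fluctuation of the H position
    about the reference NH direction (N fixed), OU in time.

    ``cone_semiangle`` (degrees) sets the root-mean-square total tilt of
    the NH vector; 0 means NH vectors rigid within the molecular frame.
    """

    cone_semiangle: float = 0.0  # degrees, rms tilt
    correlation_time: float = 50e-12  # s
    seed: int = 1

    def __post_init__(self):
        if self.cone_semiangle < 0 or self.correlation_time <= 0:
            raise InvalidParameterError("invalid internal-motion parameters")


def _ou_series(rng, n, dt, tau, sigma, shape=()):
    """Stationary Ornstein-Uhlenbeck sample paths, exact discretization."""
    phi = np.exp(-dt / tau)
    innov = sigma * np.sqrt(1.0 - phi * phi)
    x = np.empty((n,) + shape)
    x[0] = rng.normal(0.0, sigma, size=shape)
    noise = rng.normal(0.0, 1.0, size=(n - 1,) + shape)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + innov * noise[i - 1]
    return x


def simulate_rocking_series(process: RockingProcess, n_frames: int,
                            time_step: float, rng=None) -> np.ndarray:
    """Sequence of proper rotation matrices (n_frames, 3, 3) about a fixed
    pivot, sampled every ``time_step`` seconds."""
    if n_frames < 2:
        raise InvalidParameterError("need at least 2 frames")
    if time_step <= 0:
        raise InvalidParameterError("time_step must be positive")
    if rng is None:
        rng = np.random.default_rng(process.seed)

    if process.kind == "two_site_jump":
        axis = np.asarray(process.jump_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        half = np.deg2rad(process.jump_angle_phi) / 2.0
        sites = np.stack([
            Rotation.from_rotvec(-half * axis).as_matrix(),
            Rotation.from_rotvec(+half * axis).as_matrix(),
        ])
        state = _telegraph_states(rng, n_frames, time_step, process.exchange_rate)
        return sites[state]

    sigma, tau = process.angular_stddev, process.relaxation_time
    if sigma == 0.0:
        return np.broadcast_to(np.eye(3), (n_frames, 3, 3)).copy()
    v = _ou_series(rng, n_frames, time_step, tau, sigma, shape=(3,))
    return Rotation.from_rotvec(v).as_matrix()


def _telegraph_states(rng, n_frames, dt, k):
    """Two-state telegraph process with exponential dwell times (rate k
    out of each state), sampled on the frame grid."""
    states = np.zeros(n_frames, dtype=int)
    if k == 0:
        states[:] = rng.integers(0, 2)
        return states
    t_total = n_frames * dt
    s = int(rng.integers(0, 2))
    t = 0.0
    i = 0
    while t < t_total and i < n_frames:
        dwell = rng.exponential(1.0 / k)
        j = min(n_frames, int(np.ceil((t + dwell) / dt)))
        states[i:j] = s
        i = j
        t += dwell
        s = 1 - s
    return states


# ---------------------------------------------------------------- assembling

def assemble_trajectory(lattice: ReferenceLattice,
                        rocking: RockingProcess | list[RockingProcess] | None,
                        internal: InternalMotion | None,
                        n_frames: int, time_step: float,
                        pivot_atom: str = "CA") -> Trajectory:
    """Animate a reference lattice with per-molecule rocking and NH wobble.

    Each frame is the lattice coordinates with the molecule's rocking
    rotation applied about the centroid of its ``pivot_atom`` selection
    (centroids are stationary: no translational diffusion).  If a single
    :class:`RockingProcess` is given it is replicated per molecule with
    independent realizations (seeds spawned from its seed).
    """
    n_mol = lattice.n_molecules
    if rocking is None:
        processes = None
    elif isinstance(rocking, RockingProcess):
        processes = [rocking] * n_mol
        seeds = np.random.SeedSequence(rocking.seed).spawn(n_mol)
    else:
        processes = list(rocking)
        if len(processes) != n_mol:
            raise ValueError(
                f"{len(processes)} rocking processes for {n_mol} molecules")
        seeds = [np.random.SeedSequence(p.seed) for p in processes]

    atoms = lattice.atoms
    ca_mask = atoms.mask(atom_names=[pivot_atom])
    if not ca_mask.any():
        raise ValueError(f"no {pivot_atom!r} atoms for the rocking pivot")

    coords = np.empty((n_frames, n_mol, len(atoms), 3))
    for mi in range(n_mol):
        ref = lattice.coordinates[mi]
        pivot = ref[ca_mask].mean(axis=0)
        centered = ref - pivot
        if processes is None:
            coords[:, mi] = ref
        else:
            rng = np.random.default_rng(seeds[mi])
            mats = simulate_rocking_series(processes[mi], n_frames, time_step,
                                           rng=rng)
            coords[:, mi] = np.einsum("fij,aj->fai", mats, centered) + pivot

    if internal is not None and internal.cone_semiangle > 0:
        _apply_nh_wobble(coords, lattice, internal, time_step)

    return Trajectory(coords, time_step, atoms,
                      metadata={"generator": "rockdyn.synthetic",
                                "n_frames": n_frames})


def _apply_nh_wobble(coords, lattice, internal, time_step):
    """Tilt each amide H about its N by an OU angular process.

    Applied molecule-by-molecule in the laboratory frame; because the tilt
    is defined relative to the instantaneous NH direction, this commutes
    with the rigid-body rocking to within the small-angle approximation.
    """
    atoms = lattice.atoms
    n_frames, n_mol = coords.shape[:2]
    sigma_tilt = np.deg2rad(internal.cone_semiangle) / np.sqrt(2.0)
    seeds = np.random.SeedSequence(internal.seed).spawn(n_mol)
    h_idx = [i for i, n in enumerate(atoms.names) if n == "H"]
    n_by_resid = {atoms.resids[i]: i for i, n in enumerate(atoms.names) if n == "N"}
    for mi in range(n_mol):
        rng = np.random.default_rng(seeds[mi])
        for hi in h_idx:
            ni = n_by_resid.get(atoms.resids[hi])
            if ni is None:
                continue
            nh = coords[:, mi, hi] - coords[:, mi, ni]
            bond = np.linalg.norm(nh, axis=1, keepdims=True)
            u = nh / bond
            # two OU tilt components in a frame perpendicular to u
            tilt = _ou_series(rng, n_frames, time_step,
                              internal.correlation_time, sigma_tilt, shape=(2,))
            e1 = np.cross(u, [0.0, 0.0, 1.0])
            bad = np.linalg.norm(e1, axis=1) < 1e-6
            e1[bad] = np.cross(u[bad], [1.0, 0.0, 0.0])
            e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
            e2 = np.cross(u, e1)
            rotvec = tilt[:, :1] * e1 + tilt[:, 1:] * e2
            u_new = Rotation.from_rotvec(rotvec).apply(u)
            coords[:, mi, hi] = coords[:, mi, ni] + bond * u_new


# ------------------------------------------------------------- decay fixtures

def synth_decay_curve(rate: float, time_points, noise_sd: float = 0.0,
                      seed: int = 0, amplitude: float = 1.0) -> DecayCurve:
    """exp(-rate t) plus zero-mean Gaussian noise; reproducible by seed."""
    if rate < 0:
        raise InvalidParameterError("rate must be non-negative")
    t = np.asarray(time_points, dtype=float)
    if t.size == 0:
        raise InvalidParameterError("time_points must be non-empty")
    y = amplitude * np.exp(-rate * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=t.shape)
    return DecayCurve(t, y, noise_sd=noise_sd)


# ------------------------------------------------------------- toy templates

def make_helical_template(n_residues: int = 8, rise: float = 1.5,
                          radius: float = 2.3, twist_deg: float = 100.0,
                          r_nh: float = 1.02):
    """Compact helical N/H/CA toy chain used as a molecule template.

    Returns (coords (n_atoms, 3), AtomTable).  Three atoms per residue:
    backbone N, amide H (at r_NH from N, pointing outward), and CA.  The
    CA trace is non-collinear for any n_residues >= 3, as required by
    rigid-body fitting.
    """
    names, resids, xyz = [], [], []
    twist = np.deg2rad(twist_deg)
    for i in range(n_residues):
        ang = i * twist
        ca = np.array([radius * np.cos(ang), radius * np.sin(ang), rise * i])
        n = ca + np.array([0.6 * np.cos(ang + 0.8), 0.6 * np.sin(ang + 0.8), -0.9])
        out = np.array([np.cos(ang + 0.4), np.sin(ang + 0.4), -0.35])
        h = n + r_nh * out / np.linalg.norm(out)
        for nm, pos in (("N", n), ("H", h), ("CA", ca)):
            names.append(nm)
            resids.append(i + 1)
            xyz.append(pos)
    return np.array(xyz), AtomTable(names=names, resids=np.array(resids))
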