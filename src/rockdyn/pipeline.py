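"""End-to-end pipeline: simulate -> rock -> dynamics -> relax -> report.

Driven by a YAML config describing the lattice, the rocking and internal
motion processes, trajectory size, spectrometer conditions and packing
inputs.  Every stage writes tidy TSV tables plus a single structured
report; all randomness flows from the config seed, so a rerun with the
same config reproduces the report byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .conditions import SpectrometerConditions
from .crystal import UnitCellContents, matthews_solvent
from .internal import nh_vector_series, r1_nitrogen, s2_bruschweiler_wright, \
    vector_correlation, fit_multiexp
from .lattice import LatticeSpec, SymmetryOp, build_reference_lattice
from .relaxation import rocking_r1rho, solve_tau_branches
from .rocking import aggregate_and_flag, fit_biexp_base, log_lag_grid, \
    rocking_correlation, rotation_series, sphere_vectors
from .synthetic import InternalMotion, RockingProcess, assemble_trajectory, \
    make_helical_template, sigma_for_plateau

__all__ = ["run_pipeline", "load_config", "default_demo_config", "build_lattice"]


class StageError(RuntimeError):
    """Pipeline stage failure, tagged with the stage name."""

    def __init__(self, stage, exc):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


_SYMMETRY_SETS = {
    "identity": [SymmetryOp.identity()],
    # P 21 21 21 (proper orthorhombic screw axes)
    "p212121": [
        SymmetryOp(np.diag([1.0, 1.0, 1.0]), np.array([0.0, 0.0, 0.0])),
        SymmetryOp(np.diag([-1.0, -1.0, 1.0]), np.array([0.5, 0.0, 0.5])),
        SymmetryOp(np.diag([-1.0, 1.0, -1.0]), np.array([0.0, 0.5, 0.5])),
        SymmetryOp(np.diag([1.0, -1.0, -1.0]), np.array([0.5, 0.5, 0.0])),
    ],
}


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def default_demo_config(seed: int = 1) -> dict:
    """Small self-contained demo: a 4-copy orthorhombic lattice with
    restrained-diffusion rocking (target plateau 0.982, tau_s 200 ns)."""
    return {
        "seed": seed,
        "lattice": {
            "unit_cell": [34.0, 36.0, 30.0, 90.0, 90.0, 90.0],
            "symmetry": "p212121",
            "template": {"n_residues": 8},
            "replication": [1, 1, 1],
        },
        "rocking": {
            "kind": "restrained_diffusion",
            "target_s2": 0.982,
            "relaxation_time": 2.0e-7,
        },
        "internal": {"cone_semiangle": 10.0, "correlation_time": 5.0e-11},
        "trajectory": {"n_frames": 6000, "time_step": 1.0e-9},
        "conditions": {"proton_larmor": 6.0e8, "mas_rate": 3.95e4,
                       "spinlock": 1.5e4},
        "analysis": {"n_vectors": 100, "per_decade": 25, "target_rate": 12.0},
        "solvent": {"cell": [43.72, 50.36, 93.46, 90.0, 90.0, 90.0],
                    "z_asu_per_cell": 4, "chains_per_asu": 3,
                    "chain_mass": 8565.0},
    }


def build_lattice(cfg: dict, seed: int = 0):
    lat_cfg = cfg["lattice"]
    template_xyz, atoms = make_helical_template(
        n_residues=int(lat_cfg.get("template", {}).get("n_residues", 8)))
    sym = lat_cfg.get("symmetry", "identity")
    ops = _SYMMETRY_SETS[sym] if isinstance(sym, str) else [
        SymmetryOp(np.array(o["rotation"]), np.array(o["translation"]))
        for o in sym]
    n_chains = int(lat_cfg.get("n_chains_asu", 1))
    templates = np.stack([template_xyz + 1.5 * i for i in range(n_chains)])
    spec = LatticeSpec(
        unit_cell=tuple(lat_cfg["unit_cell"]), symmetry_ops=ops,
        template_coords=templates, atoms=atoms,
        replication=tuple(lat_cfg.get("replication", (1, 1, 1))))
    return build_reference_lattice(spec)


def _rocking_process(cfg: dict, seed: int) -> RockingProcess | None:
    r = cfg.get("rocking")
    if not r:
        return None
    kind = r.get("kind", "restrained_diffusion")
    if kind == "restrained_diffusion":
        sigma = r.get("angular_stddev")
        if sigma is None:
            sigma = sigma_for_plateau(float(r["target_s2"]))
        return RockingProcess(kind=kind, angular_stddev=float(sigma),
                              relaxation_time=float(r["relaxation_time"]),
                              seed=seed)
    return RockingProcess(kind=kind, jump_angle_phi=float(r["jump_angle_phi"]),
                          exchange_rate=float(r["exchange_rate"]), seed=seed)


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the configured stages and write a structured report.

    Returns the report dict; writes report.json, the mean rocking
    correlation curve and per-residue dynamics tables under ``out_dir``.
    Partial outputs are left in place if a later stage fails.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report = {"provenance": {"package": "rockdyn", "version": __version__,
                             "seed": seed, "config": config}}

    # ---------------------------------------------------------- simulate
    try:
        lattice = build_lattice(config, seed)
        process = _rocking_process(config, seed)
        icfg = config.get("internal") or {}
        internal = (InternalMotion(cone_semiangle=float(icfg["cone_semiangle"]),
                                   correlation_time=float(icfg["correlation_time"]),
                                   seed=seed + 1)
                    if icfg else None)
        tcfg = config["trajectory"]
        traj = assemble_trajectory(lattice, process, internal,
                                   int(tcfg["n_frames"]), float(tcfg["time_step"]))
        report["simulate"] = {
            "n_molecules": lattice.n_molecules, "n_frames": traj.n_frames,
            "time_step_s": traj.time_step,
            "rocking": asdict(process) if process else None,
        }
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise StageError("simulate", exc) from exc

    # -------------------------------------------------------------- rock
    try:
        acfg = config.get("analysis", {})
        series = rotation_series(traj, lattice)
        lags = log_lag_grid(traj.time_step, traj.length,
                            per_decade=int(acfg.get("per_decade", 25)))
        vectors = sphere_vectors(int(acfg.get("n_vectors", 100)))
        curves = [rocking_correlation(s, vectors, lags) for s in series]
        mean_curve, flags = aggregate_and_flag(curves)
        fit = fit_biexp_base(mean_curve)
        df = mean_curve.to_frame()
        with open(out / "g_rock_mean.tsv", "w") as fh:
            fh.write("# mean isotropic rocking correlation function\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.8f")
        report["rock"] = {
            "outliers": [series[i].molecule_id for i in np.flatnonzero(flags)],
            "fit": {"c_f": fit.c_f, "c_s": fit.c_s, "tau_f_s": fit.tau_f,
                    "tau_s_s": fit.tau_s, "plateau_s2": fit.plateau},
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("rock", exc) from exc

    # ---------------------------------------------------------- dynamics
    try:
        ccfg = config.get("conditions", {})
        cond = SpectrometerConditions(**{k: float(v) for k, v in ccfg.items()})
        vs = nh_vector_series(traj, lattice)
        s2 = s2_bruschweiler_wright(vs.concatenated())
        nh_curves = vector_correlation(vs, lags)
        rows = []
        for resid, s2_r, curve in zip(vs.residue_ids, s2, nh_curves):
            mfit = fit_multiexp(curve, max_terms=6, tau_cap=traj.length)
            rows.append((int(resid), s2_r, r1_nitrogen(mfit, cond)))
        with open(out / "dynamics.tsv", "w") as fh:
            fh.write("# residue\tS2\tR1_s-1\n")
            for resid, s2_r, r1 in rows:
                fh.write(f"{resid}\t{s2_r:.6f}\t{r1:.6f}\n")
        report["dynamics"] = {
            "mean_s2": float(np.mean([r[1] for r in rows])),
            "mean_r1": float(np.mean([r[2] for r in rows])),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("dynamics", exc) from exc

    # ------------------------------------------------------------- relax
    try:
        contribution = rocking_r1rho(fit, cond, validity_warning=False)
        target = float(acfg.get("target_rate", 12.0))
        branches = solve_tau_branches(target, max(min(fit.plateau, 1.0), 0.0),
                                      cond)
        report["relax"] = {
            "rocking_r1rho_s-1": contribution,
            "target_rate_s-1": target,
            "tau_fast_s": branches.tau_fast, "tau_slow_s": branches.tau_slow,
            "rate_max_s-1": branches.rate_max,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("relax", exc) from exc

    # ----------------------------------------------------------- solvent
    if "solvent" in config:
        try:
            scfg = config["solvent"]
            contents = UnitCellContents(tuple(scfg["cell"]),
                                        int(scfg["z_asu_per_cell"]),
                                        int(scfg["chains_per_asu"]),
                                        float(scfg["chain_mass"]))
            v_m, v_s = matthews_solvent(contents)
            report["solvent"] = {"v_m_A3_per_Da": v_m, "v_s_percent": 100 * v_s}
        except Exception as exc:  # noqa: BLE001
            raise StageError("solvent", exc) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return report
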