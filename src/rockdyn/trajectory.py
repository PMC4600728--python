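"""Trajectory container and I/O.

A :class:`Trajectory` holds coordinates of a multi-copy crystal system as a
dense array of shape ``(n_frames, n_molecules, n_atoms, 3)`` in Angstrom,
with a time step in seconds.  All molecules share one atom table (names,
residue numbers), which is what makes per-molecule rigid-body fitting and
NH-vector extraction straightforward.

Exchange formats are multi-model PDB (one MODEL per frame, one chain per
molecule, written/read via gemmi) and a tidy TSV table with one row per
frame/molecule/atom.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

__all__ = ["AtomTable", "Trajectory"]


@dataclass
class AtomTable:
    """Per-atom metadata shared by every molecule copy."""

    names: list[str]
    resids: np.ndarray  # residue number per atom
    resnames: list[str] | None = None

    def __post_init__(self):
        self.resids = np.asarray(self.resids, dtype=int)
        if len(self.names) != len(self.resids):
            raise ValueError("names and resids must have equal length")
        if self.resnames is None:
            self.resnames = ["ALA"] * len(self.names)

    def __len__(self) -> int:
        return len(self.names)

    def mask(self, atom_names=None, resid_range=None) -> np.ndarray:
        """Boolean atom mask by atom name set and inclusive residue range."""
        m = np.ones(len(self), dtype=bool)
        if atom_names is not None:
            names = set(atom_names)
            m &= np.array([n in names for n in self.names])
        if resid_range is not None:
            lo, hi = resid_range
            m &= (self.resids >= lo) & (self.resids <= hi)
        return m


@dataclass
class Trajectory:
    """Crystal trajectory: frames x molecules x atoms x 3, Angstrom."""

    coordinates: np.ndarray
    time_step: float  # s
    atoms: AtomTable
    molecule_labels: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 4 or self.coordinates.shape[-1] != 3:
            raise ValueError("coordinates must have shape (frames, molecules, atoms, 3)")
        if self.coordinates.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.coordinates.shape[2] != len(self.atoms):
            raise ValueError("atom table does not match coordinate array")
        if not self.time_step > 0:
            raise ValueError("time_step must be positive")
        if self.molecule_labels is None:
            self.molecule_labels = _default_labels(self.n_molecules)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.coordinates.shape[1]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[2]

    @property
    def length(self) -> float:
        """Total time span (n_frames - 1) * dt, seconds."""
        return (self.n_frames - 1) * self.time_step

    # ------------------------------------------------------------------ I/O

    def to_table(self) -> pd.DataFrame:
        """One row per frame/molecule/atom: frame, molecule, atom, resid, x, y, z."""
        f, m, a, _ = self.coordinates.shape
        frames = np.repeat(np.arange(f), m * a)
        mols = np.tile(np.repeat(np.arange(m), a), f)
        atoms = np.tile(np.arange(a), f * m)
        xyz = self.coordinates.reshape(-1, 3)
        return pd.DataFrame({
            "frame": frames,
            "molecule": [self.molecule_labels[i] for i in mols],
            "atom": [self.atoms.names[i] for i in atoms],
            "resid": self.atoms.resids[atoms],
            "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
        })

    def write_table(self, path, float_format: str = "%.6f") -> None:
        df = self.to_table()
        with open(path, "w") as fh:
            fh.write(f"# time_step_s\t{self.time_step:.9e}\n")
            df.to_csv(fh, sep="\t", index=False, float_format=float_format)

    @classmethod
    def read_table(cls, path) -> "Trajectory":
        time_step = None
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition("\t")
                if key == "time_step_s":
                    time_step = float(val)
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t")
        if time_step is None:
            raise ValueError("table lacks a '# time_step_s' header line")
        mols = list(dict.fromkeys(df["molecule"]))
        frames = sorted(df["frame"].unique())
        sub0 = df[(df["frame"] == frames[0]) & (df["molecule"] == mols[0])]
        atoms = AtomTable(names=list(sub0["atom"]), resids=sub0["resid"].to_numpy())
        n_f, n_m, n_a = len(frames), len(mols), len(atoms)
        df = df.sort_values("frame", kind="stable")
        coords = df[["x", "y", "z"]].to_numpy().reshape(n_f, n_m, n_a, 3)
        return cls(coords, time_step, atoms, molecule_labels=[str(m) for m in mols])

    def write_pdb(self, path, stride: int = 1) -> None:
        """Write a multi-model PDB (one MODEL per frame, one chain per molecule)."""
        st = gemmi.Structure()
        st.name = "rockdyn trajectory"
        for fi in range(0, self.n_frames, stride):
            model = gemmi.Model(str(fi + 1))
            for mi in range(self.n_molecules):
                chain = gemmi.Chain(self.molecule_labels[mi][:2])
                prev_resid = None
                res = None
                for ai in range(self.n_atoms):
                    resid = int(self.atoms.resids[ai])
                    if resid != prev_resid:
                        res = gemmi.Residue()
                        res.name = self.atoms.resnames[ai]
                        res.seqid = gemmi.SeqId(resid, " ")
                        chain.add_residue(res)
                        prev_resid = resid
                    atom = gemmi.Atom()
                    atom.name = self.atoms.names[ai]
                    el = self.atoms.names[ai][:1]
                    atom.element = gemmi.Element(el if el in "CNOHSP" else "C")
                    x, y, z = self.coordinates[fi, mi, ai]
                    atom.pos = gemmi.Position(x, y, z)
                    chain[-1].add_atom(atom)
                model.add_chain(chain)
            st.add_model(model)
        st.setup_entities()
        doc = st.make_pdb_string()
        with open(path, "w") as fh:
            fh.write(doc)

    @classmethod
    def read_pdb(cls, path, time_step: float) -> "Trajectory":
        st = gemmi.read_structure(str(path))
        frames = []
        labels = None
        atoms = None
        for model in st:
            mols = []
            for chain in model:
                xyz = []
                names, resids, resnames = [], [], []
                for res in chain:
                    for atom in res:
                        xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                        names.append(atom.name)
                        resids.append(res.seqid.num)
                        resnames.append(res.name)
                mols.append(np.array(xyz))
                if atoms is None:
                    atoms = AtomTable(names=names, resids=np.array(resids),
                                      resnames=resnames)
            if labels is None:
                labels = [chain.name for chain in model]
            frames.append(np.stack(mols))
        coords = np.stack(frames)
        return cls(coords, time_step, atoms, molecule_labels=labels)


def _default_labels(n: int) -> list[str]:
    alphabet = string.ascii_uppercase
    labels = []
    for i in range(n):
        if i < 26:
            labels.append(alphabet[i])
        else:
            labels.append(alphabet[i // 26 - 1] + alphabet[i % 26])
    return labels
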