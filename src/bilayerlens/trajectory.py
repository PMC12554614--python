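"""In-memory bilayer trajectory container and file I/O.

Coordinates are stored in Angstrom, frames ordered by time, topology
(names, residues, masses) constant across frames.  Multi-frame PDB is the
interchange format (read and written through MDAnalysis); single frames can
also be written as GRO.  Optionally a parallel set of unwrapped coordinates
is carried for displacement-based analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory", "write_pdb", "write_gro", "read_pdb"]

ELEMENT_MASSES = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007, "P": 30.974}


def mass_from_name(name: str) -> float:
    """Guess an atomic mass from a PDB-style atom name (leading element)."""
    head = name.strip()
    if not head:
        raise ValueError("empty atom name")
    el = head[0].upper()
    if el not in ELEMENT_MASSES:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    return ELEMENT_MASSES[el]


@dataclass
class Trajectory:
    """Named-atom coordinates over frames with an orthorhombic box.

    Attributes
    ----------
    atom_names, resnames, molecule_ids, masses : arrays of length n_atoms
    coords : (n_frames, n_atoms, 3) array, Angstrom (wrapped)
    box : (n_frames, 3) array, Angstrom box lengths
    times_ps : (n_frames,) strictly increasing times in ps
    unwrapped : optional (n_frames, n_atoms, 3) array, Angstrom
    leaflet : optional per-atom array of +1 (upper) / -1 (lower)
    truth : generator ground truth for synthetic systems
    """

    atom_names: np.ndarray
    resnames: np.ndarray
    molecule_ids: np.ndarray
    masses: np.ndarray
    coords: np.ndarray
    box: np.ndarray
    times_ps: np.ndarray
    unwrapped: np.ndarray | None = None
    leaflet: np.ndarray | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        n_frames, n_atoms, _ = self.coords.shape
        for arr, label in [
            (self.atom_names, "atom_names"),
            (self.resnames, "resnames"),
            (self.molecule_ids, "molecule_ids"),
            (self.masses, "masses"),
        ]:
            if len(arr) != n_atoms:
                raise ValueError(f"{label} length != atom count")
        if self.box.shape != (n_frames, 3):
            raise ValueError("box must be (n_frames, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if self.times_ps.shape != (n_frames,):
            raise ValueError("times length != frame count")
        if n_frames > 1 and np.any(np.diff(self.times_ps) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(np.asarray(self.masses, dtype=float) <= 0):
            raise ValueError("masses must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_molecules(self) -> int:
        return len(np.unique(self.molecule_ids))

    def select(self, resname: str | None = None, name: str | None = None) -> np.ndarray:
        """Boolean atom mask by residue name and/or atom name."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if resname is not None:
            mask &= np.asarray(self.resnames) == resname
        if name is not None:
            mask &= np.asarray(self.atom_names) == name
        return mask

    def translated_z(self, dz_per_frame: np.ndarray) -> "Trajectory":
        """Return a copy with per-frame rigid z shifts applied."""
        dz = np.asarray(dz_per_frame, dtype=float).reshape(self.n_frames, 1)
        coords = self.coords.copy()
        coords[:, :, 2] += dz
        unwrapped = None
        if self.unwrapped is not None:
            unwrapped = self.unwrapped.copy()
            unwrapped[:, :, 2] += dz
        return Trajectory(
            self.atom_names, self.resnames, self.molecule_ids, self.masses,
            coords, self.box, self.times_ps, unwrapped=unwrapped,
            leaflet=None if self.leaflet is None else self.leaflet.copy(),
            truth=dict(self.truth),
        )


def _as_universe(traj: Trajectory):
    import MDAnalysis as mda

    n = traj.n_atoms
    mol_ids = np.asarray(traj.molecule_ids)
    # one residue per molecule, contiguous by construction
    uniq, res_index = np.unique(mol_ids, return_inverse=True)
    res_names = [
        str(np.asarray(traj.resnames)[mol_ids == m][0]) for m in uniq
    ]
    u = mda.Universe.empty(
        n, n_residues=len(uniq), atom_resindex=res_index,
        residue_segindex=np.zeros(len(uniq), dtype=int), trajectory=True,
    )
    u.add_TopologyAttr("names", [str(x) for x in traj.atom_names])
    u.add_TopologyAttr("resnames", res_names)
    u.add_TopologyAttr("resids", (uniq % 9999) + 1)
    u.add_TopologyAttr("masses", np.asarray(traj.masses, dtype=float))
    return u


def write_pdb(traj: Trajectory, path) -> None:
    """Write all frames as a multi-MODEL PDB with CRYST1 box records."""
    import MDAnalysis as mda

    u = _as_universe(traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True, n_atoms=traj.n_atoms) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.coords[i]
                u.dimensions = [*traj.box[i], 90.0, 90.0, 90.0]
                w.write(u.atoms)


def write_gro(traj: Trajectory, path, frame: int = 0) -> None:
    """Write one frame as a GRO snapshot."""
    import MDAnalysis as mda

    u = _as_universe(traj)
    u.atoms.positions = traj.coords[frame]
    u.dimensions = [*traj.box[frame], 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_atoms) as w:
            w.write(u.atoms)


def read_pdb(path, frame_dt_ps: float = 1000.0) -> Trajectory:
    """Read a multi-frame PDB into a :class:`Trajectory`.

    PDB stores no time axis, so frame times are synthesised at
    ``frame_dt_ps`` spacing (default 1 ns).
    """
    import MDAnalysis as mda

    # PDB writers commonly emit a single CRYST1 before the first MODEL, which
    # frame iteration does not always carry; collect the records ourselves.
    cryst: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                cryst.append(np.array([float(line[6:15]), float(line[15:24]),
                                       float(line[24:33])]))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        names = u.atoms.names.copy()
        resnames = u.atoms.resnames.copy()
        mol_ids = u.atoms.resindices.copy()
        try:
            masses = u.atoms.masses.copy()
            if np.any(masses <= 0):
                raise ValueError
        except Exception:
            masses = np.array([mass_from_name(nm) for nm in names])
        coords, boxes = [], []
        for fi, ts in enumerate(u.trajectory):
            coords.append(u.atoms.positions.astype(float).copy())
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                boxes.append(ts.dimensions[:3].astype(float).copy())
            elif len(cryst) == len(u.trajectory):
                boxes.append(cryst[fi])
            elif len(cryst) >= 1:
                boxes.append(cryst[0])
            else:
                raise ValueError(f"{path}: frame without box dimensions")
    coords_arr = np.array(coords)
    n_frames = coords_arr.shape[0]
    return Trajectory(
        atom_names=names, resnames=resnames, molecule_ids=mol_ids, masses=masses,
        coords=coords_arr, box=np.array(boxes),
        times_ps=np.arange(n_frames, dtype=float) * frame_dt_ps,
    )
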