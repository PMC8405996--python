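"""In-memory trajectory container and file loaders.

A :class:`Trajectory` is a topology (:class:`~allomif.structure.StructureModel`)
plus a ``(n_frames, n_atoms, 3)`` coordinate array in Å, in topology atom
order. Multi-model PDB is read with gemmi; DCD/XTC (with a separate topology
file) through MDAnalysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .errors import FormatError, ParameterError
from .structure import ATOM_COLUMNS, StructureModel, kabsch

import pandas as pd


@dataclass
class Trajectory:
    topology: StructureModel
    coords: np.ndarray  # (n_frames, n_atoms, 3) Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ParameterError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.topology):
            raise FormatError(
                f"frame atom count {self.coords.shape[1]} != topology "
                f"atom count {len(self.topology)}"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def window(self, start: int | None = None, stop: int | None = None) -> "Trajectory":
        """Frame slice ``[start:stop]`` as a view-backed Trajectory."""
        return Trajectory(self.topology, self.coords[slice(start, stop)])

    def last(self, n: int) -> "Trajectory":
        """The final ``n`` frames (the analysis-window convention)."""
        if n <= 0 or n > self.n_frames:
            raise ParameterError(f"window of {n} frames invalid for {self.n_frames}")
        return self.window(self.n_frames - n, None)


def load_multimodel_pdb(path: str | Path) -> Trajectory:
    """Read a multi-model PDB: model 1 is the topology, all models are frames."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise FormatError(f"{path} contains no models")
    frames = []
    topo_rows = None
    n_atoms = None
    for mi, model in enumerate(st):
        rows = []
        xyz = []
        for chain in model:
            for res in chain:
                for atom in res:
                    xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
                    if mi == 0:
                        rows.append(
                            (
                                chain.name, res.seqid.num, res.name, atom.name,
                                atom.element.name,
                                atom.altloc if atom.altloc != "\x00" else "",
                                atom.occ, atom.pos.x, atom.pos.y, atom.pos.z,
                            )
                        )
        if mi == 0:
            topo_rows = rows
            n_atoms = len(xyz)
        elif len(xyz) != n_atoms:
            raise FormatError(
                f"model {mi + 1} of {path} has {len(xyz)} atoms, expected {n_atoms}"
            )
        frames.append(xyz)
    topology = StructureModel(
        pd.DataFrame(topo_rows, columns=ATOM_COLUMNS), {"source": str(path)}
    )
    return Trajectory(topology, np.array(frames, float))


def load_trajectory(traj_path: str | Path, top_path: str | Path | None = None) -> Trajectory:
    """Load a trajectory file; dispatches on extension.

    Multi-model PDB needs no separate topology; DCD/XTC/TRR require
    ``top_path`` (PDB/PSF/GRO), read through MDAnalysis.
    """
    traj_path = Path(traj_path)
    if traj_path.suffix.lower() in (".pdb", ".ent") and top_path is None:
        return load_multimodel_pdb(traj_path)
    if top_path is None:
        raise ParameterError(f"{traj_path.suffix} trajectories need a topology file")
    import MDAnalysis as mda  # deferred: heavy import

    u = mda.Universe(str(top_path), str(traj_path))
    coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], float)
    rows = []
    for atom in u.atoms:
        rows.append(
            (
                atom.segid or getattr(atom, "chainID", "A") or "A",
                int(atom.resid),
                atom.resname,
                atom.name,
                getattr(atom, "element", "") or atom.name[0],
                "",
                1.0,
                0.0, 0.0, 0.0,
            )
        )
    df = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    df[["x", "y", "z"]] = coords[0]
    topology = StructureModel(df, {"source": str(traj_path)})
    return Trajectory(topology, coords)


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write frames as MODEL/ENDMDL records (text fixture format)."""
    from .structure import _to_gemmi

    path = Path(path)
    st = _to_gemmi(traj.topology, name=path.stem)
    base_model = st[0].clone()
    while len(st) > 0:
        del st[0]
    # gemmi groups residues by chain, which permutes the original atom order
    atoms = traj.topology.atoms
    chain_order = list(dict.fromkeys(atoms["chain"]))
    perm = np.concatenate(
        [np.flatnonzero((atoms["chain"] == c).to_numpy()) for c in chain_order]
    )
    for fi in range(traj.n_frames):
        m = base_model.clone()
        m.num = fi + 1
        k = 0
        for chain in m:
            for res in chain:
                for atom in res:
                    x, y, z = traj.coords[fi, perm[k]]
                    atom.pos = gemmi.Position(float(x), float(y), float(z))
                    k += 1
        st.add_model(m)
    st.write_pdb(str(path))


def align_frames(
    traj: Trajectory,
    selection_mask: np.ndarray | None = None,
    n_iter: int = 2,
) -> np.ndarray:
    """Least-squares align every frame onto the mean structure.

    The reference is the running mean over frames (initialized at frame 0),
    refined ``n_iter`` times; alignment uses the selected atoms (default Cα)
    but the returned array contains all atoms, aligned. Removes global
    rigid-body motion so residual coordinates are internal fluctuations.
    """
    if selection_mask is None:
        selection_mask = traj.topology.ca_mask()
        if not selection_mask.any():
            selection_mask = np.ones(len(traj.topology), bool)
    sel = np.asarray(selection_mask, bool)
    if not sel.any():
        raise ParameterError("alignment selection is empty")
    coords = traj.coords.copy()
    reference = coords[0, sel]
    for _ in range(n_iter):
        for fi in range(coords.shape[0]):
            R, t, _ = kabsch(coords[fi, sel], reference)
            coords[fi] = coords[fi] @ R.T + t
        reference = coords[:, sel].mean(axis=0)
    return coords
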