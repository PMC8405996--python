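"""Crystal-structure comparison: reading models, Kabsch superposition,
post-superposition displacements, distances and ligand contact shells.

Structures are held as a flat atom table (:class:`StructureModel`), which is
sufficient for the comparison metrics used on MIF-family trimers: Cα RMSD
between variant and wild-type trimers, displacement of the N-terminal
nitrogen after superposition, Pro1-to-tartrate hydrogen-bond distances and
the set of residues contacting a bound ligand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import (
    FormatError,
    GeometryError,
    InsufficientPairingError,
    MissingAtomError,
    ParameterError,
)

WATER_RESNAMES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "DOD"}

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

ATOM_COLUMNS = [
    "chain", "resnum", "resname", "atom", "element", "altloc", "occupancy",
    "x", "y", "z",
]

#: atom key = (chain id, residue number, atom name)
AtomKey = tuple[str, int, str]


@dataclass
class StructureModel:
    """Labeled atom set of a crystal structure or trajectory topology.

    ``atoms`` is a DataFrame with columns ``chain, resnum, resname, atom,
    element, altloc, occupancy, x, y, z`` — one row per atom after the
    alternate-location policy has been applied.
    """

    atoms: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise FormatError(f"atom table lacks columns {missing}")
        coords = self.atoms[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise FormatError("non-finite atom coordinates")

    # -- basic accessors -------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(float)

    def __len__(self) -> int:
        return len(self.atoms)

    def atom_coord(self, key: AtomKey) -> np.ndarray:
        """Coordinate of the atom with key ``(chain, resnum, atom name)``."""
        chain, resnum, name = key
        sel = self.atoms[
            (self.atoms["chain"] == chain)
            & (self.atoms["resnum"] == int(resnum))
            & (self.atoms["atom"] == name)
        ]
        if sel.empty:
            raise MissingAtomError(f"atom {chain}:{resnum}:{name} not found")
        return sel[["x", "y", "z"]].to_numpy(float)[0]

    def select(self, predicate: Callable[[pd.Series], bool]) -> pd.DataFrame:
        mask = self.atoms.apply(predicate, axis=1)
        return self.atoms[mask]

    def ca_mask(self) -> np.ndarray:
        a = self.atoms
        return ((a["atom"] == "CA") & a["resname"].isin(STANDARD_AMINO_ACIDS)).to_numpy()

    def heavy_mask(self) -> np.ndarray:
        return (self.atoms["element"].str.upper() != "H").to_numpy()

    def is_water(self) -> np.ndarray:
        return self.atoms["resname"].isin(WATER_RESNAMES).to_numpy()

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Copy with coordinates mapped through ``x -> R x + t``."""
        new = self.atoms.copy()
        xyz = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        new[["x", "y", "z"]] = xyz
        return StructureModel(new, dict(self.metadata))


def model_from_arrays(
    coords: np.ndarray,
    chains: Sequence[str] | None = None,
    resnums: Sequence[int] | None = None,
    resnames: Sequence[str] | None = None,
    atom_names: Sequence[str] | None = None,
    elements: Sequence[str] | None = None,
    label: str = "synthetic",
) -> StructureModel:
    """Build a StructureModel from bare arrays (synthetic fixtures)."""
    coords = np.asarray(coords, float)
    n = len(coords)
    df = pd.DataFrame(
        {
            "chain": list(chains) if chains is not None else ["A"] * n,
            "resnum": list(resnums) if resnums is not None else list(range(1, n + 1)),
            "resname": list(resnames) if resnames is not None else ["GLY"] * n,
            "atom": list(atom_names) if atom_names is not None else ["CA"] * n,
            "element": list(elements) if elements is not None else ["C"] * n,
            "altloc": [""] * n,
            "occupancy": [1.0] * n,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
        }
    )
    return StructureModel(df, {"source": label})


# ---------------------------------------------------------------------------
# reading / writing

def _apply_altloc_policy(df: pd.DataFrame, policy: str) -> pd.DataFrame:
    if policy not in ("highest-occupancy", "first", "all"):
        raise ParameterError(f"unknown altloc policy {policy!r}")
    if policy == "all" or (df["altloc"] == "").all():
        return df
    if policy == "first":
        return df.drop_duplicates(subset=["chain", "resnum", "atom"], keep="first")
    # highest occupancy, ties broken by altloc letter (blank sorts first, then 'A')
    order = df.sort_values(
        by=["occupancy", "altloc"], ascending=[False, True], kind="stable"
    )
    order = order.drop_duplicates(subset=["chain", "resnum", "atom"], keep="first")
    return order.sort_index()


def read_structure(
    path: str | Path,
    altloc_policy: str = "highest-occupancy",
    model_index: int = 0,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    All ATOM/HETATM records are retained (waters and ligands included) so
    that e.g. tartrate is addressable by residue name. ``altloc_policy``
    selects among alternate locations: ``highest-occupancy`` (default,
    ties broken toward altloc 'A'), ``first`` or ``all``.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path} contains no models")
    st.setup_entities()
    model = st[model_index]
    rows = []
    for chain in model:
        for res in chain:
            for atom in res:
                rows.append(
                    (
                        chain.name,
                        res.seqid.num,
                        res.name,
                        atom.name,
                        atom.element.name,
                        atom.altloc if atom.altloc != "\x00" else "",
                        atom.occ,
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                    )
                )
    if not rows:
        raise FormatError(f"{path} contains no atoms with coordinates")
    df = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    df = _apply_altloc_policy(df, altloc_policy).reset_index(drop=True)
    return StructureModel(df, {"source": str(path), "name": st.name})


def _to_gemmi(model: StructureModel, name: str = "model") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for row in model.atoms.itertuples(index=False):
        ch = chains.get(row.chain)
        if ch is None:
            ch = gemmi.Chain(row.chain)
            chains[row.chain] = ch
        if len(ch) == 0 or ch[-1].seqid.num != int(row.resnum) or ch[-1].name != row.resname:
            res = gemmi.Residue()
            res.name = row.resname
            res.seqid = gemmi.SeqId(int(row.resnum), " ")
            if row.resname in WATER_RESNAMES or row.resname not in STANDARD_AMINO_ACIDS:
                res.het_flag = "H"
            else:
                res.het_flag = "A"
            ch.add_residue(res)
        res = ch[-1]
        at = gemmi.Atom()
        at.name = row.atom
        at.element = gemmi.Element(row.element)
        at.occ = float(row.occupancy)
        at.altloc = row.altloc if row.altloc else "\x00"
        at.pos = gemmi.Position(float(row.x), float(row.y), float(row.z))
        res.add_atom(at)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as PDB (``.pdb``) or mmCIF (``.cif``/``.mmcif``)."""
    path = Path(path)
    st = _to_gemmi(model, name=path.stem)
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# superposition

@dataclass
class SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    ``rotation``/``translation`` map mobile coordinates as ``R x + t``;
    ``rmsd`` is the minimized RMSD over the paired atoms.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms_used: int
    atom_pairing: list[tuple[AtomKey, AtomKey]]

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "rmsd": self.rmsd,
            "n_atoms_used": self.n_atoms_used,
        }


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid motion (SVD form) minimizing RMSD of paired points.

    Returns ``(R, t, rmsd)`` with ``reference ≈ R @ mobile + t``; ``R`` is a
    proper rotation (det +1).
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ParameterError("paired coordinate arrays must both be (n, 3)")
    n = len(P)
    if n < 3:
        raise InsufficientPairingError(f"need >= 3 paired atoms, got {n}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinearity check: rank of the centered set
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise GeometryError("mobile atom set is collinear; rotation underdetermined")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return R, t, rmsd


_SELECTIONS = {
    "ca": lambda m: m.ca_mask(),
    "heavy": lambda m: m.heavy_mask() & ~m.is_water(),
    "all": lambda m: np.ones(len(m), bool),
}


def _selection_mask(model: StructureModel, selection) -> np.ndarray:
    if callable(selection):
        return model.atoms.apply(selection, axis=1).to_numpy(bool)
    try:
        return _SELECTIONS[selection](model)
    except KeyError:
        raise ParameterError(
            f"unknown selection {selection!r}; use 'ca', 'heavy', 'all' or a predicate"
        ) from None


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    selection: str | Callable = "ca",
    chain_map: Mapping[str, str] | None = None,
) -> SuperpositionResult:
    """Kabsch superposition of ``mobile`` onto ``reference``.

    Atoms are paired by ``(mapped chain, residue number, atom name)`` after
    applying ``chain_map`` (mobile chain -> reference chain; identity by
    default). Hydrogens never enter the pairing. ``mobile`` is not modified.
    """
    chain_map = dict(chain_map) if chain_map else {}
    mob = mobile.atoms[_selection_mask(mobile, selection) & mobile.heavy_mask()]
    ref = reference.atoms[_selection_mask(reference, selection) & reference.heavy_mask()]
    ref_index = {
        (r.chain, int(r.resnum), r.atom): np.array([r.x, r.y, r.z])
        for r in ref.itertuples(index=False)
    }
    pairs: list[tuple[AtomKey, AtomKey]] = []
    P, Q = [], []
    for r in mob.itertuples(index=False):
        key_m: AtomKey = (r.chain, int(r.resnum), r.atom)
        key_r: AtomKey = (chain_map.get(r.chain, r.chain), int(r.resnum), r.atom)
        q = ref_index.get(key_r)
        if q is None:
            continue
        pairs.append((key_m, key_r))
        P.append([r.x, r.y, r.z])
        Q.append(q)
    if len(pairs) < 3:
        raise InsufficientPairingError(
            f"only {len(pairs)} atom pairs under selection; need >= 3"
        )
    R, t, rmsd = kabsch(np.array(P), np.array(Q))
    return SuperpositionResult(R, t, rmsd, len(pairs), pairs)


def superpose_best_chain_permutation(
    mobile: StructureModel,
    reference: StructureModel,
    chains: Sequence[str] = ("A", "B", "C"),
    selection: str | Callable = "ca",
) -> tuple[SuperpositionResult, dict]:
    """Search cyclic/anticyclic chain permutations, return the lowest RMSD.

    Guards against re-deposited trimers whose chains were renamed.
    """
    from itertools import permutations

    best: tuple[SuperpositionResult, dict] | None = None
    for perm in permutations(chains):
        cmap = dict(zip(chains, perm))
        try:
            res = superpose(mobile, reference, selection=selection, chain_map=cmap)
        except InsufficientPairingError:
            continue
        if best is None or res.rmsd < best[0].rmsd:
            best = (res, cmap)
    if best is None:
        raise InsufficientPairingError("no chain permutation yields >= 3 pairs")
    return best


def atom_displacement(
    mobile: StructureModel,
    reference: StructureModel,
    superposition: SuperpositionResult,
    key: AtomKey,
    reference_key: AtomKey | None = None,
) -> float:
    """Distance (Å) between a transformed mobile atom and the reference atom.

    The superposition is computed by the caller on whatever frame is
    appropriate (e.g. all trimer Cα); this measures how far a single atom —
    such as the N-terminal nitrogen — sits from its wild-type position
    after that global alignment.
    """
    a = superposition.apply(mobile.atom_coord(key))
    b = reference.atom_coord(reference_key if reference_key is not None else key)
    return float(np.linalg.norm(a - b))


def interatomic_distance(model: StructureModel, key_a: AtomKey, key_b: AtomKey) -> float:
    """Euclidean distance (Å) between two atoms of one model."""
    return float(np.linalg.norm(model.atom_coord(key_a) - model.atom_coord(key_b)))


def ligand_contacts(
    model: StructureModel,
    ligand_resname: str,
    cutoff: float = 4.0,
    include_hydrogens: bool = False,
) -> set[tuple[str, int, str]]:
    """Protein residues with >= 1 atom within ``cutoff`` Å of the ligand.

    Returns a set of ``(chain, resnum, resname)``. Waters and other
    heteroatoms are excluded from the protein side; hydrogens are ignored
    unless requested. With ``cutoff == 0`` the set is empty by definition.
    """
    if cutoff < 0:
        raise ParameterError("cutoff must be >= 0")
    lig = model.atoms[model.atoms["resname"] == ligand_resname]
    if lig.empty:
        raise MissingAtomError(f"ligand residue {ligand_resname!r} not present")
    if cutoff == 0:
        return set()
    prot_mask = model.atoms["resname"].isin(STANDARD_AMINO_ACIDS)
    if not include_hydrogens:
        prot_mask &= model.atoms["element"].str.upper() != "H"
    prot = model.atoms[prot_mask]
    if prot.empty:
        return set()
    tree = cKDTree(prot[["x", "y", "z"]].to_numpy(float))
    hits: set[tuple[str, int, str]] = set()
    idx_lists = tree.query_ball_point(lig[["x", "y", "z"]].to_numpy(float), cutoff)
    flat = sorted({i for lst in idx_lists for i in lst})
    for i in flat:
        row = prot.iloc[i]
        hits.add((row["chain"], int(row["resnum"]), row["resname"]))
    return hits


def comparison_report(
    mobile: StructureModel,
    reference: StructureModel,
    selection: str = "ca",
    chain_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One-row-per-metric CSV-ready comparison table."""
    sup = superpose(mobile, reference, selection=selection, chain_map=chain_map)
    rows = [
        {"metric": "rmsd", "selection": selection, "value_A": sup.rmsd,
         "n_atoms_used": sup.n_atoms_used},
    ]
    return pd.DataFrame(rows)
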