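"""Geometric hydrogen-bond detection and per-frame bond frequencies.

A donor–hydrogen/acceptor triple is a hydrogen bond when the heavy-atom
donor–acceptor distance is at most 3.0 Å and the angle between the D→H and
D→A vectors is at most 30° (both configurable). The per-frame frequency for
a donor-residue/acceptor-residue pair is the mean number of satisfying
triples per frame over the analysis window: a mean *count* — with several
donor hydrogens it may exceed 1 — not an occupancy fraction.

Donor and acceptor roles are asymmetric: measuring Ser62→Phe2 is a
different quantity from Phe2→Ser62.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, MissingAtomError, ParameterError
from .structure import StructureModel
from .trajectory import Trajectory

ResidueId = tuple[str, int]

#: heavy atoms that can donate (with their hydrogen name prefixes) and accept,
#: for protein backbone/side chains and water. Data, not code: pass a custom
#: table to override.
DONOR_TABLE: dict[str, dict[str, tuple[str, ...]]] = {
    "_backbone": {"N": ("H", "HN", "H1", "H2", "H3")},
    "SER": {"OG": ("HG",)},
    "THR": {"OG1": ("HG1",)},
    "TYR": {"OH": ("HH",)},
    "CYS": {"SG": ("HG",)},
    "TRP": {"NE1": ("HE1",)},
    "HIS": {"ND1": ("HD1",), "NE2": ("HE2",)},
    "LYS": {"NZ": ("HZ1", "HZ2", "HZ3")},
    "ARG": {"NE": ("HE",), "NH1": ("HH11", "HH12"), "NH2": ("HH21", "HH22")},
    "ASN": {"ND2": ("HD21", "HD22")},
    "GLN": {"NE2": ("HE21", "HE22")},
    "HOH": {"O": ("H1", "H2")},
}

ACCEPTOR_TABLE: dict[str, tuple[str, ...]] = {
    "_backbone": ("O", "OXT"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
    "CYS": ("SG",),
    "HOH": ("O",),
}


@dataclass
class HBondCriteria:
    """Geometric criteria: D–A distance cutoff and donor-angle cutoff."""

    max_distance: float = 3.0   # Å, donor heavy atom to acceptor heavy atom
    max_angle: float = 30.0     # degrees
    angle_convention: str = "donor"  # 'donor': ∠(D→H, D→A); 'hydrogen': 180−∠(D–H–A)

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ParameterError("max_distance must be > 0")
        if not (0 < self.max_angle <= 180):
            raise ParameterError("max_angle must be in (0, 180]")
        if self.angle_convention not in ("donor", "hydrogen"):
            raise ParameterError(f"unknown angle convention {self.angle_convention!r}")


def hbond_present(
    donor: np.ndarray,
    hydrogen: np.ndarray,
    acceptor: np.ndarray,
    criteria: HBondCriteria | None = None,
) -> bool:
    """Evaluate the geometric hydrogen-bond predicate for one triple."""
    criteria = criteria or HBondCriteria()
    d = np.asarray(donor, float)
    h = np.asarray(hydrogen, float)
    a = np.asarray(acceptor, float)
    da = a - d
    dist = float(np.linalg.norm(da))
    if dist < 1e-9:
        raise GeometryError("donor and acceptor coincide")
    if np.linalg.norm(h - d) >= 1.5:
        warnings.warn(
            "donor-hydrogen distance >= 1.5 Å: not covalently plausible",
            RuntimeWarning,
            stacklevel=2,
        )
    if dist > criteria.max_distance:
        return False
    dh = h - d
    if criteria.angle_convention == "donor":
        v1, v2 = dh, da
    else:  # deviation of D–H–A from linearity, measured at the hydrogen
        v1, v2 = d - h, a - h
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if criteria.angle_convention == "hydrogen":
        ang = 180.0 - ang
    return bool(ang <= criteria.max_angle)


@dataclass
class PairFrequency:
    """Mean hydrogen-bond count per frame for one donor→acceptor residue pair."""

    donor: ResidueId
    acceptor: ResidueId
    bonds_per_frame: float
    per_frame: np.ndarray
    n_frames: int


def _residue_atoms(topology: StructureModel, rid: ResidueId):
    a = topology.atoms
    sel = a[(a["chain"] == rid[0]) & (a["resnum"] == int(rid[1]))]
    if sel.empty:
        raise MissingAtomError(f"residue {rid[0]}:{rid[1]} not in topology")
    return sel


def resolve_donor_groups(
    topology: StructureModel,
    rid: ResidueId,
    donor_table: dict | None = None,
) -> list[tuple[int, int]]:
    """(donor heavy atom index, hydrogen index) pairs for a residue.

    Donor heavy atoms come from the chemistry table (backbone amide plus
    side-chain entries for the residue type); hydrogens are matched by name.
    """
    table = donor_table or DONOR_TABLE
    res = _residue_atoms(topology, rid)
    resname = res["resname"].iloc[0]
    entries: dict[str, tuple[str, ...]] = {}
    entries.update(table.get("_backbone", {}) if resname != "HOH" else {})
    entries.update(table.get(resname, {}))
    name_to_idx = {r.atom: i for i, r in zip(res.index, res.itertuples(index=False))}
    groups = []
    for heavy, hydrogens in entries.items():
        hi = name_to_idx.get(heavy)
        if hi is None:
            continue
        for hname in hydrogens:
            hh = name_to_idx.get(hname)
            if hh is not None:
                groups.append((int(hi), int(hh)))
    return groups


def resolve_acceptors(
    topology: StructureModel,
    rid: ResidueId,
    acceptor_table: dict | None = None,
) -> list[int]:
    """Acceptor heavy-atom indices for a residue."""
    table = acceptor_table or ACCEPTOR_TABLE
    res = _residue_atoms(topology, rid)
    resname = res["resname"].iloc[0]
    names = tuple(table.get("_backbone", ()) if resname != "HOH" else ())
    names += tuple(table.get(resname, ()))
    return [
        int(i)
        for i, r in zip(res.index, res.itertuples(index=False))
        if r.atom in names
    ]


def pair_frequency(
    traj: Trajectory,
    donor: ResidueId,
    acceptor: ResidueId,
    criteria: HBondCriteria | None = None,
    window: tuple[int | None, int | None] | None = None,
    donor_table: dict | None = None,
    acceptor_table: dict | None = None,
) -> PairFrequency:
    """Mean per-frame hydrogen-bond count between a donor and acceptor residue."""
    criteria = criteria or HBondCriteria()
    if window is not None:
        traj = traj.window(*window)
    groups = resolve_donor_groups(traj.topology, donor, donor_table)
    acceptors = resolve_acceptors(traj.topology, acceptor, acceptor_table)
    if not groups:
        raise MissingAtomError(
            f"no donor heavy-atom/hydrogen pairs resolved for {donor[0]}:{donor[1]}"
        )
    if not acceptors:
        raise MissingAtomError(
            f"no acceptor atoms resolved for {acceptor[0]}:{acceptor[1]}"
        )
    counts = np.zeros(traj.n_frames, int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for fi in range(traj.n_frames):
            frame = traj.coords[fi]
            c = 0
            for di, hi in groups:
                for ai in acceptors:
                    if ai == di:
                        continue
                    if hbond_present(frame[di], frame[hi], frame[ai], criteria):
                        c += 1
            counts[fi] = c
    mean = float(counts.mean()) if counts.size else 0.0
    return PairFrequency(donor, acceptor, mean, counts, int(counts.size))
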