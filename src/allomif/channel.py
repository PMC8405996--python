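"""Solvent-channel hydration analysis for trimeric MIF-family proteins.

The central channel of the trimer is bounded by two "gates": three
symmetry-related gating residues at the active-site face (Tyr99 in MIF,
Phe100 in MIF-2) and three at the opposite mouth (Val42 / Arg42). Each gate
is the triangle of the three Cα atoms. A water belongs to the channel when
its projection onto the channel axis — the line through the two gate-triangle
centroids — falls between the centroids, and (in the default cylinder mode)
its distance from the axis does not exceed the larger gate circumradius plus
a radial margin.

Persistently occupied hydration sites are isolated with a Gaussian-kernel
occupancy grid: every water-oxygen observation across frames deposits a 3D
Gaussian on a voxel grid, and voxels above ``mean + σ_level·sd`` of the
nonzero-voxel density mark the stable sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, MissingAtomError, ParameterError
from .structure import StructureModel
from .trajectory import Trajectory

ResidueId = tuple[str, int]  # (chain, residue number)


@dataclass
class ChannelDefinition:
    """Gating residues and geometric limits for channel-water counting."""

    upper_gate: tuple[ResidueId, ResidueId, ResidueId]
    lower_gate: tuple[ResidueId, ResidueId, ResidueId]
    radial_margin: float = 2.0  # Å added to the larger gate circumradius
    mode: str = "cylinder"      # 'cylinder' or 'slab' (no radial bound)
    water_resnames: tuple[str, ...] = ("HOH", "WAT", "TIP3", "SOL")

    def __post_init__(self) -> None:
        if len(set(self.upper_gate)) != 3 or len(set(self.lower_gate)) != 3:
            raise ParameterError("each gate needs exactly 3 distinct residues")
        if set(self.upper_gate) & set(self.lower_gate):
            raise ParameterError("upper and lower gates must be disjoint")
        if self.radial_margin < 0:
            raise ParameterError("radial_margin must be >= 0")
        if self.mode not in ("cylinder", "slab"):
            raise ParameterError(f"unknown mode {self.mode!r}")


@dataclass
class ResolvedGates:
    """Gate Cα coordinates for a single frame."""

    upper: np.ndarray  # (3, 3) Å
    lower: np.ndarray  # (3, 3) Å

    def __post_init__(self) -> None:
        self.upper = np.asarray(self.upper, float)
        self.lower = np.asarray(self.lower, float)
        for name, tri in (("upper", self.upper), ("lower", self.lower)):
            if tri.shape != (3, 3):
                raise ParameterError(f"{name} gate must be three 3-vectors")
            circumradius(tri)  # raises GeometryError if degenerate

    @property
    def axis(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower centroid, upper centroid)."""
        return self.lower.mean(axis=0), self.upper.mean(axis=0)

    @property
    def max_circumradius(self) -> float:
        return max(circumradius(self.upper), circumradius(self.lower))


def circumradius(triangle: np.ndarray) -> float:
    """Circumradius of a 3D triangle; GeometryError if (near-)collinear."""
    p = np.asarray(triangle, float)
    a = np.linalg.norm(p[1] - p[2])
    b = np.linalg.norm(p[0] - p[2])
    c = np.linalg.norm(p[0] - p[1])
    area2 = np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))  # = 2*area
    if area2 < 1e-9:
        raise GeometryError("gate triangle is degenerate (collinear points)")
    return float(a * b * c / (2.0 * area2))


def channel_membership(
    water: np.ndarray,
    gates: ResolvedGates,
    radial_margin: float = 2.0,
    mode: str = "cylinder",
) -> bool:
    """True iff the water lies within the gated channel volume.

    Axial condition: the projection onto the centroid-to-centroid axis lies
    between the two centroids. Radial condition (cylinder mode): distance
    from the axis <= max gate circumradius + radial_margin.
    """
    w = np.asarray(water, float)
    c0, c1 = gates.axis
    axis = c1 - c0
    length = np.linalg.norm(axis)
    if length < 1e-9:
        raise GeometryError("gate centroids coincide; channel axis undefined")
    u = axis / length
    t = float(np.dot(w - c0, u))
    if t < 0.0 or t > length:
        return False
    if mode == "slab":
        return True
    radial = float(np.linalg.norm((w - c0) - t * u))
    return radial <= gates.max_circumradius + radial_margin


@dataclass
class WaterCount:
    """Per-frame channel-water counts and their window mean."""

    per_frame: np.ndarray  # integer counts
    mean: float
    n_frames: int

    @classmethod
    def from_counts(cls, counts) -> "WaterCount":
        arr = np.asarray(counts, int)
        return cls(arr, float(arr.mean()) if arr.size else 0.0, int(arr.size))


def _resolve_gate_indices(topology: StructureModel, gate) -> list[int]:
    idx = []
    a = topology.atoms
    for chain, resnum in gate:
        sel = a.index[
            (a["chain"] == chain) & (a["resnum"] == int(resnum)) & (a["atom"] == "CA")
        ]
        if len(sel) == 0:
            raise MissingAtomError(f"gate residue {chain}:{resnum} has no CA atom")
        idx.append(int(sel[0]))
    return idx


def _water_oxygen_indices(topology: StructureModel, water_resnames) -> np.ndarray:
    a = topology.atoms
    mask = a["resname"].isin(water_resnames) & (
        a["element"].str.upper().eq("O") | a["atom"].str.startswith("O")
    )
    return np.flatnonzero(mask.to_numpy())


def count_channel_waters(
    traj: Trajectory,
    channel: ChannelDefinition,
    window: tuple[int | None, int | None] | None = None,
) -> WaterCount:
    """Channel-water count per frame and its mean over the analysis window.

    Waters are identified by residue name; the oxygen position represents
    the molecule. Emits a warning (and all-zero counts) when the topology
    holds no waters.
    """
    if window is not None:
        traj = traj.window(*window)
    up_idx = _resolve_gate_indices(traj.topology, channel.upper_gate)
    lo_idx = _resolve_gate_indices(traj.topology, channel.lower_gate)
    wat_idx = _water_oxygen_indices(traj.topology, channel.water_resnames)
    if wat_idx.size == 0:
        warnings.warn("topology contains no water residues; counts are zero",
                      RuntimeWarning, stacklevel=2)
        return WaterCount.from_counts(np.zeros(traj.n_frames, int))
    counts = np.zeros(traj.n_frames, int)
    for fi in range(traj.n_frames):
        frame = traj.coords[fi]
        gates = ResolvedGates(frame[up_idx], frame[lo_idx])
        counts[fi] = sum(
            channel_membership(frame[wi], gates, channel.radial_margin, channel.mode)
            for wi in wat_idx
        )
    return WaterCount.from_counts(counts)


def collect_channel_waters(
    traj: Trajectory,
    channel: ChannelDefinition,
    window: tuple[int | None, int | None] | None = None,
) -> np.ndarray:
    """All in-channel water-oxygen observations pooled across frames, (n, 3)."""
    if window is not None:
        traj = traj.window(*window)
    up_idx = _resolve_gate_indices(traj.topology, channel.upper_gate)
    lo_idx = _resolve_gate_indices(traj.topology, channel.lower_gate)
    wat_idx = _water_oxygen_indices(traj.topology, channel.water_resnames)
    obs = []
    for fi in range(traj.n_frames):
        frame = traj.coords[fi]
        gates = ResolvedGates(frame[up_idx], frame[lo_idx])
        for wi in wat_idx:
            if channel_membership(frame[wi], gates, channel.radial_margin, channel.mode):
                obs.append(frame[wi])
    return np.array(obs, float).reshape(-1, 3)


def gate_aperture(mean_coords: np.ndarray, topology: StructureModel, gate) -> float:
    """Mean pairwise distance among time-averaged gate Cα positions (Å)."""
    idx = _resolve_gate_indices(topology, gate)
    p = np.asarray(mean_coords, float)[idx]
    d = [np.linalg.norm(p[i] - p[j]) for i in range(3) for j in range(i + 1, 3)]
    return float(np.mean(d))


def channel_expansion(
    traj_a: Trajectory,
    traj_b: Trajectory,
    gate_a,
    gate_b=None,
) -> float:
    """Signed gate-aperture change between two trajectories (Å).

    The aperture of a trajectory is the mean of the three pairwise distances
    among the time-averaged gate Cα positions; the expansion is
    ``aperture(b) - aperture(a)`` (positive = channel mouth wider in b).
    Distances only — invariant to any rigid motion of either trajectory.
    """
    gate_b = gate_b if gate_b is not None else gate_a
    ap_a = gate_aperture(traj_a.coords.mean(axis=0), traj_a.topology, gate_a)
    ap_b = gate_aperture(traj_b.coords.mean(axis=0), traj_b.topology, gate_b)
    return ap_b - ap_a


# ---------------------------------------------------------------------------
# occupancy density grid

@dataclass
class OccupancyGrid:
    """Gaussian-kernel water-occupancy density on a regular voxel grid."""

    origin: np.ndarray       # Å, corner of voxel (0,0,0)
    spacing: float           # Å
    density: np.ndarray      # (nx, ny, nz), >= 0
    kernel_width: float      # Å (Gaussian sigma)
    n_observations: int
    metadata: dict = field(default_factory=dict)

    def total_mass(self) -> float:
        return float(self.density.sum() * self.spacing**3)

    def threshold_mask(self, sigma_level: float) -> np.ndarray:
        """Voxels with density >= mean + sigma_level·sd of nonzero voxels."""
        nz = self.density[self.density > 0]
        if nz.size == 0:
            return np.zeros_like(self.density, bool)
        cut = nz.mean() + sigma_level * nz.std()
        return self.density >= cut

    def threshold_voxel_centers(self, sigma_level: float) -> np.ndarray:
        """Coordinates (Å) of surviving voxel centers at the σ level."""
        mask = self.threshold_mask(sigma_level)
        ijk = np.argwhere(mask)
        return self.origin + (ijk + 0.5) * self.spacing

    def argmax_center(self) -> np.ndarray:
        ijk = np.unravel_index(np.argmax(self.density), self.density.shape)
        return self.origin + (np.array(ijk) + 0.5) * self.spacing


def build_occupancy_grid(
    observations: np.ndarray,
    spacing: float = 0.5,
    kernel_width: float = 1.0,
    padding: float | None = None,
) -> OccupancyGrid:
    """Deposit each water observation as a 3D Gaussian onto a voxel grid.

    ``kernel_width`` is the Gaussian σ in Å; each kernel integrates to 1, so
    the total grid mass equals the number of observations for grids that
    fully contain every kernel (padding defaults to 4σ to ensure that).
    """
    obs = np.asarray(observations, float).reshape(-1, 3)
    if obs.shape[0] < 1:
        raise ParameterError("need at least one water observation")
    if spacing <= 0:
        raise ParameterError("voxel spacing must be > 0")
    if kernel_width <= 0:
        raise ParameterError("kernel width must be > 0")
    pad = 4.0 * kernel_width if padding is None else padding
    lo = obs.min(axis=0) - pad
    hi = obs.max(axis=0) + pad
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    density = np.zeros(tuple(shape))
    axes = [lo[d] + (np.arange(shape[d]) + 0.5) * spacing for d in range(3)]
    reach = int(np.ceil(4.0 * kernel_width / spacing))
    norm = (2.0 * np.pi * kernel_width**2) ** -1.5
    for p in obs:
        ijk = np.floor((p - lo) / spacing).astype(int)
        sl = [
            slice(max(ijk[d] - reach, 0), min(ijk[d] + reach + 1, shape[d]))
            for d in range(3)
        ]
        dx = axes[0][sl[0]] - p[0]
        dy = axes[1][sl[1]] - p[1]
        dz = axes[2][sl[2]] - p[2]
        kern = np.exp(
            -(dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2)
            / (2.0 * kernel_width**2)
        )
        density[tuple(sl)] += norm * kern
    return OccupancyGrid(
        origin=lo,
        spacing=spacing,
        density=density,
        kernel_width=kernel_width,
        n_observations=obs.shape[0],
        metadata={
            "radial_bound": "cylinder membership applied upstream",
            "position_atom": "water oxygen",
        },
    )
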