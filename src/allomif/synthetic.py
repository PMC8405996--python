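"""Synthetic inputs with known ground truth for every pipeline stage.

Nothing here has force-field realism; each generator encodes exactly the
statistical structure the corresponding analysis stage measures:

* correlated Gaussian per-residue displacement series with a known pairwise
  correlation matrix (ground truth for mutual information via the Gaussian
  closed form I = -(3/2)·ln(1-ρ²), hence generalized correlation |ρ|);
* single-exponential peak-height decays with known rate, replicate delays
  and additive Gaussian intensity noise;
* water coordinates planted inside/outside a gated channel, constructed
  (and verified) against the channel-membership predicate itself;
* donor–hydrogen–acceptor geometries with prescribed distance/angle;
* rigid-body transformed and optionally perturbed coordinate pairs for
  superposition tests.

All randomness flows from the explicit ``seed`` of each spec; equal specs
and seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channel import ResolvedGates, channel_membership, circumradius
from .correlation import DisplacementSeries
from .errors import GeometryError, ParameterError
from .structure import StructureModel, model_from_arrays
from .trajectory import Trajectory


def gaussian_mutual_information(rho: float) -> float:
    """Closed-form MI (nats) of two 3D Gaussians with isotropic component ρ.

    Each Cartesian component pair contributes -(1/2)ln(1-ρ²), so the
    3-vector pair carries I = -(3/2)·ln(1-ρ²); the corresponding
    generalized correlation is exactly |ρ|.
    """
    if not -1.0 < rho < 1.0:
        raise ParameterError("rho must be in (-1, 1) for finite MI")
    return float(-1.5 * np.log1p(-rho * rho))


def gaussian_generalized_correlation(rho: float) -> float:
    """Ground-truth generalized correlation for isotropic component ρ: |ρ|."""
    return abs(float(rho))


# ---------------------------------------------------------------------------
# correlated displacement trajectories

@dataclass
class CorrelatedTrajectorySpec:
    """Gaussian displacement series with prescribed inter-residue correlation.

    ``correlation`` is the (n_residues × n_residues) per-component Pearson
    matrix, applied identically and independently to the x, y, z components
    (isotropy) — the regime where the generalized correlation equals |ρ|
    exactly.
    """

    n_frames: int
    n_residues: int
    correlation: np.ndarray | None = None  # default: identity
    per_component_sd: float = 1.0          # Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2 or self.n_residues < 1:
            raise ParameterError("need n_frames >= 2 and n_residues >= 1")
        if self.per_component_sd <= 0:
            raise ParameterError("per_component_sd must be > 0")
        if self.correlation is None:
            self.correlation = np.eye(self.n_residues)
        self.correlation = np.asarray(self.correlation, float)
        c = self.correlation
        if c.shape != (self.n_residues, self.n_residues):
            raise ParameterError("correlation matrix shape mismatch")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ParameterError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-10):
            raise ParameterError("correlation matrix must have unit diagonal")


def correlation_pair_matrix(n_residues: int, i: int, j: int, rho: float) -> np.ndarray:
    """Identity correlation with a single planted ρ between residues i and j."""
    c = np.eye(n_residues)
    c[i, j] = c[j, i] = rho
    return c


def _psd_factor(c: np.ndarray) -> np.ndarray:
    """Matrix square root of a PSD correlation matrix (eigendecomposition)."""
    w, v = np.linalg.eigh(c)
    if w.min() < -1e-8:
        raise ParameterError(
            f"correlation matrix is not positive semidefinite "
            f"(min eigenvalue {w.min():.3g})"
        )
    return v * np.sqrt(np.clip(w, 0.0, None))


def generate_correlated_trajectory(spec: CorrelatedTrajectorySpec) -> DisplacementSeries:
    """Draw displacement samples with the spec's correlation structure.

    Each Cartesian component is an independent draw from N(0, C) scaled by
    ``per_component_sd``, where C is the spec correlation matrix — so the
    empirical per-component Pearson correlation between any two residues
    converges to the planted ρ.
    """
    L = _psd_factor(spec.correlation)
    rng = np.random.default_rng(spec.seed)
    samples = np.empty((spec.n_frames, spec.n_residues, 3))
    for axis in range(3):
        z = rng.standard_normal((spec.n_frames, spec.n_residues))
        samples[:, :, axis] = spec.per_component_sd * (z @ L.T)
    labels = [("A", i + 1) for i in range(spec.n_residues)]
    return DisplacementSeries(labels, samples)


# ---------------------------------------------------------------------------
# exponential decay curves

@dataclass
class DecayCurveSpec:
    """Single-exponential peak-height decays with replicate measurements."""

    true_rate: float                     # s⁻¹
    initial_intensity: float = 100.0     # arbitrary units
    delays: np.ndarray = field(default_factory=lambda: np.array([]))
    replicate_delays: np.ndarray = field(default_factory=lambda: np.array([]))
    noise_sd: float = 0.0                # fraction of initial intensity
    seed: int = 0

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, float)
        self.replicate_delays = np.asarray(self.replicate_delays, float)
        if self.delays.size == 0:
            raise ParameterError("delay schedule must be non-empty")
        if np.any(self.delays < 0):
            raise ParameterError("delays must be non-negative")
        if not set(np.round(self.replicate_delays, 12)) <= set(np.round(self.delays, 12)):
            raise ParameterError("replicate_delays must be a subset of delays")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def generate_decay_curves(spec: DecayCurveSpec, n_residues: int = 1) -> pd.DataFrame:
    """Per-residue intensity tables over the delay schedule.

    Returns a long-form DataFrame (residue, delay_s, intensity,
    replicate_id); replicate delays appear twice (replicate_id 0 and 1).
    Noise is additive Gaussian on intensity with sd = noise_sd·I0, the error
    model implied by least-squares exponential fitting of peak heights.
    With noise_sd = 0 the table reproduces I0·exp(-R·t) exactly.
    """
    if n_residues < 1:
        raise ParameterError("n_residues must be >= 1")
    rng = np.random.default_rng(spec.seed)
    rep = set(np.round(spec.replicate_delays, 12))
    rows = []
    for residue in range(1, n_residues + 1):
        for t in spec.delays:
            n_meas = 2 if np.round(t, 12) in rep else 1
            for rid in range(n_meas):
                clean = spec.initial_intensity * np.exp(-spec.true_rate * t)
                noise = (
                    rng.normal(0.0, spec.noise_sd * spec.initial_intensity)
                    if spec.noise_sd > 0
                    else 0.0
                )
                rows.append(
                    {
                        "residue": residue,
                        "delay_s": float(t),
                        "intensity": clean + noise,
                        "replicate_id": rid,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# channel frames with planted waters

@dataclass
class ChannelFrameSpec:
    """One frame of gate Cα positions plus planted in/out channel waters."""

    gate_upper_positions: np.ndarray  # (3, 3) Å
    gate_lower_positions: np.ndarray  # (3, 3) Å
    planted_inside: int = 5
    planted_outside: int = 3
    radial_margin: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.gate_upper_positions = np.asarray(self.gate_upper_positions, float)
        self.gate_lower_positions = np.asarray(self.gate_lower_positions, float)
        for tri in (self.gate_upper_positions, self.gate_lower_positions):
            if tri.shape != (3, 3):
                raise ParameterError("gate positions must be three 3-vectors")
            circumradius(tri)  # GeometryError if collinear
        if self.planted_inside < 0 or self.planted_outside < 0:
            raise ParameterError("planted counts must be >= 0")


def default_gate_geometry(
    aperture: float = 10.0, separation: float = 15.0
) -> tuple[np.ndarray, np.ndarray]:
    """Two parallel equilateral gate triangles of side ``aperture``,
    ``separation`` Å apart along z — an idealized trimer channel."""
    r = aperture / np.sqrt(3.0)  # circumradius of an equilateral triangle
    ang = np.radians([90.0, 210.0, 330.0])
    ring = np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros(3)], axis=1)
    upper = ring + np.array([0.0, 0.0, separation])
    return upper, ring.copy()


@dataclass
class ChannelFrame:
    waters: np.ndarray         # (n, 3) planted inside then outside
    inside_mask: np.ndarray    # bool per water
    gates: ResolvedGates
    radial_margin: float


def generate_channel_frame(spec: ChannelFrameSpec) -> ChannelFrame:
    """Plant waters that provably satisfy / violate channel membership.

    Inside waters are rejection-sampled within the gated cylinder and each
    is verified against :func:`allomif.channel.channel_membership`; outside
    waters are placed beyond the gate planes or outside the radial bound
    and verified to fail the predicate.
    """
    gates = ResolvedGates(spec.gate_upper_positions, spec.gate_lower_positions)
    rng = np.random.default_rng(spec.seed)
    c0, c1 = gates.axis
    axis = c1 - c0
    length = float(np.linalg.norm(axis))
    u = axis / length
    # orthonormal frame around the axis
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(tmp, u)) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, tmp)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    rmax = gates.max_circumradius + spec.radial_margin

    inside = []
    while len(inside) < spec.planted_inside:
        t = rng.uniform(0.05, 0.95) * length
        rad = rng.uniform(0.0, 0.9 * rmax)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        w = c0 + t * u + rad * (np.cos(phi) * e1 + np.sin(phi) * e2)
        if channel_membership(w, gates, spec.radial_margin):
            inside.append(w)
    outside = []
    while len(outside) < spec.planted_outside:
        kind = rng.integers(0, 3)
        if kind == 0:      # beyond the upper gate plane
            t = length + rng.uniform(1.0, 10.0)
            rad = rng.uniform(0.0, rmax)
        elif kind == 1:    # beyond the lower gate plane
            t = -rng.uniform(1.0, 10.0)
            rad = rng.uniform(0.0, rmax)
        else:              # between gates, outside the radial bound
            t = rng.uniform(0.05, 0.95) * length
            rad = rmax + rng.uniform(0.5, 10.0)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        w = c0 + t * u + rad * (np.cos(phi) * e1 + np.sin(phi) * e2)
        if not channel_membership(w, gates, spec.radial_margin):
            outside.append(w)
    waters = np.array(inside + outside, float).reshape(-1, 3)
    mask = np.array([True] * len(inside) + [False] * len(outside))
    return ChannelFrame(waters, mask, gates, spec.radial_margin)


def channel_frame_trajectory(
    frame: ChannelFrame, n_frames: int = 1, gate_resnums=((100, 100, 100), (42, 42, 42))
) -> Trajectory:
    """Wrap a planted channel frame as a Trajectory (repeated frames).

    Gate Cα atoms go on chains A/B/C at the given residue numbers; waters
    become HOH oxygens on chain W.
    """
    up, lo = frame.gates.upper, frame.gates.lower
    coords = np.vstack([up, lo, frame.waters])
    n_wat = len(frame.waters)
    chains = ["A", "B", "C", "A", "B", "C"] + ["W"] * n_wat
    resnums = list(gate_resnums[0]) + list(gate_resnums[1]) + list(
        range(1, n_wat + 1)
    )
    resnames = ["PHE"] * 3 + ["ARG"] * 3 + ["HOH"] * n_wat
    atoms = ["CA"] * 6 + ["O"] * n_wat
    elements = ["C"] * 6 + ["O"] * n_wat
    topo = model_from_arrays(
        coords, chains=chains, resnums=resnums, resnames=resnames,
        atom_names=atoms, elements=elements, label="planted channel frame",
    )
    return Trajectory(topo, np.repeat(coords[None], n_frames, axis=0))


# ---------------------------------------------------------------------------
# hydrogen-bond geometries

def hbond_geometry(
    distance: float, angle_deg: float, dh_distance: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Donor/hydrogen/acceptor coordinates with prescribed D–A distance and
    donor angle ∠(D→H, D→A). The hydrogen sits on +x; the acceptor is
    rotated by ``angle_deg`` in the xy-plane."""
    d = np.zeros(3)
    h = np.array([dh_distance, 0.0, 0.0])
    ang = np.radians(angle_deg)
    a = distance * np.array([np.cos(ang), np.sin(ang), 0.0])
    return d, h, a


def hbond_trajectory(
    bound_frames: int,
    unbound_frames: int,
    criteria_distance: float = 3.0,
    donor_resnum: int = 62,
    acceptor_resnum: int = 2,
) -> Trajectory:
    """Two-residue trajectory where the bond geometry holds in exactly
    ``bound_frames`` of the total frames.

    The donor residue contributes its backbone amide (N–H); the acceptor
    residue its backbone carbonyl O. Bound frames place the acceptor at
    0.93·cutoff along the N→H axis; unbound frames push it far away.
    """
    n = np.zeros(3)
    h = np.array([1.0, 0.0, 0.0])
    a_bound = np.array([0.93 * criteria_distance, 0.0, 0.0])
    a_far = np.array([3.0 * criteria_distance, 0.0, 0.0])
    topo = model_from_arrays(
        np.vstack([n, h, a_bound]),
        chains=["A", "A", "A"],
        resnums=[donor_resnum, donor_resnum, acceptor_resnum],
        resnames=["SER", "SER", "PHE"],
        atom_names=["N", "H", "O"],
        elements=["N", "H", "O"],
        label="hbond fixture",
    )
    frames = []
    for fi in range(bound_frames + unbound_frames):
        acc = a_bound if fi < bound_frames else a_far
        frames.append(np.vstack([n, h, acc]))
    return Trajectory(topo, np.array(frames))


# ---------------------------------------------------------------------------
# rigid-body structure pairs

@dataclass
class ToyStructurePair:
    reference: StructureModel
    transformed: StructureModel
    applied_rotation: np.ndarray
    applied_translation: np.ndarray
    per_atom_perturbation_sd: float


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (unit-quaternion construction)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def generate_toy_structure_pair(
    n_atoms: int = 300,
    per_atom_perturbation_sd: float = 0.0,
    seed: int = 0,
    extent: float = 20.0,
) -> ToyStructurePair:
    """Reference point cloud plus a rigidly moved (and optionally perturbed)
    copy; with zero perturbation the optimal superposition RMSD is 0."""
    if n_atoms < 3:
        raise ParameterError("need >= 3 atoms")
    rng = np.random.default_rng(seed)
    ref_coords = rng.uniform(-extent, extent, size=(n_atoms, 3))
    R = random_rotation(rng)
    t = rng.uniform(-extent, extent, size=3)
    moved = ref_coords @ R.T + t
    if per_atom_perturbation_sd > 0:
        moved = moved + rng.normal(0.0, per_atom_perturbation_sd, size=moved.shape)
    reference = model_from_arrays(ref_coords, label="toy reference")
    transformed = model_from_arrays(moved, label="toy transformed")
    return ToyStructurePair(reference, transformed, R, t, per_atom_perturbation_sd)


# ---------------------------------------------------------------------------
# displacement-carrying coordinate trajectories

def wobble_trajectory(
    n_frames: int,
    n_residues: int = 50,
    wobble_residue: int = 0,
    wobble_sd: float = 1.0,
    seed: int = 0,
) -> Trajectory:
    """Static globular Cα cloud where one residue wobbles along x.

    The base geometry is a compact 3D arrangement (not a straight chain) so
    the rigid-body alignment is well conditioned and absorbs only ~1/n of
    the planted single-residue variance.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(-12.0, 12.0, size=(n_residues, 3))
    frames = np.repeat(base[None], n_frames, axis=0)
    frames[:, wobble_residue, 0] += rng.normal(0.0, wobble_sd, size=n_frames)
    topo = model_from_arrays(base, label="wobble fixture")
    return Trajectory(topo, frames)
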