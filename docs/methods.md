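# Methods

`allomif` quantifies allosteric communication in MIF-family homotrimers
(macrophage migration inhibitory factor and its homolog D-dopachrome
tautomerase, MIF-2) from three kinds of evidence: correlated internal
motion in molecular-dynamics trajectories, the hydration and hydrogen
bonding of the trimer's central solvent channel, and solution-NMR
structural/dynamic perturbation profiles, anchored by crystal-structure
comparison metrics. This note records the models, the defaults and why,
the numerical choices, and what the synthetic-data generators do and do
not emulate.

## Generalized correlation from mutual information

Residue–residue coupling is measured on Cα displacement vectors
x_i ∈ ℝ³, taken about each residue's mean position after every frame is
least-squares superposed (Cα Kabsch fit, two refinement passes against the
running mean structure) onto the analysis window's mean. The mutual
information

  I[x_i, x_j] = H[x_i] + H[x_j] − H[x_i, x_j]   (nats)

is mapped to the generalized correlation coefficient

  r[x_i, x_j] = (1 − exp(−(2/d)·I))^{1/2},  d = 3,

which lies in [0, 1), is strictly increasing in I, and — unlike Pearson
cross-correlation of displacement vectors — detects nonlinear and mutually
orthogonal correlated motions. For jointly Gaussian displacements whose
Cartesian components share an isotropic correlation ρ, the closed form is
I = −(3/2)·ln(1 − ρ²) and r = |ρ|; this identity is the calibration used
by the tests.

**Estimator.** Differential entropies of continuous 3D/6D displacement
distributions are not reliably estimated by plug-in histograms at
trajectory-scale sample counts, so the default MI estimator is the
Kraskov–Stögbauer–Grassberger k-nearest-neighbour estimator (variant 1,
Chebyshev norm) with k = 4 on the 3D marginals / 6D joint space. k = 4
is the standard bias/variance compromise for 10⁴–10⁵ samples; k is
exposed. A coarse binned estimator is available as an independent
cross-check (`method="histogram"`), and marginal entropies are reported
from the Kozachenko–Leonenko estimator. Estimates are clamped at 0 from
below; a bit-identical pair of series (for which continuous MI diverges)
returns a cap of 20 nats with a warning, and the diagonal of the r matrix
is set to 1 by convention. The minimum sample count defaults to 1000;
fewer samples raise an explicit undersampling error rather than returning
a silently biased number.

Measured behaviour with these defaults (recomputed by the test-suite and
`scripts/acceptance.py`): at 10⁵ frames the estimated r matches |ρ| within
±0.05 across ρ ∈ {0, 0.3, 0.6, 0.9}; at 10⁴ frames independent residues
show r < 0.1.

**Displacement extraction.** Alignment uses all selected Cα atoms with
uniform weights. A consequence worth knowing: the rigid-body fit absorbs
roughly (rigid degrees of freedom)/n of the variance of a motion carried
by a single residue, so a planted 1 Å wobble in a 50-residue model is
recovered with sd ≈ 0.98 Å. This is a property of trajectory alignment
itself, not of the estimator.

## Solvent-channel hydration

The channel is defined by two gates: the Cα triangles of the three
symmetry-related gating residues at the active-site face (Tyr99 in MIF,
Phe100 in MIF-2) and at the opposite mouth (Val42 / Arg42). "Between the
limits" is formalized as an axial slab capped by the gate-centroid planes:
a water's projection onto the centroid-to-centroid axis must fall between
the centroids, and, in the default cylinder mode, its distance from the
axis must not exceed the larger gate circumradius plus a 2.0 Å margin.
The radial bound and margin are configurable (slab-only mode disables the
radial test) and recorded in output metadata, because the gate atoms alone
do not pin down a unique volume. Waters are identified by residue name
(HOH/WAT/TIP3/SOL, configurable) and represented by their oxygen.

The gate aperture of a trajectory is the mean of the three pairwise
distances among the time-averaged gate Cα positions; channel expansion
between two trajectories is the signed aperture difference, a
rigid-motion-invariant scalar.

Persistent hydration sites are isolated on a voxel occupancy grid: every
in-channel water observation deposits a unit-mass 3D Gaussian of σ = 1.0 Å
on a 0.5 Å grid (approximating a 1 Å-resolution density map without any
structure-factor computation, which is out of scope), and voxels above
mean + σ_level·sd of the nonzero-voxel density mark the stable sites.
Thresholding is monotone in σ_level, and total grid mass equals the
observation count for grids padded to contain every kernel (4σ padding by
default).

## Hydrogen bonds

A donor–hydrogen/acceptor triple counts as a hydrogen bond when the
donor–acceptor heavy-atom distance is ≤ 3.0 Å and the angle between the
D→H and D→A vectors is ≤ 30°. The angle is measured at the donor
(deviation of the hydrogen from the D→A direction), the convention of the
common trajectory-analysis tools; an H-centered convention (180° minus the
D–H–A angle) is available for sensitivity checks. Donor/acceptor chemistry
comes from a small editable table covering backbone amide/carbonyl, polar
side chains and water. The pair statistic is the mean *count* of
satisfying triples per frame — with several donor hydrogens it can exceed
1 — not an occupancy fraction, and donor/acceptor roles are deliberately
asymmetric: Ser62→Phe2 and Phe2→Ser62 are different measurements.

## NMR relaxation and chemical-shift perturbation

R1 and R2 are extracted per residue by nonlinear least squares on
I(t) = I₀·e^(−R·t) over (I₀, R), initialized from a log-linear fit. The
built-in delay schedules are the experimental ones: T1 delays of 0–2500 ms
(11 points, duplicates at 20/60/600 ms) and total T2 relaxation delays of
0–203 ms (7 points, duplicates at 16.9/33.9/136/203 ms). Intensity noise
σ_I is estimated from the duplicate delays (RMS of replicate differences
divided by √2, pooled over residues), injected as an absolute per-point
weight, so rate uncertainties come from the weighted fit covariance.
Monte-Carlo behaviour at the defaults (500 residues, 2% noise): mean bias
< 1% and ≥ 99% of residues within 3σ of truth. Negative fitted rates are
flagged, never clamped. The NOE is the saturated/reference peak-height
ratio (sign preserved); R1·R2 is the elementwise product with first-order
error propagation.

Combined shift perturbations use Δδ = sqrt(ΔδH² + (w·ΔδN)²) with the
community-standard nitrogen weight w = 0.14 (configurable and recorded in
output). Line broadening is an input annotation — a residue assigned in
the wild-type peak list but absent from the variant — not an inference
from intensities.

**Outlier rule.** Per-residue profiles (CSP bars; variant-minus-wild-type
deviations from the x = y line of a relaxation correlation diagram) are
flagged against the 10% trimmed mean ± 1.5σ: the trimmed mean removes 5%
of values from each tail, σ is the sample standard deviation of the full
untrimmed profile (a switch restricts it to the trimmed set), CSP profiles
are flagged one-sided above the threshold while correlation deviations are
flagged two-sided. The deviation axis is the simple difference; the
perpendicular distance to x = y differs only by √2 and is offered as a
flag. Spearman's rho is reported over all paired residues. Thresholding is
per-comparison; pooling across datasets is a caller choice.

## Crystal-structure comparison

Structures are read from PDB or mmCIF (gemmi) keeping all ATOM/HETATM
records, so ligands (e.g. tartrate) and waters stay addressable. Alternate
locations default to highest occupancy with ties broken toward altloc 'A'.
Superposition is closed-form Kabsch (SVD with determinant correction);
atoms pair by (chain, residue number, atom name) after an optional chain
mapping, hydrogens excluded. Comparison RMSDs default to Cα atoms,
mirroring the trajectory convention; a heavy-atom selection flag exists
because deposited-structure RMSDs are sensitive to the atom set, and
`n_atoms_used` is always reported rather than guessed. A chain-permutation
search guards against re-deposited trimers with renamed chains. Ligand
contact shells collect distinct protein residues with any heavy atom
within the cutoff (4 Å default) of any ligand atom, waters excluded.
The tests verify the superposition against an independently coded
quaternion (Horn) implementation to 10⁻⁶ Å on randomized pairs.

## Synthetic data: what it does and does not show

The generators encode exactly the statistical structure each stage
measures — correlated Gaussians with a prescribed PSD per-component
correlation matrix (matrix-square-root factorization, each Cartesian
component independent, so the r = |ρ| identity holds exactly);
single-exponential decays with additive Gaussian intensity noise;
waters rejection-sampled against (and verified by) the very membership
predicate used for counting; donor–H–acceptor triples at prescribed
geometry; rigidly moved point clouds. All randomness flows from one
explicit seed per spec, and equal seeds give bit-identical output.

They have no force-field realism: no anharmonicity, no solvent structure,
no spin physics beyond monoexponential decay. Passing tests therefore
demonstrate that the estimators and statistics recover known ground truth
under their stated assumptions — not that a particular protein shows a
particular coupling. The simulation-scale observables for the MIF/MIF-2
systems themselves (channel water counts near 41–42, bond frequencies of
order 0.05–0.83 per frame, ~1 Å gate expansions) require the original
150 ns solvated-trimer trajectories, which cannot be regenerated here;
the pipeline reproduces their fixture analogs with planted ground truth
instead. Problem sizes used by the test-suite and acceptance script —
10⁴–10⁵ frames for correlation recovery, 500 residues for rate-fit
calibration, 50 superposition pairs, 1000 random profiles — were chosen
as the smallest sizes at which the statistical claims are sharp.

## Known limitations

* MI estimation assumes continuous, non-degenerate displacement
  distributions; constant coordinates or duplicated series hit the
  degeneracy cap rather than a meaningful value.
* The channel volume is a gated cylinder/slab, not a cavity triangulation;
  strongly curved or branched channels would need the slab mode plus a
  custom radial model.
* Donor/acceptor chemistry is a minimal table; nonstandard residues and
  ligand functional groups must be added by the caller.
* The exponential fit is strictly monoexponential; multi-exponential
  relaxation (e.g. strong exchange) will show as biased rates with large
  residuals, not as an automatic model switch.
* No model-free analysis, CPMG dispersion fitting, or spectral processing:
  the pipeline starts at peak heights and positions.
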