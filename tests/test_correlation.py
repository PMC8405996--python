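"""Mutual information, generalized correlation and displacement extraction."""

import numpy as np
import pytest

from allomif.correlation import (
    I_MAX,
    correlation_matrix,
    estimate_mutual_information,
    extract_displacements,
    generalized_correlation,
)
from allomif.errors import ParameterError, UndersamplingError
from allomif.structure import model_from_arrays
from allomif.synthetic import (
    CorrelatedTrajectorySpec,
    correlation_pair_matrix,
    gaussian_mutual_information,
    generate_correlated_trajectory,
    random_rotation,
    wobble_trajectory,
)
from allomif.trajectory import Trajectory


def _pair(rho, n_frames, seed=0):
    spec = CorrelatedTrajectorySpec(
        n_frames=n_frames, n_residues=2,
        correlation=correlation_pair_matrix(2, 0, 1, rho), seed=seed,
    )
    s = generate_correlated_trajectory(spec)
    return s.residue(0), s.residue(1)


class TestGeneralizedCorrelation:
    def test_zero_mi_maps_to_zero(self):
        assert generalized_correlation(0.0) == 0.0

    def test_gaussian_closed_form_point(self):
        # MI of isotropic rho=0.8 Gaussians is -(3/2)ln(0.36) = 1.5326 nats
        assert generalized_correlation(1.5326) == pytest.approx(0.800, abs=5e-4)

    def test_large_mi_saturates_toward_one(self):
        assert generalized_correlation(10.0) == pytest.approx(0.99936, abs=1e-5)

    def test_strictly_increasing_onto_unit_interval(self):
        # strictly increasing where floating point can resolve it,
        # never reaching 1 even far into the saturated tail
        mi = np.linspace(0, 15, 2000)
        r = generalized_correlation(mi)
        assert np.all(np.diff(r) > 0)
        assert r[0] == 0.0 and generalized_correlation(50.0) < 1.0

    def test_negative_mi_rejected(self):
        with pytest.raises(ParameterError):
            generalized_correlation(-0.1)


class TestMutualInformationEstimator:
    def test_independent_vectors_near_zero(self):
        x, y = _pair(0.0, 10_000, seed=2)
        assert estimate_mutual_information(x, y) < 0.05

    def test_correlated_vectors_match_closed_form(self):
        x, y = _pair(0.6, 100_000, seed=3)
        mi = estimate_mutual_information(x, y)
        assert mi == pytest.approx(gaussian_mutual_information(0.6), abs=0.1)

    def test_identical_series_capped_with_warning(self):
        x, _ = _pair(0.0, 2000, seed=4)
        with pytest.warns(RuntimeWarning, match="identical"):
            assert estimate_mutual_information(x, x) == I_MAX

    def test_symmetry_in_arguments(self):
        x, y = _pair(0.5, 5000, seed=5)
        assert estimate_mutual_information(x, y) == pytest.approx(
            estimate_mutual_information(y, x), abs=1e-10
        )

    def test_unequal_lengths_rejected(self):
        x, y = _pair(0.0, 2000, seed=6)
        with pytest.raises(ParameterError):
            estimate_mutual_information(x[:-1], y)

    def test_undersampling_error(self):
        x, y = _pair(0.0, 2000, seed=7)
        with pytest.raises(UndersamplingError):
            estimate_mutual_information(x[:100], y[:100])

    def test_added_noise_does_not_increase_mi(self):
        # data-processing inequality, up to estimator tolerance
        x, y = _pair(0.7, 20_000, seed=8)
        rng = np.random.default_rng(0)
        y_noisy = y + rng.normal(0, 1.0, y.shape)
        mi = estimate_mutual_information(x, y)
        mi_noisy = estimate_mutual_information(x, y_noisy)
        assert mi_noisy <= mi + 0.05

    def test_histogram_estimator_orders_dependence(self):
        x0, y0 = _pair(0.0, 20_000, seed=9)
        x9, y9 = _pair(0.9, 20_000, seed=9)
        lo = estimate_mutual_information(x0, y0, method="histogram")
        hi = estimate_mutual_information(x9, y9, method="histogram")
        assert hi > lo


class TestCorrelationMatrix:
    def test_planted_pair_is_unique_maximum(self):
        n_res = 6
        corr = correlation_pair_matrix(n_res, 1, 5, 0.9)
        spec = CorrelatedTrajectorySpec(
            n_frames=10_000, n_residues=n_res, correlation=corr, seed=10
        )
        result = correlation_matrix(generate_correlated_trajectory(spec))
        a, b, g = result.top_pair()
        assert {a, b} == {("A", 2), ("A", 6)}  # labels are 1-based
        assert g == pytest.approx(0.9, abs=0.05)
        off = result.gcorr.copy()
        np.fill_diagonal(off, 0.0)
        off[1, 5] = off[5, 1] = 0.0
        assert off.max() < 0.1

    def test_diagonal_is_one_and_matrix_symmetric(self):
        spec = CorrelatedTrajectorySpec(n_frames=3000, n_residues=3, seed=11)
        result = correlation_matrix(generate_correlated_trajectory(spec))
        np.testing.assert_allclose(np.diag(result.gcorr), 1.0)
        np.testing.assert_allclose(result.gcorr, result.gcorr.T)
        np.testing.assert_allclose(result.mi, result.mi.T)
        assert np.all(result.mi >= 0)

    def test_residue_permutation_permutes_rows(self):
        spec = CorrelatedTrajectorySpec(
            n_frames=3000, n_residues=4,
            correlation=correlation_pair_matrix(4, 0, 2, 0.8), seed=12,
        )
        s = generate_correlated_trajectory(spec)
        perm = [2, 0, 3, 1]
        from allomif.correlation import DisplacementSeries

        s_perm = DisplacementSeries(
            [s.labels[p] for p in perm], s.samples[:, perm, :]
        )
        r1 = correlation_matrix(s)
        r2 = correlation_matrix(s_perm)
        np.testing.assert_allclose(
            r2.gcorr, r1.gcorr[np.ix_(perm, perm)], atol=1e-10
        )


class TestExtractDisplacements:
    def _static_traj(self, n_frames=5, n_res=10):
        base = np.zeros((n_res, 3))
        base[:, 0] = 3.8 * np.arange(n_res)
        base[:, 1] = np.sin(np.arange(n_res))
        topo = model_from_arrays(base)
        return Trajectory(topo, np.repeat(base[None], n_frames, axis=0))

    def test_static_trajectory_has_zero_displacements(self):
        series = extract_displacements(self._static_traj())
        np.testing.assert_allclose(series.samples, 0.0, atol=1e-10)

    def test_rigid_rotation_removed_by_alignment(self):
        traj = self._static_traj(n_frames=8)
        rng = np.random.default_rng(13)
        frames = np.array(
            [traj.coords[0] @ random_rotation(rng).T + rng.uniform(-5, 5, 3)
             for _ in range(8)]
        )
        series = extract_displacements(Trajectory(traj.topology, frames))
        assert np.abs(series.samples).max() < 1e-6

    def test_planted_wobble_sd_recovered(self):
        traj = wobble_trajectory(n_frames=20_000, n_residues=50,
                                 wobble_residue=7, wobble_sd=1.0, seed=14)
        series = extract_displacements(traj)
        sd = series.samples[:, 7, :].std(axis=0, ddof=1)
        # rigid-body alignment absorbs ~ (rigid DOF)/n of a single residue's
        # planted variance, so recovery is slightly below 1
        assert np.linalg.norm(sd) == pytest.approx(1.0, rel=0.05)
        assert series.samples.shape == (20_000, 50, 3)
        other_sd = series.samples[:, [i for i in range(50) if i != 7], :].std(axis=0)
        assert np.linalg.norm(sd) > 10 * other_sd.max()

    def test_mean_displacement_is_zero(self):
        traj = wobble_trajectory(n_frames=500, seed=15)
        series = extract_displacements(traj)
        assert np.abs(series.samples.mean(axis=0)).max() < 1e-10
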