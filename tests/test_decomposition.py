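"""Orientation detection, demixing and the suborthogonality angle."""

import numpy as np
import pytest

from ofsca import (
    AngleSweepResult,
    DdmaConfig,
    MixSpec,
    SingularMixingError,
    Trajectory2D,
    angle_grid,
    angle_sweep,
    axial_mean,
    delta_theta,
    demix_components,
    detect_orientations,
    dma_fluctuation,
    generate_fgn,
    make_mixed_trajectory,
    mix_components,
    project_trajectory,
    run_ofsca,
)


def synthetic_sweep(alphas, n_angles=180):
    """An AngleSweepResult with prescribed alpha(theta) and dummy F."""
    alphas = np.asarray(alphas, float)
    scales = np.array([31, 61, 121])
    return AngleSweepResult(
        angles=angle_grid(n_angles), alphas=alphas,
        fluctuations=np.ones((n_angles, scales.size)),
        scales=scales, corrected=scales / 1.93, config=DdmaConfig())


class TestProjection:
    def test_axis_aligned(self, rng):
        traj = Trajectory2D(rng.standard_normal(50), rng.standard_normal(50))
        assert np.array_equal(project_trajectory(traj, 0.0), traj.c1)
        assert np.allclose(project_trajectory(traj, 90.0), traj.c2, atol=1e-15)

    def test_diagonal_unit_point(self):
        traj = Trajectory2D([1.0, 1.0], [1.0, 1.0])
        assert np.allclose(project_trajectory(traj, 45.0), np.sqrt(2.0))

    def test_sign_flip_leaves_fluctuation_invariant(self, rng):
        """alpha(theta) is 180-degree periodic: projecting at theta + 180
        flips the sign, and F is even in the series."""
        x = rng.standard_normal(600)
        cfg = DdmaConfig(scales=[5, 15, 41])
        assert np.allclose(dma_fluctuation(x, cfg).values,
                           dma_fluctuation(-x, cfg).values, rtol=1e-12)


class TestAngleSweep:
    def test_default_grid_matches_study_convention(self):
        g = angle_grid()
        assert g.size == 179
        assert g[0] == 0.0
        assert np.isclose(g[1] - g[0], 180.0 / 179.0)
        assert g[-1] < 180.0

    def test_anisotropic_mixture_shows_extrema_near_truth(
            self, illustration_trajectory):
        traj, truth = illustration_trajectory
        sweep = angle_sweep(traj)
        i_min, i_max = np.argmin(sweep.alphas), np.argmax(sweep.alphas)
        # minimum orthogonal to the strong component, maximum orthogonal
        # to the weak one; the maximum is the flatter (noisier) extremum
        assert abs(sweep.angles[i_min] - 105.0) < 8.0
        assert abs(sweep.angles[i_max] - 165.0) < 12.0
        sep = delta_theta(float(sweep.angles[i_min]), float(sweep.angles[i_max]))
        assert 45.0 < sep < 75.0  # illustration separation ~ 50-60 deg
        assert sweep.anisotropy_range > 0.05

    def test_isotropic_input_is_flat(self):
        e1 = generate_fgn(0.6, 10_000, seed=21).values
        e2 = generate_fgn(0.6, 10_000, seed=22).values
        sweep = angle_sweep(Trajectory2D(e1, e2))
        assert sweep.anisotropy_range <= 0.05

    def test_rotation_equivariance(self):
        """Rotating the input plane by +20 deg shifts the detected
        extrema by +20 deg (mod 180) within one grid step."""
        traj, _ = make_mixed_trajectory(MixSpec(n=4096, seed=77))
        phi = np.deg2rad(20.0)
        rot = np.array([[np.cos(phi), -np.sin(phi)],
                        [np.sin(phi), np.cos(phi)]])
        xy = traj.as_matrix() @ rot.T
        rotated = Trajectory2D(xy[:, 0], xy[:, 1], fs=traj.fs)
        step = 180.0 / 179.0
        a = detect_orientations(angle_sweep(traj))
        b = detect_orientations(angle_sweep(rotated))
        for orig, rot_ in [(a[0], b[0]), (a[1], b[1])]:
            d = abs((rot_ - orig - 20.0) + 90.0) % 180.0 - 90.0
            assert abs(d) <= step + 1e-9
        # the separation statistic is rotation invariant (one grid step)
        assert abs(delta_theta(a[2], a[3]) - delta_theta(b[2], b[3])) <= 2 * step

    def test_sweep_dataframe_long_format(self, illustration_trajectory):
        traj, _ = illustration_trajectory
        sweep = angle_sweep(traj, n_angles=8)
        df = sweep.to_dataframe()
        assert len(df) == 8 * sweep.scales.size
        assert set(df.columns) == {"theta", "scale", "corrected_scale",
                                   "F", "alpha"}


class TestDetectOrientations:
    def test_plus_ninety_rule_forced_example(self):
        alphas = np.full(180, 0.6)
        alphas[105] = 0.3   # argmin at 105 deg
        alphas[165] = 0.9   # argmax at 165 deg
        tmin, tmax, th1, th2, flags = detect_orientations(
            synthetic_sweep(alphas))
        assert (tmin, tmax) == (105.0, 165.0)
        assert (th1, th2) == (15.0, 75.0)
        assert not flags

    def test_tie_breaks_to_lowest_index(self):
        alphas = np.full(180, 0.6)
        alphas[[40, 140]] = 0.2
        alphas[[60, 160]] = 0.9
        tmin, tmax, *_ = detect_orientations(synthetic_sweep(alphas))
        assert tmin == 40.0 and tmax == 60.0

    def test_flat_sweep_flags_degeneracy(self):
        *_, flags = detect_orientations(synthetic_sweep(np.full(180, 0.5)))
        assert "degenerate_anisotropy" in flags


class TestDemix:
    def test_roundtrip_identity(self, rng):
        e1, e2 = rng.standard_normal((2, 1000))
        for t1, t2 in [(15.0, 75.0), (3.0, 120.0), (100.0, 179.0)]:
            traj = mix_components(e1, e2, t1, t2)
            r1, r2 = demix_components(traj, t1, t2)
            assert np.allclose(r1, e1, rtol=1e-10, atol=1e-10)
            assert np.allclose(r2, e2, rtol=1e-10, atol=1e-10)

    def test_orthogonal_axes_passthrough(self, rng):
        traj = Trajectory2D(rng.standard_normal(100), rng.standard_normal(100))
        r1, r2 = demix_components(traj, 0.0, 90.0)
        assert np.allclose(r1, traj.c1, atol=1e-12)
        assert np.allclose(r2, traj.c2, atol=1e-12)

    def test_matches_linear_solve_oracle(self, rng):
        from ofsca import mixing_matrix
        traj = Trajectory2D(rng.standard_normal(200), rng.standard_normal(200))
        t1, t2 = 37.0, 151.0
        r1, r2 = demix_components(traj, t1, t2)
        expected = np.linalg.solve(mixing_matrix(t1, t2), traj.as_matrix().T)
        assert np.allclose(np.vstack([r1, r2]), expected, rtol=1e-12)

    def test_near_collinear_rejected(self):
        traj = Trajectory2D(np.ones(10), np.ones(10))
        with pytest.raises(SingularMixingError, match="collinear"):
            demix_components(traj, 30.0, 30.01)


class TestDeltaTheta:
    @pytest.mark.parametrize("t1,t2,expected", [
        (178.0, 96.0, 82.0),   # the young-adult example angles
        (0.0, 90.0, 90.0),
        (170.0, 10.0, 20.0),   # wrap-around, not 160
        (15.0, 75.0, 60.0),
    ])
    def test_reduction(self, t1, t2, expected):
        assert np.isclose(delta_theta(t1, t2), expected)

    def test_equal_angles_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            delta_theta(45.0, 45.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            delta_theta(190.0, 10.0)


class TestAxialMean:
    def test_plain_mean_midrange(self):
        assert np.isclose(axial_mean([14.0, 16.0]), 15.0)

    def test_wraparound(self):
        assert np.isclose(axial_mean([178.0, 2.0]), 0.0, atol=1e-9)


class TestRunOfsca:
    def test_illustration_recovery_single_seed(self, illustration_trajectory):
        traj, truth = illustration_trajectory
        est = run_ofsca(traj)
        assert abs(est.theta1_hat - truth["theta1"]) < 5.0
        assert abs(est.theta2_hat - truth["theta2"]) < 8.0
        assert abs(est.h1 - 0.60) < 0.08
        assert abs(est.h2 - 0.40) < 0.08
        assert est.h1 >= est.h2
        assert 0 < est.delta_theta <= 90
        assert est.sweep is not None

    def test_scale_invariance(self, illustration_trajectory):
        traj, _ = illustration_trajectory
        scaled = Trajectory2D(traj.c1 * 50.0, traj.c2 * 50.0, fs=traj.fs)
        a, b = run_ofsca(traj, keep_sweep=False), run_ofsca(scaled,
                                                            keep_sweep=False)
        assert a.theta1_hat == b.theta1_hat
        assert a.theta2_hat == b.theta2_hat
        assert np.isclose(a.h1, b.h1, atol=1e-9)
        assert np.isclose(a.h2, b.h2, atol=1e-9)

    def test_white_noise_is_degenerate_isotropic(self):
        rng = np.random.default_rng(31)
        traj = Trajectory2D(rng.standard_normal(10_000),
                            rng.standard_normal(10_000))
        est = run_ofsca(traj, keep_sweep=False)
        assert abs(est.h1 - 0.5) < 0.05
        assert abs(est.h2 - 0.5) < 0.05
        assert "degenerate_anisotropy" in est.flags

    def test_rank_one_input_flagged(self):
        """A pure single-component input has no second direction: every
        projection is a rescaling of the same series, so alpha(theta) is
        flat and the estimate is flagged degenerate."""
        e1 = generate_fgn(0.7, 4096, seed=5).values
        traj = mix_components(e1, np.zeros(4096), 30.0, 120.0)
        est = run_ofsca(traj, keep_sweep=False)
        assert est.flags & {"degenerate_anisotropy", "degenerate_component"}
        assert est.anisotropy_range < 1e-6

    def test_rank_one_demix_recovers_zero_component(self):
        """Demixing a rank-1 trajectory at the true angles returns a
        near-zero second component."""
        e1 = generate_fgn(0.7, 2048, seed=6).values
        traj = mix_components(e1, np.zeros(2048), 30.0, 120.0)
        r1, r2 = demix_components(traj, 30.0, 120.0)
        assert np.allclose(r1, e1, atol=1e-10)
        assert np.var(r2) < 1e-20 * np.var(r1)
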