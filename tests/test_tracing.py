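"""Flux density, equal-flux division, arcuate fitting, skew maps and the
iterative tracer, each against an independent oracle where one exists."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fiberflux.geometry import ArcuateModel, DEFAULT_RADII, GeometryError, PolarAnnulusMap
from fiberflux.tracing import (
    TraceError,
    beta_from_model,
    build_skew_map,
    divide_equal_flux,
    fit_arcuate_model,
    flux_density,
    ring_flux,
    trace_iterate,
)
from fiberflux.synthetic import SyntheticEyeSpec, TrajectoryFamilyParams, generate_eye


def brute_force_divide(density_samples, n_dense=100_000, hemisphere=(0.0, 180.0),
                       n_tracks=32):
    """Independent oracle: dense cumulative-sum inversion of the
    piecewise-linear interpolant of the sampled density."""
    n = density_samples.size
    theta_s = np.arange(n + 1) * 360.0 / n
    f = np.append(density_samples, density_samples[0])
    lo, hi = hemisphere
    theta_d = np.linspace(lo, hi, n_dense)
    fd = np.interp(theta_d, theta_s, f)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (fd[1:] + fd[:-1]) * np.diff(theta_d))])
    targets = cum[-1] * np.arange(1, n_tracks) / n_tracks
    inner = np.interp(targets, cum, theta_d)
    return np.concatenate([[lo], inner, [hi]])


class TestFluxDensity:
    def _uniform(self, t_um, r):
        return PolarAnnulusMap(radii=np.array([r]),
                               values=np.full((1, 1024), t_um))

    def test_zero_thickness_zero_flux(self):
        fd = flux_density(self._uniform(0.0, 2.0))
        assert np.all(fd.values == 0.0)

    def test_per_bin_value(self):
        # T = 0.1 mm on ring r = 2.0: per-bin flux = 0.1 * 2.0 * 2pi/1024
        fd = flux_density(self._uniform(100.0, 2.0))
        np.testing.assert_allclose(fd.values, 1.22718e-3, rtol=1e-5)

    def test_ring_flux_closed_form(self):
        fd = flux_density(self._uniform(100.0, 2.0))
        assert ring_flux(fd)[0] == pytest.approx(2 * np.pi * 2.0 * 0.1, rel=1e-12)

    def test_grid_mismatch_rejected(self):
        t = self._uniform(100.0, 2.0)
        bad = PolarAnnulusMap(radii=np.array([2.0]), values=np.ones((1, 512)),
                              quantity="cos_beta")
        with pytest.raises(TraceError):
            flux_density(t, cos_beta=bad)


class TestDivideEqualFlux:
    def test_uniform_density_equal_spacing(self):
        bounds = divide_equal_flux(np.ones(1024))
        np.testing.assert_allclose(bounds, np.arange(33) * 5.625, atol=1e-9)

    def test_two_rectangular_bumps(self):
        # flux only in [20, 60] and [120, 160]: boundaries land only inside
        # the bumps, except the median boundary which splits the dead zone
        theta = np.arange(1024) * 360.0 / 1024
        dens = (((theta >= 20) & (theta < 60)) | ((theta >= 120) & (theta < 160))).astype(float)
        bounds = divide_equal_flux(dens)
        inner = bounds[1:-1]
        in_first = np.sum((inner > 19) & (inner < 61))
        in_second = np.sum((inner > 119) & (inner < 161))
        assert in_first == 15 and in_second == 15
        assert abs(bounds[16] - 90.0) < 1.0  # dead-zone midpoint
        # oracle agreement away from the plateau boundary
        oracle = brute_force_divide(dens)
        keep = np.r_[0:16, 17:33]
        np.testing.assert_allclose(bounds[keep], oracle[keep], atol=0.01)

    def test_equal_division_by_construction(self):
        # integrate the piecewise-linear density between the returned
        # boundaries with an independent dense quadrature
        rng = np.random.default_rng(3)
        dens = rng.uniform(0.2, 2.0, 1024)
        bounds = divide_equal_flux(dens)
        theta_s = np.arange(1025) * 360.0 / 1024
        f = np.append(dens, dens[0])
        theta_d = np.linspace(0.0, 180.0, 2_000_001)
        fd = np.interp(theta_d, theta_s, f)
        cum = np.concatenate([[0.0],
                              np.cumsum(0.5 * (fd[1:] + fd[:-1]) * np.diff(theta_d))])
        cb = np.interp(bounds, theta_d, cum)
        fluxes = np.diff(cb)
        np.testing.assert_allclose(fluxes, fluxes.mean(), rtol=1e-7)

    def test_zero_hemisphere_flux_rejected(self):
        dens = np.zeros(1024)
        dens[600:700] = 1.0  # flux only in the inferior hemisphere
        with pytest.raises(TraceError, match="degenerate"):
            divide_equal_flux(dens, hemisphere=(0.0, 180.0))

    def test_plateau_boundary_at_midpoint(self):
        # two bumps separated by a dead zone: the 16th boundary (between the
        # bump halves) must sit mid-plateau
        theta = np.arange(1024) * 360.0 / 1024
        dens = (((theta >= 0) & (theta < 45)) | ((theta > 135) & (theta <= 180))).astype(float)
        bounds = divide_equal_flux(dens)
        assert abs(bounds[16] - 90.0) < 0.5

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_division_invariants_on_arbitrary_densities(self, seed):
        # for any nonnegative density with positive hemisphere flux:
        # boundaries are sorted, stay inside the hemisphere, and include
        # the fixed borders
        rng = np.random.default_rng(seed)
        dens = rng.gamma(shape=rng.uniform(0.3, 3.0), scale=1.0, size=1024)
        dens[rng.uniform(size=1024) < rng.uniform(0, 0.4)] = 0.0  # dead zones
        bounds = divide_equal_flux(dens)
        assert bounds[0] == 0.0 and bounds[-1] == 180.0
        assert np.all(np.diff(bounds) >= 0.0)
        assert np.all((bounds >= 0.0) & (bounds <= 180.0))

    def test_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            coef = rng.normal(0, 1, 6)
            theta = np.radians(np.arange(1024) * 360.0 / 1024)
            dens = 1.5 + sum(c * np.sin((k + 1) * theta + k) for k, c in enumerate(coef))
            dens = np.maximum(dens, 0.0)
            for hemi in ((0.0, 180.0), (180.0, 360.0)):
                got = divide_equal_flux(dens, hemisphere=hemi)
                oracle = brute_force_divide(dens, hemisphere=hemi)
                assert np.max(np.abs(got - oracle)) < 0.01


class TestFitArcuateModel:
    def test_exact_recovery(self):
        m = ArcuateModel(a=30.0, b=2.0, c=1.5)
        fit = fit_arcuate_model(DEFAULT_RADII, m.angle(DEFAULT_RADII))
        assert abs(fit.a - 30.0) < 1e-6
        assert abs(fit.b - 2.0) < 1e-6
        assert abs(fit.c - 1.5) < 1e-6

    @pytest.mark.parametrize("a,b,c", [(10.0, -4.0, 2.2), (300.0, 0.3, 0.4),
                                       (100.0, 1.0, 1.0)])
    def test_exact_recovery_across_shapes(self, a, b, c):
        m = ArcuateModel(a=a, b=b, c=c)
        fit = fit_arcuate_model(DEFAULT_RADII, m.angle(DEFAULT_RADII))
        assert np.allclose([fit.a, fit.b, fit.c], [a, b, c], atol=1e-5)

    def test_constant_samples_flagged_radial(self):
        fit = fit_arcuate_model(DEFAULT_RADII, np.full(21, 45.0))
        assert fit.a == pytest.approx(45.0)
        assert fit.b == 0.0 and fit.c == 1.0 and fit.zero_b

    def test_too_few_samples_rejected(self):
        with pytest.raises(TraceError):
            fit_arcuate_model(DEFAULT_RADII[:4], np.zeros(4))

    def test_noisy_intercept_unbiased(self):
        # 0.5 deg angular noise at 21 radii: the exponent-profile fit is
        # noisy per draw (CRLB ~0.75 deg for this shape) but unbiased
        m = ArcuateModel(a=30.0, b=2.0, c=1.5)
        rng = np.random.default_rng(7)
        a_hat = [fit_arcuate_model(DEFAULT_RADII,
                                   m.angle(DEFAULT_RADII) + rng.normal(0, 0.5, 21)).a
                 for _ in range(100)]
        assert abs(np.mean(a_hat) - 30.0) < 0.5


class TestBeta:
    def test_radial_model_zero_beta(self):
        m = ArcuateModel(a=45.0, b=0.0, c=1.0)
        assert beta_from_model(m, 3.0) == 0.0
        assert np.cos(np.radians(beta_from_model(m, 2.0))) == pytest.approx(1.0, abs=1e-12)

    def test_finite_difference_oracle(self):
        h = 1e-6
        for a, b, c in [(30.0, 2.0, 1.5), (0.0, -3.0, 2.5), (90.0, 0.7, 0.3)]:
            m = ArcuateModel(a=a, b=b, c=c)
            for r in (1.5, 2.4, 3.5):
                dphi = (m.angle(r + h) - m.angle(r - h)) / (2 * h)
                expected = np.degrees(np.arctan(r * np.radians(dphi)))
                assert abs(beta_from_model(m, r) - expected) < 1e-6

    def test_below_r0_rejected(self):
        with pytest.raises(GeometryError):
            beta_from_model(ArcuateModel(a=0.0, b=1.0, c=1.0), 0.3)


class TestSkewMap:
    def test_radial_trajectory_gives_unit_map(self):
        radial = generate_eye(SyntheticEyeSpec(
            seed=5, family=TrajectoryFamilyParams(bump_height=0.0, arc_b_max=0.0),
            macular_termination=False, noise_sd_um=0.0))
        sk = build_skew_map(radial.truth_trajectory, DEFAULT_RADII, 1024)
        np.testing.assert_allclose(sk.values, 1.0, atol=1e-12)

    def test_uniform_arcuate_field_analytic(self, family):
        # all tracks share (b, c): interpolation between centrelines is exact
        from fiberflux.geometry import TrajectoryMap, N_TRACKS_PER_HEMISPHERE
        b, c = 2.0, 1.5
        models = []
        for k, m in enumerate(family.boundaries):
            sign = 1.0 if k <= N_TRACKS_PER_HEMISPHERE else -1.0
            keep_fixed = k in (0, N_TRACKS_PER_HEMISPHERE)
            models.append(ArcuateModel(a=m.a, b=0.0 if keep_fixed else sign * b,
                                       c=c, r0=m.r0, zero_b=keep_fixed))
        traj = TrajectoryMap(models)
        sk = build_skew_map(traj, DEFAULT_RADII, 1024)
        theta = sk.theta
        # between centrelines beta is exactly constant; only the ramps to the
        # fixed borders (within ~one track width + arc shift) deviate
        interior = (theta > 25) & (theta < 145)
        for i, r in enumerate(DEFAULT_RADII):
            beta = np.degrees(np.arctan(r * np.radians(b * c * (r - 0.85) ** (c - 1))))
            got = np.degrees(np.arccos(np.clip(sk.values[i, interior], -1, 1)))
            assert np.max(np.abs(got - beta)) < 0.5


class TestTraceIterate:
    def test_radial_eye_converges_at_iteration_two(self):
        eye = generate_eye(SyntheticEyeSpec(
            seed=6, family=TrajectoryFamilyParams(bump_height=0.0, arc_b_max=0.0),
            macular_termination=False, noise_sd_um=0.0))
        res = trace_iterate(eye.polar_thickness)
        assert res.converged and res.n_iterations == 2
        assert np.max(np.abs(res.beta)) < 0.01

    def test_boundary_recovery_on_conserved_eye(self, conserved_eye, conserved_trace):
        truth = conserved_eye.truth_trajectory.boundary_angles(DEFAULT_RADII)
        rec = conserved_trace.trajectory.boundary_angles(DEFAULT_RADII)
        assert np.median(np.abs(rec - truth)) < 1.0
        assert conserved_trace.converged
        assert conserved_trace.deltas[-1] < 0.01

    def test_track_monotonicity_after_convergence(self, conserved_trace):
        assert conserved_trace.trajectory.validate_non_crossing(DEFAULT_RADII)

    def test_flux_conservation_after_convergence(self, conserved_eye, conserved_trace):
        fd = flux_density(conserved_eye.polar_thickness, conserved_trace.skew)
        rf = ring_flux(fd)
        assert rf.std() / rf.mean() < 0.005

    def test_idempotent_at_fixed_point(self, conserved_eye, conserved_trace):
        res2 = trace_iterate(conserved_eye.polar_thickness,
                             initial_beta=conserved_trace.beta)
        b1 = conserved_trace.trajectory.boundary_angles(DEFAULT_RADII)
        b2 = res2.trajectory.boundary_angles(DEFAULT_RADII)
        assert np.max(np.abs(b1 - b2)) < 0.01
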