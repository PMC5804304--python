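"""Coordinate conventions, domain types and registration invariants."""

import numpy as np
import pytest

from fiberflux.geometry import (
    DEFAULT_N_THETA,
    DEFAULT_RADII,
    ArcuateModel,
    EyeMeta,
    GeometryError,
    PolarAnnulusMap,
    TrajectoryMap,
    canonical_to_physical,
    compute_mpa,
    physical_to_canonical,
    register_orientation,
    unregister_orientation,
)


def meta_right(mpa_deg: float = 0.0, d: float = 4.0) -> EyeMeta:
    m = np.radians(mpa_deg)
    return EyeMeta(laterality="right", axial_length=24.46, disc_center=(0.0, 0.0),
                   fovea_center=(-d * np.cos(m), -d * np.sin(m)))


class TestComputeMpa:
    @pytest.mark.parametrize(
        "disc, fovea, expected",
        [
            ((0.0, 0.0), (-4.0, 0.0), 0.0),
            ((0.0, 0.0), (-4.0, -0.4767), 6.8),  # healthy-group mean geometry
            ((0.0, 0.0), (-3.0, -3.0), 45.0),
        ],
    )
    def test_examples(self, disc, fovea, expected):
        assert compute_mpa(disc, fovea) == pytest.approx(expected, abs=5e-3)

    def test_coincident_points_rejected(self):
        with pytest.raises(GeometryError):
            compute_mpa((1.0, 1.0), (1.0, 1.0))


class TestEyeMeta:
    def test_axial_length_bounds(self):
        with pytest.raises(GeometryError):
            EyeMeta("right", 31.0, (0, 0), (-4, 0))

    def test_fovea_must_be_temporal(self):
        with pytest.raises(GeometryError):
            EyeMeta("right", 24.0, (0, 0), (4, 0))
        with pytest.raises(GeometryError):
            EyeMeta("left", 24.0, (0, 0), (-4, 0))

    def test_roundtrip_dict(self):
        m = meta_right(6.8)
        assert EyeMeta.from_dict(m.to_dict()) == m


class TestAngularWarp:
    def test_identity_when_mpa_zero(self):
        theta = np.linspace(0, 359.9, 100)
        np.testing.assert_allclose(canonical_to_physical(theta, 0.0), theta)

    def test_borders_exact(self):
        for m in (-8.0, 0.0, 6.8):
            assert canonical_to_physical(np.array([0.0]), m)[0] == 0.0
            assert canonical_to_physical(np.array([180.0]), m)[0] == 180.0 + m

    def test_inverse(self):
        theta = np.linspace(0, 359.5, 321)
        for m in (-5.0, 6.8):
            back = physical_to_canonical(canonical_to_physical(theta, m), m)
            np.testing.assert_allclose(back, theta, atol=1e-10)


class TestRegistration:
    def _raw_map(self, seed=0):
        rng = np.random.default_rng(seed)
        values = rng.uniform(40, 160, size=(3, DEFAULT_N_THETA))
        return PolarAnnulusMap(radii=np.array([1.5, 2.5, 3.5]), values=values)

    def test_right_eye_zero_mpa_is_identity(self):
        pmap = self._raw_map()
        out = register_orientation(pmap, meta_right(0.0))
        np.testing.assert_allclose(out.values, pmap.values, atol=1e-12)

    def test_round_trip_zero_mpa_exact(self):
        pmap = self._raw_map(1)
        meta = meta_right(0.0)
        back = unregister_orientation(register_orientation(pmap, meta), meta)
        assert np.max(np.abs(back.values - pmap.values)) < 1e-9

    def test_round_trip_tilted_within_interp_tolerance(self):
        # smooth field: warp + inverse warp error is interpolation-level
        theta = np.arange(DEFAULT_N_THETA) * 360.0 / DEFAULT_N_THETA
        values = 100 + 30 * np.sin(np.radians(theta))[None, :] * np.ones((3, 1))
        pmap = PolarAnnulusMap(radii=np.array([1.5, 2.5, 3.5]), values=values)
        meta = meta_right(6.8)
        back = unregister_orientation(register_orientation(pmap, meta), meta)
        assert np.max(np.abs(back.values - pmap.values)) < 1e-3

    def test_mpa_lands_at_180(self):
        # a bump placed along the tilted MPA direction must appear at 180 deg
        theta = np.arange(DEFAULT_N_THETA) * 360.0 / DEFAULT_N_THETA
        m = 6.8
        bump = np.exp(-((theta - (180.0 + m)) / 5.0) ** 2)
        pmap = PolarAnnulusMap(radii=np.array([2.0]), values=bump[None, :],
                               quantity="flux_density")
        out = register_orientation(pmap, meta_right(m))
        assert abs(out.theta[np.argmax(out.values[0])] - 180.0) < 0.5


class TestArcuateModel:
    def test_angle_at_r0_is_a(self):
        m = ArcuateModel(a=30.0, b=2.0, c=1.5)
        assert m.angle(m.r0) == pytest.approx(30.0)

    def test_positive_exponent_required(self):
        with pytest.raises(GeometryError):
            ArcuateModel(a=0.0, b=1.0, c=0.0)

    def test_evaluation_below_r0_rejected(self):
        with pytest.raises(GeometryError):
            ArcuateModel(a=0.0, b=1.0, c=1.0).angle(0.5)

    def test_serialization_roundtrip(self):
        m = ArcuateModel(a=30.0, b=2.0, c=1.5, zero_b=False)
        assert ArcuateModel.from_dict(m.to_dict()) == m


class TestTrajectoryMap:
    def test_centerline_is_border_midpoint(self, family):
        radii = DEFAULT_RADII
        bnd = family.boundary_angles(radii)
        cl = family.centerline_angles(radii)
        upper = np.roll(bnd, -1, axis=0)
        upper[-1] += 360.0
        np.testing.assert_allclose(cl, 0.5 * (bnd + upper))

    def test_non_crossing_validation(self, family):
        assert family.validate_non_crossing(DEFAULT_RADII)
        models = [m for m in family.boundaries]
        models[5], models[6] = models[6], models[5]  # swap breaks order
        assert not TrajectoryMap(models).validate_non_crossing(DEFAULT_RADII)
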