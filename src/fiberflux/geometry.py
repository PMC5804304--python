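"""Coordinate conventions and core domain types for nerve fiber flux analysis.

Fundus (raw) frame
------------------
Cartesian coordinates in millimetres on the retina, ``x`` increasing rightward
in the en-face image, ``y`` increasing superiorly.  For a right eye the fovea
lies at ``x`` smaller than the disc centre (temporal side); for a left eye at
larger ``x``.

Canonical polar frame
---------------------
All registered maps share one angular convention around the disc centre:

* 0 deg  = nasal horizontal midline,
* 180 deg = temporal maculopapillary-axis (MPA) direction,
* angles increase counterclockwise for right eyes and clockwise for left
  eyes, so the superior hemisphere is always (0, 180) deg and the inferior
  hemisphere (180, 360) deg.

Because the nasal midline is horizontal while the MPA is tilted by the MPA
angle ``m``, registration maps the superior physical arc ``[0, 180+m]``
linearly onto ``[0, 180]`` and the inferior arc ``[180+m, 360]`` onto
``[180, 360]``.  For ``m = 0`` this is the identity.

Angles are degrees everywhere in the public API; radians appear only inside
trigonometric evaluation.  Thickness is stored in micrometres; flux in mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "EyeMeta",
    "CartesianMap",
    "PolarAnnulusMap",
    "ArcuateModel",
    "TrajectoryMap",
    "FluxTable",
    "DEFAULT_RADII",
    "DEFAULT_N_THETA",
    "R0_MM",
    "compute_mpa",
    "mpa_tilt",
    "canonical_to_physical",
    "physical_to_canonical",
    "canonical_direction",
    "canonical_fovea",
    "register_orientation",
    "unregister_orientation",
    "periodic_interp",
]

#: Reference radius of the arcuate trajectory model / anchor circle (mm).
R0_MM = 0.85

#: 21 sampling rings spanning disc-centred diameters 3.0-7.0 mm.
DEFAULT_RADII = np.round(np.linspace(1.5, 3.5, 21), 10)

#: Angular samples per ring.
DEFAULT_N_THETA = 1024

Laterality = Literal["right", "left"]


class GeometryError(ValueError):
    """Raised for inconsistent eye geometry or map conventions."""


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------


@dataclass
class EyeMeta:
    """Per-eye acquisition metadata in fundus millimetre coordinates."""

    laterality: Laterality
    axial_length: float  # mm
    disc_center: tuple[float, float]  # (x, y) mm
    fovea_center: tuple[float, float]  # (x, y) mm
    disc_ellipse: tuple[float, float, float] = (0.75, 0.9, 0.0)  # semi-axes mm, rot deg

    def __post_init__(self) -> None:
        if self.laterality not in ("right", "left"):
            raise GeometryError(f"laterality must be 'right' or 'left', got {self.laterality!r}")
        if not (20.0 <= self.axial_length <= 30.0):
            raise GeometryError(f"axial length {self.axial_length} mm outside [20, 30] mm")
        dx = self.fovea_center[0] - self.disc_center[0]
        if self.laterality == "right" and dx >= 0:
            raise GeometryError("right eye: fovea must be temporal (x < disc x)")
        if self.laterality == "left" and dx <= 0:
            raise GeometryError("left eye: fovea must be temporal (x > disc x)")

    @property
    def mpa_angle(self) -> float:
        """Signed angle (deg) between the maculopapillary axis and horizontal."""
        return compute_mpa(self.disc_center, self.fovea_center)

    @property
    def disc_fovea_distance(self) -> float:
        dx = self.fovea_center[0] - self.disc_center[0]
        dy = self.fovea_center[1] - self.disc_center[1]
        return float(np.hypot(dx, dy))

    def to_dict(self) -> dict:
        return {
            "laterality": self.laterality,
            "axial_length": self.axial_length,
            "disc_center": list(self.disc_center),
            "fovea_center": list(self.fovea_center),
            "disc_ellipse": list(self.disc_ellipse),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EyeMeta":
        return cls(
            laterality=d["laterality"],
            axial_length=float(d["axial_length"]),
            disc_center=tuple(d["disc_center"]),
            fovea_center=tuple(d["fovea_center"]),
            disc_ellipse=tuple(d.get("disc_ellipse", (0.75, 0.9, 0.0))),
        )


def compute_mpa(disc_center: Sequence[float], fovea_center: Sequence[float]) -> float:
    """Signed MPA angle in degrees, positive when the fovea sits below the disc.

    The maculopapillary axis runs from the fovea to the disc centre; the
    returned value is the acute angle between that axis and the horizontal,
    in (-90, 90) degrees.
    """
    dx = disc_center[0] - fovea_center[0]
    dy = disc_center[1] - fovea_center[1]
    if dx == 0 and dy == 0:
        raise GeometryError("disc and fovea centers coincide; MPA undefined")
    if dx == 0:
        raise GeometryError("disc and fovea are vertically aligned; MPA angle undefined")
    return float(np.degrees(np.arctan2(dy, abs(dx))))


def mpa_tilt(meta: EyeMeta) -> float:
    """MPA tilt ``m`` used by the angular registration warp (deg).

    Positive when the fovea lies inferior to the disc (the common anatomy),
    in which case the superior physical arc spans ``180 + m`` degrees.
    Identical for a left eye and its mirrored right-eye twin.
    """
    return compute_mpa(meta.disc_center, meta.fovea_center)


# ---------------------------------------------------------------------------
# angular registration warp
# ---------------------------------------------------------------------------


def canonical_to_physical(theta: np.ndarray, m: float) -> np.ndarray:
    """Map canonical angles (deg) to physical angles measured from the nasal
    horizontal in the superior-positive sense, for MPA tilt ``m`` (deg)."""
    theta = np.asarray(theta, dtype=float) % 360.0
    sup = theta <= 180.0
    out = np.empty_like(theta)
    out[sup] = theta[sup] * (180.0 + m) / 180.0
    out[~sup] = (180.0 + m) + (theta[~sup] - 180.0) * (180.0 - m) / 180.0
    return out


def physical_to_canonical(psi: np.ndarray, m: float) -> np.ndarray:
    """Inverse of :func:`canonical_to_physical`."""
    psi = np.asarray(psi, dtype=float) % 360.0
    split = 180.0 + m
    sup = psi <= split
    out = np.empty_like(psi)
    out[sup] = psi[sup] * 180.0 / (180.0 + m)
    out[~sup] = 180.0 + (psi[~sup] - split) * 180.0 / (180.0 - m)
    return out


def canonical_direction(theta: np.ndarray, meta: EyeMeta) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors in the fundus frame for canonical angles ``theta`` (deg).

    Applies the per-hemisphere registration warp and the laterality-dependent
    handedness, so ``theta = 0`` points along the nasal horizontal and
    ``theta = 180`` along the temporal MPA.
    """
    m = mpa_tilt(meta)
    psi = np.radians(canonical_to_physical(np.asarray(theta, dtype=float), m))
    if meta.laterality == "right":
        return np.cos(psi), np.sin(psi)
    return -np.cos(psi), np.sin(psi)


def canonical_fovea(meta: EyeMeta) -> tuple[float, float]:
    """Fovea position in the canonical disc-centred Cartesian frame.

    The canonical frame has x along the nasal direction (theta = 0) and
    y superior (theta = 90); the fovea sits on the temporal MPA, i.e. exactly
    at ``(-D, 0)`` with D the disc-fovea distance.
    """
    return (-meta.disc_fovea_distance, 0.0)


# ---------------------------------------------------------------------------
# map containers
# ---------------------------------------------------------------------------


@dataclass
class CartesianMap:
    """Scalar field on a square fundus grid (row = y, col = x).

    ``x = origin[0] + j * pitch`` and ``y = origin[1] + i * pitch`` for array
    element ``values[i, j]``; ``pitch`` in mm.
    """

    values: np.ndarray
    pitch: float
    origin: tuple[float, float]
    quantity: str = "thickness_um"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GeometryError("CartesianMap values must be 2-D")
        if self.pitch <= 0:
            raise GeometryError("pixel pitch must be positive")

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + self.pitch * np.arange(self.values.shape[1])

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + self.pitch * np.arange(self.values.shape[0])

    def copy(self) -> "CartesianMap":
        return CartesianMap(self.values.copy(), self.pitch, tuple(self.origin), self.quantity)


VALID_QUANTITIES = ("thickness_um", "flux_density", "cos_beta", "gamma")


@dataclass
class PolarAnnulusMap:
    """Scalar field sampled on a fixed (ring x angle) grid around the disc.

    ``values[i, j]`` is the field at radius ``radii[i]`` and canonical angle
    ``j * 360 / n_theta`` degrees.  Samples are treated as bin averages for
    integration (periodic rectangle rule is exact) and as point values for
    interpolation.
    """

    radii: np.ndarray
    values: np.ndarray
    quantity: str = "thickness_um"

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.radii.size:
            raise GeometryError("values first axis must match number of rings")
        if self.quantity not in VALID_QUANTITIES:
            raise GeometryError(f"unknown quantity {self.quantity!r}")
        if self.quantity == "thickness_um" and np.any(self.values < 0):
            raise GeometryError("thickness values must be nonnegative")
        if self.quantity == "cos_beta" and (
            np.any(self.values <= 0) or np.any(self.values > 1 + 1e-12)
        ):
            raise GeometryError("cos beta values must lie in (0, 1]")
        if self.quantity == "gamma" and np.any(self.values < 1 - 1e-12):
            raise GeometryError("gamma values must be >= 1")

    @property
    def n_theta(self) -> int:
        return self.values.shape[1]

    @property
    def theta(self) -> np.ndarray:
        """Canonical sample angles in degrees."""
        return np.arange(self.n_theta) * (360.0 / self.n_theta)

    @property
    def dtheta(self) -> float:
        """Angular bin width in degrees."""
        return 360.0 / self.n_theta

    def copy(self) -> "PolarAnnulusMap":
        return PolarAnnulusMap(self.radii.copy(), self.values.copy(), self.quantity)

    def like(self, values: np.ndarray, quantity: str) -> "PolarAnnulusMap":
        return PolarAnnulusMap(self.radii.copy(), values, quantity)


def periodic_interp(theta_q: np.ndarray, theta_s: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Linear interpolation on a periodic 360-deg angular grid.

    ``theta_s`` must be the uniform sample grid ``k * 360 / n``; rows of
    ``values`` may be multidimensional with angle on the last axis.
    """
    n = theta_s.size
    step = 360.0 / n
    pos = (np.asarray(theta_q, dtype=float) % 360.0) / step
    i0 = np.floor(pos).astype(int) % n
    frac = pos - np.floor(pos)
    i1 = (i0 + 1) % n
    return values[..., i0] * (1.0 - frac) + values[..., i1] * frac


def register_orientation(pmap: PolarAnnulusMap, meta: EyeMeta) -> PolarAnnulusMap:
    """Register a raw-orientation polar map into the canonical convention.

    The raw convention samples angles counterclockwise from the +x fundus
    axis.  The registered map has the nasal midline at 0 deg, the temporal
    MPA at 180 deg and superior angles in (0, 180) for either laterality.
    Uses periodic linear interpolation in angle.
    """
    if meta.disc_center is None or meta.fovea_center is None:  # pragma: no cover
        raise GeometryError("registration requires disc and fovea centers")
    m = mpa_tilt(meta)
    psi = canonical_to_physical(pmap.theta, m)
    if meta.laterality == "right":
        lam = psi
    else:
        lam = (180.0 - psi) % 360.0
    out = periodic_interp(lam, pmap.theta, pmap.values)
    return pmap.like(out, pmap.quantity)


def unregister_orientation(pmap: PolarAnnulusMap, meta: EyeMeta) -> PolarAnnulusMap:
    """Inverse of :func:`register_orientation` (to interpolation tolerance)."""
    m = mpa_tilt(meta)
    lam = pmap.theta
    if meta.laterality == "right":
        psi = lam
    else:
        psi = (180.0 - lam) % 360.0
    theta = physical_to_canonical(psi, m)
    out = periodic_interp(theta, pmap.theta, pmap.values)
    return pmap.like(out, pmap.quantity)


# ---------------------------------------------------------------------------
# trajectory model
# ---------------------------------------------------------------------------


@dataclass
class ArcuateModel:
    """Arcuate trajectory ``phi(r) = a + b * (r - r0)**c`` in degrees.

    ``a`` is the angular position at the reference radius ``r0`` (anchor
    circle, 0.85 mm); ``b`` is real and ``c`` a positive exponent controlling
    how quickly the arc bends with radius.  Evaluation is defined for
    ``r >= r0`` only.
    """

    a: float
    b: float
    c: float = 1.0
    r0: float = R0_MM
    zero_b: bool = False
    fallback_linear: bool = False
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise GeometryError(f"arcuate exponent c must be positive, got {self.c}")

    def _check(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        if np.any(r < self.r0 - 1e-12):
            raise GeometryError(f"arcuate model defined only for r >= r0 = {self.r0} mm")
        return np.maximum(r, self.r0)

    def angle(self, r) -> np.ndarray | float:
        """Angular position (deg) at radius ``r`` (mm)."""
        rr = self._check(r)
        out = self.a + self.b * np.power(rr - self.r0, self.c)
        return float(out) if np.isscalar(r) else out

    def dphi_dr(self, r) -> np.ndarray | float:
        """d(phi)/dr in degrees per mm.

        At ``r == r0`` the derivative is 0 for c > 1, ``b`` for c == 1 and
        unbounded for c < 1 (returned as inf); the analysis annulus starts
        well outside r0, so this limit matters only for extrapolation.
        """
        rr = self._check(r)
        d = rr - self.r0
        with np.errstate(divide="ignore"):
            out = self.b * self.c * np.power(d, self.c - 1.0)
        if self.c == 1.0:
            out = np.full_like(d, self.b)
        return float(out) if np.isscalar(r) else out

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c, "r0": self.r0,
            "zero_b": self.zero_b, "fallback_linear": self.fallback_linear,
            "rms_residual": self.rms_residual,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArcuateModel":
        return cls(**d)


N_TRACKS_PER_HEMISPHERE = 32
N_TRACKS = 2 * N_TRACKS_PER_HEMISPHERE  # 64
N_BOUNDARIES = N_TRACKS  # 62 fitted inner borders + 2 fixed hemisphere borders


@dataclass
class TrajectoryMap:
    """64 track boundary trajectories around the disc.

    Boundary index 0 is the fixed nasal-midline border (0 deg at all radii)
    and index 32 the fixed temporal-MPA border (180 deg); indices 1-31 are the
    superior inner boundaries, 33-63 the inferior ones, in increasing
    canonical angle.  Track ``n`` spans boundaries ``n`` to ``n+1`` (mod 64);
    tracks 0-31 are superior, 32-63 inferior.  The centreline of a track is
    the midpoint of its two borders at each radius.
    """

    boundaries: list[ArcuateModel]

    def __post_init__(self) -> None:
        if len(self.boundaries) != N_BOUNDARIES:
            raise GeometryError(f"expected {N_BOUNDARIES} boundary models")

    # -- evaluation ---------------------------------------------------------

    def boundary_angles(self, radii: np.ndarray) -> np.ndarray:
        """Boundary angular positions, shape (n_boundaries, n_radii), deg."""
        radii = np.atleast_1d(np.asarray(radii, dtype=float))
        return np.stack([m.angle(radii) for m in self.boundaries])

    def boundary_dphi(self, radii: np.ndarray) -> np.ndarray:
        radii = np.atleast_1d(np.asarray(radii, dtype=float))
        return np.stack([m.dphi_dr(radii) for m in self.boundaries])

    def centerline_angles(self, radii: np.ndarray) -> np.ndarray:
        """Track centreline angles, shape (64, n_radii), deg."""
        ang = self.boundary_angles(radii)
        upper = np.roll(ang, -1, axis=0).copy()
        upper[-1] += 360.0  # track 63 wraps to the nasal border at 360 deg
        return 0.5 * (ang + upper)

    def centerline_dphi(self, radii: np.ndarray) -> np.ndarray:
        d = self.boundary_dphi(radii)
        return 0.5 * (d + np.roll(d, -1, axis=0))

    def hemisphere(self, track: int) -> str:
        return "superior" if track < N_TRACKS_PER_HEMISPHERE else "inferior"

    def validate_non_crossing(self, radii: np.ndarray, tol: float = 1e-9) -> bool:
        """True iff boundaries are strictly monotone in index at every radius."""
        ang = self.boundary_angles(radii)
        sup = ang[: N_TRACKS_PER_HEMISPHERE + 1]  # includes MPA border
        inf = np.vstack([ang[N_TRACKS_PER_HEMISPHERE:], np.full((1, ang.shape[1]), 360.0)])
        return bool(np.all(np.diff(sup, axis=0) > tol) and np.all(np.diff(inf, axis=0) > tol))

    def to_dict(self) -> dict:
        return {"boundaries": [m.to_dict() for m in self.boundaries]}

    @classmethod
    def from_dict(cls, d: dict) -> "TrajectoryMap":
        return cls([ArcuateModel.from_dict(b) for b in d["boundaries"]])


# ---------------------------------------------------------------------------
# flux bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class FluxTable:
    """Per-ring, per-track, per-sector nerve fiber flux in mm^2."""

    per_track_flux: np.ndarray  # (n_rings, 64)
    track_flux: np.ndarray  # (64,)
    sector_flux: np.ndarray | None = None  # (8,)
    sector_labels: list[str] | None = None
    track_sector: np.ndarray | None = None  # (64,) sector index per track
    ring_aggregation: str = "mean"

    @property
    def overall_flux(self) -> float:
        return float(self.track_flux.sum())

    def __post_init__(self) -> None:
        self.per_track_flux = np.asarray(self.per_track_flux, dtype=float)
        self.track_flux = np.asarray(self.track_flux, dtype=float)
        if np.any(self.per_track_flux < -1e-12):
            raise GeometryError("flux entries must be nonnegative")

    def to_dict(self) -> dict:
        d = {
            "per_track_flux": self.per_track_flux.tolist(),
            "track_flux": self.track_flux.tolist(),
            "overall_flux": self.overall_flux,
            "ring_aggregation": self.ring_aggregation,
        }
        if self.sector_flux is not None:
            d["sector_flux"] = self.sector_flux.tolist()
            d["sector_labels"] = self.sector_labels
            d["track_sector"] = self.track_sector.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FluxTable":
        return cls(
            per_track_flux=np.asarray(d["per_track_flux"]),
            track_flux=np.asarray(d["track_flux"]),
            sector_flux=np.asarray(d["sector_flux"]) if "sector_flux" in d else None,
            sector_labels=d.get("sector_labels"),
            track_sector=np.asarray(d["track_sector"]) if "track_sector" in d else None,
            ring_aggregation=d.get("ring_aggregation", "mean"),
        )
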