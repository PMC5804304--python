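"""Ganglion-cell compensation coefficient for the macular side.

Nerve fiber flux is conserved along a track only where no fibers originate;
temporally, fibers terminate on macular retinal ganglion cells (RGC) and the
flux decays with radius.  Assuming the flux reduction is proportional to the
RGC count integrated along the track footprint, a fiber crosses disc-radius
``r`` iff its soma lies beyond ``r`` along the track, so

    Phi(r) = Phi(r_in) * (1 - L(r) / L_inf),   gamma(r) = 1 / (1 - L(r)/L_inf)

where ``L(r)`` is the RGC count in the track footprint between the innermost
ring and ``r`` and ``L_inf`` the count out to a beyond-map allowance radius.
Multiplying the measured flux by ``gamma`` restores a conserved quantity.
The coefficient is only computed for angular positions 110-270 deg (the
macular side) and set to 1 elsewhere, where RGC density is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    N_TRACKS_PER_HEMISPHERE,
    PolarAnnulusMap,
    TrajectoryMap,
)

__all__ = [
    "RgcDensityModel",
    "rgc_density",
    "track_termination_fractions",
    "termination_field",
    "compensation_map",
    "COMPENSATION_ZONE_DEG",
]

#: Angular zone (canonical degrees) where gamma is computed; 1 elsewhere.
COMPENSATION_ZONE_DEG = (110.0, 270.0)

#: Default share of a temporal track's fibers originating peripheral to the
#: beyond-map allowance radius (they dilute the terminated fraction).
PERIPHERAL_FIBER_FRACTION = 0.55


@dataclass
class RgcDensityModel:
    """Radially symmetric, foveally peaked parametric RGC density profile.

    Zero inside the foveal pit, a smooth rise to a peak ring, and an
    exponential decay outside -- the qualitative shape of histological human
    RGC density maps.  If ``total_cells`` is given, the profile is rescaled
    so its 2-D integral equals that count; otherwise ``peak_density`` is
    used as-is.
    """

    peak_density: float = 35_000.0  # cells / mm^2
    pit_radius: float = 0.15  # mm, RGC-free foveal pit
    peak_radius: float = 1.7  # mm eccentricity of the density peak ring
    decay_scale: float = 1.5  # mm, exponential decay outside the peak
    total_cells: float | None = None

    def _unit_profile(self, ecc: np.ndarray) -> np.ndarray:
        ecc = np.asarray(ecc, dtype=float)
        out = np.zeros_like(ecc)
        rise = (ecc > self.pit_radius) & (ecc < self.peak_radius)
        t = (ecc[rise] - self.pit_radius) / (self.peak_radius - self.pit_radius)
        out[rise] = np.sin(0.5 * np.pi * t) ** 2
        tail = ecc >= self.peak_radius
        out[tail] = np.exp(-(ecc[tail] - self.peak_radius) / self.decay_scale)
        return out

    @property
    def scale(self) -> float:
        """Peak density after optional total-count normalization."""
        if self.total_cells is None:
            return self.peak_density
        e = np.linspace(0.0, self.peak_radius + 25.0 * self.decay_scale, 20_000)
        integral = np.trapezoid(self._unit_profile(e) * 2.0 * np.pi * e, e)
        return self.total_cells / integral

    def density_at_eccentricity(self, ecc) -> np.ndarray | float:
        out = self.scale * self._unit_profile(np.atleast_1d(ecc))
        return float(out[0]) if np.isscalar(ecc) else out

    def to_dict(self) -> dict:
        return {
            "peak_density": self.peak_density,
            "pit_radius": self.pit_radius,
            "peak_radius": self.peak_radius,
            "decay_scale": self.decay_scale,
            "total_cells": self.total_cells,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RgcDensityModel":
        return cls(**d)


def rgc_density(point, model: RgcDensityModel, fovea=(0.0, 0.0)) -> float:
    """RGC density (cells/mm^2) at a fundus point (x, y) in mm."""
    ecc = float(np.hypot(point[0] - fovea[0], point[1] - fovea[1]))
    return float(model.density_at_eccentricity(ecc))


class CompensationError(ValueError):
    pass


def track_termination_fractions(
    trajectory: TrajectoryMap,
    rgc: RgcDensityModel,
    radii: np.ndarray,
    disc_fovea_distance: float = 4.0,
    r_inner: float | None = None,
    r_allowance: float = 8.0,
    zone: tuple[float, float] = COMPENSATION_ZONE_DEG,
    ds: float = 0.005,
    r_freeze: float = 4.0,
    peripheral_fiber_fraction: float = PERIPHERAL_FIBER_FRACTION,
) -> np.ndarray:
    """Fraction of each track's fibers terminated by each radius, (64, n_r).

    For each track, RGC density is integrated over the track footprint
    (width x arc element) along the centreline from the innermost ring to a
    beyond-map allowance radius; the fraction terminated by radius ``r`` is
    the partial over the total fiber complement of the track.  The total
    includes, beyond the footprint integral, a ``peripheral_fiber_fraction``
    share of fibers originating in peripheral retina outside the allowance
    radius (sparse but vast catchment), which caps the compensation at
    moderate values.  Termination only accrues while the centreline lies
    inside the compensation zone, so nasal tracks get 0.
    """
    radii = np.asarray(radii, dtype=float)
    r_in = float(radii.min()) if r_inner is None else r_inner
    fov = (-disc_fovea_distance, 0.0)
    s = np.arange(r_in, r_allowance + ds, ds)
    # beyond the trust radius the fitted arcs are no longer meaningful; the
    # footprint continues radially with frozen angle and width
    s_eval = np.minimum(s, r_freeze)
    bnd = trajectory.boundary_angles(s_eval)  # (64, n_s)
    upper = np.roll(bnd, -1, axis=0).copy()
    upper[-1] += 360.0
    width_rad = np.maximum(np.deg2rad(upper - bnd), 1e-4)
    center = 0.5 * (bnd + upper)  # deg, track centrelines
    cx = s[None, :] * np.cos(np.radians(center))
    cy = s[None, :] * np.sin(np.radians(center))
    ecc = np.hypot(cx - fov[0], cy - fov[1])
    dens = rgc.scale * rgc._unit_profile(ecc)
    in_zone = (center % 360.0 >= zone[0]) & (center % 360.0 <= zone[1])
    integrand = dens * width_rad * s[None, :] * in_zone
    cum = np.concatenate(
        [np.zeros((integrand.shape[0], 1)),
         np.cumsum(0.5 * (integrand[:, 1:] + integrand[:, :-1]) * ds, axis=1)],
        axis=1,
    )
    total = cum[:, -1] / max(1.0 - peripheral_fiber_fraction, 1e-9)
    frac = np.zeros((bnd.shape[0], radii.size))
    active = total > 0
    if np.any(active):
        at_r = np.stack([np.interp(radii, s, cum[k]) for k in range(cum.shape[0])])
        frac[active] = at_r[active] / total[active, None]
    if np.any(frac >= 1.0):
        raise CompensationError("RGC model terminates an entire track inside the map")
    return frac


def termination_field(
    trajectory: TrajectoryMap,
    per_track: np.ndarray,
    radii: np.ndarray,
    n_theta: int,
    zone: tuple[float, float] = COMPENSATION_ZONE_DEG,
) -> np.ndarray:
    """Interpolate per-track values onto the (ring x angle) grid.

    Linear in angle between track centrelines within each hemisphere, with
    clamped ends; forced to 0 outside the compensation zone.
    """
    radii = np.asarray(radii, dtype=float)
    theta = np.arange(n_theta) * (360.0 / n_theta)
    cl = trajectory.centerline_angles(radii)  # (64, n_r)
    out = np.zeros((radii.size, n_theta))
    sup = theta <= 180.0
    h = N_TRACKS_PER_HEMISPHERE
    for i in range(radii.size):
        for mask, rows in ((sup, slice(0, h)), (~sup, slice(h, None))):
            nodes = cl[rows, i]
            order = np.argsort(nodes)
            out[i, mask] = np.interp(theta[mask], nodes[order], per_track[rows, i][order])
    in_zone = (theta >= zone[0]) & (theta <= zone[1])
    out[:, ~in_zone] = 0.0
    return out


def compensation_map(
    reference_trajectory: TrajectoryMap,
    rgc: RgcDensityModel,
    radii: np.ndarray,
    n_theta: int,
    disc_fovea_distance: float = 4.0,
    zone: tuple[float, float] = COMPENSATION_ZONE_DEG,
    r_allowance: float = 8.0,
    peripheral_fiber_fraction: float = PERIPHERAL_FIBER_FRACTION,
) -> PolarAnnulusMap:
    """Compensation coefficient map ``gamma(r, theta) >= 1``.

    ``gamma = 1 / (1 - f)`` with ``f`` the interpolated terminated-fiber
    fraction; exactly 1 for angular positions outside the compensation zone.
    """
    radii = np.asarray(radii, dtype=float)
    frac = track_termination_fractions(
        reference_trajectory, rgc, radii,
        disc_fovea_distance=disc_fovea_distance,
        zone=zone, r_allowance=r_allowance,
        peripheral_fiber_fraction=peripheral_fiber_fraction,
    )
    f = termination_field(reference_trajectory, frac, radii, n_theta, zone=zone)
    gamma = 1.0 / (1.0 - f)
    return PolarAnnulusMap(radii=radii.copy(), values=gamma, quantity="gamma")
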