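"""Convert a Cartesian NFL thickness map plus metadata into a corrected,
registered polar annulus map.

Order of corrections: ILM tilt correction first (a per-pixel optical
correction), then optical magnification (a global transverse rescale), then
polar resampling with orientation registration folded into the sampling
directions.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage

from .geometry import (
    DEFAULT_N_THETA,
    DEFAULT_RADII,
    CartesianMap,
    EyeMeta,
    GeometryError,
    PolarAnnulusMap,
    canonical_direction,
    compute_mpa,
)

__all__ = [
    "compute_mpa",
    "tilt_correct",
    "magnification_correct",
    "resample_polar",
    "REFERENCE_AXIAL_LENGTH_MM",
    "NODAL_OFFSET_MM",
]

#: Default reference axial length for magnification correction (mm).
REFERENCE_AXIAL_LENGTH_MM = 24.46

#: Distance between the eye's second nodal point and the cornea in the
#: Bennett-style magnification factor q = 0.01306 * (AL - 1.82).
NODAL_OFFSET_MM = 1.82


def tilt_correct(thickness: CartesianMap, ilm_elevation: CartesianMap) -> CartesianMap:
    """Correct thickness for ILM surface tilt: ``T' = T * cos(alpha)``.

    ``alpha`` is the angle between the local ILM surface normal and the OCT
    axial (z) direction.  For an elevation graph ``z = h(x, y)`` in mm,
    ``cos(alpha) = 1 / sqrt(1 + |grad h|^2)``, so the corrected thickness is
    never larger than the measured one.  The gradient uses central
    differences (one-sided at the borders).
    """
    if thickness.values.shape != ilm_elevation.values.shape or not np.isclose(
        thickness.pitch, ilm_elevation.pitch
    ):
        raise GeometryError("thickness and ILM elevation maps must share the grid")
    gy, gx = np.gradient(ilm_elevation.values, ilm_elevation.pitch)
    cos_alpha = 1.0 / np.sqrt(1.0 + gx**2 + gy**2)
    out = thickness.copy()
    out.values = thickness.values * cos_alpha
    return out


def magnification_correct(
    cmap: CartesianMap,
    meta: EyeMeta,
    reference_axial_length: float = REFERENCE_AXIAL_LENGTH_MM,
) -> tuple[CartesianMap, EyeMeta]:
    """Rescale transverse dimensions for ocular magnification.

    The transverse pixel pitch (and every transverse coordinate derived from
    the image, including disc and fovea centres) is multiplied by
    ``s = (AL - 1.82) / (AL_ref - 1.82)``; thickness values are unchanged.
    """
    al = meta.axial_length
    if al <= NODAL_OFFSET_MM or reference_axial_length <= NODAL_OFFSET_MM:
        raise GeometryError("axial length must exceed the 1.82 mm nodal offset")
    s = (al - NODAL_OFFSET_MM) / (reference_axial_length - NODAL_OFFSET_MM)
    out = cmap.copy()
    out.pitch = cmap.pitch * s
    out.origin = (cmap.origin[0] * s, cmap.origin[1] * s)
    new_meta = replace(
        meta,
        disc_center=(meta.disc_center[0] * s, meta.disc_center[1] * s),
        fovea_center=(meta.fovea_center[0] * s, meta.fovea_center[1] * s),
        disc_ellipse=(meta.disc_ellipse[0] * s, meta.disc_ellipse[1] * s, meta.disc_ellipse[2]),
    )
    return out, new_meta


def resample_polar(
    cmap: CartesianMap,
    meta: EyeMeta,
    radii: np.ndarray | None = None,
    n_theta: int = DEFAULT_N_THETA,
) -> PolarAnnulusMap:
    """Resample a Cartesian map onto registered concentric rings.

    Samples 21 rings (radii 1.5-3.5 mm by default) at ``n_theta`` angular
    positions in the canonical orientation (nasal midline at 0 deg, temporal
    MPA at 180 deg, superior hemisphere in (0, 180) for either laterality),
    using bilinear interpolation.
    """
    radii = DEFAULT_RADII if radii is None else np.asarray(radii, dtype=float)
    x0, y0 = cmap.origin
    xmax = x0 + cmap.pitch * (cmap.values.shape[1] - 1)
    ymax = y0 + cmap.pitch * (cmap.values.shape[0] - 1)
    cx, cy = meta.disc_center
    for r in radii:
        if cx - r < x0 or cx + r > xmax or cy - r < y0 or cy + r > ymax:
            raise GeometryError(
                f"ring r = {r:g} mm exceeds the map extent "
                f"[{x0:g}, {xmax:g}] x [{y0:g}, {ymax:g}] mm around the disc"
            )
    theta = np.arange(n_theta) * (360.0 / n_theta)
    ux, uy = canonical_direction(theta, meta)
    px = cx + np.outer(radii, ux)  # (n_r, n_theta)
    py = cy + np.outer(radii, uy)
    rows = (py - y0) / cmap.pitch
    cols = (px - x0) / cmap.pitch
    vals = ndimage.map_coordinates(cmap.values, [rows, cols], order=1, mode="nearest")
    if cmap.quantity == "thickness_um":
        vals = np.maximum(vals, 0.0)
    return PolarAnnulusMap(radii=radii, values=vals, quantity=cmap.quantity)
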