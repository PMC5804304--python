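"""Iterative equal-flux trajectory tracing.

The tracer recovers nerve fiber trajectories from a registered polar NFL
thickness map using conservation of nerve fiber flux: the perpendicular
cross-sectional area ``dPhi = T * gamma * cos(beta) * r * dtheta`` carried by
a bundle is the same on every sampling ring, so dividing each ring's flux
into equal parts per hemisphere and following the division boundaries across
rings yields the fiber trajectories.  Because a ring transects oblique fibers
at skew angle ``beta``, the apparent cross-section must be multiplied by
``cos(beta)`` -- which itself depends on the trajectory -- hence the
iteration: start with ``beta = 0``, divide, fit arcuate models
``phi(r) = a + b (r - r0)^c`` to the boundaries, rebuild the skew map from
the fitted models, and repeat until the skew map changes by less than 0.01
degrees anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .geometry import (
    N_BOUNDARIES,
    N_TRACKS_PER_HEMISPHERE,
    R0_MM,
    ArcuateModel,
    GeometryError,
    PolarAnnulusMap,
    TrajectoryMap,
)

__all__ = [
    "flux_density",
    "ring_flux",
    "divide_equal_flux",
    "fit_arcuate_model",
    "beta_from_model",
    "beta_field",
    "build_skew_map",
    "trace_iterate",
    "TraceResult",
]

UM_PER_MM = 1000.0


class TraceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# flux density
# ---------------------------------------------------------------------------


def flux_density(
    thickness: PolarAnnulusMap,
    cos_beta: PolarAnnulusMap | None = None,
    gamma: PolarAnnulusMap | None = None,
) -> PolarAnnulusMap:
    """Per-bin nerve fiber flux ``dPhi = T * gamma * cos(beta) * r * dtheta``.

    Thickness enters in mm (converted from the stored micrometres); the
    result is mm^2 of perpendicular fiber cross-section per angular bin.
    Total ring flux is the plain sum over bins (periodic rectangle rule).
    """
    vals = thickness.values
    if np.any(vals < 0):
        raise TraceError("negative thickness in flux computation")
    for other, name in ((cos_beta, "cos_beta"), (gamma, "gamma")):
        if other is not None and other.values.shape != vals.shape:
            raise TraceError(f"{name} map grid does not match the thickness map")
    t_mm = vals / UM_PER_MM
    cb = cos_beta.values if cos_beta is not None else 1.0
    g = gamma.values if gamma is not None else 1.0
    dtheta_rad = np.deg2rad(thickness.dtheta)
    flux = t_mm * g * cb * thickness.radii[:, None] * dtheta_rad
    return thickness.like(flux, "flux_density")


def ring_flux(flux: PolarAnnulusMap) -> np.ndarray:
    """Total flux of each ring (mm^2)."""
    return flux.values.sum(axis=1)


# ---------------------------------------------------------------------------
# equal-flux division
# ---------------------------------------------------------------------------


def divide_equal_flux(
    density: np.ndarray,
    n_theta: int | None = None,
    hemisphere: tuple[float, float] = (0.0, 180.0),
    n_tracks: int = N_TRACKS_PER_HEMISPHERE,
) -> np.ndarray:
    """Angles dividing one hemisphere of one ring into equal-flux tracks.

    ``density`` is the flux per *degree* sampled on the uniform full-circle
    grid ``k * 360 / n_theta``.  The density is treated as piecewise linear
    between samples; its cumulative (piecewise quadratic) is inverted
    exactly at the ``n_tracks`` equal quantiles.  Returns ``n_tracks + 1`` angles including
    the two fixed hemisphere borders.  A boundary falling on a zero-density
    plateau is placed at the plateau midpoint.
    """
    density = np.asarray(density, dtype=float)
    n = density.size if n_theta is None else n_theta
    if density.size != n:
        raise TraceError("density length does not match n_theta")
    if np.any(density < 0):
        raise TraceError("flux density must be nonnegative")
    step = 360.0 / n
    lo, hi = hemisphere
    i_lo, i_hi = lo / step, hi / step
    if abs(i_lo - round(i_lo)) > 1e-9 or abs(i_hi - round(i_hi)) > 1e-9:
        raise TraceError("hemisphere borders must lie on the angular grid")
    idx = np.arange(int(round(i_lo)), int(round(i_hi)) + 1) % n
    theta = lo + step * np.arange(idx.size)
    f = density[idx]
    # piecewise-linear cumulative flux (trapezoid)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * step)])
    total = cum[-1]
    if total <= 0:
        raise TraceError("zero hemisphere flux: degenerate eye")
    targets = total * np.arange(1, n_tracks) / n_tracks
    eps = 1e-12 * total
    bounds = np.empty(n_tracks + 1)
    bounds[0], bounds[-1] = lo, hi
    for k, q in enumerate(targets, start=1):
        i = int(np.searchsorted(cum, q - eps, side="left"))
        i = min(max(i, 1), cum.size - 1)
        if abs(cum[i] - q) <= eps:
            # target hits a knot; if it starts a zero-density plateau, place
            # the boundary at the plateau midpoint
            j0 = i
            while j0 > 0 and abs(cum[j0 - 1] - q) <= eps:
                j0 -= 1
            j1 = i
            while j1 < cum.size - 1 and abs(cum[j1 + 1] - q) <= eps:
                j1 += 1
            bounds[k] = 0.5 * (theta[j0] + theta[j1])
        else:
            # within a segment the density is linear, so the cumulative is
            # quadratic; invert it exactly (stable root form)
            f0, f1 = f[i - 1], f[i]
            d = q - cum[i - 1]
            a2 = (f1 - f0) / (2.0 * step)
            disc = f0 * f0 + 4.0 * a2 * d
            denom = f0 + np.sqrt(max(disc, 0.0))
            if denom > 0:
                x = 2.0 * d / denom
            else:  # f0 == 0 and rising density
                x = np.sqrt(d / a2) if a2 > 0 else 0.0
            bounds[k] = theta[i - 1] + min(max(x, 0.0), step)
    return bounds


# ---------------------------------------------------------------------------
# arcuate model fitting
# ---------------------------------------------------------------------------

C_BOUNDS = (0.05, 5.0)
C_STARTS = (0.5, 1.0, 2.0)


def _solve_ab(u: np.ndarray, phi: np.ndarray) -> tuple[float, float, float]:
    """Least-squares (a, b) for ``phi = a + b u`` plus the SSE (2x2 normal eqs)."""
    n = u.size
    su, sp = u.sum(), phi.sum()
    suu, sup_ = (u * u).sum(), (u * phi).sum()
    det = n * suu - su * su
    if det <= 1e-300:
        a = sp / n
        return a, 0.0, float(((phi - a) ** 2).sum())
    b = (n * sup_ - su * sp) / det
    a = (sp - b * su) / n
    resid = phi - a - b * u
    return float(a), float(b), float((resid**2).sum())


def fit_arcuate_model(
    radii: np.ndarray,
    angles: np.ndarray,
    r0: float = R0_MM,
    c_bounds: tuple[float, float] = C_BOUNDS,
) -> ArcuateModel:
    """Fit ``phi(r) = a + b (r - r0)^c`` to boundary angle samples.

    The problem is linear in (a, b) for fixed c, so the exponent is profiled
    out: a coarse log-spaced sweep over c (multi-started, bounds (0.05, 5])
    is refined by bounded 1-D minimisation.  Constant samples leave c
    unidentifiable; they are reported as ``b = 0, c = 1`` with the
    ``zero_b`` flag set.  If the nonlinear refinement fails the linear
    model (c = 1) is returned with ``fallback_linear`` set.
    """
    radii = np.asarray(radii, dtype=float)
    angles = np.asarray(angles, dtype=float)
    ok = np.isfinite(angles) & np.isfinite(radii)
    radii, angles = radii[ok], angles[ok]
    if radii.size < 5:
        raise TraceError("need at least 5 finite samples to fit an arcuate model")
    d = radii - r0
    if np.any(d <= 0):
        raise TraceError("all sample radii must exceed r0")
    if np.ptp(angles) < 1e-10:
        return ArcuateModel(a=float(angles.mean()), b=0.0, c=1.0, r0=r0, zero_b=True)

    logd = np.log(d)

    def sse(c: float) -> float:
        return _solve_ab(np.exp(c * logd), angles)[2]

    lo, hi = c_bounds
    grid = np.unique(np.concatenate([
        np.geomspace(lo, hi, 25), np.asarray(C_STARTS, dtype=float)
    ]))
    grid = grid[(grid >= lo) & (grid <= hi)]
    vals = np.array([sse(c) for c in grid])
    k = int(np.argmin(vals))
    bracket_lo = grid[max(k - 1, 0)]
    bracket_hi = grid[min(k + 1, grid.size - 1)]
    try:
        res = optimize.minimize_scalar(
            sse, bounds=(bracket_lo, bracket_hi), method="bounded",
            options={"xatol": 1e-12},
        )
        c_best = float(res.x) if res.fun <= vals[k] else float(grid[k])
    except Exception:
        a, b, s = _solve_ab(d, angles)
        return ArcuateModel(a=a, b=b, c=1.0, r0=r0, fallback_linear=True,
                            rms_residual=float(np.sqrt(s / radii.size)))
    a, b, s = _solve_ab(np.exp(c_best * logd), angles)
    return ArcuateModel(a=a, b=b, c=c_best, r0=r0,
                        rms_residual=float(np.sqrt(s / radii.size)))


def beta_from_model(model: ArcuateModel, r) -> np.ndarray | float:
    """Skew angle beta (deg) of a trajectory at radius r.

    ``tan(beta) = r * dphi/dr`` with phi in radians; |beta| < 90 deg.
    """
    rr = np.asarray(r, dtype=float)
    if np.any(rr < model.r0 - 1e-12):
        raise GeometryError("beta undefined for r < r0")
    dphi = np.deg2rad(model.dphi_dr(rr))
    out = np.degrees(np.arctan(rr * dphi))
    return float(out) if np.isscalar(r) else out


# ---------------------------------------------------------------------------
# skew map
# ---------------------------------------------------------------------------


def _hemisphere_interp(theta_grid, node_angles, node_values):
    """Linear interpolation with clamped ends inside one hemisphere."""
    order = np.argsort(node_angles)
    return np.interp(theta_grid, node_angles[order], node_values[order])


def beta_field(
    trajectory: TrajectoryMap, radii: np.ndarray, n_theta: int
) -> np.ndarray:
    """Skew angle beta (deg) on the full (ring x angle) grid.

    At each ring, beta is evaluated analytically on the 32 track centrelines
    of each hemisphere (mean of the two border derivatives) plus the two
    hemisphere border lines, then linearly interpolated in angle within each
    hemisphere with clamped ends.
    """
    radii = np.asarray(radii, dtype=float)
    theta = np.arange(n_theta) * (360.0 / n_theta)
    cl_ang = trajectory.centerline_angles(radii)  # (64, n_r)
    cl_dphi = np.deg2rad(trajectory.centerline_dphi(radii))
    cl_beta = np.degrees(np.arctan(radii[None, :] * cl_dphi))
    b0 = trajectory.boundaries[0]
    b32 = trajectory.boundaries[N_TRACKS_PER_HEMISPHERE]
    bd0 = np.degrees(np.arctan(radii * np.deg2rad(b0.dphi_dr(radii))))
    bd32 = np.degrees(np.arctan(radii * np.deg2rad(b32.dphi_dr(radii))))

    sup_mask = theta <= 180.0
    out = np.empty((radii.size, n_theta))
    for i in range(radii.size):
        nodes_s = np.concatenate([[0.0], cl_ang[:N_TRACKS_PER_HEMISPHERE, i], [180.0]])
        vals_s = np.concatenate([[bd0[i]], cl_beta[:N_TRACKS_PER_HEMISPHERE, i], [bd32[i]]])
        nodes_i = np.concatenate([[180.0], cl_ang[N_TRACKS_PER_HEMISPHERE:, i], [360.0]])
        vals_i = np.concatenate([[bd32[i]], cl_beta[N_TRACKS_PER_HEMISPHERE:, i], [bd0[i]]])
        out[i, sup_mask] = _hemisphere_interp(theta[sup_mask], nodes_s, vals_s)
        out[i, ~sup_mask] = _hemisphere_interp(theta[~sup_mask], nodes_i, vals_i)
    return out


def build_skew_map(
    trajectory: TrajectoryMap, radii: np.ndarray, n_theta: int
) -> PolarAnnulusMap:
    """cos(beta) map derived from a trajectory map (the "skew map")."""
    beta = beta_field(trajectory, np.asarray(radii, dtype=float), n_theta)
    return PolarAnnulusMap(
        radii=np.asarray(radii, dtype=float),
        values=np.cos(np.radians(beta)),
        quantity="cos_beta",
    )


# ---------------------------------------------------------------------------
# iteration
# ---------------------------------------------------------------------------


@dataclass
class TraceResult:
    trajectory: TrajectoryMap
    skew: PolarAnnulusMap  # cos beta
    beta: np.ndarray  # (n_r, n_theta) deg
    boundary_samples: np.ndarray  # (64, n_r) raw division angles, last iteration
    deltas: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False
    diverged: bool = False


def _divide_all_rings(
    thickness: PolarAnnulusMap,
    cos_beta_vals: np.ndarray,
    gamma_vals: np.ndarray,
) -> np.ndarray:
    """Equal-flux boundary angles for all rings, shape (64, n_r)."""
    n_r = thickness.radii.size
    n_theta = thickness.n_theta
    dens = (
        thickness.values / UM_PER_MM
        * gamma_vals * cos_beta_vals
        * thickness.radii[:, None] * (np.pi / 180.0)
    )  # flux per degree
    bnd = np.empty((N_BOUNDARIES, n_r))
    for i in range(n_r):
        sup = divide_equal_flux(dens[i], n_theta, hemisphere=(0.0, 180.0))
        inf = divide_equal_flux(dens[i], n_theta, hemisphere=(180.0, 360.0))
        bnd[:N_TRACKS_PER_HEMISPHERE, i] = sup[:-1]  # 0 .. boundary 31
        bnd[N_TRACKS_PER_HEMISPHERE:, i] = inf[:-1]  # 180 .. boundary 63
    return bnd


def _fit_all_boundaries(bnd: np.ndarray, radii: np.ndarray, r0: float) -> TrajectoryMap:
    models: list[ArcuateModel] = []
    for k in range(N_BOUNDARIES):
        if k == 0:
            models.append(ArcuateModel(a=0.0, b=0.0, c=1.0, r0=r0, zero_b=True))
        elif k == N_TRACKS_PER_HEMISPHERE:
            models.append(ArcuateModel(a=180.0, b=0.0, c=1.0, r0=r0, zero_b=True))
        else:
            models.append(fit_arcuate_model(radii, bnd[k], r0=r0))
    return TrajectoryMap(models)


def trace_iterate(
    thickness: PolarAnnulusMap,
    gamma: PolarAnnulusMap | None = None,
    tol_deg: float = 0.01,
    max_iter: int = 50,
    r0: float = R0_MM,
    initial_beta: np.ndarray | None = None,
) -> TraceResult:
    """Run the iterative equal-flux tracing algorithm on a registered map.

    Starting from ``beta = 0``, alternate equal-flux division, per-boundary
    arcuate-model fitting and skew-map reconstruction until the skew angle
    changes by less than ``tol_deg`` (default 0.01 deg) anywhere on the
    (ring x angle) grid, or ``max_iter`` is reached.  A divergence guard
    stops the loop if the change grows three iterations in a row.
    """
    radii = thickness.radii
    n_theta = thickness.n_theta
    gamma_vals = gamma.values if gamma is not None else np.ones_like(thickness.values)
    if gamma is not None and gamma.values.shape != thickness.values.shape:
        raise TraceError("gamma map grid does not match the thickness map")

    if initial_beta is not None:
        beta_prev = np.asarray(initial_beta, dtype=float).copy()
        if beta_prev.shape != (radii.size, n_theta):
            raise TraceError("initial beta grid does not match the thickness map")
    else:
        beta_prev = np.zeros((radii.size, n_theta))
    deltas: list[float] = []
    traj = None
    bnd = None
    beta_new = beta_prev
    converged = False
    diverged = False
    it = 0
    for it in range(1, max_iter + 1):
        cosb = np.cos(np.radians(beta_prev))
        bnd = _divide_all_rings(thickness, cosb, gamma_vals)
        traj = _fit_all_boundaries(bnd, radii, r0)
        beta_new = beta_field(traj, radii, n_theta)
        delta = float(np.max(np.abs(beta_new - beta_prev)))
        deltas.append(delta)
        if it >= 2 and delta < tol_deg:
            converged = True
            beta_prev = beta_new
            break
        if len(deltas) >= 4 and deltas[-1] > deltas[-2] > deltas[-3] > deltas[-4]:
            diverged = True
            break
        beta_prev = beta_new

    skew = PolarAnnulusMap(radii=radii.copy(), values=np.cos(np.radians(beta_prev)),
                           quantity="cos_beta")
    return TraceResult(
        trajectory=traj,
        skew=skew,
        beta=beta_prev,
        boundary_samples=bnd,
        deltas=deltas,
        n_iterations=it,
        converged=converged,
        diverged=diverged,
    )
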