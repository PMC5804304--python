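"""Synthetic eyes with known ground truth.

Every stage of the pipeline is testable against this generator: it builds a
family of arcuate track trajectories, synthesises a thickness map whose flux
is exactly conserved along those tracks (up to the macular ganglion-cell
termination schedule and any wedge defects), renders the map both on the
polar analysis grid and as a Cartesian fundus map, and returns the ground
truth alongside.

Construction on each ring: track ``n`` of angular width ``w_n(r)`` carries
flux ``Phi_n(r) = Phi_n * (1 - f_n(r)) * defect_scale``, so the thickness is
``T = dPhi/dtheta / (r cos(beta))``.  The per-bin flux is integrated exactly
from the piecewise-constant track densities, so total ring flux is conserved
to machine precision before noise; smoothing with a narrow periodic kernel
happens on the flux density (sum-preserving) before the termination and
defect factors, keeping the generator an exact oracle for the tracer.

The thickness map shows the classic double-hump profile (thick
superotemporal/inferotemporal bundles) because track widths follow a
double-hump angular density while per-track flux stays equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .compensation import (
    RgcDensityModel,
    termination_field,
    track_termination_fractions,
)
from .geometry import (
    DEFAULT_N_THETA,
    DEFAULT_RADII,
    N_BOUNDARIES,
    N_TRACKS,
    N_TRACKS_PER_HEMISPHERE,
    ArcuateModel,
    CartesianMap,
    EyeMeta,
    GeometryError,
    PolarAnnulusMap,
    R0_MM,
    TrajectoryMap,
    physical_to_canonical,
)
from .preprocess import NODAL_OFFSET_MM, REFERENCE_AXIAL_LENGTH_MM
from .tracing import build_skew_map

__all__ = [
    "TrajectoryFamilyParams",
    "SyntheticEyeSpec",
    "SyntheticEye",
    "default_family",
    "generate_eye",
    "generate_cohort",
]


# ---------------------------------------------------------------------------
# trajectory family
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryFamilyParams:
    """Parameters of the normative synthetic trajectory family.

    Track widths follow a double-hump angular density (von-Mises-shaped
    bumps at the superotemporal and inferotemporal bundle positions); the
    arcuate curvature amplitude ``b`` peaks in the arcuate bundles and
    vanishes nasally, where fibers run radially.
    """

    bump_height: float = 2.2
    bump_kappa: float = 5.25  # ~25 deg angular SD
    bump_centers: tuple[float, float] = (120.0, 240.0)
    arc_b_max: float = 4.0  # deg / mm^c curvature amplitude
    arc_center: float = 115.0  # deg from the nasal midline
    arc_width: float = 55.0
    c_base: float = 1.2
    c_bump: float = 0.6
    c_width: float = 50.0
    r0: float = R0_MM

    def width_density(self, theta: np.ndarray) -> np.ndarray:
        th = np.radians(np.asarray(theta, dtype=float))
        g = np.ones_like(th)
        for c0 in self.bump_centers:
            g += self.bump_height * np.exp(
                self.bump_kappa * (np.cos(th - np.radians(c0)) - 1.0)
            )
        return g

    def _elevation(self, a: np.ndarray) -> np.ndarray:
        """Angular distance from the nasal midline, in [0, 180]."""
        a = np.asarray(a, dtype=float) % 360.0
        return np.where(a <= 180.0, a, 360.0 - a)

    def b_of(self, a: np.ndarray) -> np.ndarray:
        u = self._elevation(a)
        mag = self.arc_b_max * np.exp(-(((u - self.arc_center) / self.arc_width) ** 2))
        sign = np.where((np.asarray(a) % 360.0) <= 180.0, 1.0, -1.0)
        return sign * mag

    def c_of(self, a: np.ndarray) -> np.ndarray:
        u = self._elevation(a)
        return self.c_base + self.c_bump * np.exp(-(((u - self.arc_center) / self.c_width) ** 2))


def _anchor_angles(params: TrajectoryFamilyParams) -> np.ndarray:
    """64 boundary anchor angles from the width density (equal-flux at r0)."""
    anchors = np.empty(N_BOUNDARIES)
    for h, (lo, hi) in enumerate(((0.0, 180.0), (180.0, 360.0))):
        th = np.linspace(lo, hi, 20_001)
        g = params.width_density(th)
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (g[1:] + g[:-1]) * np.diff(th))])
        targets = cum[-1] * np.arange(N_TRACKS_PER_HEMISPHERE) / N_TRACKS_PER_HEMISPHERE
        anchors[h * N_TRACKS_PER_HEMISPHERE:(h + 1) * N_TRACKS_PER_HEMISPHERE] = np.interp(
            targets, cum, th
        )
    return anchors


def _family_from_anchors(anchors: np.ndarray, params: TrajectoryFamilyParams) -> TrajectoryMap:
    models = []
    for k, a in enumerate(anchors):
        if k == 0:
            models.append(ArcuateModel(a=0.0, b=0.0, c=1.0, r0=params.r0, zero_b=True))
        elif k == N_TRACKS_PER_HEMISPHERE:
            models.append(ArcuateModel(a=180.0, b=0.0, c=1.0, r0=params.r0, zero_b=True))
        else:
            models.append(ArcuateModel(
                a=float(a), b=float(params.b_of(a)), c=float(params.c_of(a)), r0=params.r0
            ))
    return TrajectoryMap(models)


def default_family(params: TrajectoryFamilyParams | None = None) -> TrajectoryMap:
    """The canonical (population-mean) synthetic trajectory family."""
    params = params or TrajectoryFamilyParams()
    return _family_from_anchors(_anchor_angles(params), params)


def _smooth_warp(rng: np.random.Generator, sd_deg: float, n_modes: int = 3):
    """Random smooth angular warp vanishing at the hemisphere borders.

    A low-order sine series in the anchor angle with pointwise variance
    ``sd_deg**2`` on average; smoothness preserves boundary ordering.
    """
    coef = rng.normal(0.0, sd_deg * np.sqrt(2.0 / n_modes), size=n_modes)

    def warp(a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        out = np.zeros_like(a)
        for k, ck in enumerate(coef, start=1):
            out += ck * np.sin(k * np.pi * a / 180.0)
        return out

    return warp


def _jittered_family(
    family_params: TrajectoryFamilyParams,
    rng: np.random.Generator,
    jitter_sd_deg: float,
    radii_check: np.ndarray,
    jitter_ref_radius: float = 3.5,
) -> TrajectoryMap:
    """Family with inter-eye variability that grows with radius.

    Individual eyes agree closely at the anchor circle and diverge outward
    (population variability of trajectory positions increases with radial
    distance from the disc), so the jitter perturbs each boundary's
    curvature coefficient ``b`` such that the boundary angle at the
    reference radius (outermost ring) shifts by a smooth random field with
    pointwise SD ``jitter_sd_deg``.
    """
    anchors = _anchor_angles(family_params)
    base = _family_from_anchors(anchors, family_params)
    if jitter_sd_deg <= 0:
        return base
    for _ in range(50):
        warp = _smooth_warp(rng, jitter_sd_deg)
        shift = warp(anchors)  # boundary shift at the reference radius, deg
        models = []
        for k, m in enumerate(base.boundaries):
            if k in (0, N_TRACKS_PER_HEMISPHERE):
                models.append(m)
                continue
            db = shift[k] / (jitter_ref_radius - m.r0) ** m.c
            models.append(ArcuateModel(a=m.a, b=m.b + db, c=m.c, r0=m.r0))
        traj = TrajectoryMap(models)
        if traj.validate_non_crossing(radii_check):
            return traj
    raise GeometryError("could not draw a non-crossing jittered trajectory")


# ---------------------------------------------------------------------------
# eye specification
# ---------------------------------------------------------------------------


@dataclass
class SyntheticEyeSpec:
    """Everything needed to synthesise one eye, with reproducible seeding."""

    seed: int = 0
    laterality: str = "right"
    axial_length: float = REFERENCE_AXIAL_LENGTH_MM
    mpa_angle: float | None = None  # deg; None -> draw N(6.8, 3.1)
    disc_fovea_distance: float = 4.0  # mm
    family: TrajectoryFamilyParams = field(default_factory=TrajectoryFamilyParams)
    jitter_sd_deg: float = 0.0
    overall_flux_mm2: float = 1.5  # equal per-track flux by default
    track_flux_mm2: np.ndarray | None = None  # (64,) overrides overall_flux
    macular_termination: bool = True
    rgc: RgcDensityModel = field(default_factory=RgcDensityModel)
    defects: list[tuple[int, int, float]] = field(default_factory=list)  # (lo, hi, scale) inclusive tracks
    noise_sd_um: float = 2.0
    radii: np.ndarray = field(default_factory=lambda: DEFAULT_RADII.copy())
    n_theta: int = DEFAULT_N_THETA
    smoothing_fwhm_deg: float = 1.4
    cartesian_n: int = 320  # 8 x 8 mm grid
    radial_margin_mm: float = 0.1

    def __post_init__(self) -> None:
        for lo, hi, scale in self.defects:
            if not (0 < scale <= 1):
                raise GeometryError("defect scale factors must lie in (0, 1]")
            if not (0 <= lo <= hi < N_TRACKS):
                raise GeometryError("defect track range out of bounds")


@dataclass
class SyntheticEye:
    """A generated eye: measured-like maps plus full ground truth."""

    spec: SyntheticEyeSpec
    meta: EyeMeta
    polar_thickness: PolarAnnulusMap  # registered canonical, analysis radii
    cartesian_thickness: CartesianMap  # raw fundus frame, nominal (uncorrected) mm
    truth_trajectory: TrajectoryMap
    truth_track_flux: np.ndarray  # (64,) mm^2, pre-termination / pre-defect
    truth_termination: np.ndarray  # (n_r, n_theta) terminated fraction field
    truth_cos_beta: PolarAnnulusMap
    mpa_angle: float


def _exact_bin_flux(bounds: np.ndarray, track_flux: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Per-bin flux from piecewise-constant track densities, integrated exactly.

    ``bounds``: 64 ascending boundary angles starting at 0; ``edges``:
    ascending bin-edge angles covering [0, 360].
    """
    b = np.concatenate([bounds, [360.0]])
    cum_tracks = np.concatenate([[0.0], np.cumsum(track_flux)])
    k = np.clip(np.searchsorted(b, edges, side="right") - 1, 0, N_TRACKS - 1)
    width = b[k + 1] - b[k]
    cum = cum_tracks[k] + track_flux[k] * (edges - b[k]) / width
    return np.diff(cum)


def _apply_wedge(dens: np.ndarray, step: float, lo_a: float, hi_a: float,
                 scale: float) -> np.ndarray:
    """Multiply a per-degree density by a sharp wedge mask, conservatively.

    Samples are bin averages; a cut angle falling mid-bin cannot be split
    correctly by any bin-average reader, so the edge bin's allocation
    deficit is shifted into its neighbour such that the bin-linear
    cumulative is exact at both cut angles *and* within-wedge totals scale
    exactly.  This leaves a one-bin rim at each edge (like the steep wall of
    a real wedge defect) instead of a smeared edge.
    """
    n = dens.size
    orig = dens.copy()
    # fractional overlap of each bin with the wedge (angle space, wrap-safe)
    e_lo = (np.arange(n) - 0.5) * step
    ov = np.zeros(n)
    for off in (-360.0, 0.0, 360.0):
        a, b = lo_a + off, hi_a + off
        ov += np.clip(np.minimum(e_lo + step, b) - np.maximum(e_lo, a), 0.0, step)
    ov = np.clip(ov / step, 0.0, 1.0)
    out = orig * (1.0 - (1.0 - scale) * ov)
    if (hi_a - lo_a) % 360.0 < 3 * step:  # degenerate sliver: mask only
        return out

    def bin_of(angle):
        k = int(np.floor(angle / step + 0.5)) % n
        x = (angle - (k - 0.5) * step) % 360.0
        return k, x

    # lower cut: healthy below, defect above
    k, x = bin_of(lo_a % 360.0)
    delta = orig[k] * x * (1.0 - scale) / step  # in per-degree units of bin flux
    out[k] -= delta
    out[(k - 1) % n] += delta
    # upper cut: defect below, healthy above
    k, x = bin_of(hi_a % 360.0)
    delta = orig[k] * x * (1.0 - scale) / step
    out[k] += delta
    j = (k - 1) % n
    while delta > 0:
        take = min(delta, out[j])
        out[j] -= take
        delta -= take
        j = (j - 1) % n
    return out


def generate_eye(spec: SyntheticEyeSpec) -> SyntheticEye:
    """Synthesise one eye from its specification (deterministic per seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    radii = np.asarray(spec.radii, dtype=float)
    n_theta = spec.n_theta
    step = 360.0 / n_theta

    traj = _jittered_family(spec.family, rng, spec.jitter_sd_deg, radii)
    mpa = spec.mpa_angle if spec.mpa_angle is not None else float(rng.normal(6.8, 3.1))
    mpa = float(np.clip(mpa, -25.0, 25.0))

    track_flux = (
        np.asarray(spec.track_flux_mm2, dtype=float)
        if spec.track_flux_mm2 is not None
        else np.full(N_TRACKS, spec.overall_flux_mm2 / N_TRACKS)
    )

    # extended radial grid so the Cartesian rendering has support just
    # outside the analysis annulus
    dr = float(np.min(np.diff(radii)))
    radii_ext = np.round(np.concatenate([
        [radii[0] - spec.radial_margin_mm], radii, [radii[-1] + spec.radial_margin_mm]
    ]), 10)
    inner_rows = slice(1, 1 + radii.size)

    bnd = traj.boundary_angles(radii_ext) % 360.0  # (64, n_ext)
    bnd[0] = 0.0
    edges = np.arange(n_theta + 1) * step - 0.5 * step  # bin edges around samples
    dens = np.empty((radii_ext.size, n_theta))
    for i in range(radii_ext.size):
        b = np.sort(bnd[:, i])
        # shift edges into [b0, b0+360) by periodicity of the density
        e = edges.copy()
        flux_bins = _exact_bin_flux(b, track_flux, np.clip(e, 0.0, 360.0))
        # first bin straddles 0/360: add the wrapped part [359.82.., 360]
        wrap = _exact_bin_flux(b, track_flux, np.array([360.0 + e[0], 360.0]))
        flux_bins[0] += wrap[0]
        dens[i] = flux_bins / step  # flux per degree

    # sum-preserving periodic smoothing of the flux density
    if spec.smoothing_fwhm_deg > 0:
        sigma = spec.smoothing_fwhm_deg / 2.3548200450309493 / step
        dens = ndimage.gaussian_filter1d(dens, sigma, axis=1, mode="wrap")

    # macular termination schedule (shared with the compensation module)
    if spec.macular_termination:
        frac = track_termination_fractions(
            traj, spec.rgc, radii_ext,
            disc_fovea_distance=spec.disc_fovea_distance,
            r_inner=float(radii.min()),
        )
        f_field_ext = termination_field(traj, frac, radii_ext, n_theta)
    else:
        f_field_ext = np.zeros_like(dens)
    dens = dens * (1.0 - f_field_ext)

    # wedge defects: sharp multiplicative loss within the tracks' true spans,
    # rasterized conservatively (see _apply_wedge)
    for lo, hi, scale in spec.defects:
        for i in range(radii_ext.size):
            lo_a = bnd[lo, i]
            hi_a = bnd[(hi + 1) % N_TRACKS, i] if hi + 1 < N_TRACKS else 360.0
            dens[i] = _apply_wedge(dens[i], step, lo_a, hi_a, scale)

    cosb_ext = build_skew_map(traj, radii_ext, n_theta).values
    t_um = dens * (180.0 / np.pi) / (radii_ext[:, None] * cosb_ext) * 1000.0

    if spec.noise_sd_um > 0:
        t_um = t_um + rng.normal(0.0, spec.noise_sd_um, size=t_um.shape)
    t_um = np.maximum(t_um, 0.0)

    polar = PolarAnnulusMap(radii=radii.copy(), values=t_um[inner_rows].copy(),
                            quantity="thickness_um")

    # --- metadata and Cartesian rendering -------------------------------
    d = spec.disc_fovea_distance
    mrad = np.radians(mpa)
    if spec.laterality == "right":
        fovea = (-d * np.cos(mrad), -d * np.sin(mrad))
    else:
        fovea = (d * np.cos(mrad), -d * np.sin(mrad))
    meta_true = EyeMeta(
        laterality=spec.laterality, axial_length=spec.axial_length,
        disc_center=(0.0, 0.0), fovea_center=fovea,
    )
    cart_true = _render_cartesian(t_um, radii_ext, spec, meta_true, mpa)

    # optical magnification: an eye longer than the reference is imaged with
    # a nominally too-small pixel pitch; preprocessing undoes this
    s = (spec.axial_length - NODAL_OFFSET_MM) / (REFERENCE_AXIAL_LENGTH_MM - NODAL_OFFSET_MM)
    cart_nominal = CartesianMap(
        values=cart_true.values, pitch=cart_true.pitch / s,
        origin=(cart_true.origin[0] / s, cart_true.origin[1] / s),
        quantity="thickness_um",
    )
    meta_nominal = replace(
        meta_true,
        disc_center=(0.0, 0.0),
        fovea_center=(fovea[0] / s, fovea[1] / s),
    )

    return SyntheticEye(
        spec=spec,
        meta=meta_nominal,
        polar_thickness=polar,
        cartesian_thickness=cart_nominal,
        truth_trajectory=traj,
        truth_track_flux=track_flux,
        truth_termination=f_field_ext[inner_rows].copy(),
        truth_cos_beta=PolarAnnulusMap(radii=radii.copy(),
                                       values=cosb_ext[inner_rows].copy(),
                                       quantity="cos_beta"),
        mpa_angle=mpa,
    )


def _render_cartesian(
    t_um: np.ndarray,
    radii_ext: np.ndarray,
    spec: SyntheticEyeSpec,
    meta: EyeMeta,
    mpa: float,
) -> CartesianMap:
    """Render the polar truth onto a raw-frame 8 x 8 mm Cartesian grid."""
    n = spec.cartesian_n
    pitch = 8.0 / n
    coords = (np.arange(n) - (n - 1) / 2.0) * pitch
    x, y = np.meshgrid(coords, coords)  # row = y
    r = np.hypot(x, y)
    if meta.laterality == "right":
        psi = np.degrees(np.arctan2(y, x)) % 360.0
    else:
        psi = np.degrees(np.arctan2(y, -x)) % 360.0
    theta = physical_to_canonical(psi, mpa)

    # bilinear interpolation in (r, theta); radial clamp, periodic in angle
    ri = np.clip((r - radii_ext[0]) / (radii_ext[1] - radii_ext[0]),
                 0.0, radii_ext.size - 1.0)
    i0 = np.floor(ri).astype(int)
    i1 = np.minimum(i0 + 1, radii_ext.size - 1)
    fr = ri - i0
    n_theta = spec.n_theta
    tj = theta / (360.0 / n_theta)
    j0 = np.floor(tj).astype(int) % n_theta
    j1 = (j0 + 1) % n_theta
    ft = tj - np.floor(tj)
    vals = (
        t_um[i0, j0] * (1 - fr) * (1 - ft)
        + t_um[i0, j1] * (1 - fr) * ft
        + t_um[i1, j0] * fr * (1 - ft)
        + t_um[i1, j1] * fr * ft
    )
    return CartesianMap(values=vals, pitch=pitch,
                        origin=(float(coords[0]), float(coords[0])),
                        quantity="thickness_um")


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def generate_cohort(
    n_healthy: int = 24,
    n_glaucoma: int = 10,
    seed: int = 0,
    base_spec: SyntheticEyeSpec | None = None,
    jitter_sd_deg: float = 5.0,
) -> dict:
    """Generate a study cohort sharing one trajectory family.

    Healthy eyes get smooth inter-eye angular jitter; glaucoma eyes
    additionally carry one or two arcuate wedge defects with scale factors
    in (0.3, 0.6).  Returns ``{"healthy": [...], "glaucoma": [...],
    "manifest": {...}}`` with all ground truth recorded in the manifest.
    """
    base = base_spec or SyntheticEyeSpec()
    ss = np.random.SeedSequence(seed)
    eye_seeds = ss.generate_state(n_healthy + n_glaucoma + 1)
    defect_rng = np.random.default_rng(np.random.SeedSequence(int(eye_seeds[-1])))

    healthy, glaucoma = [], []
    manifest = {"seed": seed, "n_healthy": n_healthy, "n_glaucoma": n_glaucoma, "eyes": []}
    for i in range(n_healthy):
        spec = replace(base, seed=int(eye_seeds[i]) % (2**31), jitter_sd_deg=jitter_sd_deg,
                       defects=[])
        eye = generate_eye(spec)
        healthy.append(eye)
        manifest["eyes"].append(_manifest_entry("healthy", eye))
    for i in range(n_glaucoma):
        sup = bool(defect_rng.integers(0, 2))
        start = int(defect_rng.integers(16, 23)) if sup else int(defect_rng.integers(38, 45))
        length = int(defect_rng.integers(4, 9))
        scale = float(defect_rng.uniform(0.3, 0.6))
        defects = [(start, min(start + length - 1, N_TRACKS - 1), scale)]
        spec = replace(base, seed=int(eye_seeds[n_healthy + i]) % (2**31),
                       jitter_sd_deg=jitter_sd_deg, defects=defects)
        eye = generate_eye(spec)
        glaucoma.append(eye)
        manifest["eyes"].append(_manifest_entry("glaucoma", eye))
    return {"healthy": healthy, "glaucoma": glaucoma, "manifest": manifest}


def _manifest_entry(group: str, eye: SyntheticEye) -> dict:
    return {
        "group": group,
        "seed": eye.spec.seed,
        "laterality": eye.spec.laterality,
        "mpa_angle": eye.mpa_angle,
        "axial_length": eye.spec.axial_length,
        "defects": [list(d) for d in eye.spec.defects],
        "noise_sd_um": eye.spec.noise_sd_um,
        "track_flux_mm2": eye.truth_track_flux.tolist(),
        "trajectory": eye.truth_trajectory.to_dict(),
    }
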