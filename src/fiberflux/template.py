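"""Normative trajectory template and reference flux distributions.

Per-eye traced trajectories (registered, laterality-normalized,
magnification-corrected) are averaged boundary-wise in angle space at the
shared sampling radii and refit to the arcuate model, which also lets the
template be extrapolated inward to the anchor circle and slightly outward of
the measured annulus.  Normative per-track and per-sector flux references
are empirical (mean, SD and 5th percentile) over the healthy cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    DEFAULT_N_THETA,
    DEFAULT_RADII,
    N_BOUNDARIES,
    N_TRACKS_PER_HEMISPHERE,
    ArcuateModel,
    FluxTable,
    GeometryError,
    PolarAnnulusMap,
    TrajectoryMap,
)
from .tracing import build_skew_map, fit_arcuate_model

__all__ = [
    "NormativeTemplate",
    "NormativeFlux",
    "average_trajectories",
    "extrapolate_model",
    "build_normative_flux",
    "EXTRAPOLATION_MARGIN_MM",
]

#: Outward extrapolation margin past the outermost fitted ring (mm).
EXTRAPOLATION_MARGIN_MM = 0.5


@dataclass
class NormativeTemplate:
    """Population-average trajectory map with per-boundary variability."""

    trajectory: TrajectoryMap
    radii: np.ndarray
    boundary_sd: np.ndarray  # (64, n_r) angular SD across eyes, deg
    n_eyes: int
    gamma_provenance: dict | None = None
    config_hash: str | None = None

    def cos_beta_map(self, n_theta: int = DEFAULT_N_THETA) -> PolarAnnulusMap:
        return build_skew_map(self.trajectory, self.radii, n_theta)

    def outer_sd_summary(self) -> np.ndarray:
        """Per-boundary angular SD at the outermost radius (deg)."""
        return self.boundary_sd[:, -1]

    def to_dict(self) -> dict:
        return {
            "trajectory": self.trajectory.to_dict(),
            "radii": self.radii.tolist(),
            "boundary_sd": self.boundary_sd.tolist(),
            "n_eyes": self.n_eyes,
            "gamma_provenance": self.gamma_provenance,
            "config_hash": self.config_hash,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeTemplate":
        return cls(
            trajectory=TrajectoryMap.from_dict(d["trajectory"]),
            radii=np.asarray(d["radii"], dtype=float),
            boundary_sd=np.asarray(d["boundary_sd"], dtype=float),
            n_eyes=int(d["n_eyes"]),
            gamma_provenance=d.get("gamma_provenance"),
            config_hash=d.get("config_hash"),
        )


def average_trajectories(
    trajectories: list[TrajectoryMap],
    radii: np.ndarray | None = None,
    config_hash: str | None = None,
) -> NormativeTemplate:
    """Average per-eye trajectory maps into a normative template.

    Averaging happens on boundary angular positions at the shared radii (not
    on the (a, b, c) parameters, which are non-linearly coupled), followed by
    a refit of the arcuate model per boundary.  Per-boundary angular SD at
    each radius is retained as the population variability summary.
    """
    if len(trajectories) < 2:
        raise GeometryError("need at least 2 eyes to build a normative template")
    radii = DEFAULT_RADII if radii is None else np.asarray(radii, dtype=float)
    angles = np.stack([t.boundary_angles(radii) for t in trajectories])  # (E, 64, n_r)
    mean = angles.mean(axis=0)
    sd = angles.std(axis=0, ddof=1)
    r0 = trajectories[0].boundaries[0].r0
    models: list[ArcuateModel] = []
    for k in range(N_BOUNDARIES):
        if k == 0:
            models.append(ArcuateModel(a=0.0, b=0.0, c=1.0, r0=r0, zero_b=True))
        elif k == N_TRACKS_PER_HEMISPHERE:
            models.append(ArcuateModel(a=180.0, b=0.0, c=1.0, r0=r0, zero_b=True))
        else:
            models.append(fit_arcuate_model(radii, mean[k], r0=r0))
    traj = TrajectoryMap(models)
    return NormativeTemplate(
        trajectory=traj, radii=radii.copy(), boundary_sd=sd,
        n_eyes=len(trajectories), config_hash=config_hash,
    )


def extrapolate_model(
    model: ArcuateModel,
    r_target: float,
    r_fit_max: float = float(DEFAULT_RADII[-1]),
    margin: float = EXTRAPOLATION_MARGIN_MM,
) -> float:
    """Evaluate the arcuate model outside the fitted annulus.

    Valid from the anchor circle ``r0`` out to ``r_fit_max + margin``
    (default 4.0 mm); beyond that, individual deviation from the population
    trajectory is amplified and evaluation is refused.
    """
    if r_target < model.r0:
        raise GeometryError(f"extrapolation target {r_target} mm below r0 = {model.r0} mm")
    cap = r_fit_max + margin
    if r_target > cap:
        raise GeometryError(
            f"extrapolation target {r_target} mm beyond the {cap:g} mm limit"
        )
    return float(model.angle(r_target))


@dataclass
class NormativeFlux:
    """Empirical per-track and per-sector reference flux distributions."""

    track_mean: np.ndarray
    track_sd: np.ndarray
    track_p5: np.ndarray
    sector_mean: np.ndarray | None = None
    sector_sd: np.ndarray | None = None
    sector_p5: np.ndarray | None = None
    sector_labels: list[str] | None = None
    overall_mean: float = 0.0
    overall_p5: float = 0.0
    n_eyes: int = 0
    config_hash: str | None = None

    def to_dict(self) -> dict:
        def tl(x):
            return None if x is None else np.asarray(x).tolist()

        return {
            "track_mean": tl(self.track_mean),
            "track_sd": tl(self.track_sd),
            "track_p5": tl(self.track_p5),
            "sector_mean": tl(self.sector_mean),
            "sector_sd": tl(self.sector_sd),
            "sector_p5": tl(self.sector_p5),
            "sector_labels": self.sector_labels,
            "overall_mean": self.overall_mean,
            "overall_p5": self.overall_p5,
            "n_eyes": self.n_eyes,
            "config_hash": self.config_hash,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeFlux":
        def arr(x):
            return None if x is None else np.asarray(x, dtype=float)

        return cls(
            track_mean=arr(d["track_mean"]), track_sd=arr(d["track_sd"]),
            track_p5=arr(d["track_p5"]), sector_mean=arr(d.get("sector_mean")),
            sector_sd=arr(d.get("sector_sd")), sector_p5=arr(d.get("sector_p5")),
            sector_labels=d.get("sector_labels"),
            overall_mean=float(d.get("overall_mean", 0.0)),
            overall_p5=float(d.get("overall_p5", 0.0)),
            n_eyes=int(d.get("n_eyes", 0)), config_hash=d.get("config_hash"),
        )


def build_normative_flux(
    healthy_tables: list[FluxTable],
    config_hash: str | None = None,
) -> NormativeFlux:
    """Mean, SD and 5th percentile of track/sector flux over healthy eyes.

    The 5th percentile is the linear-interpolated empirical order statistic
    (numpy's default), preferred over ``mean - 1.645 SD`` for small-cohort
    robustness.
    """
    if len(healthy_tables) < 2:
        raise GeometryError("need at least 2 eyes for a normative reference")
    tracks = np.stack([t.track_flux for t in healthy_tables])  # (E, 64)
    out = NormativeFlux(
        track_mean=tracks.mean(axis=0),
        track_sd=tracks.std(axis=0, ddof=1),
        track_p5=np.percentile(tracks, 5.0, axis=0),
        n_eyes=len(healthy_tables),
        config_hash=config_hash,
    )
    overall = np.array([t.overall_flux for t in healthy_tables])
    out.overall_mean = float(overall.mean())
    out.overall_p5 = float(np.percentile(overall, 5.0))
    if healthy_tables[0].sector_flux is not None:
        sectors = np.stack([t.sector_flux for t in healthy_tables])
        out.sector_mean = sectors.mean(axis=0)
        out.sector_sd = sectors.std(axis=0, ddof=1)
        out.sector_p5 = np.percentile(sectors, 5.0, axis=0)
        out.sector_labels = healthy_tables[0].sector_labels
    return out
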