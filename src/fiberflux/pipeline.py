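"""End-to-end orchestration: simulate -> preprocess -> trace -> gamma ->
template -> analyze.

Building a normative template requires healthy eyes only; diseased eyes are
never traced (flux conservation does not hold in them) -- they receive the
healthy template and are quantified against the normative reference.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

from .compensation import RgcDensityModel, compensation_map
from .config import PipelineConfig, config_hash
from .geometry import PolarAnnulusMap
from .io import save_json, save_polar
from .preprocess import magnification_correct, resample_polar
from .sectors import SectorScheme, classify_sectors, deviation_map, nff_per_track, propagate_sectors
from .synthetic import SyntheticEye, SyntheticEyeSpec, default_family, generate_cohort
from .template import average_trajectories, build_normative_flux
from .tracing import trace_iterate

__all__ = ["run_pipeline", "preprocess_eye", "analyze_eye", "build_reference_gamma"]

log = logging.getLogger("fiberflux")


def preprocess_eye(eye: SyntheticEye, config: PipelineConfig) -> PolarAnnulusMap:
    """Magnification-correct and polar-resample one eye's Cartesian map."""
    cart, meta = magnification_correct(eye.cartesian_thickness, eye.meta)
    return resample_polar(cart, meta, radii=config.grid.radii, n_theta=config.grid.n_theta)


def build_reference_gamma(config: PipelineConfig) -> PolarAnnulusMap:
    """Compensation coefficient map from the canonical reference trajectory.

    Like the published procedure, gamma is derived once from a literature-
    style average trajectory and a parametric RGC density model, then used
    for tracing every healthy eye.
    """
    comp = config.compensation
    rgc = RgcDensityModel(
        peak_density=comp.rgc.peak_density,
        pit_radius=comp.rgc.pit_radius_mm,
        peak_radius=comp.rgc.peak_radius_mm,
        decay_scale=comp.rgc.decay_scale_mm,
    )
    return compensation_map(
        default_family(), rgc, config.grid.radii, config.grid.n_theta,
        disc_fovea_distance=comp.disc_fovea_distance_mm,
        zone=tuple(comp.zone_deg), r_allowance=comp.r_allowance_mm,
        peripheral_fiber_fraction=comp.peripheral_fiber_fraction,
    )


def analyze_eye(polar, template, sector_geometry, normative, config, chash) -> dict:
    """Per-eye report: flux table, sector classification, deviations."""
    table = nff_per_track(polar, template, sector_geometry,
                          ring_aggregation=config.normative.ring_aggregation)
    report = {"flux": table.to_dict(), "config_hash": chash,
              "anchor_angles_deg": list(config.sectors.anchor_angles_deg)}
    if normative is not None:
        report["classification"] = classify_sectors(table, normative, config_hash=chash)
        dev, _ = deviation_map(table.track_flux, normative.track_mean)
        report["track_deviation_percent"] = dev.tolist()
    return report


def run_pipeline(
    config: PipelineConfig | None = None,
    out_dir: str | Path = "nff_run",
    seed: int = 0,
) -> dict:
    """Run the full synthetic-cohort pipeline and write the artifact tree.

    Deterministic for a fixed (config, seed).  Writes the normative template,
    the normative flux reference and one report per eye; stage timings and
    convergence diagnostics go to a separate log file so reports are
    byte-identical across reruns.
    """
    config = config or PipelineConfig()
    chash = config_hash(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    diagnostics: dict[str, object] = {}

    def stage(name):
        log.info("stage: %s", name)
        return time.perf_counter()

    t0 = stage("simulate")
    syn = config.synthetic
    base = SyntheticEyeSpec(
        overall_flux_mm2=syn.overall_flux_mm2,
        macular_termination=syn.macular_termination,
        noise_sd_um=syn.noise_sd_um,
        radii=config.grid.radii, n_theta=config.grid.n_theta,
        cartesian_n=syn.cartesian_n,
    )
    cohort = generate_cohort(syn.n_healthy, syn.n_glaucoma, seed=seed,
                             base_spec=base, jitter_sd_deg=syn.jitter_sd_deg)
    save_json(out / "manifest.json", cohort["manifest"])
    timings["simulate"] = time.perf_counter() - t0

    t0 = stage("preprocess")
    healthy_polar = [preprocess_eye(e, config) for e in cohort["healthy"]]
    glaucoma_polar = [preprocess_eye(e, config) for e in cohort["glaucoma"]]
    timings["preprocess"] = time.perf_counter() - t0

    t0 = stage("gamma")
    gamma = build_reference_gamma(config)
    save_polar(out / "gamma.csv", gamma)
    timings["gamma"] = time.perf_counter() - t0

    t0 = stage("trace")
    traces = []
    for i, polar in enumerate(healthy_polar):
        res = trace_iterate(polar, gamma=gamma, tol_deg=config.trace.tol_deg,
                            max_iter=config.trace.max_iter, r0=config.trace.r0_mm)
        traces.append(res)
        log.info("traced healthy eye %d: %d iterations, converged=%s",
                 i, res.n_iterations, res.converged)
    diagnostics["trace"] = [
        {"eye": i, "iterations": r.n_iterations, "converged": r.converged,
         "final_delta_deg": r.deltas[-1] if r.deltas else None}
        for i, r in enumerate(traces)
    ]
    timings["trace"] = time.perf_counter() - t0

    t0 = stage("template")
    template = average_trajectories([r.trajectory for r in traces],
                                    radii=config.grid.radii, config_hash=chash)
    template.gamma_provenance = {"source": "canonical reference trajectory",
                                 "rgc": config.compensation.rgc.model_dump()}
    scheme = SectorScheme(anchor_diameter=config.sectors.anchor_diameter_mm,
                          anchor_angles=tuple(config.sectors.anchor_angles_deg),
                          labels=tuple(config.sectors.labels))
    geometry = propagate_sectors(template, scheme)
    tables = [nff_per_track(p, template, geometry,
                            ring_aggregation=config.normative.ring_aggregation)
              for p in healthy_polar]
    normative = build_normative_flux(tables, config_hash=chash)
    save_json(out / "template.json", {
        "template": template.to_dict(), "scheme": scheme.to_dict(),
        "normative_flux": normative.to_dict(), "config_hash": chash,
    })
    timings["template"] = time.perf_counter() - t0

    t0 = stage("analyze")
    reports = {"healthy": [], "glaucoma": []}
    for group, polars in (("healthy", healthy_polar), ("glaucoma", glaucoma_polar)):
        for i, polar in enumerate(polars):
            rep = analyze_eye(polar, template, geometry, normative, config, chash)
            reports[group].append(rep)
            save_json(out / f"report_{group}_{i:02d}.json", rep)
    timings["analyze"] = time.perf_counter() - t0

    save_json(out / "pipeline_log.json",
              {"timings_s": timings, "diagnostics": diagnostics, "seed": seed,
               "config_hash": chash})
    return {
        "template": template, "normative": normative, "scheme": scheme,
        "geometry": geometry, "reports": reports, "cohort": cohort,
        "traces": traces, "gamma": gamma, "config_hash": chash, "out_dir": out,
    }
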