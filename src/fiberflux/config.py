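"""Configuration schema for the whole pipeline.

All physical constants of the analysis (reference radius r0 = 0.85 mm, ring
range 1.5-3.5 mm, 1024 angular samples, 0.01 deg convergence tolerance, the
110-270 deg compensation zone, the 1.7-mm anchor circle, the 5% normative
cutoff) live here with their standard defaults rather than being hard-coded
at call sites; outputs carry a hash of the configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    r_min_mm: float = 1.5
    r_max_mm: float = 3.5
    n_rings: int = 21
    n_theta: int = 1024

    @property
    def radii(self) -> np.ndarray:
        return np.round(np.linspace(self.r_min_mm, self.r_max_mm, self.n_rings), 10)


class TraceConfig(_Strict):
    r0_mm: float = 0.85
    tol_deg: float = 0.01
    max_iter: int = 50


class RgcConfig(_Strict):
    peak_density: float = 35_000.0
    pit_radius_mm: float = 0.15
    peak_radius_mm: float = 1.7
    decay_scale_mm: float = 1.5


class CompensationConfig(_Strict):
    zone_deg: tuple[float, float] = (110.0, 270.0)
    r_allowance_mm: float = 8.0
    disc_fovea_distance_mm: float = 4.0
    peripheral_fiber_fraction: float = 0.55
    rgc: RgcConfig = Field(default_factory=RgcConfig)


class SectorConfig(_Strict):
    anchor_diameter_mm: float = 1.7
    anchor_angles_deg: tuple[float, ...] = (0.0, 50.0, 95.0, 140.0, 180.0, 220.0, 265.0, 310.0)
    labels: tuple[str, ...] = (
        "sup_TF", "sup_OA", "sup_IA", "sup_PM",
        "inf_PM", "inf_IA", "inf_OA", "inf_TF",
    )


class NormativeConfig(_Strict):
    cutoff_percentile: float = 5.0
    ring_aggregation: str = "mean"


class SyntheticConfig(_Strict):
    n_healthy: int = 24
    n_glaucoma: int = 10
    jitter_sd_deg: float = 5.0
    noise_sd_um: float = 2.0
    overall_flux_mm2: float = 1.5
    macular_termination: bool = True
    cartesian_n: int = 320


class PipelineConfig(_Strict):
    grid: GridConfig = Field(default_factory=GridConfig)
    trace: TraceConfig = Field(default_factory=TraceConfig)
    compensation: CompensationConfig = Field(default_factory=CompensationConfig)
    sectors: SectorConfig = Field(default_factory=SectorConfig)
    normative: NormativeConfig = Field(default_factory=NormativeConfig)
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of a configuration (provenance tag on outputs)."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
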