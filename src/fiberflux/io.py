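"""Plain-text I/O: CSV numeric grids with JSON sidecars.

Cartesian maps are CSV grids (row = y, col = x) with a sidecar recording
pixel pitch, origin and eye metadata; polar maps are CSV (ring x angle)
grids with a sidecar recording ring radii and the angular convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CartesianMap, EyeMeta, PolarAnnulusMap

__all__ = [
    "save_cartesian", "load_cartesian",
    "save_polar", "load_polar",
    "save_json", "load_json",
]

CANONICAL_CONVENTION = (
    "0 deg = nasal horizontal midline, 180 deg = temporal MPA; angles "
    "increase counterclockwise for right eyes and clockwise for left eyes; "
    "superior hemisphere = (0, 180) deg"
)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_cartesian(path, cmap: CartesianMap, meta: EyeMeta | None = None) -> None:
    path = Path(path)
    pd.DataFrame(cmap.values).to_csv(path, header=False, index=False, float_format="%.6g")
    side = {
        "pitch_mm": cmap.pitch,
        "origin_mm": list(cmap.origin),
        "quantity": cmap.quantity,
        "shape": list(cmap.values.shape),
    }
    if meta is not None:
        side["meta"] = meta.to_dict()
    _sidecar(path).write_text(json.dumps(side, indent=1))


def load_cartesian(path) -> tuple[CartesianMap, EyeMeta | None]:
    path = Path(path)
    values = pd.read_csv(path, header=None).to_numpy(dtype=float)
    side = json.loads(_sidecar(path).read_text())
    cmap = CartesianMap(values=values, pitch=float(side["pitch_mm"]),
                        origin=tuple(side["origin_mm"]),
                        quantity=side.get("quantity", "thickness_um"))
    meta = EyeMeta.from_dict(side["meta"]) if "meta" in side else None
    return cmap, meta


def save_polar(path, pmap: PolarAnnulusMap) -> None:
    path = Path(path)
    pd.DataFrame(pmap.values).to_csv(path, header=False, index=False, float_format="%.8g")
    side = {
        "radii_mm": pmap.radii.tolist(),
        "n_theta": pmap.n_theta,
        "quantity": pmap.quantity,
        "angular_convention": CANONICAL_CONVENTION,
    }
    _sidecar(path).write_text(json.dumps(side, indent=1))


def load_polar(path) -> PolarAnnulusMap:
    path = Path(path)
    values = pd.read_csv(path, header=None).to_numpy(dtype=float)
    side = json.loads(_sidecar(path).read_text())
    return PolarAnnulusMap(radii=np.asarray(side["radii_mm"], dtype=float),
                           values=values, quantity=side.get("quantity", "thickness_um"))


def save_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())
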