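"""Structured pipeline configuration (YAML-backed).

One config file describes a whole run: canister geometry and refractive
indices, the turntable rig, silhouette thresholds, carving resolution, and
the synthetic shape used by ``simulate``.  Unknown keys are rejected so
typos fail loudly; CLI flags override individual keys.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .camera import Intrinsics
from .carve import CarveConfig
from .errors import ValidationError
from .optics import (
    DEFAULT_HEIGHT_MM,
    DEFAULT_OUTER_RADIUS_MM,
    DEFAULT_WALL_MM,
    Cylinder,
    OpticalMedia,
)
from .scenes import AxisCube, SceneShape, Sphere, TurntableRig, make_branching_root
from .silhouette import SilhouetteConfig

__all__ = ["PipelineConfig", "load_config"]


def _take(d: dict, allowed: set[str], where: str) -> dict:
    unknown = set(d) - allowed
    if unknown:
        raise ValidationError(f"unknown keys in {where}: {sorted(unknown)}")
    return d


@dataclass
class PipelineConfig:
    cylinder: Cylinder = field(default_factory=Cylinder)
    media: OpticalMedia = field(default_factory=OpticalMedia)
    rig: TurntableRig = field(default_factory=TurntableRig)
    silhouette: SilhouetteConfig = field(default_factory=SilhouetteConfig)
    carve: CarveConfig = field(default_factory=lambda: CarveConfig(s_min=1.0))
    shape_spec: dict = field(default_factory=lambda: {"kind": "cube", "side_mm": 50.0})
    grid_resolution: tuple[int, int] = (800, 600)
    supersample: int = 2
    refraction: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def make_shape(self) -> SceneShape:
        spec = dict(self.shape_spec)
        kind = spec.pop("kind", "cube")
        center_z = self.cylinder.height / 2.0
        if kind == "cube":
            side = float(spec.pop("side_mm", 50.0))
            center = spec.pop("center", [0.0, 0.0, center_z])
            _take(spec, set(), "shape")
            return AxisCube(center=np.asarray(center, float), side=side)
        if kind == "sphere":
            radius = float(spec.pop("radius_mm", 20.0))
            center = spec.pop("center", [0.0, 0.0, center_z])
            _take(spec, set(), "shape")
            return Sphere(center=np.asarray(center, float), radius=radius)
        if kind == "root":
            seed = int(spec.pop("seed", self.seed))
            n_branches = int(spec.pop("n_branches", 6))
            _take(spec, {"trunk_radius", "taper"}, "shape")
            return make_branching_root(
                seed=seed, n_branches=n_branches, cylinder=self.cylinder, **spec
            )
        raise ValidationError(f"unknown shape kind {kind!r}")

    def config_hash(self) -> str:
        """Stable digest of the config, logged for provenance."""
        blob = {
            "cylinder": [self.cylinder.inner_radius, self.cylinder.outer_radius, self.cylinder.height],
            "media": asdict(self.media),
            "rig": [self.rig.n_views, self.rig.ring_radius, self.rig.camera_z],
            "silhouette": asdict(self.silhouette),
            "carve": asdict(self.carve),
            "shape": self.shape_spec,
            "grid": list(self.grid_resolution),
            "supersample": self.supersample,
            "refraction": self.refraction,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(blob, sort_keys=True).encode()).hexdigest()[:12]


def _cylinder_from(d: dict) -> Cylinder:
    d = _take(dict(d), {"outer_radius_mm", "wall_mm", "height_mm"}, "scene.cylinder")
    outer = float(d.get("outer_radius_mm", DEFAULT_OUTER_RADIUS_MM))
    wall = float(d.get("wall_mm", DEFAULT_WALL_MM))
    height = float(d.get("height_mm", DEFAULT_HEIGHT_MM))
    return Cylinder(inner_radius=outer - wall, outer_radius=outer, height=height)


def _rig_from(d: dict, cylinder: Cylinder) -> TurntableRig:
    d = _take(
        dict(d),
        {"n_views", "ring_radius_mm", "camera_z_mm", "look_at_z_mm",
         "fx", "fy", "cx", "cy", "width", "height"},
        "rig",
    )
    width = int(d.get("width", 800))
    height = int(d.get("height", 600))
    intr = Intrinsics(
        fx=float(d.get("fx", 1000.0)),
        fy=float(d.get("fy", 1000.0)),
        cx=float(d.get("cx", (width - 1) / 2.0)),
        cy=float(d.get("cy", (height - 1) / 2.0)),
        width=width,
        height=height,
    )
    z = float(d.get("camera_z_mm", cylinder.height / 2.0))
    return TurntableRig(
        n_views=int(d.get("n_views", 40)),
        ring_radius=float(d.get("ring_radius_mm", 300.0)),
        camera_z=z,
        look_at=np.array([0.0, 0.0, float(d.get("look_at_z_mm", cylinder.height / 2.0))]),
        intrinsics=intr,
    )


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML pipeline config; missing file/blocks fall back to defaults."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError("config root must be a mapping")
    if overrides:
        raw = {**raw, **overrides}
    _take(
        dict(raw),
        {"scene", "rig", "silhouette", "carve", "shape", "render", "seed", "log_level"},
        "config",
    )
    scene = raw.get("scene", {}) or {}
    _take(dict(scene), {"cylinder", "media"}, "scene")
    cylinder = _cylinder_from(scene.get("cylinder", {}) or {})
    media_d = _take(dict(scene.get("media", {}) or {}), {"n_air", "n_acrylic", "n_water"}, "scene.media")
    media = OpticalMedia(**{k: float(v) for k, v in media_d.items()})
    rig = _rig_from(raw.get("rig", {}) or {}, cylinder)
    sil_d = _take(
        dict(raw.get("silhouette", {}) or {}),
        {"polarity", "hysteresis_low_frac", "hysteresis_high_frac", "open_radius", "use_edges"},
        "silhouette",
    )
    sil = SilhouetteConfig(**sil_d)
    carve_d = _take(
        dict(raw.get("carve", {}) or {}),
        {"s_min_mm", "tau_full", "tau_empty", "min_views_to_carve", "max_depth"},
        "carve",
    )
    if "s_min_mm" in carve_d:
        carve_d["s_min"] = float(carve_d.pop("s_min_mm"))
    carve_cfg = CarveConfig(s_min=1.0, **carve_d) if "s_min" not in carve_d else CarveConfig(**carve_d)
    render = _take(
        dict(raw.get("render", {}) or {}),
        {"grid_width", "grid_height", "supersample", "refraction"},
        "render",
    )
    return PipelineConfig(
        cylinder=cylinder,
        media=media,
        rig=rig,
        silhouette=sil,
        carve=carve_cfg,
        shape_spec=dict(raw.get("shape", {}) or {"kind": "cube", "side_mm": 50.0}),
        grid_resolution=(int(render.get("grid_width", 800)), int(render.get("grid_height", 600))),
        supersample=int(render.get("supersample", 2)),
        refraction=bool(render.get("refraction", True)),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
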