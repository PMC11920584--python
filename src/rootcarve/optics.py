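"""Snell's-law raytracing through the cylindrical growth canister.

Light reaching the camera from a submerged root crosses two refractive
interfaces: water -> acrylic at the inner wall and acrylic -> air at the
outer wall.  Traced camera-to-scene, each pixel's ray therefore bends twice
before it travels through the nutrient solution.  Ignoring this makes
objects appear shifted and compressed and corrupts any silhouette-based
reconstruction, so carving consumes the *refracted* ray field computed here
rather than straight pinhole rays.

For every pixel of a (default 800x600) grid the tracer records the point
where the ray enters the water (on the inner cylinder surface) and its
direction inside the water.  Rays that miss the canister walls, exit through
the end caps, or undergo total internal reflection carry a validity flag and
never contribute carving evidence.

All vector quantities are in world millimetres; refractive indices are
dimensionless (air 1.00, acrylic 1.49, water 1.33 by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .camera import CameraView
from .errors import InvalidSceneGeometryError, ValidationError
from .silhouette import Silhouette

__all__ = [
    "Cylinder",
    "OpticalMedia",
    "Ray",
    "RayField",
    "VoxelVisibility",
    "refract_direction",
    "intersect_cylinder",
    "trace_view",
    "pixel_visibility_mask",
    "visible_fraction",
    "interior_roi",
    "downsample_mask",
]

_EPS = 1e-9

# 6-in diameter x 6-in tall acrylic stock; 1/8-in wall.
DEFAULT_OUTER_RADIUS_MM = 76.2
DEFAULT_WALL_MM = 3.175
DEFAULT_HEIGHT_MM = 152.4


@dataclass(frozen=True)
class Cylinder:
    """Canister geometry: a thick-walled cylinder, axis +z, base at origin.

    ``origin`` is the center of the top opening (net-pot plane); the cylinder
    occupies axial coordinates [0, height] along ``axis`` (+z points down
    into the liquid in the package convention).
    """

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    inner_radius: float = DEFAULT_OUTER_RADIUS_MM - DEFAULT_WALL_MM
    outer_radius: float = DEFAULT_OUTER_RADIUS_MM
    height: float = DEFAULT_HEIGHT_MM

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        axis = np.asarray(self.axis, dtype=float).reshape(3)
        norm = np.linalg.norm(axis)
        if norm < _EPS:
            raise ValidationError("cylinder axis must be non-zero")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axis", axis / norm)
        if not (0 < self.inner_radius < self.outer_radius):
            raise ValidationError("need 0 < inner_radius < outer_radius")
        if self.height <= 0:
            raise ValidationError("height must be positive")

    def radial_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance of point(s) from the cylinder axis."""
        p = np.atleast_2d(points) - self.origin
        ax = p @ self.axis
        radial = p - ax[..., None] * self.axis
        return np.linalg.norm(radial, axis=-1)

    def axial_coordinate(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.axis

    def contains_water(self, points: np.ndarray) -> np.ndarray:
        """True where a point lies in the inner (liquid) volume."""
        r = self.radial_distance(points)
        z = self.axial_coordinate(points)
        return (r <= self.inner_radius) & (z >= 0) & (z <= self.height)


@dataclass(frozen=True)
class OpticalMedia:
    """Refractive indices of the three media the rays traverse."""

    n_air: float = 1.00
    n_acrylic: float = 1.49
    n_water: float = 1.33

    def __post_init__(self) -> None:
        if min(self.n_air, self.n_acrylic, self.n_water) < 1.0:
            raise ValidationError("refractive indices must be >= 1")

    @property
    def uniform(self) -> bool:
        return self.n_air == self.n_acrylic == self.n_water


@dataclass(frozen=True)
class Ray:
    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n < _EPS:
            raise ValidationError("ray direction must be non-zero")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / n)


def refract_direction(
    incident: np.ndarray, normal: np.ndarray, n1: float, n2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vector-form Snell's law at an interface.

    ``incident`` and ``normal`` are unit vectors (broadcastable, last axis 3)
    with the normal oriented against the incident ray (incident . normal < 0).
    Returns ``(refracted, valid)``: the unit refracted direction
    ``t = eta d + (eta cos_i - cos_t) n`` with ``eta = n1/n2``, and a mask
    that is False where total internal reflection occurs (no refracted ray).
    """
    d = np.asarray(incident, dtype=float)
    n = np.asarray(normal, dtype=float)
    eta = n1 / n2
    cos_i = -np.sum(d * n, axis=-1)
    sin2_t = eta**2 * (1.0 - cos_i**2)
    valid = sin2_t <= 1.0
    cos_t = np.sqrt(np.clip(1.0 - sin2_t, 0.0, None))
    t = eta * d + (eta * cos_i - cos_t)[..., None] * n
    norm = np.linalg.norm(t, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(norm > _EPS, t / norm, t)
    return t, valid


def intersect_cylinder(
    origins: np.ndarray,
    directions: np.ndarray,
    cylinder: Cylinder,
    radius_select: str = "outer",
    t_min: float = _EPS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest ray intersection with one wall of the canister.

    Solves the quadratic for the infinite cylinder of the selected radius and
    accepts the smallest parameter ``t > t_min`` whose axial coordinate lies
    within [0, height] (rays leaving through the open end caps count as
    misses).  Returns ``(points, outward_normals, valid)`` with inputs
    broadcast over the leading axes.
    """
    if radius_select not in ("inner", "outer"):
        raise ValidationError("radius_select must be 'inner' or 'outer'")
    r = cylinder.inner_radius if radius_select == "inner" else cylinder.outer_radius
    o = np.atleast_2d(np.asarray(origins, dtype=float)) - cylinder.origin
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    a_hat = cylinder.axis

    d_perp = d - (d @ a_hat)[..., None] * a_hat
    o_perp = o - (o @ a_hat)[..., None] * a_hat
    a = np.sum(d_perp * d_perp, axis=-1)
    b = 2.0 * np.sum(o_perp * d_perp, axis=-1)
    c = np.sum(o_perp * o_perp, axis=-1) - r * r

    disc = b * b - 4 * a * c
    solvable = (a > _EPS) & (disc >= 0)
    sq = np.sqrt(np.where(disc >= 0, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (-b - sq) / (2 * a)
        t2 = (-b + sq) / (2 * a)

    t_hit = np.full(a.shape, np.nan)
    valid = np.zeros(a.shape, dtype=bool)
    for t_cand in (t1, t2):
        z = (o + t_cand[..., None] * d) @ a_hat
        ok = solvable & ~valid & (t_cand > t_min) & (z >= 0) & (z <= cylinder.height)
        t_hit = np.where(ok, t_cand, t_hit)
        valid |= ok

    points = cylinder.origin + o + t_hit[..., None] * d
    rel = points - cylinder.origin
    radial = rel - ((rel @ a_hat)[..., None] * a_hat)
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = radial / np.linalg.norm(radial, axis=-1, keepdims=True)
    return points, normals, valid


@dataclass
class RayField:
    """Per-pixel refracted rays on the inner cylinder surface for one view.

    ``origins``/``directions`` have shape (rows, cols, 3); ``valid`` marks
    rays that reached the water (no miss, no end-cap exit, no TIR).  Invalid
    rays carry NaN origins/directions and never carve.
    """

    origins: np.ndarray
    directions: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.valid.shape

    @property
    def n_rays(self) -> int:
        """Number of primary rays cast (grid rows x cols)."""
        return int(np.prod(self.valid.shape))

    def as_tensor(self) -> np.ndarray:
        """Dense 3 x rows x cols direction tensor (the canonical layout)."""
        return np.moveaxis(self.directions, -1, 0)

    def save(self, path: str | Path) -> None:
        """Cache to a .npz file (arrays: origins, directions, valid, meta JSON)."""
        np.savez_compressed(
            path,
            origins=self.origins,
            directions=self.directions,
            valid=self.valid,
            meta=np.frombuffer(json.dumps(self.meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path: str | Path) -> "RayField":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode()) if "meta" in data else {}
            return cls(
                origins=data["origins"],
                directions=data["directions"],
                valid=data["valid"],
                meta=meta,
            )


def _pixel_grid_rays(
    view: CameraView, grid_resolution: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """World-space pinhole rays through the centers of a (cols, rows) grid.

    The grid spans the full sensor; when its resolution differs from the
    sensor's, grid pixel centers are mapped proportionally into image pixel
    coordinates (decoupling the ray budget from the 12-MP sensor).
    """
    gw, gh = grid_resolution
    K = view.intrinsics
    cols = (np.arange(gw) + 0.5) * (K.width / gw) - 0.5
    rows = (np.arange(gh) + 0.5) * (K.height / gh) - 0.5
    u, v = np.meshgrid(cols, rows)
    xn = (u - K.cx) / K.fx
    yn = (v - K.cy) / K.fy
    d_cam = np.stack([xn, yn, np.ones_like(xn)], axis=-1)
    d_world = d_cam @ view.extrinsics.R  # R^T applied to each row vector
    d_world /= np.linalg.norm(d_world, axis=-1, keepdims=True)
    origin = np.broadcast_to(view.camera_center, d_world.shape)
    return origin.copy(), d_world


def trace_view(
    view: CameraView,
    cylinder: Cylinder,
    media: OpticalMedia,
    grid_resolution: tuple[int, int] = (800, 600),
) -> RayField:
    """Trace a full grid of camera rays into the water volume.

    Each primary ray is refracted at the outer wall (air -> acrylic), carried
    through the wall to the inner wall, and refracted again (acrylic ->
    water).  With all three indices equal the result reduces to straight
    pinhole rays re-anchored on the inner surface.

    Raises :class:`InvalidSceneGeometryError` if the camera sits inside the
    canister.
    """
    C = view.camera_center
    r_cam = cylinder.radial_distance(C)[0]
    z_cam = cylinder.axial_coordinate(C)[0]
    if r_cam < cylinder.outer_radius and 0 < z_cam < cylinder.height:
        raise InvalidSceneGeometryError("camera must be outside the canister")

    origins, dirs = _pixel_grid_rays(view, grid_resolution)
    shape = origins.shape[:2]
    o_flat = origins.reshape(-1, 3)
    d_flat = dirs.reshape(-1, 3)

    # Stage 1: air -> acrylic at the outer wall.
    p_out, n_out, hit_out = intersect_cylinder(o_flat, d_flat, cylinder, "outer")
    d_wall, no_tir1 = refract_direction(d_flat, n_out, media.n_air, media.n_acrylic)
    valid = hit_out & no_tir1

    # Stage 2: acrylic -> water at the inner wall.
    p_in, n_in, hit_in = intersect_cylinder(p_out, d_wall, cylinder, "inner")
    d_water, no_tir2 = refract_direction(d_wall, n_in, media.n_acrylic, media.n_water)
    valid &= hit_in & no_tir2

    p_in = np.where(valid[:, None], p_in, np.nan)
    d_water = np.where(valid[:, None], d_water, np.nan)
    return RayField(
        origins=p_in.reshape(*shape, 3),
        directions=d_water.reshape(*shape, 3),
        valid=valid.reshape(shape),
        meta={
            "image_id": view.image_id,
            "grid_resolution": list(grid_resolution),
            "media": [media.n_air, media.n_acrylic, media.n_water],
        },
    )


@dataclass(frozen=True)
class VoxelVisibility:
    """Binary per-pixel mask of rays covering one voxel."""

    mask: np.ndarray
    out_of_volume: bool = False


def _slab_hits(
    origins: np.ndarray, directions: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Axis-aligned box test for semi-infinite rays (t >= 0), vectorized."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / directions
        t_lo = (lo - origins) * inv
        t_hi = (hi - origins) * inv
    near = np.minimum(t_lo, t_hi)
    far = np.maximum(t_lo, t_hi)
    # Rays parallel to an axis: inside the slab -> (-inf, +inf), else miss.
    parallel = np.abs(directions) < 1e-14
    inside = (origins >= lo) & (origins <= hi)
    near = np.where(parallel, np.where(inside, -np.inf, np.inf), near)
    far = np.where(parallel, np.where(inside, np.inf, -np.inf), far)
    t_near = np.max(near, axis=-1)
    t_far = np.min(far, axis=-1)
    return (t_far >= np.maximum(t_near, 0.0)) & np.isfinite(t_far)


def pixel_visibility_mask(
    voxel_center: np.ndarray,
    voxel_half_size: float,
    rayfield: RayField,
    cylinder: Cylinder | None = None,
) -> VoxelVisibility:
    """Mask of grid pixels whose refracted ray intersects a voxel cube.

    The in-water segment is treated as a semi-infinite ray from its
    inner-surface origin (voxels live inside the liquid).  If ``cylinder``
    is given and the voxel cube lies entirely outside the water volume, an
    empty mask with ``out_of_volume=True`` is returned.
    """
    c = np.asarray(voxel_center, dtype=float).reshape(3)
    h = float(voxel_half_size)
    if cylinder is not None:
        corners = c + h * _CORNER_SIGNS
        if not cylinder.contains_water(corners).any():
            return VoxelVisibility(
                mask=np.zeros(rayfield.grid_shape, dtype=bool), out_of_volume=True
            )
    lo, hi = c - h, c + h
    hits = _slab_hits(rayfield.origins, rayfield.directions, lo, hi)
    return VoxelVisibility(mask=hits & rayfield.valid)


_CORNER_SIGNS = np.array(
    [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float
)


def visible_fraction(
    mask: np.ndarray | VoxelVisibility, silhouette: Silhouette | np.ndarray
) -> float:
    """Fraction of a voxel's covering rays that land in the silhouette.

    ``|mask AND silhouette| / |mask|``; 0 when the mask is empty.  Shapes
    must already agree (resample the silhouette to the ray grid first).
    """
    m = mask.mask if isinstance(mask, VoxelVisibility) else np.asarray(mask, bool)
    s = silhouette.mask if isinstance(silhouette, Silhouette) else np.asarray(silhouette, bool)
    if m.shape != s.shape:
        raise ValidationError(f"mask {m.shape} and silhouette {s.shape} differ")
    total = int(m.sum())
    if total == 0:
        return 0.0
    return int((m & s).sum()) / total


def interior_roi(
    view: CameraView,
    cylinder: Cylinder,
    media: OpticalMedia | None = None,
    grid_resolution: tuple[int, int] = (800, 600),
) -> np.ndarray:
    """Pixels whose ray reaches the liquid: the canister-interior ROI mask."""
    media = media or OpticalMedia()
    return trace_view(view, cylinder, media, grid_resolution).valid


def downsample_mask(mask: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resample of a binary mask onto the ray grid shape."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = grid_shape
    ri = np.clip(((np.arange(rows) + 0.5) * mask.shape[0] / rows).astype(int), 0, mask.shape[0] - 1)
    ci = np.clip(((np.arange(cols) + 0.5) * mask.shape[1] / cols).astype(int), 0, mask.shape[1] - 1)
    return mask[np.ix_(ri, ci)]
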