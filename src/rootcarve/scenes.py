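"""Synthetic ground-truth scenes: analytic shapes, camera rings, renders.

Every stage of the pipeline is testable without lab data: shapes of known
volume (validation cubes, spheres, randomized branching "roots" built from
tapered capsules) are placed inside the simulated canister and
forward-rendered to silhouettes through the same optical model the carver
inverts — optionally with the two-interface refraction enabled, so
render/carve pairs can be matched or deliberately mismatched to expose the
refraction error.

The default turntable rig mirrors the imaging protocol: 40 cameras at
equidistant angles on a horizontal ring around the canister.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .camera import CameraView, Correspondences, Extrinsics, Intrinsics, MarkerGrid
from .errors import InvalidSceneGeometryError, ValidationError
from .optics import Cylinder, OpticalMedia, trace_view
from .silhouette import Silhouette

__all__ = [
    "SceneShape",
    "AxisCube",
    "Sphere",
    "CylinderSegment",
    "Capsule",
    "BranchingRoot",
    "TurntableRig",
    "make_branching_root",
    "render_silhouette",
    "make_marker_detections",
    "make_marker_grid",
]


class SceneShape:
    """Base for analytic test shapes: inside-test + ray intersection."""

    kind: str = "shape"

    def contains(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def volume(self) -> float | None:
        """Closed-form volume in mm^3, or None if only Monte-Carlo applies."""
        return None

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def segment_hits(self, origins: np.ndarray, directions: np.ndarray) -> np.ndarray:
        """True per ray if the semi-infinite ray (t >= 0) meets the shape.

        Default implementation samples the inside-test densely along each
        ray across the shape's bounding sphere; exact shapes override it.
        """
        lo, hi = self.bounds()
        c = (lo + hi) / 2.0
        rad = float(np.linalg.norm(hi - lo) / 2.0)
        step = self._sample_step()
        n_steps = max(int(np.ceil(2 * rad / step)) + 1, 2)
        o = np.atleast_2d(origins)
        d = np.atleast_2d(directions)
        tc = np.maximum(np.sum((c - o) * d, axis=-1), 0.0)
        ts = np.linspace(-rad, rad, n_steps)
        hits = np.zeros(len(o), dtype=bool)
        chunk = max(1, 2_000_000 // n_steps)
        for i in range(0, len(o), chunk):
            t = tc[i : i + chunk, None] + ts[None, :]
            t = np.maximum(t, 0.0)
            pts = o[i : i + chunk, None, :] + t[..., None] * d[i : i + chunk, None, :]
            hits[i : i + chunk] = self.contains(pts.reshape(-1, 3)).reshape(t.shape).any(axis=1)
        return hits

    def _sample_step(self) -> float:
        return 0.5

    def mc_volume(self, seed: int = 0, n: int = 1_000_000) -> tuple[float, float]:
        """Monte-Carlo volume estimate and its standard error (mm^3)."""
        rng = np.random.default_rng(seed)
        lo, hi = self.bounds()
        box = float(np.prod(hi - lo))
        n_in = 0
        for start in range(0, n, 1_000_000):
            m = min(1_000_000, n - start)
            pts = rng.uniform(lo, hi, size=(m, 3))
            n_in += int(self.contains(pts).sum())
        p = n_in / n
        se = box * float(np.sqrt(p * (1 - p) / n))
        return box * p, se


@dataclass(frozen=True)
class AxisCube(SceneShape):
    """Axis-aligned cube (the 3D-printed validation target)."""

    center: np.ndarray
    side: float
    kind: str = "cube"

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        if self.side <= 0:
            raise ValidationError("cube side must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        return np.all(np.abs(np.atleast_2d(points) - self.center) <= self.side / 2.0, axis=-1)

    def volume(self) -> float:
        return self.side**3

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        h = self.side / 2.0
        return self.center - h, self.center + h

    def segment_hits(self, origins: np.ndarray, directions: np.ndarray) -> np.ndarray:
        from .optics import _slab_hits

        lo, hi = self.bounds()
        return _slab_hits(np.atleast_2d(origins), np.atleast_2d(directions), lo, hi)


@dataclass(frozen=True)
class Sphere(SceneShape):
    center: np.ndarray
    radius: float
    kind: str = "sphere"

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        if self.radius <= 0:
            raise ValidationError("radius must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        return np.linalg.norm(np.atleast_2d(points) - self.center, axis=-1) <= self.radius

    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        r = self.radius
        return self.center - r, self.center + r

    def segment_hits(self, origins: np.ndarray, directions: np.ndarray) -> np.ndarray:
        o = np.atleast_2d(origins) - self.center
        d = np.atleast_2d(directions)
        b = np.sum(o * d, axis=-1)
        c = np.sum(o * o, axis=-1) - self.radius**2
        disc = b * b - c
        ok = disc >= 0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        t2 = -b + sq
        return ok & (t2 >= 0)


@dataclass(frozen=True)
class Capsule(SceneShape):
    """Tapered capsule: all points within radius r(u) of segment p0 -> p1,
    where r interpolates linearly from r0 to r1 along the segment."""

    p0: np.ndarray
    p1: np.ndarray
    r0: float
    r1: float
    kind: str = "capsule"

    def __post_init__(self) -> None:
        object.__setattr__(self, "p0", np.asarray(self.p0, dtype=float).reshape(3))
        object.__setattr__(self, "p1", np.asarray(self.p1, dtype=float).reshape(3))
        if min(self.r0, self.r1) <= 0:
            raise ValidationError("capsule radii must be positive")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        axis = self.p1 - self.p0
        L2 = axis @ axis
        if L2 < 1e-18:
            return np.linalg.norm(p - self.p0, axis=-1) <= max(self.r0, self.r1)
        u = np.clip(((p - self.p0) @ axis) / L2, 0.0, 1.0)
        proj = self.p0 + u[..., None] * axis
        r_u = self.r0 + (self.r1 - self.r0) * u
        return np.linalg.norm(p - proj, axis=-1) <= r_u

    def volume(self) -> float | None:
        if self.r0 == self.r1:
            # cylinder plus the two hemispherical caps
            return np.pi * self.r0**2 * self.length + 4.0 / 3.0 * np.pi * self.r0**3
        return None

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        r = max(self.r0, self.r1)
        return np.minimum(self.p0, self.p1) - r, np.maximum(self.p0, self.p1) + r

    def _sample_step(self) -> float:
        return min(self.r0, self.r1) / 2.0

    def segment_hits(self, origins: np.ndarray, directions: np.ndarray) -> np.ndarray:
        """Pruned sampling: only rays passing near the capsule axis are
        densely sampled, over the capsule's own parameter span."""
        o = np.atleast_2d(origins)
        d = np.atleast_2d(directions)
        hits = np.zeros(len(o), dtype=bool)
        # Coarse prune: rays missing the capsule's bounding sphere.
        mid = (self.p0 + self.p1) / 2.0
        r_sphere = self.length / 2.0 + max(self.r0, self.r1) + 1e-6
        rel0 = mid - o
        t0 = np.maximum(np.einsum("mc,mc->m", rel0, d), 0.0)
        coarse = np.linalg.norm(rel0 - t0[:, None] * d, axis=-1) <= r_sphere
        if not coarse.any():
            return hits
        cidx = np.flatnonzero(coarse)
        o_c, d_c = o[cidx], d[cidx]
        n_axis = 16
        q = self.p0 + np.linspace(0.0, 1.0, n_axis)[:, None] * (self.p1 - self.p0)
        margin = self.length / (2 * (n_axis - 1)) + 1e-6
        r_max = max(self.r0, self.r1) + margin
        # Distance from each axis sample to each surviving ray (t >= 0).
        rel = q[None, :, :] - o_c[:, None, :]  # (M, K, 3)
        t_proj = np.einsum("mkc,mc->mk", rel, d_c)
        t_proj = np.maximum(t_proj, 0.0)
        closest = t_proj[..., None] * d_c[:, None, :]
        dist = np.linalg.norm(rel - closest, axis=-1)
        near = dist.min(axis=1) <= r_max
        if not near.any():
            return hits
        idx = cidx[near]
        t_lo = np.maximum(t_proj[near].min(axis=1) - r_max, 0.0)
        t_hi = t_proj[near].max(axis=1) + r_max
        step = self._sample_step()
        n_steps = max(int(np.ceil((t_hi - t_lo).max() / step)) + 1, 2)
        frac = np.linspace(0.0, 1.0, n_steps)
        chunk = max(1, 2_000_000 // n_steps)
        for i in range(0, len(idx), chunk):
            sel = idx[i : i + chunk]
            t = t_lo[i : i + chunk, None] + (t_hi[i : i + chunk] - t_lo[i : i + chunk])[:, None] * frac[None, :]
            pts = o[sel, None, :] + t[..., None] * d[sel, None, :]
            hits[sel] = self.contains(pts.reshape(-1, 3)).reshape(t.shape).any(axis=1)
        return hits


@dataclass(frozen=True)
class CylinderSegment(SceneShape):
    """Finite solid cylinder between two points (flat caps)."""

    p0: np.ndarray
    p1: np.ndarray
    radius: float
    kind: str = "cylinder-segment"

    def __post_init__(self) -> None:
        object.__setattr__(self, "p0", np.asarray(self.p0, dtype=float).reshape(3))
        object.__setattr__(self, "p1", np.asarray(self.p1, dtype=float).reshape(3))
        if self.radius <= 0:
            raise ValidationError("radius must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        axis = self.p1 - self.p0
        L2 = axis @ axis
        u = ((p - self.p0) @ axis) / L2
        proj = self.p0 + u[..., None] * axis
        return (u >= 0) & (u <= 1) & (np.linalg.norm(p - proj, axis=-1) <= self.radius)

    def volume(self) -> float:
        return float(np.pi * self.radius**2 * np.linalg.norm(self.p1 - self.p0))

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        r = self.radius
        return np.minimum(self.p0, self.p1) - r, np.maximum(self.p0, self.p1) + r

    def _sample_step(self) -> float:
        return self.radius / 2.0


@dataclass(frozen=True)
class BranchingRoot(SceneShape):
    """Union of tapered capsules along a branching tree."""

    capsules: tuple[Capsule, ...]
    kind: str = "branching-root"

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        inside = np.zeros(len(p), dtype=bool)
        for cap in self.capsules:
            inside |= cap.contains(p)
        return inside

    def segment_hits(self, origins: np.ndarray, directions: np.ndarray) -> np.ndarray:
        o = np.atleast_2d(origins)
        d = np.atleast_2d(directions)
        hits = np.zeros(len(o), dtype=bool)
        for cap in self.capsules:
            todo = ~hits
            if not todo.any():
                break
            hits[todo] = cap.segment_hits(o[todo], d[todo])
        return hits

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        los, his = zip(*(c.bounds() for c in self.capsules))
        return np.min(los, axis=0), np.max(his, axis=0)

    def _sample_step(self) -> float:
        return min(min(c.r0, c.r1) for c in self.capsules) / 2.0

    def volume(self) -> float | None:
        if len(self.capsules) == 1:
            return self.capsules[0].volume()
        return None


def make_branching_root(
    seed: int,
    n_branches: int = 6,
    trunk_radius: float = 3.0,
    trunk_length: float = 80.0,
    taper: float = 0.6,
    branch_length_frac: float = 0.5,
    cylinder: Cylinder | None = None,
    margin: float = 10.0,
) -> BranchingRoot:
    """Grow a random capsule tree inside the canister (seed-deterministic).

    A trunk descends from just below the net-pot plane; each branch sprouts
    from a uniformly random point on a random existing segment, heads
    predominantly downward, and carries ``taper`` times its parent's radius.
    Branch endpoints are pulled back inside the liquid volume (minus
    ``margin``) when a random direction would escape it.
    """
    rng = np.random.default_rng(seed)
    cyl = cylinder or Cylinder()
    r_max = cyl.inner_radius - margin
    z_lo, z_hi = margin / 2.0, cyl.height - margin

    def clamp(p: np.ndarray) -> np.ndarray:
        p = p.copy()
        rad = np.hypot(p[0], p[1])
        if rad > r_max:
            p[:2] *= r_max / rad
        p[2] = np.clip(p[2], z_lo, z_hi)
        return p

    tilt = rng.normal(0.0, 0.08, size=2)
    top = np.array([0.0, 0.0, z_lo])
    tip = clamp(top + np.array([tilt[0], tilt[1], 1.0]) / np.linalg.norm([tilt[0], tilt[1], 1.0]) * trunk_length)
    capsules = [Capsule(top, tip, trunk_radius, trunk_radius * taper)]
    for _ in range(n_branches):
        parent = capsules[rng.integers(0, len(capsules))]
        u = rng.uniform(0.2, 0.9)
        start = parent.p0 + u * (parent.p1 - parent.p0)
        r_start = (parent.r0 + (parent.r1 - parent.r0) * u) * taper
        direction = rng.normal(size=3)
        direction[2] = abs(direction[2]) + 0.5  # bias downward (+z)
        direction /= np.linalg.norm(direction)
        length = parent.length * branch_length_frac * rng.uniform(0.6, 1.2)
        end = clamp(start + direction * length)
        r_start = max(r_start, 0.5)
        capsules.append(Capsule(start, end, r_start, max(r_start * taper, 0.3)))
    return BranchingRoot(capsules=tuple(capsules))


@dataclass(frozen=True)
class TurntableRig:
    """Ring of equidistant-angle cameras around the canister.

    With ``n_views=40`` consecutive cameras are 9 degrees apart.  All
    cameras look at a point on the canister axis; camera +v (image down)
    aligns with world +z (down into the liquid).
    """

    n_views: int = 40
    ring_radius: float = 300.0
    camera_z: float = 76.2
    look_at: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 76.2]))
    intrinsics: Intrinsics = field(
        default_factory=lambda: Intrinsics(
            fx=1000.0, fy=1000.0, cx=399.5, cy=299.5, width=800, height=600
        )
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "look_at", np.asarray(self.look_at, dtype=float).reshape(3))
        if self.n_views < 1:
            raise ValidationError("need at least one view")

    def camera_centers(self) -> np.ndarray:
        theta = 2 * np.pi * np.arange(self.n_views) / self.n_views
        return np.column_stack(
            [
                self.ring_radius * np.cos(theta),
                self.ring_radius * np.sin(theta),
                np.full(self.n_views, self.camera_z),
            ]
        )

    def views(self, cylinder: Cylinder | None = None) -> list[CameraView]:
        if cylinder is not None and self.ring_radius <= cylinder.outer_radius:
            raise InvalidSceneGeometryError("cameras must sit outside the canister")
        out = []
        for i, C in enumerate(self.camera_centers()):
            z_cam = self.look_at - C
            z_cam = z_cam / np.linalg.norm(z_cam)
            y0 = np.array([0.0, 0.0, 1.0])
            x_cam = np.cross(y0, z_cam)
            x_cam /= np.linalg.norm(x_cam)
            y_cam = np.cross(z_cam, x_cam)
            R = np.vstack([x_cam, y_cam, z_cam])
            out.append(
                CameraView(self.intrinsics, Extrinsics(R, -R @ C), image_id=f"view_{i:03d}")
            )
        return out


def render_silhouette(
    shape: SceneShape,
    view: CameraView,
    cylinder: Cylinder | None = None,
    media: OpticalMedia | None = None,
    grid_resolution: tuple[int, int] = (800, 600),
    refraction: bool = True,
    supersample: int = 2,
) -> Silhouette:
    """Forward-render a binary silhouette of a shape from one view.

    With ``refraction`` on, rays are bent at both canister walls exactly as
    in :func:`rootcarve.optics.trace_view` and the shape is intersected with
    the in-water segments; rays that miss the canister or suffer TIR render
    as background.  With it off, straight pinhole rays are used (the
    uniform-medium limit).  Each output pixel is supersampled
    ``supersample x supersample`` and set by majority vote.
    """
    from .optics import _pixel_grid_rays

    gw, gh = grid_resolution
    ss = max(1, int(supersample))
    hi_res = (gw * ss, gh * ss)
    if refraction:
        if cylinder is None:
            raise ValidationError("refraction rendering needs the cylinder geometry")
        rf = trace_view(view, cylinder, media or OpticalMedia(), hi_res)
        o = rf.origins.reshape(-1, 3)
        d = rf.directions.reshape(-1, 3)
        ok = rf.valid.ravel()
        hits = np.zeros(o.shape[0], dtype=bool)
        if ok.any():
            hits[ok] = shape.segment_hits(o[ok], d[ok])
    else:
        origins, dirs = _pixel_grid_rays(view, hi_res)
        hits = shape.segment_hits(origins.reshape(-1, 3), dirs.reshape(-1, 3))
    hit_img = hits.reshape(gh * ss, gw * ss).astype(float)
    if ss > 1:
        hit_img = hit_img.reshape(gh, ss, gw, ss).mean(axis=(1, 3))
    mask = hit_img >= 0.5
    return Silhouette(
        mask=mask,
        provenance={
            "synthetic": True,
            "shape": shape.kind,
            "refraction": refraction,
            "supersample": ss,
            "view": view.image_id,
        },
    )


def make_marker_grid(
    n_cols: int = 12,
    pot_radius: float = 40.0,
    z_rows: tuple[float, float] = (-20.0, -8.0),
    marker_size_mm: float = 10.0,
) -> MarkerGrid:
    """Two-row fiducial strip wrapped around the net-pot perimeter.

    Rows sit above the net-pot plane (negative z = above the liquid).
    """
    ids, centers = [], []
    for r, z in enumerate(z_rows):
        for c in range(n_cols):
            theta = 2 * np.pi * c / n_cols
            ids.append(r * n_cols + c)
            centers.append([pot_radius * np.cos(theta), pot_radius * np.sin(theta), z])
    return MarkerGrid(
        ids=np.array(ids),
        centers=np.array(centers),
        rows=len(z_rows),
        cols=n_cols,
        marker_size_mm=marker_size_mm,
    )


def make_marker_detections(
    rig: TurntableRig,
    grid: MarkerGrid,
    noise_px: float = 0.0,
    seed: int = 0,
) -> dict[str, Correspondences]:
    """Project marker centers into every rig view (+ optional pixel noise).

    Markers on the far side of the pot (outward normal facing away from the
    camera) and markers projecting outside the image are excluded, mimicking
    what a detector could actually see.
    """
    from .camera import project_point

    rng = np.random.default_rng(seed)
    out: dict[str, Correspondences] = {}
    for view in rig.views():
        C = view.camera_center
        world, image = [], []
        for center in grid.centers:
            normal = np.array([center[0], center[1], 0.0])
            nn = np.linalg.norm(normal)
            if nn > 0 and normal @ (C - center) <= 0:
                continue  # back side of the pot
            uv, behind = project_point(view, center)
            if behind:
                continue
            if not (0 <= uv[0] < view.intrinsics.width and 0 <= uv[1] < view.intrinsics.height):
                continue
            world.append(center)
            image.append(uv)
        image = np.asarray(image, dtype=float)
        if noise_px > 0 and image.size:
            image = image + rng.normal(0.0, noise_px, size=image.shape)
        out[view.image_id] = Correspondences(np.asarray(world), image)
    return out
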