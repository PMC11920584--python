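"""Camera models, fiducial-based pose estimation, and turntable geometry.

The imaging rig photographs a hydroponic canister from a ring of viewpoints.
Because the camera is carried by a low-cost arm rather than fixed mounts, each
view's pose is recovered from a strip of fiducial markers of known 3D layout
wrapped around the net pot: given >= 4 (3D marker center, 2D detection) pairs
the Perspective-n-Point problem yields the world->camera rigid transform.
Projection matrices P = K [R | t] then drive silhouette back-projection, and a
circle of best fit through the recovered camera centers summarizes (and sanity
checks) the turntable ring.

Conventions: right-handed world frame, millimetres, origin on the canister
axis at the net-pot plane with +z pointing down into the liquid; pixel origin
at the top-left, (u, v) = (column, row), 0-based.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateGeometryError,
    InsufficientCorrespondencesError,
    UndefinedProjectionError,
    ValidationError,
)

__all__ = [
    "Intrinsics",
    "Extrinsics",
    "CameraView",
    "MarkerGrid",
    "Correspondences",
    "CircleFit",
    "estimate_pose",
    "projection_matrix",
    "project_point",
    "fit_circle",
    "load_marker_layout",
    "load_detections",
    "save_poses",
    "load_poses",
]


@dataclass(frozen=True)
class Intrinsics:
    """Pinhole intrinsics in pixel units.

    Parameters
    ----------
    fx, fy : float
        Focal lengths in pixels.
    cx, cy : float
        Principal point in pixels.
    width, height : int
        Sensor size in pixels.
    dist : ndarray or None
        Optional radial distortion coefficients ``(k1, k2)`` applied to
        normalized image coordinates before the pixel mapping.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    dist: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValidationError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValidationError("principal point must lie inside the image")

    @property
    def K(self) -> np.ndarray:
        """3x3 upper-triangular intrinsic matrix."""
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )


@dataclass(frozen=True)
class Extrinsics:
    """World->camera rigid transform: ``x_cam = R @ x_world + t``.

    ``reproj_rms`` carries the RMS reprojection residual (pixels) when the
    pose came out of :func:`estimate_pose`.
    """

    R: np.ndarray
    t: np.ndarray
    reproj_rms: float | None = None

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        t = np.asarray(self.t, dtype=float).reshape(3)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)
        if R.shape != (3, 3):
            raise ValidationError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValidationError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation must be proper (det = +1)")
        if not np.all(np.isfinite(t)):
            raise ValidationError("translation must be finite")

    @property
    def camera_center(self) -> np.ndarray:
        """Camera center in world coordinates, ``C = -R^T t``."""
        return -self.R.T @ self.t

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous extrinsic matrix."""
        M = np.eye(4)
        M[:3, :3] = self.R
        M[:3, 3] = self.t
        return M

    @classmethod
    def identity(cls) -> "Extrinsics":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class CameraView:
    """One calibrated view: intrinsics + pose + source image identifier."""

    intrinsics: Intrinsics
    extrinsics: Extrinsics
    image_id: str = ""

    @property
    def P(self) -> np.ndarray:
        """3x4 projection matrix ``K [R | t]``."""
        return projection_matrix(self.intrinsics, self.extrinsics)

    @property
    def camera_center(self) -> np.ndarray:
        return self.extrinsics.camera_center


@dataclass(frozen=True)
class MarkerGrid:
    """Known 3D layout of the fiducial strip around the net pot.

    Two rows of markers wrap the pot perimeter, so several markers face any
    viewing direction. Marker IDs must be unique; all centers should sit on a
    common cylinder of the pot radius (checked loosely).
    """

    ids: np.ndarray
    centers: np.ndarray  # (N, 3) mm
    rows: int = 2
    cols: int = 0
    marker_size_mm: float = 10.0
    radius_tol_mm: float = 1.0

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids)
        centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "centers", centers)
        if len(np.unique(ids)) != len(ids):
            raise ValidationError("marker IDs must be unique")
        if len(ids) != len(centers):
            raise ValidationError("ids and centers length mismatch")
        r = np.hypot(centers[:, 0], centers[:, 1])
        if r.size and (r.max() - r.min()) > 2 * self.radius_tol_mm:
            raise ValidationError(
                "marker centers do not lie on a common cylinder "
                f"(radial spread {r.max() - r.min():.3f} mm)"
            )


@dataclass(frozen=True)
class Correspondences:
    """Paired (3D world point mm, 2D image point px) detections for one image."""

    world: np.ndarray  # (N, 3)
    image: np.ndarray  # (N, 2)

    def __post_init__(self) -> None:
        world = np.atleast_2d(np.asarray(self.world, dtype=float))
        image = np.atleast_2d(np.asarray(self.image, dtype=float))
        object.__setattr__(self, "world", world)
        object.__setattr__(self, "image", image)
        if world.shape[0] != image.shape[0]:
            raise ValidationError("world/image point counts differ")

    def __len__(self) -> int:
        return self.world.shape[0]


def projection_matrix(intrinsics: Intrinsics, extrinsics: Extrinsics) -> np.ndarray:
    """Build the 3x4 projection matrix ``P = K [R | t]``.

    Projecting a homogeneous world point through ``P`` and dividing by the
    third coordinate yields the pixel position (ignoring distortion).
    """
    Rt = np.hstack([extrinsics.R, extrinsics.t.reshape(3, 1)])
    return intrinsics.K @ Rt


def _apply_distortion(xn: np.ndarray, dist: np.ndarray | None) -> np.ndarray:
    if dist is None:
        return xn
    k = np.zeros(2)
    k[: len(dist)] = np.asarray(dist, dtype=float)[:2]
    r2 = np.sum(xn**2, axis=-1, keepdims=True)
    return xn * (1.0 + k[0] * r2 + k[1] * r2**2)


def project_point(
    view: CameraView, world_point: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Project world point(s) to pixel coordinates.

    Returns ``(uv, behind)`` where ``uv`` has shape (..., 2) and ``behind`` is
    a boolean flag per point, true when the point lies behind the camera
    (non-positive depth).  A point at the camera center has no projection.
    """
    pts = np.asarray(world_point, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    cam = (view.extrinsics.R @ pts.T).T + view.extrinsics.t
    depth = cam[:, 2]
    if np.any(np.linalg.norm(cam, axis=1) < 1e-12):
        raise UndefinedProjectionError("world point coincides with camera center")
    behind = depth <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        xn = cam[:, :2] / depth[:, None]
    xn = _apply_distortion(xn, view.intrinsics.dist)
    K = view.intrinsics
    uv = np.column_stack([K.fx * xn[:, 0] + K.cx, K.fy * xn[:, 1] + K.cy])
    if single:
        return uv[0], behind[0]
    return uv, behind


# ---------------------------------------------------------------------------
# PnP pose estimation
# ---------------------------------------------------------------------------


def _check_degenerate(world: np.ndarray) -> None:
    centered = world - world.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("correspondences are collinear")


def _dlt_extrinsics(world: np.ndarray, xn: np.ndarray) -> Extrinsics:
    """Direct linear transform for [R|t] from normalized image coordinates."""
    n = len(world)
    A = np.zeros((2 * n, 12))
    Xh = np.hstack([world, np.ones((n, 1))])
    A[0::2, 0:4] = Xh
    A[0::2, 8:12] = -xn[:, 0:1] * Xh
    A[1::2, 4:8] = Xh
    A[1::2, 8:12] = -xn[:, 1:2] * Xh
    _, _, Vt = np.linalg.svd(A)
    M = Vt[-1].reshape(3, 4)
    # Fix sign so points have positive depth, then scale so R is orthonormal.
    depths = Xh @ M[2]
    if np.sum(depths > 0) < n / 2:
        M = -M
    Rr = M[:, :3]
    scale = np.linalg.det(Rr)
    scale = np.cbrt(scale) if scale > 0 else (np.linalg.norm(Rr, ord=2) / 1.0)
    M = M / scale
    U, _, Vt2 = np.linalg.svd(M[:, :3])
    R = U @ Vt2
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt2
    return Extrinsics(R, M[:, 3])


def _refine_pose(
    init: Extrinsics,
    world: np.ndarray,
    image: np.ndarray,
    intrinsics: Intrinsics,
) -> Extrinsics:
    rvec0 = Rotation.from_matrix(init.R).as_rotvec()
    x0 = np.concatenate([rvec0, init.t])

    def residuals(x: np.ndarray) -> np.ndarray:
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        view = CameraView(intrinsics, Extrinsics(R, x[3:]))
        uv, _ = project_point(view, world)
        return (uv - image).ravel()

    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    R = Rotation.from_rotvec(sol.x[:3]).as_matrix()
    rms = float(np.sqrt(np.mean(sol.fun**2))) if sol.fun.size else 0.0
    return Extrinsics(R, sol.x[3:], reproj_rms=rms)


def estimate_pose(
    correspondences: Correspondences, intrinsics: Intrinsics
) -> Extrinsics:
    """Recover the camera pose from marker correspondences (PnP).

    A direct linear transform provides the initial estimate (with a small set
    of deterministic restarts when fewer than six pairs are available), which
    is then refined by Levenberg-Marquardt minimization of the total squared
    pixel reprojection error.  The returned :class:`Extrinsics` carries the
    residual RMS in pixels.

    Raises
    ------
    InsufficientCorrespondencesError
        If fewer than 4 pairs are supplied.
    DegenerateGeometryError
        If the 3D points are collinear.
    """
    n = len(correspondences)
    if n < 4:
        raise InsufficientCorrespondencesError(
            f"PnP requires at least 4 correspondences, got {n}"
        )
    world, image = correspondences.world, correspondences.image
    _check_degenerate(world)
    Kinv = np.linalg.inv(intrinsics.K)
    xn = (Kinv @ np.hstack([image, np.ones((n, 1))]).T).T[:, :2]

    candidates: list[Extrinsics] = []
    if n >= 6:
        candidates.append(_dlt_extrinsics(world, xn))
    else:
        # Minimal case: deterministic multi-start around plausible standoffs.
        span = float(np.linalg.norm(np.ptp(world, axis=0))) or 1.0
        for dz in (2.0, 5.0, 10.0, 20.0):
            t0 = -world.mean(axis=0)
            t0 = np.array([0.0, 0.0, dz * span]) + t0
            candidates.append(Extrinsics(np.eye(3), t0))
        for axis in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])):
            R0 = Rotation.from_rotvec(np.pi / 2 * axis).as_matrix()
            c = world.mean(axis=0)
            candidates.append(Extrinsics(R0, -R0 @ c + np.array([0, 0, 3 * span])))

    best: Extrinsics | None = None
    for cand in candidates:
        try:
            refined = _refine_pose(cand, world, image, intrinsics)
        except (np.linalg.LinAlgError, ValidationError):  # pragma: no cover
            continue
        if best is None or refined.reproj_rms < best.reproj_rms:
            best = refined
    if best is None:  # pragma: no cover
        raise DegenerateGeometryError("pose refinement failed for all starts")
    return best


# ---------------------------------------------------------------------------
# Circle of best fit through camera centers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle through 3D points: center, radius, plane normal."""

    center: np.ndarray
    radius: float
    normal: np.ndarray
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))


def fit_circle(points: np.ndarray) -> CircleFit:
    """Fit a circle to >= 3 points in 3D (least squares).

    The best-fit plane comes from the SVD of the centered points; within that
    plane an algebraic (Kasa) fit seeds a geometric Gauss-Newton refinement of
    center and radius.  Per-point radial residuals (distance to center minus
    radius, in-plane) are attached.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("circle fit needs at least 3 points")
    mean = pts.mean(axis=0)
    centered = pts - mean
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("points are collinear; no unique circle")
    normal = Vt[2]
    e1, e2 = Vt[0], Vt[1]
    xy = np.column_stack([centered @ e1, centered @ e2])

    # Kasa algebraic fit: minimizes |x|^2 - 2 a.x - c over (a, c).
    A = np.column_stack([2 * xy, np.ones(len(xy))])
    b = np.sum(xy**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    a0 = sol[:2]
    r0 = float(np.sqrt(sol[2] + a0 @ a0))

    def residuals(p: np.ndarray) -> np.ndarray:
        return np.hypot(xy[:, 0] - p[0], xy[:, 1] - p[1]) - p[2]

    fit = least_squares(residuals, np.array([a0[0], a0[1], r0]), method="lm")
    cx, cy, r = fit.x
    center = mean + cx * e1 + cy * e2
    return CircleFit(center=center, radius=float(r), normal=normal, residuals=residuals(fit.x))


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------


def load_marker_layout(path: str | Path, **kwargs) -> MarkerGrid:
    """Read a marker layout CSV with columns id, x_mm, y_mm, z_mm."""
    ids, centers = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ids.append(int(row["id"]))
            centers.append([float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])])
    return MarkerGrid(ids=np.array(ids), centers=np.array(centers), **kwargs)


def load_detections(path: str | Path) -> dict[str, dict[int, np.ndarray]]:
    """Read detections CSV (image, id, u_px, v_px) -> {image: {id: (u, v)}}."""
    out: dict[str, dict[int, np.ndarray]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["image"], {})[int(row["id"])] = np.array(
                [float(row["u_px"]), float(row["v_px"])]
            )
    return out


def build_correspondences(
    grid: MarkerGrid, detections: dict[int, np.ndarray]
) -> Correspondences:
    """Match detected marker IDs against the known layout."""
    world, image = [], []
    id_to_center = {int(i): c for i, c in zip(grid.ids, grid.centers)}
    for mid, uv in sorted(detections.items()):
        if mid in id_to_center:
            world.append(id_to_center[mid])
            image.append(uv)
    if not world:
        raise InsufficientCorrespondencesError("no detections match the layout")
    return Correspondences(np.array(world), np.array(image))


def save_poses(views: list[CameraView], path: str | Path) -> None:
    """Write per-image poses and intrinsics as JSON."""
    payload = {}
    for v in views:
        payload[v.image_id] = {
            "R": v.extrinsics.R.tolist(),
            "t": v.extrinsics.t.tolist(),
            "intrinsics": {
                "fx": v.intrinsics.fx,
                "fy": v.intrinsics.fy,
                "cx": v.intrinsics.cx,
                "cy": v.intrinsics.cy,
                "width": v.intrinsics.width,
                "height": v.intrinsics.height,
            },
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_poses(path: str | Path) -> list[CameraView]:
    """Read poses written by :func:`save_poses`."""
    payload = json.loads(Path(path).read_text())
    views = []
    for image_id, blk in payload.items():
        intr = Intrinsics(**blk["intrinsics"])
        ext = Extrinsics(np.array(blk["R"]), np.array(blk["t"]))
        views.append(CameraView(intr, ext, image_id=image_id))
    return views
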