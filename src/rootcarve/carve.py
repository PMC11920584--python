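"""Octree-based space carving against per-view silhouettes.

The reconstruction volume (an axis-aligned cube circumscribing the liquid
column of the canister) starts as one occupied voxel.  Following the
mark-and-refine scheme, each queued voxel is classified against every view
by the fraction of its covering rays that land inside that view's
silhouette: all of them -> consistent ("occupied for this view"), none of
them -> inconsistent (carved), some -> ambiguous, so the voxel splits into
its eight children and the children are re-queued.  Splitting stops at the
target leaf size; the surviving occupied leaves form the discrete visual
hull and their summed cube volumes, V = sum(s_i^3), give the root-volume
estimate.

Two visibility backends implement the per-view coverage test:

* a refracted backend that intersects each voxel with the precomputed
  in-water ray segments of a :class:`~rootcarve.optics.RayField`, and
* a projective backend for the uniform-index (no refraction) limit that
  counts silhouette pixels inside the projected corner bounding box using an
  integral image — a conservative superset of the exact footprint, so the
  all/none decisions remain safe.

Carving is evidence-driven: a voxel unseen by a view keeps its state, and a
voxel seen by no view at all stays occupied and is reported separately as
unobserved volume.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .camera import CameraView
from .errors import (
    AlignmentError,
    EmptyModelError,
    GridMemoryError,
    NoEvidenceError,
    ValidationError,
)
from .optics import Cylinder, RayField, _slab_hits, pixel_visibility_mask, visible_fraction
from .silhouette import Silhouette

__all__ = [
    "VoxelState",
    "CarveConfig",
    "ViewEvidence",
    "OctreeNode",
    "OctreeModel",
    "FlatGrid",
    "classify_voxel",
    "carve",
    "total_volume",
    "to_flat_grid",
    "export_mesh",
]

# Fixed octant order (---, --+, -+-, -++, +--, +-+, ++-, +++) for determinism.
_OCTANTS = np.array(
    [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float
)


class VoxelState(enum.Enum):
    OCCUPIED = "occupied"
    EMPTY = "empty"
    UNDECIDED = "undecided"
    UNSEEN = "unseen"


@dataclass(frozen=True)
class CarveConfig:
    """Carving thresholds and resolution.

    ``tau_full``/``tau_empty`` bound the covering-ray fraction for the
    all/none classification (defaults 1.0 / 0.0: any disagreement splits).
    ``s_min`` is the target leaf side in mm (default 0.27 mm, the working
    resolution of the calibration experiments; coarser values trade
    fidelity for speed).
    ``min_views_to_carve`` relaxes intersection semantics: a voxel is carved
    once at least that many views find it empty (1 = classic visual hull).
    """

    tau_full: float = 1.0
    tau_empty: float = 0.0
    s_min: float = 0.27
    min_views_to_carve: int = 1
    max_depth: int | None = None
    max_grid_cells: int = 2**27

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau_empty < self.tau_full <= 1.0):
            raise ValidationError("need 0 <= tau_empty < tau_full <= 1")
        if self.s_min <= 0:
            raise ValidationError("s_min must be positive")
        if self.min_views_to_carve < 1:
            raise ValidationError("min_views_to_carve must be >= 1")


@dataclass(frozen=True)
class ViewEvidence:
    """One view's carving evidence: pose + silhouette (+ refracted rays).

    When ``rayfield`` is None the view is treated as refraction-free and
    classified by direct projection.
    """

    view: CameraView
    silhouette: Silhouette
    rayfield: RayField | None = None


@dataclass
class OctreeNode:
    """One octree cell; children (exactly 8, fixed octant order) tile it."""

    center: np.ndarray
    size: float
    state: VoxelState = VoxelState.UNDECIDED
    children: tuple["OctreeNode", ...] = ()

    def is_leaf(self) -> bool:
        return not self.children


# ---------------------------------------------------------------------------
# Visibility backends
# ---------------------------------------------------------------------------


class _ProjectiveBackend:
    """Straight-ray coverage counts via an integral image.

    The voxel footprint is over-approximated by the pixel bounding box of
    its eight projected corners (projection of a convex body is the convex
    hull of the projected vertices, so the box is a superset).  Counting
    silhouette pixels in the box with a summed-area table makes each
    classification O(1).
    """

    def __init__(self, view: CameraView, silhouette: Silhouette):
        self.R = view.extrinsics.R
        self.t = view.extrinsics.t
        K = view.intrinsics
        mask = silhouette.mask
        self.h, self.w = mask.shape
        # Grid may be decoupled from the sensor: scale pixel coordinates.
        self.sx = self.w / K.width
        self.sy = self.h / K.height
        self.fx, self.fy = K.fx, K.fy
        self.cx, self.cy = K.cx, K.cy
        sat = np.zeros((self.h + 1, self.w + 1), dtype=np.int64)
        np.cumsum(np.cumsum(mask, axis=0), axis=1, out=sat[1:, 1:])
        self.sat = sat

    def classify_batch(self, centers: np.ndarray, size: float) -> tuple[np.ndarray, np.ndarray]:
        corners = centers[:, None, :] + (size / 2.0) * _OCTANTS[None, :, :]
        cam = corners @ self.R.T + self.t
        depth = cam[..., 2]
        seen = np.all(depth > 1e-9, axis=1)
        depth = np.where(depth > 1e-9, depth, 1.0)
        u = (self.fx * cam[..., 0] / depth + self.cx + 0.5) * self.sx - 0.5
        v = (self.fy * cam[..., 1] / depth + self.cy + 0.5) * self.sy - 0.5
        # Pixels whose centers fall inside the projected bounding box.
        c0 = np.ceil(u.min(axis=1) - 1e-9).astype(np.int64)
        c1 = np.floor(u.max(axis=1) + 1e-9).astype(np.int64)
        r0 = np.ceil(v.min(axis=1) - 1e-9).astype(np.int64)
        r1 = np.floor(v.max(axis=1) + 1e-9).astype(np.int64)
        c0 = np.clip(c0, 0, self.w - 1)
        c1 = np.clip(c1, -1, self.w - 1)
        r0 = np.clip(r0, 0, self.h - 1)
        r1 = np.clip(r1, -1, self.h - 1)
        seen &= (c1 >= c0) & (r1 >= r0)
        total = np.where(seen, (c1 - c0 + 1) * (r1 - r0 + 1), 0)
        sat = self.sat
        covered = (
            sat[r1 + 1, c1 + 1] - sat[r0, c1 + 1] - sat[r1 + 1, c0] + sat[r0, c0]
        )
        return np.where(seen, covered, 0), total


class _RayFieldBackend:
    """Refracted-ray coverage counts via the voxel slab test."""

    _CHUNK_ELEMS = 4_000_000

    def __init__(self, rayfield: RayField, silhouette: Silhouette):
        if rayfield.grid_shape != silhouette.mask.shape:
            raise AlignmentError(
                f"ray grid {rayfield.grid_shape} vs silhouette {silhouette.mask.shape}"
            )
        flat_valid = rayfield.valid.ravel()
        self.origins = rayfield.origins.reshape(-1, 3)[flat_valid]
        self.dirs = rayfield.directions.reshape(-1, 3)[flat_valid]
        self.sil = silhouette.mask.ravel()[flat_valid]

    def classify_batch(self, centers: np.ndarray, size: float) -> tuple[np.ndarray, np.ndarray]:
        n = len(centers)
        m = len(self.origins)
        covered = np.zeros(n, dtype=np.int64)
        total = np.zeros(n, dtype=np.int64)
        if m == 0:
            return covered, total
        chunk = max(1, self._CHUNK_ELEMS // m)
        half = size / 2.0
        for i in range(0, n, chunk):
            c = centers[i : i + chunk]
            lo = (c - half)[:, None, :]
            hi = (c + half)[:, None, :]
            hits = _slab_hits(self.origins[None, :, :], self.dirs[None, :, :], lo, hi)
            total[i : i + chunk] = hits.sum(axis=1)
            covered[i : i + chunk] = (hits & self.sil[None, :]).sum(axis=1)
        return covered, total


def _make_backend(ev: ViewEvidence):
    if ev.rayfield is None:
        return _ProjectiveBackend(ev.view, ev.silhouette)
    return _RayFieldBackend(ev.rayfield, ev.silhouette)


def classify_voxel(
    node: OctreeNode | tuple[np.ndarray, float],
    view: CameraView,
    silhouette: Silhouette,
    rayfield: RayField | None = None,
    config: CarveConfig | None = None,
    cylinder: Cylinder | None = None,
) -> VoxelState:
    """Classify one voxel against one view.

    Returns OCCUPIED when the covering-ray fraction inside the silhouette is
    >= tau_full, EMPTY when <= tau_empty, UNDECIDED in between, and UNSEEN
    when no ray covers the voxel (the voxel must then keep its prior state —
    absence of evidence cannot carve).
    """
    cfg = config or CarveConfig()
    if isinstance(node, OctreeNode):
        center, size = node.center, node.size
    else:
        center, size = node
    center = np.asarray(center, dtype=float).reshape(1, 3)
    if rayfield is not None:
        vis = pixel_visibility_mask(center[0], size / 2.0, rayfield, cylinder)
        if not vis.mask.any():
            return VoxelState.UNSEEN
        frac = visible_fraction(vis, silhouette)
        total = 1
    else:
        backend = _ProjectiveBackend(view, silhouette)
        covered, total_arr = backend.classify_batch(center, size)
        total = int(total_arr[0])
        if total == 0:
            return VoxelState.UNSEEN
        frac = covered[0] / total
    if frac >= cfg.tau_full:
        return VoxelState.OCCUPIED
    if frac <= cfg.tau_empty:
        return VoxelState.EMPTY
    return VoxelState.UNDECIDED


# ---------------------------------------------------------------------------
# Geometric pre-mask against the liquid cylinder
# ---------------------------------------------------------------------------

_GEO_INSIDE, _GEO_OUTSIDE, _GEO_STRADDLE = 0, 1, 2


def _box_vs_cylinder(centers: np.ndarray, size: float, cyl: Cylinder) -> np.ndarray:
    """Classify axis-aligned cubes against the inner liquid volume."""
    if abs(cyl.axis @ np.array([0.0, 0.0, 1.0])) < 1.0 - 1e-9:
        return np.full(len(centers), _GEO_STRADDLE, dtype=np.int8)  # pragma: no cover
    half = size / 2.0
    dx = np.abs(centers[:, 0] - cyl.origin[0])
    dy = np.abs(centers[:, 1] - cyl.origin[1])
    z = centers[:, 2] - cyl.origin[2]
    r = cyl.inner_radius
    min_d2 = np.maximum(dx - half, 0) ** 2 + np.maximum(dy - half, 0) ** 2
    max_d2 = (dx + half) ** 2 + (dy + half) ** 2
    z_out = (z - half >= cyl.height) | (z + half <= 0)
    z_in = (z - half >= 0) & (z + half <= cyl.height)
    out = (min_d2 >= r * r) | z_out
    inside = (max_d2 <= r * r) & z_in
    codes = np.full(len(centers), _GEO_STRADDLE, dtype=np.int8)
    codes[out] = _GEO_OUTSIDE
    codes[inside] = _GEO_INSIDE
    return codes


# ---------------------------------------------------------------------------
# The carver
# ---------------------------------------------------------------------------

_ST_OCCUPIED, _ST_EMPTY, _ST_SPLIT = 0, 1, 2


@dataclass
class _Level:
    size: float
    centers: np.ndarray
    status: np.ndarray  # _ST_* per node
    unobserved: np.ndarray  # True where occupied purely for lack of evidence


@dataclass
class OctreeModel:
    """Carved octree: per-level arrays of node centers and final states."""

    root_center: np.ndarray
    root_size: float
    s_min: float
    levels: list[_Level] = field(default_factory=list)
    n_views: int = 0

    def occupied_leaves(self) -> list[tuple[float, np.ndarray]]:
        """List of (leaf side mm, centers (N, 3)) per refinement level."""
        out = []
        for lv in self.levels:
            occ = lv.status == _ST_OCCUPIED
            if occ.any():
                out.append((lv.size, lv.centers[occ]))
        return out

    @property
    def n_occupied(self) -> int:
        return sum(len(c) for _, c in self.occupied_leaves())

    @property
    def leaf_size(self) -> float:
        """Side length of the finest leaves actually produced."""
        return self.levels[-1].size if self.levels else self.root_size

    def unobserved_volume_mL(self) -> float:
        v = 0.0
        for lv in self.levels:
            n = int((lv.unobserved & (lv.status == _ST_OCCUPIED)).sum())
            v += n * lv.size**3
        return v / 1000.0

    def to_tree(self) -> OctreeNode:
        """Materialize the explicit node tree (small models only)."""
        def build(center: np.ndarray, size: float, depth: int) -> OctreeNode:
            lv = self.levels[depth]
            idx = np.flatnonzero(np.all(np.isclose(lv.centers, center, atol=size * 1e-6), axis=1))
            if idx.size == 0:  # pragma: no cover
                return OctreeNode(center, size, VoxelState.EMPTY)
            st = lv.status[idx[0]]
            if st == _ST_SPLIT:
                kids = tuple(
                    build(center + (size / 4.0) * off, size / 2.0, depth + 1)
                    for off in _OCTANTS
                )
                return OctreeNode(center, size, VoxelState.UNDECIDED, kids)
            state = VoxelState.OCCUPIED if st == _ST_OCCUPIED else VoxelState.EMPTY
            return OctreeNode(center, size, state)

        return build(self.root_center, self.root_size, 0)


def carve(
    views: list[ViewEvidence],
    config: CarveConfig | None = None,
    cylinder: Cylinder | None = None,
    root_center: np.ndarray | None = None,
    root_size: float | None = None,
) -> OctreeModel:
    """Breadth-first mark-and-refine space carving.

    Each level's nodes are classified against every view; a node empty in
    ``min_views_to_carve`` views is carved, a node ambiguous in any view (or
    straddling the liquid boundary) splits while its children would still be
    >= ``s_min``, and everything else is kept occupied.  The root cube
    defaults to the axis-aligned cube circumscribing the liquid column of
    ``cylinder``.
    """
    cfg = config or CarveConfig()
    if not views:
        raise NoEvidenceError("carving requires at least one view")
    shapes = {ev.silhouette.mask.shape for ev in views}
    if len(shapes) > 1:
        raise AlignmentError(f"inconsistent silhouette shapes: {sorted(shapes)}")

    if root_center is None or root_size is None:
        if cylinder is None:
            raise ValidationError("need either a cylinder or an explicit root box")
        root_size = float(max(2 * cylinder.inner_radius, cylinder.height))
        root_center = cylinder.origin + cylinder.axis * (cylinder.height / 2.0)
    root_center = np.asarray(root_center, dtype=float).reshape(3)

    backends = [_make_backend(ev) for ev in views]
    model = OctreeModel(root_center=root_center, root_size=float(root_size), s_min=cfg.s_min, n_views=len(views))

    centers = root_center.reshape(1, 3)
    size = float(root_size)
    depth = 0
    while len(centers):
        n = len(centers)
        geo = (
            _box_vs_cylinder(centers, size, cylinder)
            if cylinder is not None
            else np.full(n, _GEO_INSIDE, dtype=np.int8)
        )
        n_empty_views = np.zeros(n, dtype=np.int32)
        any_undecided = np.zeros(n, dtype=bool)
        seen_any = np.zeros(n, dtype=bool)
        active = geo != _GEO_OUTSIDE
        if active.any():
            act_idx = np.flatnonzero(active)
            act_centers = centers[act_idx]
            for be in backends:
                covered, total = be.classify_batch(act_centers, size)
                seen = total > 0
                with np.errstate(invalid="ignore", divide="ignore"):
                    frac = np.where(seen, covered / np.maximum(total, 1), 0.0)
                v_empty = seen & (frac <= cfg.tau_empty)
                v_full = seen & (frac >= cfg.tau_full)
                n_empty_views[act_idx] += v_empty
                any_undecided[act_idx] |= seen & ~v_empty & ~v_full
                seen_any[act_idx] |= seen

        empty = (geo == _GEO_OUTSIDE) | (n_empty_views >= cfg.min_views_to_carve)
        splittable = size / 2.0 >= cfg.s_min * (1 - 1e-9)
        if cfg.max_depth is not None and depth >= cfg.max_depth:
            splittable = False
        want_split = ~empty & (any_undecided | (geo == _GEO_STRADDLE))
        if splittable:
            split = want_split
        else:
            split = np.zeros(n, dtype=bool)
            # Terminal straddle nodes: keep only those centered in the liquid.
            if cylinder is not None:
                term = (geo == _GEO_STRADDLE) & ~empty
                empty |= term & ~cylinder.contains_water(centers)

        status = np.full(n, _ST_OCCUPIED, dtype=np.int8)
        status[empty] = _ST_EMPTY
        status[split & ~empty] = _ST_SPLIT
        unobserved = (status == _ST_OCCUPIED) & ~seen_any
        model.levels.append(_Level(size=size, centers=centers, status=status, unobserved=unobserved))

        parents = centers[status == _ST_SPLIT]
        if len(parents) == 0:
            break
        centers = (parents[:, None, :] + (size / 4.0) * _OCTANTS[None, :, :]).reshape(-1, 3)
        size /= 2.0
        depth += 1
    return model


def total_volume(model: OctreeModel) -> float:
    """Total occupied volume, V = sum over leaves of s_i^3, in mL."""
    v_mm3 = sum(size**3 * len(centers) for size, centers in model.occupied_leaves())
    return v_mm3 / 1000.0


@dataclass(frozen=True)
class FlatGrid:
    """Dense occupancy grid sampled from an octree at uniform spacing."""

    occupancy: np.ndarray  # bool (nx, ny, nz)
    origin: np.ndarray  # world position of the grid's low corner
    spacing: float

    @property
    def volume_mL(self) -> float:
        return float(self.occupancy.sum()) * self.spacing**3 / 1000.0


def to_flat_grid(model: OctreeModel, s: float | None = None, max_cells: int | None = None) -> FlatGrid:
    """Sample the octree onto a dense grid at resolution ``s``.

    ``s`` defaults to the finest leaf size; it must subdivide the root cube
    evenly.  Guarded by a cell cap to avoid accidental huge allocations.
    """
    s = float(s if s is not None else model.leaf_size)
    n = int(round(model.root_size / s))
    if abs(n * s - model.root_size) > 1e-6 * model.root_size:
        raise ValidationError(f"spacing {s} does not evenly divide root size {model.root_size}")
    cap = max_cells if max_cells is not None else CarveConfig().max_grid_cells
    if n**3 > cap:
        raise GridMemoryError(f"grid {n}^3 exceeds cell cap {cap}")
    occ = np.zeros((n, n, n), dtype=bool)
    origin = model.root_center - model.root_size / 2.0
    for size, centers in model.occupied_leaves():
        k = int(round(size / s))
        lo = np.rint((centers - origin - size / 2.0) / s).astype(int)
        if k == 1:
            occ[lo[:, 0], lo[:, 1], lo[:, 2]] = True
        else:
            for i0, j0, k0 in lo:
                occ[i0 : i0 + k, j0 : j0 + k, k0 : k0 + k] = True
    return FlatGrid(occupancy=occ, origin=origin, spacing=s)


# Quad corner offsets per face direction, wound so normals point outward.
_FACE_TABLES = {
    (+1, 0, 0): [(1, 0, 0), (1, 1, 0), (1, 1, 1), (1, 0, 1)],
    (-1, 0, 0): [(0, 0, 0), (0, 0, 1), (0, 1, 1), (0, 1, 0)],
    (0, +1, 0): [(0, 1, 0), (0, 1, 1), (1, 1, 1), (1, 1, 0)],
    (0, -1, 0): [(0, 0, 0), (1, 0, 0), (1, 0, 1), (0, 0, 1)],
    (0, 0, +1): [(0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)],
    (0, 0, -1): [(0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 0, 0)],
}


def export_mesh(model: OctreeModel, path: str | Path | None = None, s: float | None = None):
    """Export the occupied set as a watertight cube-union surface mesh.

    The octree is flattened at the finest leaf size and boundary faces
    (occupied cell with empty neighbor) are emitted as outward-wound quads;
    shared faces between adjacent occupied cells cancel.  The signed mesh
    volume therefore equals the voxel volume exactly.  Writes PLY/OBJ/STL
    when ``path`` is given; returns the :class:`trimesh.Trimesh`.
    """
    import trimesh

    grid = to_flat_grid(model, s)
    occ = grid.occupancy
    if not occ.any():
        raise EmptyModelError("cannot mesh an empty model")
    pad = np.pad(occ, 1, constant_values=False)
    quads = []
    for (dx, dy, dz), table in _FACE_TABLES.items():
        nb = pad[1 + dx : pad.shape[0] - 1 + dx,
                 1 + dy : pad.shape[1] - 1 + dy,
                 1 + dz : pad.shape[2] - 1 + dz]
        idx = np.argwhere(occ & ~nb)
        if idx.size == 0:
            continue
        offs = np.array(table, dtype=float)  # (4, 3)
        quads.append(idx[:, None, :] + offs[None, :, :])
    cells = np.concatenate(quads, axis=0)  # (F, 4, 3) in cell units
    key = np.rint(cells.reshape(-1, 3) * 2).astype(np.int64)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    vertices = grid.origin + uniq / 2.0 * grid.spacing
    f = inv.reshape(-1, 4)
    faces = np.concatenate([f[:, [0, 1, 2]], f[:, [0, 2, 3]]], axis=0)
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if path is not None:
        mesh.export(str(Path(path)))
    return mesh
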