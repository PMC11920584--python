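"""Hybrid silhouette extraction for backlit root images.

Thin roots photograph as faint, pixel-wide strokes while storage organs
(radish, carrot) form large dark blobs; neither a pure edge detector nor a
single global threshold captures both.  The pipeline here combines the two:

1. a global Otsu threshold segments large dark structures,
2. Sobel gradient magnitude + hysteresis thresholding keeps thin, connected
   root edges that the global threshold misses,
3. the union of both masks, restricted to a region-of-interest (the canister
   interior as seen by the camera), is cleaned with a morphological opening.

The resulting binary mask is the carving evidence for one view.  Every
threshold actually used is recorded in the silhouette's provenance so a mask
can be audited or regenerated bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ConstantImageError, InvalidThresholdError, ValidationError

__all__ = [
    "Silhouette",
    "SilhouetteConfig",
    "otsu_threshold",
    "sobel_magnitude",
    "hysteresis_threshold",
    "simple_threshold",
    "morphological_open",
    "extract_silhouette",
    "read_gray_image",
    "write_silhouette",
]

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


@dataclass(frozen=True)
class Silhouette:
    """Binary foreground mask (True = root) plus extraction provenance."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.dtype != bool:
            m = m.astype(bool)
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def foreground_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SilhouetteConfig:
    """Tunable parameters of the hybrid pipeline.

    ``polarity`` is 'dark' for dark roots on a bright backlit background
    (the default rig) or 'bright' for the opposite.  Hysteresis thresholds
    are expressed as fractions of the Otsu threshold of the normalized
    gradient magnitude, anchoring the otherwise free parameters to a
    histogram-derived quantity.
    """

    polarity: str = "dark"
    hysteresis_low_frac: float = 0.5
    hysteresis_high_frac: float = 1.0
    open_radius: int = 1
    use_edges: bool = True

    def __post_init__(self) -> None:
        if self.polarity not in ("dark", "bright"):
            raise ValidationError("polarity must be 'dark' or 'bright'")
        if not (0 < self.hysteresis_low_frac <= self.hysteresis_high_frac):
            raise ValidationError("need 0 < low_frac <= high_frac")
        if self.open_radius < 0:
            raise ValidationError("open_radius must be >= 0")


def _as_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        # ITU-R BT.601 luma
        img = img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114
    if img.ndim != 2 or img.size == 0:
        raise ValidationError("image must be a non-empty 2D array")
    if not np.all(np.isfinite(img)):
        raise ValidationError("image contains non-finite values")
    return img


def otsu_threshold(image: np.ndarray) -> float:
    """Global threshold maximizing between-class variance (Otsu).

    Raises :class:`ConstantImageError` when the image has a single intensity
    value, for which no threshold is defined.
    """
    img = _as_gray(image)
    if np.ptp(img) == 0:
        raise ConstantImageError("Otsu threshold undefined for a constant image")
    arr = np.asarray(image)
    if (
        arr.ndim == 2
        and np.issubdtype(arr.dtype, np.integer)
        and arr.min() >= 0
        and arr.max() <= 255
    ):
        # Exact exhaustive maximization over the 8-bit histogram; pixels
        # <= threshold form the low class.
        hist = np.bincount(arr.ravel().astype(np.int64), minlength=256).astype(float)
        levels = np.arange(256, dtype=float)
        w0 = np.cumsum(hist)
        w1 = w0[-1] - w0
        cum = np.cumsum(hist * levels)
        with np.errstate(invalid="ignore", divide="ignore"):
            mu0 = cum / w0
            mu1 = (cum[-1] - cum) / w1
            var = w0 * w1 * (mu0 - mu1) ** 2
        var[(w0 == 0) | (w1 == 0)] = -1.0
        t_low = int(np.argmax(var))
        t_next = int(np.argmax(hist[t_low + 1 :] > 0)) + t_low + 1
        # Midway between the two classes; same partition as the cut itself.
        return (t_low + t_next) / 2.0
    return float(threshold_otsu(img))


def sobel_magnitude(image: np.ndarray) -> np.ndarray:
    """Gradient magnitude sqrt(gx^2 + gy^2) from 3x3 Sobel kernels.

    Borders are handled by reflection.
    """
    img = _as_gray(image)
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    return np.hypot(gx, gy)


def hysteresis_threshold(
    magnitude: np.ndarray, low: float, high: float
) -> np.ndarray:
    """Double threshold with 8-connected hysteresis linking.

    Pixels >= ``high`` are kept unconditionally; pixels in ``[low, high)``
    are kept iff they connect (8-connectivity, through other kept pixels) to
    a strong pixel.
    """
    if not (0 <= low <= high):
        raise InvalidThresholdError(f"need 0 <= low <= high, got {low}, {high}")
    mag = np.asarray(magnitude, dtype=float)
    strong = mag >= high
    weak = mag >= low
    labels, n = ndimage.label(weak, structure=_EIGHT)
    if n == 0:
        return np.zeros_like(weak)
    keep = np.zeros(n + 1, dtype=bool)
    keep[np.unique(labels[strong])] = True
    keep[0] = False
    return keep[labels]


def simple_threshold(
    image: np.ndarray, threshold: float, polarity: str = "dark"
) -> np.ndarray:
    """Global threshold with configurable foreground polarity.

    'dark' marks pixels strictly below the threshold as foreground (backlit
    roots); 'bright' marks pixels strictly above it.
    """
    img = _as_gray(image)
    if polarity == "dark":
        return img < threshold
    if polarity == "bright":
        return img > threshold
    raise ValidationError("polarity must be 'dark' or 'bright'")


def morphological_open(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Binary opening (erosion then dilation) with a square element.

    The structuring element is a (2*radius+1) square; radius 0 is a no-op.
    Opening removes isolated specks up to the element size and is idempotent.
    """
    m = np.asarray(mask, dtype=bool)
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    if radius == 0:
        return m.copy()
    k = 2 * radius + 1
    return ndimage.binary_opening(m, structure=np.ones((k, k), dtype=bool))


def extract_silhouette(
    image: np.ndarray,
    config: SilhouetteConfig | None = None,
    roi: np.ndarray | None = None,
) -> Silhouette:
    """Run the full hybrid pipeline on one image.

    The edge channel (Sobel + hysteresis) preserves thin roots; the global
    Otsu channel captures large structures.  Their union, restricted to the
    optional region-of-interest mask, is opened to drop speckle.
    """
    cfg = config or SilhouetteConfig()
    img = _as_gray(image)
    provenance: dict = {"polarity": cfg.polarity, "open_radius": cfg.open_radius}

    if np.ptp(img) == 0:
        # Featureless frame: empty silhouette rather than an error, so batch
        # runs on blank background captures degrade gracefully.
        mask = np.zeros(img.shape, dtype=bool)
        provenance["constant_image"] = True
        return Silhouette(mask=mask, provenance=provenance)

    t_global = otsu_threshold(img)
    provenance["otsu_threshold"] = t_global
    solid = simple_threshold(img, t_global, cfg.polarity)

    if cfg.use_edges:
        mag = sobel_magnitude(img)
        mmax = mag.max()
        mag_n = mag / mmax if mmax > 0 else mag
        if np.ptp(mag_n) > 0:
            t_edge = otsu_threshold(mag_n)
        else:  # pragma: no cover - flat gradient of non-constant image
            t_edge = 0.5
        low = cfg.hysteresis_low_frac * t_edge
        high = cfg.hysteresis_high_frac * t_edge
        edges = hysteresis_threshold(mag_n, low, high)
        # The Sobel response straddles a boundary: its outer half lies on
        # background pixels hugging the dark region. Drop edge pixels that
        # touch the solid mask but sit on the background side of the global
        # threshold, so large structures are not inflated by a halo.
        fringe = ndimage.binary_dilation(solid, structure=_EIGHT) & ~solid
        background = img >= t_global if cfg.polarity == "dark" else img <= t_global
        edges &= ~(fringe & background)
        provenance["hysteresis_low"] = low
        provenance["hysteresis_high"] = high
    else:
        edges = np.zeros_like(solid)

    combined = solid | edges
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != combined.shape:
            raise ValidationError("ROI shape does not match image")
        combined &= roi
        provenance["roi"] = True
    opened = morphological_open(combined, cfg.open_radius)
    return Silhouette(mask=opened, provenance=provenance)


# ---------------------------------------------------------------------------
# Image and mask I/O
# ---------------------------------------------------------------------------


def read_gray_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image (8/16-bit, gray or RGB) as float in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    arr = arr.astype(float)
    if arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[..., :3]
    if arr.max() > 1.0:
        arr = arr / (65535.0 if arr.max() > 255 else 255.0)
    return _as_gray(arr)


def write_silhouette(
    sil: Silhouette, path: str | Path, sidecar: bool = True
) -> None:
    """Write a silhouette as 1-bit PNG plus an optional JSON provenance sidecar."""
    path = Path(path)
    Image.fromarray(sil.mask).convert("1").save(path)
    if sidecar:
        path.with_suffix(".json").write_text(json.dumps(sil.provenance, indent=1))
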