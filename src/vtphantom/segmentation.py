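"""Edge-enhanced, semi-automatic articulator segmentation.

The pipeline mirrors how dynamic speech images are segmented in practice:

1. each frame is augmented with a Canny edge map scaled to a fraction
   (default 0.2) of the frame maximum, which sharpens tissue boundaries for
   thresholding;
2. a whole-head binary mask is produced by thresholding (Otsu by default),
   filling enclosed signal voids in non-speech tissue while preserving the
   upper airway (border-connected air, or air components marked by a user
   seed point);
3. each articulator mask is the Hadamard product of the per-frame head mask
   with a fixed user-drawn region-of-interest polygon large enough to
   contain the articulator's full range of motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, filters
from skimage.draw import polygon2mask

from .core import Geometry, RegionMaskSeries

ARTICULATORS = ("velum", "tongue", "epiglottis", "mandible", "maxilla")


@dataclass(frozen=True)
class RoiSpec:
    """A named, frame-invariant region-of-interest polygon.

    Vertices are (row, col) pixel coordinates, 0-based.  A pixel belongs to
    the ROI when its centre is inside the polygon under the even-odd rule
    (``skimage.draw.polygon2mask``); rasterisation is deterministic.
    """

    region_name: str
    polygon: tuple  # ((r, c), ...)

    def __post_init__(self):
        if self.region_name not in ARTICULATORS:
            raise ValueError(
                f"region_name must be one of {ARTICULATORS}, got {self.region_name!r}"
            )
        poly = tuple((float(r), float(c)) for r, c in self.polygon)
        if len(poly) < 3:
            raise ValueError("polygon needs >= 3 vertices")
        if _self_intersects(poly):
            raise ValueError("polygon must be simple (non-self-intersecting)")
        object.__setattr__(self, "polygon", poly)

    def rasterise(self, shape: tuple[int, int]) -> np.ndarray:
        return polygon2mask(shape, np.asarray(self.polygon))


def _segments_cross(p, q, r, s) -> bool:
    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

    return (
        orient(p, q, r) != orient(p, q, s)
        and orient(r, s, p) != orient(r, s, q)
        and 0 not in (orient(p, q, r), orient(p, q, s), orient(r, s, p), orient(r, s, q))
    )


def _self_intersects(poly) -> bool:
    n = len(poly)
    edges = [(poly[i], poly[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue  # shared-vertex neighbours
            if _segments_cross(*edges[i], *edges[j]):
                return True
    return False


@dataclass
class EnhancedFrame:
    """A frame plus the weight of the Canny edge contribution added to it."""

    pixels: np.ndarray
    edge_weight: float


def enhance_edges(
    frame: np.ndarray,
    edge_weight: float = 0.2,
    sigma: float = 1.0,
    high_quantile: float = 0.90,
    low_fraction: float = 0.4,
) -> EnhancedFrame:
    """Add a scaled binary Canny edge map to ``frame``.

    Output is ``frame + edge_weight * max(frame) * edges``.  Hysteresis
    thresholds are taken from the gradient-magnitude histogram: the high
    threshold is its ``high_quantile`` percentile, the low threshold
    ``low_fraction`` of that.  A constant frame has no edges and is
    returned unchanged.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame must be finite")
    if edge_weight < 0:
        raise ValueError(f"edge_weight must be >= 0, got {edge_weight}")
    peak = frame.max()
    if edge_weight == 0 or np.ptp(frame) == 0:
        return EnhancedFrame(pixels=frame.copy(), edge_weight=edge_weight)
    grad = filters.sobel(frame)
    mags = grad[grad > 0]
    high = np.percentile(mags, 100 * high_quantile) if mags.size else None
    low = low_fraction * high if high is not None else None
    edges = feature.canny(frame, sigma=sigma, low_threshold=low, high_threshold=high)
    return EnhancedFrame(pixels=frame + edge_weight * peak * edges, edge_weight=edge_weight)


def head_mask(
    frame: EnhancedFrame | np.ndarray,
    threshold: float | str = "otsu",
    keep_airway: bool = True,
    airway_seeds: tuple = (),
) -> np.ndarray:
    """Threshold a frame into a whole-head mask with the airway kept open.

    Pixels above ``threshold`` (Otsu's threshold when ``"otsu"``) form the
    initial mask.  Below-threshold components are then classified: those
    reaching the image border stay background (the mouth opening makes the
    oral/pharyngeal airway border-connected); enclosed components are signal
    voids in non-speech tissue and are filled, unless ``keep_airway`` is set
    and the component touches one of ``airway_seeds`` (row, col) points --
    the "user input" that keeps e.g. a sealed nasopharynx as air.
    """
    pixels = frame.pixels if isinstance(frame, EnhancedFrame) else np.asarray(frame, float)
    if threshold == "otsu":
        if np.ptp(pixels) == 0:
            raise ValueError("cannot auto-threshold a constant frame")
        threshold = filters.threshold_otsu(pixels)
    mask = pixels > threshold
    if not mask.any():
        raise ValueError(f"threshold {threshold} leaves an empty head mask")
    below = ~mask
    labels, n = ndimage.label(below)
    border_labels = set(np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]
    ])))
    border_labels.discard(0)
    airway_labels = set()
    if keep_airway:
        for r, c in airway_seeds:
            lab = labels[int(r), int(c)]
            if lab == 0:
                warnings.warn(f"airway seed ({r}, {c}) is not in an air region")
            else:
                airway_labels.add(lab)
    fill = below & ~np.isin(labels, sorted(border_labels | airway_labels))
    return mask | fill


def articulator_masks(
    head_masks: np.ndarray,
    rois: list[RoiSpec],
    fps: float = 1.0,
    geometry: Geometry | None = None,
) -> RegionMaskSeries:
    """Per-frame articulator masks: head mask Hadamard-multiplied with each
    rasterised ROI polygon.  The ``head`` region is the head mask minus the
    union of articulator masks (overlap between articulators is resolved
    later by the mask-optimisation stage)."""
    head_masks = np.asarray(head_masks, dtype=bool)
    if head_masks.ndim == 2:
        head_masks = head_masks[None]
    T, H, W = head_masks.shape
    seen = set()
    masks: dict[str, np.ndarray] = {}
    union = np.zeros_like(head_masks)
    for roi in rois:
        if roi.region_name in seen:
            raise ValueError(f"duplicate ROI for region {roi.region_name!r}")
        seen.add(roi.region_name)
        for r, c in roi.polygon:
            if not (0 <= r <= H - 1 and 0 <= c <= W - 1):
                raise ValueError(f"ROI {roi.region_name!r} vertex ({r}, {c}) out of bounds")
        raster = roi.rasterise((H, W))
        region = head_masks & raster
        if not region.any():
            warnings.warn(f"ROI {roi.region_name!r} is disjoint from the head mask")
        masks[roi.region_name] = region
        union |= region
    masks["head"] = head_masks & ~union
    geometry = geometry or Geometry(matrix=H, fov_mm=float(H))
    return RegionMaskSeries(masks=masks, fps=fps, geometry=geometry)
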