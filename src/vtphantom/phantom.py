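"""Mask optimisation, distance-transform interpolation and phantom rendering.

The phantom is a set of per-frame binary region masks that is (1) cleaned
morphologically, (2) made pairwise disjoint by prioritised logical
operations (``mask AND NOT higher-priority masks``), (3) interpolated in
time by thresholding linear blends of signed Euclidean distance transforms,
(4) resampled to the target grid, and (5) rendered as uniform-intensity
frames whose centred FFT is the k-space phantom.

The signed distance convention is negative inside the object with the
boundary included by ``d <= 0``; all temporal and spatial interpolation
operates on that signed field so the interpolants stay binary masks.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import morphology

from .core import (
    DynamicImageSeries,
    Geometry,
    KSpaceSeries,
    RegionMaskSeries,
    cfft2,
    cifft2,
)

#: signed distance assigned to an empty mask so objects shrink to extinction
_EMPTY_DIST_FACTOR = 4.0


def clean_mask(mask: np.ndarray, min_component_px: int = 4, radius_px: int = 1) -> np.ndarray:
    """Morphological mask optimisation.

    Removes connected components below ``min_component_px``, applies closing
    then opening with a disk of ``radius_px`` to smooth rough protrusions,
    and fills interior holes (signal voids, e.g. susceptibility dropout in
    the tongue).  Empty input yields empty output.
    """
    if radius_px < 0:
        raise ValueError(f"radius_px must be >= 0, got {radius_px}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    # max_size semantics: removes components smaller than min_component_px
    out = morphology.remove_small_objects(mask, max_size=min_component_px - 1)
    if radius_px > 0:
        disk = morphology.disk(radius_px)
        out = morphology.closing(out, disk)
        out = morphology.opening(out, disk)
    return ndimage.binary_fill_holes(out)


def resolve_overlaps(series: RegionMaskSeries) -> RegionMaskSeries:
    """Remove mask overlap with prioritised logical operators.

    Regions are visited in priority order; each becomes
    ``mask AND NOT union(higher-priority masks)``.  The head region comes
    last in the default order and therefore additionally loses every
    articulator pixel.  Output masks are pairwise disjoint per frame.
    """
    out = {}
    claimed = None
    for region in series.regions:
        m = series.masks[region]
        if claimed is None:
            out[region] = m.copy()
            claimed = m.copy()
        else:
            out[region] = m & ~claimed
            claimed = claimed | out[region]
    return series.copy_with(masks=out)


def signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed EDT: positive outside, negative inside, boundary pixels < 0."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.full(mask.shape, _EMPTY_DIST_FACTOR * max(mask.shape), dtype=float)
    if mask.all():
        return np.full(mask.shape, -_EMPTY_DIST_FACTOR * max(mask.shape), dtype=float)
    return ndimage.distance_transform_edt(~mask) - ndimage.distance_transform_edt(mask)


def interp_mask_pair(A: np.ndarray, B: np.ndarray, alpha: float) -> np.ndarray:
    """Shape-interpolate two binary masks at blend position ``alpha``.

    Thresholds the linear blend of the signed Euclidean distance transforms
    at zero: ``{(1-alpha) d(A) + alpha d(B) <= 0}``.  Endpoints are exact
    (``alpha=0 -> A``, ``alpha=1 -> B``); an empty side is given a large
    positive distance so the object shrinks towards extinction.
    """
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape != B.shape:
        raise ValueError("masks must share a shape")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if alpha == 0.0:
        return A.copy()
    if alpha == 1.0:
        return B.copy()
    d = (1.0 - alpha) * signed_distance(A) + alpha * signed_distance(B)
    return d <= 0


def upsample_time(series: RegionMaskSeries, factor: int) -> RegionMaskSeries:
    """Raise the mask frame rate by ``factor`` via EDT interpolation.

    Produces ``factor * (T - 1) + 1`` frames: native frames are hit exactly
    at indices ``t * factor``; intermediates use blend positions
    ``j / factor``.  Output fps is ``input fps * factor``.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return series.copy_with()
    T = series.n_frames
    if T < 2:
        raise ValueError("need >= 2 frames to interpolate in time")
    T_out = factor * (T - 1) + 1
    out = {}
    for region, m in series.masks.items():
        res = np.zeros((T_out,) + m.shape[1:], dtype=bool)
        for t in range(T - 1):
            res[t * factor] = m[t]
            if np.array_equal(m[t], m[t + 1]):
                res[t * factor + 1 : (t + 1) * factor] = m[t]
                continue
            dA, dB = signed_distance(m[t]), signed_distance(m[t + 1])
            for j in range(1, factor):
                a = j / factor
                res[t * factor + j] = (1 - a) * dA + a * dB <= 0
        res[-1] = m[-1]
        out[region] = res
    return series.copy_with(masks=out, fps=series.fps * factor)


def resample_space(series: RegionMaskSeries, matrix: int, fov_mm: float) -> RegionMaskSeries:
    """Resample masks onto a ``matrix`` x ``matrix`` grid spanning ``fov_mm``.

    Target pixel centres are mapped into the source grid (both centred on
    the FOV midpoint), the signed distance field is looked up by nearest
    neighbour and thresholded at zero, which preserves binarity.
    """
    if matrix < 32:
        raise ValueError(f"matrix must be >= 32, got {matrix}")
    src = series.geometry
    if matrix == src.matrix and fov_mm == src.fov_mm:
        return series.copy_with()
    # target pixel centre positions in source index units
    tgt = (np.arange(matrix) - (matrix - 1) / 2) * (fov_mm / matrix)
    src_idx = tgt / src.pixel_mm + (src.matrix - 1) / 2
    rr, cc = np.meshgrid(src_idx, src_idx, indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()])
    out = {}
    for region, m in series.masks.items():
        res = np.zeros((series.n_frames, matrix, matrix), dtype=bool)
        for t in range(series.n_frames):
            d = signed_distance(m[t])
            vals = ndimage.map_coordinates(d, coords, order=0, mode="nearest")
            res[t] = (vals <= 0).reshape(matrix, matrix)
        out[region] = res
    return series.copy_with(masks=out, geometry=Geometry(matrix=matrix, fov_mm=fov_mm))


def render_phantom(series: RegionMaskSeries, intensity_table: dict) -> DynamicImageSeries:
    """Render disjoint masks as uniform-intensity frames on zero background."""
    regions = series.regions
    total = None
    for r in regions:
        s = series.masks[r].astype(np.uint8)
        total = s if total is None else total + s
    if total is not None and (total > 1).any():
        raise ValueError("masks overlap; run resolve_overlaps before rendering")
    shape = (series.n_frames, series.geometry.matrix, series.geometry.matrix)
    frames = np.zeros(shape, dtype=float)
    for r in regions:
        frames += intensity_table[r] * series.masks[r]
    return DynamicImageSeries(
        frames=frames,
        fps=series.fps,
        geometry=series.geometry,
        intensity_table=dict(intensity_table),
    )


def phantom_kspace(series: DynamicImageSeries) -> KSpaceSeries:
    """Centred per-frame 2D FFT of the phantom (DC bin = frame sum)."""
    if not np.all(np.isfinite(series.frames)):
        raise ValueError("frames must be finite")
    return KSpaceSeries(frames=cfft2(series.frames), fps=series.fps, geometry=series.geometry)


def kspace_to_images(kspace: KSpaceSeries) -> np.ndarray:
    """Inverse of :func:`phantom_kspace` (complex frames)."""
    return cifft2(kspace.frames)
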