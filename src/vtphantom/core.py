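"""Shared containers and Fourier conventions.

All modules share one discrete Fourier convention: arrays are *centred*,
i.e. the DC bin sits at index ``N // 2`` along each axis, image coordinates
are ``x = index - N // 2`` pixels and k-space coordinates are expressed in
cycles/pixel within ``[-0.5, 0.5)``.  The forward transform uses the
negative exponent ``exp(-i 2 pi k . x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Fixed region priority used when removing mask overlap: rigid structures
#: outrank mobile ones, the catch-all head region always loses.
REGION_PRIORITY = ("maxilla", "mandible", "epiglottis", "velum", "tongue", "head")

#: Default uniform region intensities (arbitrary units in [0, 1], chosen for
#: contrast similar to bSSFP speech images; not based on T1/T2 properties).
DEFAULT_INTENSITIES = {
    "head": 0.5,
    "tongue": 0.8,
    "velum": 0.9,
    "epiglottis": 0.7,
    "mandible": 0.6,
    "maxilla": 0.6,
}


def cfft2(x: np.ndarray) -> np.ndarray:
    """Centred 2D forward DFT (negative exponent, DC at ``N//2``)."""
    axes = (-2, -1)
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x, axes=axes), axes=axes), axes=axes)


def cifft2(x: np.ndarray) -> np.ndarray:
    """Centred 2D inverse DFT (adjoint of :func:`cfft2` up to ``1/N**2``)."""
    axes = (-2, -1)
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(x, axes=axes), axes=axes), axes=axes)


def cifft1(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Centred 1D inverse DFT along ``axis``."""
    return np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(x, axes=axis), axis=axis), axes=axis
    )


@dataclass(frozen=True)
class Geometry:
    """Square acquisition grid: matrix size (pixels) and field of view (mm)."""

    matrix: int
    fov_mm: float

    def __post_init__(self):
        if self.matrix < 2:
            raise ValueError(f"matrix must be >= 2, got {self.matrix}")
        if self.fov_mm <= 0:
            raise ValueError(f"fov_mm must be positive, got {self.fov_mm}")

    @property
    def pixel_mm(self) -> float:
        return self.fov_mm / self.matrix


@dataclass
class DynamicImageSeries:
    """Ordered real- or complex-valued frames with geometry and frame rate."""

    frames: np.ndarray  # (T, N, N)
    fps: float
    geometry: Geometry
    intensity_table: dict | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, N, N) array")
        if self.frames.shape[0] < 1:
            raise ValueError("need at least one frame")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def copy_with(self, **kw) -> "DynamicImageSeries":
        return replace(self, **kw)


@dataclass
class RegionMaskSeries:
    """Per-region, per-frame binary masks sharing one grid and frame rate.

    ``masks`` maps region name to a boolean ``(T, N, N)`` array.  Disjointness
    across regions is only guaranteed after :func:`vtphantom.phantom.resolve_overlaps`.
    """

    masks: dict[str, np.ndarray]
    fps: float
    geometry: Geometry
    region_order: tuple = REGION_PRIORITY

    def __post_init__(self):
        shapes = set()
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.ndim != 3:
                raise ValueError(f"mask {name!r} must be (T, N, N)")
            self.masks[name] = m
            shapes.add(m.shape)
        if len(shapes) > 1:
            raise ValueError("all region masks must share one shape")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return next(iter(self.masks.values())).shape[0]

    @property
    def regions(self) -> list[str]:
        """Region names in priority order, then any extras in insertion order."""
        ordered = [r for r in self.region_order if r in self.masks]
        ordered += [r for r in self.masks if r not in ordered]
        return ordered

    def frame_masks(self, t: int) -> dict[str, np.ndarray]:
        return {r: self.masks[r][t] for r in self.regions}

    def copy_with(self, **kw) -> "RegionMaskSeries":
        masks = kw.pop("masks", {r: m.copy() for r, m in self.masks.items()})
        return RegionMaskSeries(
            masks=masks,
            fps=kw.pop("fps", self.fps),
            geometry=kw.pop("geometry", self.geometry),
            region_order=kw.pop("region_order", self.region_order),
        )


@dataclass
class KSpaceSeries:
    """Per-frame complex k-space on the Cartesian grid (centred convention)."""

    frames: np.ndarray  # (T, N, N) complex
    fps: float
    geometry: Geometry

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=complex)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, N, N) array")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]
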