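"""Acquisition simulation: sampling, noise, segmented rates, multi-coil.

Samples the image-domain phantom along arbitrary trajectories with the
gridding NUFFT, adds complex Gaussian image noise, lowers the frame rate
either by image averaging or by assembling segmented Cartesian k-space
across consecutive frames, and simulates multi-coil acquisition (analytic
ring-of-coils sensitivity maps, per-coil noise, uniform phase-encode
undersampling with a separately stored auto-calibration block).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import DynamicImageSeries, Geometry, KSpaceSeries, cfft2
from .nufft import Gridder
from .trajectories import Trajectory


def nufft_sample(frame: np.ndarray, traj: Trajectory, gridder: Gridder | None = None) -> np.ndarray:
    """Forward-sample one frame at the trajectory's k-space locations."""
    frame = np.asarray(frame)
    if frame.shape != (traj.matrix, traj.matrix):
        raise ValueError(
            f"frame shape {frame.shape} does not match trajectory matrix {traj.matrix}"
        )
    gridder = gridder or Gridder(traj.matrix)
    return gridder.forward(frame.astype(complex), traj.points)


def sample_series(series: DynamicImageSeries, traj: Trajectory) -> np.ndarray:
    """Forward-sample every frame; returns (T, P) complex samples."""
    gridder = Gridder(traj.matrix)
    return np.stack([gridder.forward(f.astype(complex), traj.points) for f in series.frames])


def add_image_noise(series: DynamicImageSeries, level: float, seed: int) -> DynamicImageSeries:
    """Add complex Gaussian noise in image space.

    The per-channel (real/imaginary) standard deviation is
    ``level * max |series|`` -- "5% noise" means ``level=0.05``.  The result
    is complex-valued even for real input; deterministic under ``seed``.
    """
    if level < 0:
        raise ValueError(f"level must be >= 0, got {level}")
    if level == 0:
        return series.copy_with(frames=series.frames.copy())
    rng = np.random.default_rng(seed)
    sd = level * np.abs(series.frames).max()
    noise = rng.normal(0.0, sd, series.frames.shape) + 1j * rng.normal(
        0.0, sd, series.frames.shape
    )
    return series.copy_with(frames=series.frames + noise)


def segment_frames(
    kspace: KSpaceSeries, n_segments: int, reverse: bool = True
) -> KSpaceSeries:
    """Assemble a lower-frame-rate segmented Cartesian acquisition.

    Phase-encode lines (rows) are partitioned into ``n_segments`` contiguous
    blocks.  Output frame ``g`` takes its ``j``-th acquired block from
    source frame ``g * n_segments + j``; with ``reverse`` (the default) the
    blocks are ordered last-block-first, so the centre-most early block of
    k-space comes from the latest contributing frame.  Output fps is input
    fps divided by ``n_segments``; trailing frames that do not fill a whole
    output frame are dropped with a warning.
    """
    if n_segments < 1:
        raise ValueError(f"n_segments must be >= 1, got {n_segments}")
    if n_segments == 1:
        return KSpaceSeries(kspace.frames.copy(), kspace.fps, kspace.geometry)
    T = kspace.n_frames
    n_out = T // n_segments
    if n_out == 0:
        raise ValueError(f"need >= {n_segments} frames, got {T}")
    if T % n_segments:
        warnings.warn(
            f"dropping {T % n_segments} trailing frames not filling a segment block"
        )
    N = kspace.frames.shape[1]
    blocks = np.array_split(np.arange(N), n_segments)
    if reverse:
        blocks = blocks[::-1]
    out = np.empty((n_out, N, kspace.frames.shape[2]), dtype=complex)
    for g in range(n_out):
        for j, rows in enumerate(blocks):
            out[g, rows] = kspace.frames[g * n_segments + j, rows]
    return KSpaceSeries(out, kspace.fps / n_segments, kspace.geometry)


def average_frames(series: DynamicImageSeries, n: int) -> DynamicImageSeries:
    """Lower the frame rate by averaging non-overlapping blocks of ``n`` frames."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n == 1:
        return series.copy_with(frames=series.frames.copy())
    T = series.n_frames
    n_out = T // n
    if n_out == 0:
        raise ValueError(f"need >= {n} frames, got {T}")
    if T % n:
        warnings.warn(f"dropping {T % n} trailing frames not filling an average block")
    trimmed = series.frames[: n_out * n]
    frames = trimmed.reshape(n_out, n, *trimmed.shape[1:]).mean(axis=1)
    return series.copy_with(frames=frames, fps=series.fps / n)


@dataclass
class CoilArray:
    """Complex coil sensitivity maps normalised to unit sum-of-squares."""

    maps: np.ndarray            # (C, N, N) complex
    ring_radius: float          # coil-centre distance from FOV centre, pixels
    falloff_px: float           # Gaussian magnitude falloff width, pixels

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=complex)
        if self.maps.ndim != 3:
            raise ValueError("maps must be (C, N, N)")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]


def make_coil_maps(
    n_coils: int,
    matrix: int,
    ring_radius_frac: float = 0.55,
    falloff_frac: float = 0.4,
    phase_cycles: float = 0.25,
) -> CoilArray:
    """Analytic ring-of-coils sensitivity model.

    Coil centres sit equally spaced on a circle of radius
    ``ring_radius_frac * matrix`` pixels (just outside the FOV); each map
    has a Gaussian magnitude falloff of width ``falloff_frac * matrix`` from
    its centre and a smooth phase advancing ``phase_cycles`` cycles across
    the FOV diagonal with distance from the coil.  Maps are normalised so
    the pixelwise sum of squared magnitudes is 1 everywhere.
    """
    if n_coils < 1:
        raise ValueError(f"n_coils must be >= 1, got {n_coils}")
    r = np.arange(matrix)[:, None] - (matrix - 1) / 2
    c = np.arange(matrix)[None, :] - (matrix - 1) / 2
    ring = ring_radius_frac * matrix
    width = falloff_frac * matrix
    maps = np.empty((n_coils, matrix, matrix), dtype=complex)
    for i in range(n_coils):
        ang = 2 * np.pi * i / n_coils
        cy, cx = ring * np.sin(ang), ring * np.cos(ang)
        d = np.hypot(r - cy, c - cx)
        mag = np.exp(-(d**2) / (2 * width**2))
        phase = 2 * np.pi * phase_cycles * d / (np.sqrt(2) * matrix)
        maps[i] = mag * np.exp(1j * phase)
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= sos
    return CoilArray(maps=maps, ring_radius=ring, falloff_px=width)


def coil_images(
    series: DynamicImageSeries,
    coils: CoilArray,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-coil image series: ``S_c * frame`` plus complex Gaussian noise.

    Returns (T, C, N, N) complex; noise is independent across frames,
    coils and channels with per-channel SD ``noise_sigma``.
    """
    N = series.geometry.matrix
    if coils.maps.shape[1:] != (N, N):
        raise ValueError("coil maps do not match the series geometry")
    imgs = series.frames[:, None, :, :] * coils.maps[None, :, :, :]
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        imgs = imgs + rng.normal(0.0, noise_sigma, imgs.shape) + 1j * rng.normal(
            0.0, noise_sigma, imgs.shape
        )
    return imgs


@dataclass
class MultiCoilKSpace:
    """Undersampled multi-coil Cartesian k-space plus sampling metadata.

    ``data`` is the zero-filled (T, C, N, N) grid holding only the uniform
    pattern's lines; the auto-calibration block is stored separately in
    ``acs_data`` (T, C, acs_lines, N) and is not counted in the sampled-line
    budget.  Row indices refer to the centred grid (DC row ``N // 2``).
    """

    data: np.ndarray
    pattern: np.ndarray         # sampled phase-encode row indices
    R: int
    acs_lines: int
    fps: float
    geometry: Geometry
    acs_data: np.ndarray | None = None
    noise_sigma: float = 0.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_coils(self) -> int:
        return self.data.shape[1]

    @property
    def acs_rows(self) -> np.ndarray:
        N = self.data.shape[2]
        return np.arange(N // 2 - self.acs_lines // 2, N // 2 + self.acs_lines // 2)


def multicoil_kspace(coil_frames: np.ndarray) -> np.ndarray:
    """Centred FFT of per-coil images (T, C, N, N) -> (T, C, N, N)."""
    return cfft2(coil_frames)


def undersample(
    kspace_multicoil: np.ndarray,
    R: int,
    acs_lines: int,
    fps: float,
    geometry: Geometry,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> MultiCoilKSpace:
    """Retain every R-th phase-encode line plus a centred ACS block.

    The uniform pattern starts at row 0, giving ``N // R`` sampled lines
    regardless of the ACS size (the ACS block is additionally acquired and
    stored separately for calibration).  Non-sampled rows are zeroed.
    """
    data = np.asarray(kspace_multicoil, dtype=complex)
    if data.ndim != 4:
        raise ValueError("kspace_multicoil must be (T, C, N, N)")
    N = data.shape[2]
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    if R > N:
        raise ValueError(f"R={R} exceeds the number of phase-encode lines {N}")
    if acs_lines < 0 or (acs_lines % 2 and acs_lines != 0):
        raise ValueError(f"acs_lines must be 0 or a positive even count, got {acs_lines}")
    pattern = np.arange(0, N, R)
    out = np.zeros_like(data)
    out[:, :, pattern, :] = data[:, :, pattern, :]
    acs_data = None
    if acs_lines:
        rows = np.arange(N // 2 - acs_lines // 2, N // 2 + acs_lines // 2)
        acs_data = data[:, :, rows, :].copy()
    return MultiCoilKSpace(
        data=out, pattern=pattern, R=R, acs_lines=acs_lines, fps=fps,
        geometry=geometry, acs_data=acs_data, noise_sigma=noise_sigma, seed=seed,
    )
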