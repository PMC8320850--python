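"""Non-uniform FFT by Kaiser-Bessel convolution gridding.

Evaluates the centred Fourier sum ``S(k) = sum_x f(x) exp(-i 2 pi k . x)``
(type 2, image -> arbitrary samples) and its adjoint (type 1, samples ->
image) for k in cycles/pixel and x = index - N//2.  The implementation uses
a 2x oversampled grid, a width-8 Kaiser-Bessel kernel with the Beatty shape
parameter, and an apodisation profile computed as the exact inverse DFT of
the integer-sampled kernel so that forward and adjoint share one scale.
Worst-case relative error is well below 1e-3 (on-grid samples agree with the
FFT to ~1e-8).
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0

from .core import cfft2

_OS = 2          # grid oversampling factor
_WIDTH = 8       # kernel full width in oversampled grid units


def _kb_beta(width: int, os: float) -> float:
    # Beatty et al. min-aliasing shape parameter.
    return np.pi * np.sqrt((width / os) ** 2 * (os - 0.5) ** 2 - 0.8)


def _kb_kernel(u: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Kaiser-Bessel taps at (possibly fractional) offsets ``u``."""
    arg = 1.0 - (2.0 * u / width) ** 2
    out = np.zeros_like(u, dtype=float)
    ok = arg > 0
    out[ok] = i0(beta * np.sqrt(arg[ok]))
    return out


class Gridder:
    """Reusable gridding plan for one image matrix size."""

    def __init__(self, matrix: int, os: int = _OS, width: int = _WIDTH):
        if matrix < 2:
            raise ValueError("matrix must be >= 2")
        self.matrix = int(matrix)
        self.os = int(os)
        self.width = int(width)
        self.grid = self.os * self.matrix
        self.beta = _kb_beta(self.width, self.os)
        # Apodisation: inverse DFT of the integer-sampled kernel, evaluated on
        # the (cropped, centred) image grid.  Using the sampled kernel rather
        # than its continuous transform makes the scale self-consistent.
        G, N = self.grid, self.matrix
        taps_idx = np.arange(-(self.width // 2), self.width // 2 + 1)
        taps = _kb_kernel(taps_idx.astype(float), self.width, self.beta)
        spec = np.zeros(G)
        spec[(taps_idx + G // 2) % G] += taps
        prof = np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(spec))).real * G
        self._apod1d = prof[G // 2 - N // 2 : G // 2 - N // 2 + N]
        self._apod2d = np.outer(self._apod1d, self._apod1d)

    # -- helpers ---------------------------------------------------------
    def _neighbour_weights(self, points: np.ndarray):
        """Per-point grid neighbour indices and kernel weights (separable)."""
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be (P, 2) [kx, ky]")
        G = self.grid
        half = self.width // 2
        offs = np.arange(-half + 1, half + 1)  # width taps around floor(u)
        idx = []
        wts = []
        for d in range(2):
            u = pts[:, d] * G + G // 2
            base = np.floor(u).astype(int)
            j = base[:, None] + offs[None, :]          # (P, W)
            w = _kb_kernel(u[:, None] - j, self.width, self.beta)
            idx.append(np.mod(j, G))
            wts.append(w)
        return idx, wts

    # -- transforms ------------------------------------------------------
    def forward(self, image: np.ndarray, points: np.ndarray) -> np.ndarray:
        """Type-2 NUFFT: sample ``image`` at ``points`` (kx, ky) cycles/px."""
        image = np.asarray(image)
        N, G = self.matrix, self.grid
        if image.shape != (N, N):
            raise ValueError(f"image must be {(N, N)}, got {image.shape}")
        pre = image / self._apod2d
        pad = np.zeros((G, G), dtype=complex)
        lo = G // 2 - N // 2
        pad[lo : lo + N, lo : lo + N] = pre
        spec = cfft2(pad)
        (ix, iy), (wx, wy) = self._neighbour_weights(points)
        # gather: rows are ky (axis 0), columns kx (axis 1)
        sub = spec[iy[:, :, None], ix[:, None, :]]     # (P, W, W)
        return np.einsum("pij,pi,pj->p", sub, wy, wx)

    def adjoint(self, samples: np.ndarray, points: np.ndarray) -> np.ndarray:
        """Type-1 NUFFT: ``sum_p s_p exp(+i 2 pi k_p . x)`` on the N x N grid."""
        samples = np.asarray(samples, dtype=complex)
        N, G = self.matrix, self.grid
        (ix, iy), (wx, wy) = self._neighbour_weights(points)
        contrib = samples[:, None, None] * wy[:, :, None] * wx[:, None, :]
        grid = np.zeros((G, G), dtype=complex)
        np.add.at(grid, (iy[:, :, None], ix[:, None, :]), contrib)
        axes = (-2, -1)
        img = np.fft.fftshift(
            np.fft.ifft(
                np.fft.ifft(np.fft.ifftshift(grid, axes=axes), axis=-1), axis=-2
            ),
            axes=axes,
        ) * (G * G)
        lo = G // 2 - N // 2
        return img[lo : lo + N, lo : lo + N] / self._apod2d


def nufft2(image: np.ndarray, points: np.ndarray) -> np.ndarray:
    """One-shot forward NUFFT (builds a plan for ``image``'s matrix size)."""
    return Gridder(image.shape[0]).forward(image, points)


def nufft2_adjoint(samples: np.ndarray, points: np.ndarray, matrix: int) -> np.ndarray:
    """One-shot adjoint NUFFT onto a ``matrix`` x ``matrix`` grid."""
    return Gridder(matrix).adjoint(samples, points)


def direct_dft2(image: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Brute-force evaluation of the same Fourier sum (testing oracle).

    O(P * N^2); only intended for small problems.
    """
    image = np.asarray(image)
    N = image.shape[0]
    x = np.arange(N) - N // 2
    X, Y = np.meshgrid(x, x, indexing="xy")  # X: columns, Y: rows
    pts = np.asarray(points, dtype=float)
    out = np.empty(len(pts), dtype=complex)
    for p, (kx, ky) in enumerate(pts):
        out[p] = np.sum(image * np.exp(-2j * np.pi * (kx * X + ky * Y)))
    return out
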