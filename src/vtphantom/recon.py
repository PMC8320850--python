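"""Image reconstruction: inverse FFT, gridding, SENSE and GRAPPA.

SENSE unfolds uniformly undersampled Cartesian data pixel by pixel: for
each pixel of the reduced field of view the aliasing model built from the
coil sensitivity maps gives an ``n_coils x R`` linear system whose
least-squares solution recovers the R folded pixels.  GRAPPA instead fills
the missing phase-encode lines in k-space with linear kernels calibrated on
the fully sampled auto-calibration (ACS) block, restores the acquired data
verbatim, and combines coils by root sum of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import KSpaceSeries, cifft2
from .nufft import Gridder
from .sampling import CoilArray, MultiCoilKSpace
from .trajectories import Trajectory


@dataclass
class ReconResult:
    """Reconstructed magnitude frames plus method provenance."""

    frames: np.ndarray          # (T, N, N) real
    method: str
    params: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def ifft_recon(kspace: KSpaceSeries, magnitude: bool = True) -> ReconResult:
    """Centred inverse DFT of fully sampled Cartesian k-space."""
    img = cifft2(kspace.frames)
    return ReconResult(
        frames=np.abs(img) if magnitude else img, method="ifft",
        params={"matrix": kspace.frames.shape[-1]},
    )


def gridding_recon(
    samples: np.ndarray, traj: Trajectory, matrix: int | None = None
) -> ReconResult:
    """Density-compensated adjoint-NUFFT (gridding) reconstruction.

    ``samples`` is (P,) or (T, P).  The trajectory must carry density
    compensation weights; the image is the adjoint transform of the
    dcf-weighted samples, which for a fully sampled Cartesian trajectory
    coincides with the inverse FFT.
    """
    if traj.dcf is None:
        raise ValueError("trajectory has no dcf; call Trajectory.with_dcf() first")
    matrix = matrix or traj.matrix
    samples = np.atleast_2d(np.asarray(samples, dtype=complex))
    gridder = Gridder(matrix)
    frames = np.stack(
        [np.abs(gridder.adjoint(s * traj.dcf, traj.points)) for s in samples]
    )
    return ReconResult(frames=frames, method="gridding", params={"kind": traj.kind})


def sos_combine(coil_frames: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares coil combination over the coil axis.

    Accepts (C, N, N) or (T, C, N, N); the coil axis is the third from the
    end's left neighbour, i.e. axis -3.
    """
    coil_frames = np.asarray(coil_frames)
    if coil_frames.ndim < 3:
        raise ValueError("need at least (C, N, N)")
    return np.sqrt(np.sum(np.abs(coil_frames) ** 2, axis=-3))


class UnderdeterminedError(ValueError):
    """Raised when the SENSE unfold has more folded pixels than coils."""


def _alias_weights(pattern: np.ndarray, N: int, R: int) -> np.ndarray:
    """Complex weights of the R point-spread replicas of the sampling comb.

    Computed numerically from the inverse DFT of the row mask (standard,
    non-centred indexing); replica ``s`` sits at a circular shift of
    ``s * N // R`` rows.
    """
    mask = np.zeros(N)
    mask[pattern] = 1.0
    psf = np.fft.ifft(np.fft.ifftshift(mask))  # pattern rows are centred indices
    delta = N // R
    return psf[np.arange(R) * delta]


def sense_recon(
    acq: MultiCoilKSpace,
    coils: CoilArray,
    lam: float = 0.0,
    allow_underdetermined: bool = False,
) -> ReconResult:
    """Pixelwise SENSE unfolding of uniformly undersampled Cartesian data.

    For each pixel of the reduced FOV the aliased coil values are
    ``A_c = sum_s w_s S_c(y_s) f(y_s)`` over the R fold positions ``y_s``;
    the ``n_coils x R`` system is solved by (optionally Tikhonov-damped)
    least squares.  Requires ``R <= n_coils`` unless
    ``allow_underdetermined``, in which case a heavily regularised solution
    is returned with a warning.
    """
    T, C, N, _ = acq.data.shape
    R = acq.R
    if N % R:
        raise ValueError(f"R={R} must divide the matrix size {N}")
    if R > C:
        if not allow_underdetermined:
            raise UnderdeterminedError(
                f"R={R} folded pixels but only {C} coils; unfold is underdetermined"
            )
        warnings.warn(f"R={R} > n_coils={C}: returning a regularised least-norm unfold")
        lam = max(lam, 1e-2)
    maps = coils.maps
    if maps.shape != (C, N, N):
        raise ValueError("coil maps do not match the acquisition geometry")
    w = _alias_weights(acq.pattern, N, R)
    delta = N // R
    # work in standard (non-centred) row indexing where fold shifts are clean
    maps_std = np.fft.ifftshift(maps, axes=(-2,))
    out = np.empty((T, N, N), dtype=float)
    shifts = np.arange(R) * delta
    for t in range(T):
        aliased = cifft2(acq.data[t])  # replica weights w_s carry the 1/R scale
        aliased_std = np.fft.ifftshift(aliased, axes=(-2,))
        # E[y0, x, c, s] = w_s * S_c((y0 - s*delta) % N, x)
        fold_rows = (np.arange(delta)[:, None] - shifts[None, :]) % N  # (delta, R)
        S_fold = maps_std[:, fold_rows, :]            # (C, delta, R, N)
        E = np.transpose(S_fold, (1, 3, 0, 2)) * w[None, None, None, :]
        d = np.transpose(aliased_std[:, :delta, :], (1, 2, 0))  # (delta, N, C)
        Eh = np.conj(np.transpose(E, (0, 1, 3, 2)))
        EhE = Eh @ E
        if lam > 0:
            tr = np.trace(EhE, axis1=-2, axis2=-1).real / R
            EhE = EhE + (lam * tr)[..., None, None] * np.eye(R)
        rhs = np.einsum("yxrc,yxc->yxr", Eh, d)
        f = np.linalg.solve(EhE, rhs[..., None])[..., 0]  # (delta, N, R)
        full_std = np.empty((N, N), dtype=complex)
        for s in range(R):
            rows = (np.arange(delta) - shifts[s]) % N
            full_std[rows, :] = f[:, :, s]
        out[t] = np.abs(np.fft.fftshift(full_std, axes=(0,)))
    return ReconResult(
        frames=out, method="sense", params={"R": R, "n_coils": C, "lam": lam}
    )


class CalibrationError(ValueError):
    """Raised when the ACS block is too small to calibrate GRAPPA kernels."""


def grappa_recon(
    acq: MultiCoilKSpace,
    kernel: tuple[int, int] = (2, 3),
    lam: float = 1e-6,
) -> ReconResult:
    """GRAPPA reconstruction of uniformly undersampled Cartesian data.

    For each missing-line offset, a linear kernel mapping
    ``ky_neighbors`` acquired lines x ``kx_neighbors`` columns x all coils
    to the missing samples of every coil is calibrated on the ACS block by
    Tikhonov-regularised least squares (``lam`` scales the mean diagonal of
    the normal matrix) and applied across the grid with truncated (edge-
    clamped) neighbourhoods.  Acquired lines and the ACS block are restored
    verbatim; coils are combined by root sum of squares.
    """
    ky_n, kx_n = kernel
    if ky_n < 1 or kx_n < 1 or kx_n % 2 == 0:
        raise ValueError("kernel must have >= 1 ky neighbours and an odd kx width")
    T, C, N, _ = acq.data.shape
    R = acq.R
    if R == 1:
        return ReconResult(
            frames=sos_combine(cifft2(acq.data)), method="grappa",
            params={"R": 1, "kernel": kernel},
        )
    if acq.acs_data is None or acq.acs_lines < R * ky_n + 1:
        raise CalibrationError(
            f"GRAPPA with R={R} and {ky_n} ky neighbours needs >= {R * ky_n + 1} "
            f"ACS lines, got {acq.acs_lines}"
        )
    dx = np.arange(kx_n) - kx_n // 2
    # acquired-line offsets relative to the lattice row below the target
    dy_src = np.arange(ky_n) * R
    out = np.empty((T, N, N), dtype=float)
    for t in range(T):
        acs = acq.acs_data[t]                      # (C, A, N)
        A = acs.shape[1]
        weights = {}
        for r in range(1, R):
            n_y = A - dy_src[-1]
            ys = np.arange(n_y)
            xs = np.arange(kx_n // 2, N - kx_n // 2)
            # sources (C, ky_n, n_y, n_x, kx_n) -> rows of the design matrix
            src = acs[:, (ys[:, None] + dy_src[None, :]), :][
                :, :, :, (xs[:, None] + dx[None, :])
            ]  # (C, n_y, ky_n, n_x, kx_n)
            X = np.transpose(src, (1, 3, 0, 2, 4)).reshape(n_y * len(xs), -1)
            tgt_rows = ys + r
            valid = tgt_rows < A
            Y = acs[:, tgt_rows[valid], :][:, :, xs]
            Y = np.transpose(Y, (1, 2, 0)).reshape(-1, C)
            X = X.reshape(n_y, len(xs), -1)[valid].reshape(-1, X.shape[-1])
            XhX = np.conj(X.T) @ X
            reg = lam * np.mean(np.diag(XhX).real)
            W = np.linalg.solve(XhX + reg * np.eye(XhX.shape[0]), np.conj(X.T) @ Y)
            weights[r] = W
        filled = acq.data[t].copy()
        acquired = np.zeros(N, dtype=bool)
        acquired[acq.pattern] = True
        for m in range(N):
            if acquired[m]:
                continue
            r = m % R
            base = m - r
            # truncated neighbourhood at the top edge: slide the source
            # stencil down so every source row is an acquired lattice row
            max_base = ((N - 1 - dy_src[-1]) // R) * R
            rows = np.clip(min(base, max_base) + dy_src, 0, N - 1)
            cols = np.clip(np.arange(N)[:, None] + dx[None, :], 0, N - 1)
            src = filled[:, rows, :][:, :, cols]   # (C, ky_n, N, kx_n)
            X = np.transpose(src, (2, 0, 1, 3)).reshape(N, -1)
            filled[:, m, :] = (X @ weights[r]).T
        # data consistency: acquired pattern and ACS restored verbatim
        filled[:, acq.pattern, :] = acq.data[t][:, acq.pattern, :]
        filled[:, acq.acs_rows, :] = acs
        out[t] = sos_combine(cifft2(filled))
    return ReconResult(
        frames=out, method="grappa",
        params={"R": R, "kernel": kernel, "acs_lines": acq.acs_lines, "lam": lam},
    )
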