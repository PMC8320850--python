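"""Quantitative and qualitative image-fidelity evaluation.

Fidelity is reported as per-frame RMSE normalised by the reference frame's
intensity range and expressed in percent; when the reconstruction runs at a
lower frame rate than the reference, only the temporal points common to
both series are compared (a low-rate frame is aligned by default with the
last reference frame that contributed to it).  EPI odd/even misalignment is
quantified by the N/2 ghost energy ratio, and the two qualitative flags of
speech-image assessment ("velum and tongue discernible?", "aliasing
artefacts apparent?") can be entered by an operator or filled by automated
surrogates (region Dice and ghost energy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import DynamicImageSeries, RegionMaskSeries
from .recon import ReconResult


@dataclass
class EvalReport:
    """Per-frame and mean RMSE (percent) plus optional qualitative flags."""

    per_frame_rmse: list[float]
    mean_rmse: float
    compared_frames: list[int]
    ghost_ratio: float | None = None
    velum_tongue_discernible: bool | None = None
    aliasing_artefacts: bool | None = None
    config: dict = field(default_factory=dict)


def _common_frame_indices(n_ref: int, fps_ref: float, n_test: int, fps_test: float,
                          alignment: str) -> list[tuple[int, int]]:
    """(ref_index, test_index) pairs of temporal points common to both series."""
    if fps_test > fps_ref + 1e-9:
        raise ValueError("test frame rate exceeds the reference frame rate")
    ratio = fps_ref / fps_test
    n = int(round(ratio))
    if abs(ratio - n) > 1e-6:
        raise ValueError(f"frame-rate ratio {ratio} is not an integer")
    if alignment == "last":
        offset = n - 1
    elif alignment == "centre":
        offset = (n - 1) // 2
    else:
        raise ValueError(f"alignment must be 'last' or 'centre', got {alignment!r}")
    pairs = [(g * n + offset, g) for g in range(n_test) if g * n + offset < n_ref]
    if not pairs:
        raise ValueError("no temporal points common to both series")
    return pairs


def rmse_series(
    reference: DynamicImageSeries,
    test: ReconResult | DynamicImageSeries,
    test_fps: float | None = None,
    alignment: str = "last",
) -> EvalReport:
    """Per-frame RMSE of ``test`` against the fully sampled reference.

    ``RMSE% = 100 * sqrt(mean((ref - test)^2)) / (max(ref) - min(ref))``
    per compared frame; the mean is the arithmetic mean over compared
    frames.  ``test_fps`` defaults to the reference rate (frame-for-frame
    comparison).
    """
    test_frames = np.abs(np.asarray(test.frames))
    ref_frames = np.abs(np.asarray(reference.frames))
    if test_frames.shape[1:] != ref_frames.shape[1:]:
        raise ValueError("matrix mismatch between reference and test")
    fps_test = test_fps if test_fps is not None else reference.fps
    pairs = _common_frame_indices(
        ref_frames.shape[0], reference.fps, test_frames.shape[0], fps_test, alignment
    )
    per_frame = []
    for ref_i, test_i in pairs:
        ref = ref_frames[ref_i]
        rng = ref.max() - ref.min()
        if rng == 0:
            raise ValueError(f"reference frame {ref_i} has zero intensity range")
        err = np.sqrt(np.mean((ref - test_frames[test_i]) ** 2))
        per_frame.append(100.0 * err / rng)
    return EvalReport(
        per_frame_rmse=per_frame,
        mean_rmse=float(np.mean(per_frame)),
        compared_frames=[p[0] for p in pairs],
        config={"alignment": alignment, "fps_test": fps_test, "fps_ref": reference.fps},
    )


def ghost_ratio(
    image: np.ndarray,
    axis: int = 0,
    support: np.ndarray | None = None,
    support_threshold: float = 0.1,
) -> float:
    """Energy ratio of the N/2 ghost to the in-support signal.

    The image is circularly shifted by N/2 along ``axis``; the ghost energy
    is measured where the shifted support lands on background of the
    unshifted support, divided by the in-support energy.  ``support``
    defaults to ``|image| > support_threshold * max|image|``; for simulated
    data pass the ground-truth support instead.
    """
    img = np.abs(np.asarray(image))
    N = img.shape[axis]
    if N % 2:
        raise ValueError(f"matrix must be even along axis {axis}")
    if support is None:
        support = img > support_threshold * img.max()
    support = np.asarray(support, dtype=bool)
    ghost_region = np.roll(support, N // 2, axis=axis) & ~support
    sig = float(np.sum(img[support] ** 2))
    if sig == 0:
        raise ValueError("empty support")
    return float(np.sum(img[ghost_region] ** 2)) / sig


def region_dice(
    recon_frame: np.ndarray,
    masks: RegionMaskSeries,
    intensity_table: dict,
    frame: int = 0,
    dilate_px: int = 2,
) -> dict[str, float]:
    """Per-region recovery Dice after half-intensity thresholding.

    For each region, the reconstruction is thresholded at half that
    region's nominal intensity and compared with the reference mask over
    the region's own vicinity (the mask dilated by ``dilate_px``) excluding
    pixels that belong to other tissue regions.  This scores the two
    clinically relevant failure modes of speech images -- loss of organ
    signal (pixels inside the organ dropping below half intensity) and
    artefactual fill-in of adjacent airway (background pixels next to the
    organ, e.g. the velopharyngeal gap, rising above half intensity) --
    while the organ's contrast against neighbouring tissue is a separate
    question of intensity assignment, not shape recovery.  This is the
    automated surrogate for the "velum and tongue discernible?" flag.
    """
    img = np.abs(np.asarray(recon_frame))
    regions = [r for r in masks.regions if r in intensity_table]
    dice = {}
    for r in regions:
        ref = masks.masks[r][frame]
        others = np.zeros_like(ref)
        for s in regions:
            if s != r:
                others |= masks.masks[s][frame]
        window = ndimage.binary_dilation(ref, iterations=dilate_px) & ~others
        cand = (img >= 0.5 * intensity_table[r]) & window
        denom = cand.sum() + ref.sum()
        dice[r] = 2.0 * np.sum(cand & ref) / denom if denom else 1.0
    return dice


def quality_report(reports: list[EvalReport], sweep: list[dict] | None = None) -> pd.DataFrame:
    """Tabulate a parameter sweep: one row per configuration.

    ``sweep`` supplies the per-configuration parameters (frame rate, coils,
    ACS lines, R, lines sampled, ...); RMSE and any qualitative flags come
    from the matching :class:`EvalReport`.
    """
    columns = [
        "fps", "n_coils", "acs_lines", "R", "lines_sampled", "method",
        "mean_rmse_pct", "velum_tongue_discernible", "aliasing_artefacts",
    ]
    rows = []
    sweep = sweep or [{} for _ in reports]
    for rep, meta in zip(reports, sweep):
        row = {c: meta.get(c) for c in columns}
        row["mean_rmse_pct"] = rep.mean_rmse
        if rep.velum_tongue_discernible is not None:
            row["velum_tongue_discernible"] = rep.velum_tongue_discernible
        if rep.aliasing_artefacts is not None:
            row["aliasing_artefacts"] = rep.aliasing_artefacts
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)
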