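"""Procedural mid-sagittal vocal-tract anatomy with speech-like motion.

Generates a stylised dynamic image series of a head in the mid-sagittal
plane built from six uniform-intensity regions (head, velum, tongue,
epiglottis, mandible, maxilla) on a zero background, together with exact
ground-truth region masks.  Two motion classes are emulated:

* velopharyngeal opening/closing -- the velum flap swings towards the
  posterior pharyngeal wall following a clipped sinusoid per cycle, with a
  sustained contact plateau at each closure;
* tongue advancement -- the tongue body translates anteriorly and back
  following an independent sinusoid.

The anatomy is deliberately schematic (ellipses and rectangles): downstream
acquisition/reconstruction simulation needs uniform regions, a patent
airway and realistic motion topology, not traced anatomy.  Anterior is the
low-column side of the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DEFAULT_INTENSITIES, Geometry, DynamicImageSeries, RegionMaskSeries

REGIONS = ("head", "velum", "tongue", "epiglottis", "mandible", "maxilla")

# Layout constants as fractions of the matrix size (rows down, columns right).
_HEAD_CENTRE = (0.50, 0.48)
_HEAD_SEMI = (0.44, 0.40)
_ORAL_ROWS = (0.50, 0.58)        # oral airway channel, open to the anterior border
_ORAL_COL_MAX = 0.64
_PHARYNX_COLS = (0.58, 0.66)     # vertical airway; wall tissue starts at 0.66
_PHARYNX_ROWS = (0.26, 0.80)
_VELUM_ROWS = (0.34, 0.42)
_VELUM_COL_MIN = 0.50
_WALL_COL = 0.66
_MAXILLA = ((0.42, 0.50), (0.12, 0.58))
_MANDIBLE = ((0.62, 0.82), (0.10, 0.22))
_TONGUE_CENTRE = (0.66, 0.40)
_TONGUE_SEMI = (0.09, 0.13)
_EPIGLOTTIS_CENTRE = (0.78, 0.56)
_EPIGLOTTIS_SEMI = (0.035, 0.03)
_GAP_MAX_FRAC = 0.06             # peak velopharyngeal gap


class ParameterError(ValueError):
    """Raised when an anatomy parameter violates its invariant."""


@dataclass(frozen=True)
class AnatomyParams:
    """Parameters of the procedural anatomy generator.

    ``velum_cycles`` open/close events are spread uniformly over the series;
    each cycle must span at least 4 frames.  ``tongue_excursion_px`` is the
    peak anterior displacement of the tongue body in pixels.
    """

    matrix_size: int = 256
    fov_mm: float = 300.0
    fps: float = 30.0
    n_frames: int = 60
    velum_cycles: int = 2
    tongue_excursion_px: float = 10.0
    region_intensities: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    seed: int = 0

    def validate(self) -> None:
        if self.matrix_size < 32:
            raise ParameterError(f"matrix_size must be >= 32, got {self.matrix_size}")
        if self.n_frames < 2:
            raise ParameterError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.fps <= 0:
            raise ParameterError(f"fps must be positive, got {self.fps}")
        if self.velum_cycles < 0:
            raise ParameterError(f"velum_cycles must be >= 0, got {self.velum_cycles}")
        if self.velum_cycles > 0 and self.n_frames / self.velum_cycles < 4:
            raise ParameterError(
                "each velum cycle must span >= 4 frames: "
                f"{self.n_frames} frames / {self.velum_cycles} cycles"
            )
        if self.tongue_excursion_px < 0:
            raise ParameterError("tongue_excursion_px must be >= 0")
        missing = set(REGIONS) - set(self.region_intensities)
        if missing:
            raise ParameterError(f"region_intensities missing {sorted(missing)}")
        for name, v in self.region_intensities.items():
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"region_intensities[{name!r}]={v} not in [0, 1]")


@dataclass
class GroundTruth:
    """Exact region masks and the frames at which the velum touches the wall."""

    masks: RegionMaskSeries
    closure_frames: list[int]


def default_speech_params() -> AnatomyParams:
    """Defaults matching the phantom's target resolution: 256 matrix,
    300 mm FOV, 30 fps, two velopharyngeal closure cycles over 2 s."""
    return AnatomyParams()


def _ellipse(N: int, centre, semi) -> np.ndarray:
    r = np.arange(N)[:, None]
    c = np.arange(N)[None, :]
    cy, cx = centre[0] * N, centre[1] * N
    ay, ax = semi[0] * N, semi[1] * N
    return ((r - cy) / ay) ** 2 + ((c - cx) / ax) ** 2 <= 1.0


def _rect(N: int, rows, cols) -> np.ndarray:
    m = np.zeros((N, N), dtype=bool)
    r0, r1 = int(round(rows[0] * N)), int(round(rows[1] * N))
    c0, c1 = int(round(cols[0] * N)), int(round(cols[1] * N))
    m[r0:r1, c0:c1] = True
    return m


def velum_gap_fraction(tau: np.ndarray) -> np.ndarray:
    """Clipped sinusoid gap profile over one cycle, ``tau`` in [0, 1).

    Zero (closed, with a sustained plateau) at the cycle ends, peaking
    mid-cycle.  The clipping keeps the velum in contact with the posterior
    wall for roughly the first and last 6% of each cycle.
    """
    return np.clip(1.25 * np.sin(np.pi * np.asarray(tau, dtype=float)) - 0.25, 0.0, None)


def _velum_gap_px(params: AnatomyParams, t: int, gap_max: int) -> int:
    if params.velum_cycles == 0:
        return gap_max  # static anatomy rests open
    cycle_len = params.n_frames / params.velum_cycles
    tau = (t % cycle_len) / cycle_len
    return int(round(gap_max * float(velum_gap_fraction(tau))))


def _tongue_shift_px(params: AnatomyParams, t: int) -> float:
    # independent sinusoid; positive = anterior (towards lower columns)
    return params.tongue_excursion_px * np.sin(2 * np.pi * t / params.n_frames)


def generate_anatomy(params: AnatomyParams) -> tuple[DynamicImageSeries, GroundTruth]:
    """Build the dynamic phantom series and its exact ground truth.

    Deterministic for a fixed seed (the seed perturbs the head outline by
    about one percent so distinct seeds give distinct subjects).  Returned
    masks are pairwise disjoint and exactly partition the nonzero support of
    every frame.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    N = params.matrix_size
    jitter = 1.0 + 0.01 * rng.uniform(-1.0, 1.0, size=2)
    head_semi = (_HEAD_SEMI[0] * jitter[0], _HEAD_SEMI[1] * jitter[1])

    skull = _ellipse(N, _HEAD_CENTRE, head_semi)
    oral = _rect(N, _ORAL_ROWS, (0.0, _ORAL_COL_MAX))
    pharynx = _rect(N, _PHARYNX_ROWS, _PHARYNX_COLS)
    airway = oral | pharynx
    maxilla = _rect(N, *_MAXILLA) & skull
    mandible = _rect(N, *_MANDIBLE) & skull
    epiglottis = _ellipse(N, _EPIGLOTTIS_CENTRE, _EPIGLOTTIS_SEMI) & skull

    wall_col = int(round(_WALL_COL * N))
    gap_max = max(2, int(round(_GAP_MAX_FRAC * N)))
    vr0, vr1 = int(round(_VELUM_ROWS[0] * N)), int(round(_VELUM_ROWS[1] * N))
    vc0 = int(round(_VELUM_COL_MIN * N))

    frames = np.zeros((params.n_frames, N, N), dtype=float)
    masks = {r: np.zeros((params.n_frames, N, N), dtype=bool) for r in REGIONS}
    closure_frames: list[int] = []

    for t in range(params.n_frames):
        gap = _velum_gap_px(params, t, gap_max)
        velum = np.zeros((N, N), dtype=bool)
        velum[vr0:vr1, vc0 : wall_col - gap] = True
        velum &= skull

        shift = _tongue_shift_px(params, t)
        centre = (_TONGUE_CENTRE[0], _TONGUE_CENTRE[1] - shift / N)
        tongue = _ellipse(N, centre, _TONGUE_SEMI) & skull

        head = skull & ~airway
        # priority de-overlap (rigid > mobile > head), articulators keep shape
        order = {
            "maxilla": maxilla,
            "mandible": mandible,
            "epiglottis": epiglottis,
            "velum": velum,
            "tongue": tongue,
            "head": head,
        }
        claimed = np.zeros((N, N), dtype=bool)
        for name, m in order.items():
            m = m & ~claimed
            claimed |= m
            masks[name][t] = m
            frames[t][m] = params.region_intensities[name]

        if gap == 0:
            closure_frames.append(t)

    geom = Geometry(matrix=N, fov_mm=params.fov_mm)
    series = DynamicImageSeries(
        frames=frames,
        fps=params.fps,
        geometry=geom,
        intensity_table=dict(params.region_intensities),
    )
    mask_series = RegionMaskSeries(masks=masks, fps=params.fps, geometry=geom)
    return series, GroundTruth(masks=mask_series, closure_frames=closure_frames)


def velum_wall_gap_px(masks: RegionMaskSeries, t: int) -> int:
    """Brute-force pixel scan of the air gap between velum tip and posterior
    wall along the velum-wall axis (used to verify closure frames)."""
    velum = masks.masks["velum"][t]
    head = masks.masks["head"][t]
    rows = np.where(velum.any(axis=1))[0]
    if rows.size == 0:
        raise ValueError(f"no velum pixels in frame {t}")
    gaps = []
    for r in rows:
        vcols = np.where(velum[r])[0]
        tip = vcols.max()
        wall = np.where(head[r, tip + 1 :])[0]
        if wall.size:
            gaps.append(int(wall.min()))
    if not gaps:
        raise ValueError(f"no posterior wall found in frame {t}")
    return min(gaps)
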