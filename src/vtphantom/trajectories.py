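"""k-space trajectory design and Voronoi density compensation.

All trajectories live in normalized coordinates (cycles/pixel) inside the
square [-0.5, 0.5).  Four families are provided:

* ``cartesian`` -- N full phase-encode lines on the centred grid;
* ``epi``       -- the Cartesian grid with every odd-indexed line's readout
                   (kx) coordinates offset by a fraction of the grid step,
                   emulating the odd/even misalignment of blipped EPI;
* ``radial``    -- uniformly rotated diameters; the Nyquist spoke count for
                   matrix N is ceil(pi N / 2);
* ``spiral``    -- Archimedean interleaves with arc-length sample spacing
                   and edge azimuthal gap bounded by the grid step (Nyquist).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi, QhullError

TRAJECTORY_KINDS = ("cartesian", "epi", "radial", "spiral")


@dataclass
class Trajectory:
    """Ordered k-space sample locations with optional density weights.

    ``groups`` assigns each point to its readout (line / spoke / interleaf).
    """

    kind: str
    points: np.ndarray          # (P, 2) [kx, ky] in cycles/pixel
    matrix: int
    groups: np.ndarray          # (P,) int readout index
    dcf: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.groups = np.asarray(self.groups, dtype=int)
        if self.kind not in TRAJECTORY_KINDS:
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (P, 2)")
        if np.any(np.abs(self.points) > 0.5):
            raise ValueError("points must lie within [-0.5, 0.5]")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def with_dcf(self) -> "Trajectory":
        """Return a copy carrying Voronoi density-compensation weights.

        Disc-coverage trajectories (radial, spiral) use quadrature-true cell
        areas clipped to the sampled disc, so the unsampled square corners
        act as a filter rather than inflating edge-sample weights; grid
        trajectories use the normalised (sum = 1) weights, which for them
        coincide with the true cell areas.
        """
        if self.dcf is not None:
            return self
        if self.kind in ("radial", "spiral"):
            radius = float(np.hypot(*self.points.T).max()) + 0.5 / self.matrix
            dcf = voronoi_dcf(self.points, clip_radius=radius, normalise=False)
        else:
            dcf = voronoi_dcf(self.points)
        return Trajectory(
            kind=self.kind, points=self.points, matrix=self.matrix,
            groups=self.groups, dcf=dcf,
        )


def nyquist_spokes(matrix: int) -> int:
    """Spoke count for azimuthal Nyquist sampling of an N x N matrix."""
    return int(np.ceil(np.pi * matrix / 2))


def _grid_coords(matrix: int) -> np.ndarray:
    return (np.arange(matrix) - matrix // 2) / matrix


def make_trajectory(kind: str, matrix: int, **options) -> Trajectory:
    """Design a trajectory of the requested ``kind`` for an N x N matrix.

    Options: ``line_shift`` (epi, fraction of the grid step, default 0.25),
    ``n_spokes`` (radial, default the Nyquist count), ``n_interleaves``
    (spiral, default ``max(1, round(16 * matrix / 256))``).
    """
    if matrix < 16:
        raise ValueError(f"matrix must be >= 16, got {matrix}")
    if kind == "cartesian":
        return _cartesian(matrix)
    if kind == "epi":
        return _epi(matrix, float(options.pop("line_shift", 0.25)))
    if kind == "radial":
        n = options.pop("n_spokes", None)
        return _radial(matrix, nyquist_spokes(matrix) if n is None else int(n))
    if kind == "spiral":
        default_il = max(1, int(round(16 * matrix / 256)))
        return _spiral(matrix, int(options.pop("n_interleaves", default_il)))
    raise ValueError(f"unknown trajectory kind {kind!r}")


def _cartesian(matrix: int) -> Trajectory:
    k = _grid_coords(matrix)
    ky, kx = np.meshgrid(k, k, indexing="ij")  # line-major: one ky per line
    pts = np.stack([kx.ravel(), ky.ravel()], axis=1)
    groups = np.repeat(np.arange(matrix), matrix)
    return Trajectory(kind="cartesian", points=pts, matrix=matrix, groups=groups)


def _epi(matrix: int, line_shift: float) -> Trajectory:
    base = _cartesian(matrix)
    pts = base.points.copy()
    odd = base.groups % 2 == 1
    pts[odd, 0] += line_shift / matrix
    # keep within the normalized square (wrap the single out-of-range column)
    pts[:, 0] = (pts[:, 0] + 0.5) % 1.0 - 0.5
    return Trajectory(kind="epi", points=pts, matrix=matrix, groups=base.groups)


def _radial(matrix: int, n_spokes: int) -> Trajectory:
    if n_spokes < 1:
        raise ValueError(f"n_spokes must be >= 1, got {n_spokes}")
    radii = _grid_coords(matrix)  # diameter: N samples from -0.5 to 0.5-1/N
    angles = np.arange(n_spokes) * np.pi / n_spokes
    pts = np.empty((n_spokes * matrix, 2))
    for s, a in enumerate(angles):
        pts[s * matrix : (s + 1) * matrix, 0] = radii * np.cos(a)
        pts[s * matrix : (s + 1) * matrix, 1] = radii * np.sin(a)
    groups = np.repeat(np.arange(n_spokes), matrix)
    return Trajectory(kind="radial", points=pts, matrix=matrix, groups=groups)


def _spiral(matrix: int, n_interleaves: int) -> Trajectory:
    if n_interleaves < 1:
        raise ValueError(f"n_interleaves must be >= 1, got {n_interleaves}")
    dk = 1.0 / matrix
    kmax = 0.5 - dk / 2
    # Archimedean r = a * theta with radial pitch n_il * dk per turn
    a = n_interleaves * dk / (2 * np.pi)
    pts_one = [(0.0, 0.0)]
    theta = 0.0
    while True:
        # arc-length step ds = sqrt(a^2 + r^2) dtheta <= dk (Nyquist along
        # the arc); evaluated at the step end so the bound holds while the
        # radius grows within the step
        dtheta = 0.9 * dk / np.sqrt(a * a + (a * theta) ** 2)
        for _ in range(3):
            dtheta = 0.9 * dk / np.sqrt(a * a + (a * (theta + dtheta)) ** 2)
        theta += dtheta
        r = a * theta
        if r > kmax:
            break
        pts_one.append((theta, r))
    pts = []
    groups = []
    for i in range(n_interleaves):
        rot = 2 * np.pi * i / n_interleaves
        for theta, r in pts_one:
            pts.append((r * np.cos(theta + rot), r * np.sin(theta + rot)))
            groups.append(i)
    return Trajectory(
        kind="spiral", points=np.asarray(pts), matrix=matrix, groups=np.asarray(groups)
    )


def voronoi_dcf(
    points: np.ndarray,
    clip_radius: float | None = None,
    normalise: bool = True,
) -> np.ndarray:
    """Density-compensation weights from Voronoi cell areas.

    The normalized square is the periodic Nyquist cell, so boundary cells
    are bounded by tessellating the points together with their eight
    periodic replicas (shifts of +-1 cycle/pixel); each original point then
    owns a bounded cell and the areas tile the square exactly.  Duplicated
    points (e.g. the shared radial centre) split their cell area equally.
    With ``clip_radius`` set, cells are additionally intersected with the
    disc of that radius (for trajectories that cover a disc rather than the
    square).  Weights are normalised to sum to 1 unless ``normalise`` is
    False, in which case the raw cell areas are returned (their sum is the
    covered fraction of the square).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
        raise ValueError("need >= 4 (P, 2) points")
    uniq, inverse, counts = np.unique(pts, axis=0, return_inverse=True, return_counts=True)
    centred = uniq - uniq.mean(axis=0)
    if np.linalg.svd(centred, compute_uv=False)[1] < 1e-12:
        raise ValueError("degenerate tessellation: all points are collinear")
    replicas = [
        uniq + np.array([sx, sy])
        for sx in (-1.0, 0.0, 1.0)
        for sy in (-1.0, 0.0, 1.0)
        if (sx, sy) != (0.0, 0.0)
    ]
    try:
        vor = Voronoi(np.concatenate([uniq] + replicas))
    except QhullError as exc:
        raise ValueError("degenerate tessellation (collinear points?)") from exc
    disc = None
    if clip_radius is not None:
        from shapely.geometry import Point, Polygon

        disc = Point(0.0, 0.0).buffer(clip_radius, quad_segs=64)
    areas = np.empty(len(uniq))
    for i in range(len(uniq)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise ValueError("unbounded Voronoi cell despite periodic replication")
        poly = vor.vertices[region]
        if disc is not None and np.hypot(poly[:, 0], poly[:, 1]).max() > clip_radius:
            from shapely.geometry import Polygon

            areas[i] = Polygon(poly).intersection(disc).area
            continue
        x, y = poly[:, 0], poly[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    w = areas[inverse] / counts[inverse]
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate tessellation: zero total area")
    return w / total if normalise else w
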