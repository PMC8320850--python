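"""Mask optimisation, EDT interpolation, resampling, rendering, k-space."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vtphantom.core import Geometry, RegionMaskSeries, cifft2
from vtphantom.phantom import (
    clean_mask,
    interp_mask_pair,
    kspace_to_images,
    phantom_kspace,
    render_phantom,
    resample_space,
    resolve_overlaps,
    signed_distance,
    upsample_time,
)


def disk(N, centre, radius):
    r = np.arange(N)[:, None]
    c = np.arange(N)[None, :]
    return (r - centre[0]) ** 2 + (c - centre[1]) ** 2 <= radius**2


class TestCleanMask:
    def test_isolated_pixel_removed(self):
        m = disk(32, (16, 16), 6)
        m[2, 2] = True
        out = clean_mask(m, min_component_px=2, radius_px=0)
        assert not out[2, 2]
        assert out[16, 16]

    def test_interior_hole_filled(self):
        m = disk(32, (16, 16), 8)
        m[16, 16] = False
        out = clean_mask(m, min_component_px=2, radius_px=0)
        assert out[16, 16]

    def test_smooth_disk_idempotent(self):
        """Closing+opening with radius 1 leaves a smooth disk unchanged
        (checked against a brute-force dilate/erode oracle)."""
        m = disk(32, (16, 16), 9)
        out = clean_mask(m, min_component_px=2, radius_px=1)
        assert np.array_equal(out, m)
        # brute-force oracle: shift-union dilation then shift-intersection erosion
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if abs(dr) + abs(dc) <= 1]

        def dil(x):
            return np.any([np.roll(np.roll(x, dr, 0), dc, 1) for dr, dc in offsets], axis=0)

        def ero(x):
            return np.all([np.roll(np.roll(x, dr, 0), dc, 1) for dr, dc in offsets], axis=0)

        assert np.array_equal(ero(dil(m)), m)  # the disk is closing-invariant

    def test_empty_in_empty_out(self):
        assert not clean_mask(np.zeros((8, 8), bool)).any()


class TestResolveOverlaps:
    def _series(self, masks):
        return RegionMaskSeries(
            masks={k: v[None] for k, v in masks.items()},
            fps=1.0, geometry=Geometry(matrix=16, fov_mm=16.0),
            region_order=tuple(masks),
        )

    def test_lower_priority_loses_overlap(self):
        A = disk(16, (8, 6), 4)
        B = disk(16, (8, 10), 4)
        out = resolve_overlaps(self._series({"velum": A, "tongue": B}))
        assert np.array_equal(out.masks["velum"][0], A)
        assert np.array_equal(out.masks["tongue"][0], B & ~A)

    def test_disjoint_unchanged(self):
        A = disk(16, (4, 4), 2)
        B = disk(16, (12, 12), 2)
        out = resolve_overlaps(self._series({"velum": A, "tongue": B}))
        assert np.array_equal(out.masks["tongue"][0], B)

    def test_identical_masks_lower_becomes_empty(self):
        A = disk(16, (8, 8), 4)
        out = resolve_overlaps(self._series({"velum": A, "tongue": A.copy()}))
        assert not out.masks["tongue"][0].any()

    def test_head_loses_all_articulators(self, small_anatomy):
        _, series, truth = small_anatomy
        out = resolve_overlaps(truth.masks)
        head = out.masks["head"]
        for r in out.regions:
            if r != "head":
                assert not (head & out.masks[r]).any()


class TestInterpMaskPair:
    def test_endpoints_exact(self):
        A = disk(32, (16, 12), 5)
        B = disk(32, (16, 20), 5)
        assert np.array_equal(interp_mask_pair(A, B, 0.0), A)
        assert np.array_equal(interp_mask_pair(A, B, 1.0), B)

    def test_translated_disk_midpoint_centroid(self):
        """Brute-force signed-distance oracle: midpoint of a pure translation."""
        A = disk(32, (16, 12), 5)
        B = disk(32, (16, 20), 5)
        mid = interp_mask_pair(A, B, 0.5)
        cen = np.argwhere(mid).mean(axis=0)
        assert np.linalg.norm(cen - np.array([16.0, 16.0])) < 1.0
        # oracle: per-pixel nearest-boundary scan gives the same interpolant
        dA = _brute_signed_distance(A)
        dB = _brute_signed_distance(B)
        assert np.array_equal(mid, 0.5 * dA + 0.5 * dB <= 0)

    def test_identical_masks_fixed_point(self):
        A = disk(32, (16, 16), 6)
        for a in (0.0, 0.3, 0.5, 0.9, 1.0):
            assert np.array_equal(interp_mask_pair(A, A, a), A)

    def test_symmetry(self):
        A = disk(32, (10, 10), 5)
        B = disk(32, (20, 22), 7)
        for a in (0.25, 0.5, 0.75):
            assert np.array_equal(interp_mask_pair(A, B, a), interp_mask_pair(B, A, 1 - a))

    def test_empty_pair_and_single_empty(self):
        A = disk(16, (8, 8), 3)
        E = np.zeros((16, 16), bool)
        assert not interp_mask_pair(E, E, 0.5).any()
        shrunk = interp_mask_pair(A, E, 0.5)
        assert shrunk.sum() < A.sum()
        assert not interp_mask_pair(A, E, 0.9).any()  # near extinction


def _brute_signed_distance(mask):
    """O(N^4) nearest-opposite-pixel scan (oracle for signed_distance)."""
    N = mask.shape[0]
    coords = np.argwhere(np.ones_like(mask))
    inside = np.argwhere(mask)
    outside = np.argwhere(~mask)
    d = np.zeros(mask.shape)
    for r, c in coords:
        if mask[r, c]:
            d[r, c] = -np.sqrt(((outside - (r, c)) ** 2).sum(axis=1).min())
        else:
            d[r, c] = np.sqrt(((inside - (r, c)) ** 2).sum(axis=1).min())
    return d


def test_signed_distance_matches_brute_force():
    m = disk(16, (8, 6), 4)
    assert np.allclose(signed_distance(m), _brute_signed_distance(m))


class TestUpsampleTime:
    def _series(self, frames, fps=10.0):
        return RegionMaskSeries(
            masks={"velum": np.asarray(frames)}, fps=fps,
            geometry=Geometry(matrix=32, fov_mm=32.0),
        )

    def test_factor_one_identity(self):
        s = self._series([disk(32, (16, 12), 5), disk(32, (16, 20), 5)])
        out = upsample_time(s, 1)
        assert out.fps == s.fps
        assert np.array_equal(out.masks["velum"], s.masks["velum"])

    def test_10_to_30_fps(self):
        frames = [disk(32, (16, 10 + 2 * t), 5) for t in range(4)]
        out = upsample_time(self._series(frames, fps=10.0), 3)
        assert out.fps == 30.0
        assert out.n_frames == 3 * 3 + 1
        for t in range(4):
            assert np.array_equal(out.masks["velum"][3 * t], frames[t])

    def test_static_series_stays_static(self):
        A = disk(32, (16, 16), 6)
        out = upsample_time(self._series([A, A, A]), 3)
        for t in range(out.n_frames):
            assert np.array_equal(out.masks["velum"][t], A)

    def test_single_frame_with_factor_errors(self):
        with pytest.raises(ValueError):
            upsample_time(self._series([disk(32, (16, 16), 5)]), 2)


class TestResampleSpace:
    def test_identity_grid_unchanged(self):
        s = RegionMaskSeries(
            masks={"velum": disk(64, (32, 32), 10)[None]}, fps=1.0,
            geometry=Geometry(matrix=64, fov_mm=300.0),
        )
        out = resample_space(s, 64, 300.0)
        assert np.array_equal(out.masks["velum"], s.masks["velum"])

    def test_upsampled_disk_area_scales(self):
        s = RegionMaskSeries(
            masks={"velum": disk(64, (32, 32), 12)[None]}, fps=1.0,
            geometry=Geometry(matrix=64, fov_mm=300.0),
        )
        out = resample_space(s, 256, 300.0)
        assert out.geometry.matrix == 256
        assert out.geometry.fov_mm == 300.0
        ratio = out.masks["velum"].sum() / s.masks["velum"].sum()
        assert ratio == pytest.approx(16.0, rel=0.05)


class TestRenderAndKSpace:
    def test_render_values_and_sum_rule(self, small_anatomy):
        _, series, truth = small_anatomy
        table = series.intensity_table
        rendered = render_phantom(truth.masks, table)
        assert np.array_equal(rendered.frames, series.frames)
        acc = np.zeros_like(series.frames)
        for r in truth.masks.regions:
            acc += table[r] * truth.masks.masks[r]
        assert np.array_equal(rendered.frames, acc)

    def test_overlapping_masks_rejected(self):
        A = disk(16, (8, 8), 4)
        s = RegionMaskSeries(
            masks={"velum": A[None], "tongue": A[None]}, fps=1.0,
            geometry=Geometry(matrix=16, fov_mm=16.0),
        )
        with pytest.raises(ValueError, match="overlap"):
            render_phantom(s, {"velum": 0.9, "tongue": 0.8})

    def test_dc_bin_is_frame_sum(self, small_anatomy):
        _, series, _ = small_anatomy
        ks = phantom_kspace(series)
        N = series.geometry.matrix
        assert np.allclose(ks.frames[:, N // 2, N // 2], series.frames.sum(axis=(1, 2)))

    def test_uniform_frame_spectrum_is_dc_only(self):
        from vtphantom.core import DynamicImageSeries

        c = 0.7
        s = DynamicImageSeries(np.full((1, 16, 16), c), 1.0, Geometry(16, 300.0))
        F = phantom_kspace(s).frames[0]
        assert abs(F[8, 8] - c * 256) < 1e-10
        F[8, 8] = 0
        assert np.abs(F).max() < 1e-10

    def test_impulse_has_flat_spectrum(self):
        from vtphantom.core import DynamicImageSeries

        img = np.zeros((1, 16, 16))
        img[0, 8, 8] = 1.0
        F = phantom_kspace(DynamicImageSeries(img, 1.0, Geometry(16, 300.0))).frames[0]
        assert np.allclose(np.abs(F), 1.0, atol=1e-12)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_fft_round_trip_random_frames(self, seed):
        from vtphantom.core import DynamicImageSeries

        rng = np.random.default_rng(seed)
        frames = rng.normal(size=(2, 32, 32))
        s = DynamicImageSeries(frames, 1.0, Geometry(32, 300.0))
        back = kspace_to_images(phantom_kspace(s))
        assert np.abs(back - frames).max() < 1e-10
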