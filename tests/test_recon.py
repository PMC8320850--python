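"""Reconstruction: iFFT, gridding, SENSE unfolding, GRAPPA."""

import numpy as np
import pytest

from vtphantom.core import cfft2, cifft2, KSpaceSeries, Geometry
from vtphantom.phantom import phantom_kspace
from vtphantom.recon import (
    CalibrationError,
    UnderdeterminedError,
    gridding_recon,
    grappa_recon,
    ifft_recon,
    sense_recon,
    sos_combine,
)
from vtphantom.sampling import (
    coil_images,
    make_coil_maps,
    multicoil_kspace,
    nufft_sample,
    undersample,
)
from vtphantom.trajectories import make_trajectory


def nrmse(a, b):
    return np.linalg.norm(a - b) / np.linalg.norm(b)


class TestIfftRecon:
    def test_round_trip(self, small_anatomy):
        _, series, _ = small_anatomy
        rec = ifft_recon(phantom_kspace(series))
        assert np.abs(rec.frames - series.frames).max() < 1e-10

    def test_dc_only_spectrum_is_uniform(self):
        k = np.zeros((1, 16, 16), dtype=complex)
        k[0, 8, 8] = 256.0
        rec = ifft_recon(KSpaceSeries(k, 1.0, Geometry(16, 300)))
        assert np.allclose(rec.frames, 1.0)

    def test_linearity_before_magnitude(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(1, 16, 16)) + 1j * rng.normal(size=(1, 16, 16))
        Y = rng.normal(size=(1, 16, 16))
        geo = Geometry(16, 300)
        rx = ifft_recon(KSpaceSeries(X, 1.0, geo), magnitude=False).frames
        ry = ifft_recon(KSpaceSeries(Y, 1.0, geo), magnitude=False).frames
        rxy = ifft_recon(KSpaceSeries(2 * X + 3 * Y, 1.0, geo), magnitude=False).frames
        assert np.abs(rxy - (2 * rx + 3 * ry)).max() < 1e-10


class TestGriddingRecon:
    def test_full_cartesian_matches_ifft(self, static_frame_128):
        series, _ = static_frame_128
        frame = series.frames[0]
        traj = make_trajectory("cartesian", 128).with_dcf()
        rec = gridding_recon(nufft_sample(frame, traj), traj)
        ref = ifft_recon(phantom_kspace(series)).frames[0]
        assert nrmse(rec.frames[0], ref) < 1e-3  # normalized RMSE < 0.1%

    def test_missing_dcf_rejected(self):
        traj = make_trajectory("radial", 32)
        with pytest.raises(ValueError, match="dcf"):
            gridding_recon(np.zeros(traj.n_points, complex), traj)

    def test_radial_psf_peak_dominates_sidelobes(self):
        """Unit impulse through a Nyquist radial round trip: sharp peak."""
        N = 64
        img = np.zeros((N, N))
        img[N // 2, N // 2] = 1.0
        traj = make_trajectory("radial", N).with_dcf()
        rec = gridding_recon(nufft_sample(img, traj), traj).frames[0]
        peak = rec[N // 2, N // 2]
        rec_wo = rec.copy()
        rec_wo[N // 2 - 1 : N // 2 + 2, N // 2 - 1 : N // 2 + 2] = 0
        assert np.argmax(rec) == np.ravel_multi_index((N // 2, N // 2), (N, N))
        assert peak / rec_wo.max() > 10

    @pytest.mark.parametrize("kind", ["radial", "spiral"])
    def test_nyquist_noncartesian_recovers_all_regions(self, kind, static_frame_128):
        from vtphantom.evaluation import region_dice

        series, truth = static_frame_128
        traj = make_trajectory(kind, 128).with_dcf()
        rec = gridding_recon(nufft_sample(series.frames[0], traj), traj)
        dice = region_dice(rec.frames[0], truth.masks, series.intensity_table)
        assert all(v >= 0.8 for v in dice.values()), dice


@pytest.fixture(scope="module")
def multicoil_setup(moving_series_60):
    series, _ = moving_series_60
    short = series.copy_with(frames=series.frames[:4])
    maps = make_coil_maps(8, 128)
    ks = multicoil_kspace(coil_images(short, maps, noise_sigma=0.0))
    return short, maps, ks


class TestSenseRecon:
    def test_r1_equals_weighted_combine(self, multicoil_setup):
        series, maps, ks = multicoil_setup
        acq = undersample(ks, 1, 0, series.fps, series.geometry)
        rec = sense_recon(acq, maps)
        combine = np.abs(
            np.sum(np.conj(maps.maps)[None] * cifft2(ks), axis=1)
            / np.sum(np.abs(maps.maps) ** 2, axis=0)
        )
        assert np.abs(rec.frames - combine).max() < 1e-6

    def test_noise_free_r2_recovers_phantom(self, multicoil_setup):
        series, maps, ks = multicoil_setup
        acq = undersample(ks, 2, 0, series.fps, series.geometry)
        rec = sense_recon(acq, maps)
        err = 100 * np.sqrt(np.mean((rec.frames - series.frames) ** 2)) / np.ptp(
            series.frames
        )
        assert err < 1.0

    @pytest.mark.parametrize("R", [2, 4, 8])
    def test_noise_free_exact_maps_recover_at_any_feasible_r(self, multicoil_setup, R):
        series, maps, ks = multicoil_setup
        acq = undersample(ks, R, 0, series.fps, series.geometry)
        rec = sense_recon(acq, maps)
        assert nrmse(rec.frames, np.abs(series.frames)) < 0.01

    def test_underdetermined_flagged(self, moving_series_60):
        series, _ = moving_series_60
        short = series.copy_with(frames=series.frames[:1])
        maps = make_coil_maps(2, 128)
        ks = multicoil_kspace(coil_images(short, maps))
        acq = undersample(ks, 4, 0, short.fps, short.geometry)
        with pytest.raises(UnderdeterminedError):
            sense_recon(acq, maps)
        with pytest.warns(UserWarning, match="underdetermined|least-norm"):
            sense_recon(acq, maps, allow_underdetermined=True)


class TestGrappaRecon:
    def test_r1_identity_with_sos(self, multicoil_setup):
        series, maps, ks = multicoil_setup
        acq = undersample(ks, 1, 0, series.fps, series.geometry)
        rec = grappa_recon(acq)
        ref = sos_combine(cifft2(ks))
        assert np.abs(rec.frames - ref).max() < 1e-10

    def test_rmse_improves_with_coil_count(self, moving_series_60):
        """Table-style trend: 8 coils < 4 coils < 2 coils at R=2, ACS=10."""
        series, _ = moving_series_60
        short = series.copy_with(frames=series.frames[:2])
        errs = {}
        for C in (2, 4, 8):
            maps = make_coil_maps(C, 128)
            ks = multicoil_kspace(coil_images(short, maps))
            acq = undersample(ks, 2, 10, short.fps, short.geometry)
            rec = grappa_recon(acq)
            errs[C] = nrmse(rec.frames, short.frames)
        assert errs[8] < errs[4] < errs[2]

    def test_rmse_non_increasing_with_acs(self, multicoil_setup):
        series, maps, ks = multicoil_setup
        errs = []
        for acs in (10, 20, 40):
            acq = undersample(ks, 2, acs, series.fps, series.geometry)
            errs.append(nrmse(grappa_recon(acq).frames, series.frames))
        assert errs[0] >= errs[1] >= errs[2]

    def test_insufficient_acs_names_requirement(self, multicoil_setup):
        series, maps, ks = multicoil_setup
        acq = undersample(ks, 4, 6, series.fps, series.geometry)
        with pytest.raises(CalibrationError, match="ACS"):
            grappa_recon(acq)

    def test_acquired_lines_restored_verbatim(self, multicoil_setup):
        series, maps, ks = multicoil_setup
        acq = undersample(ks, 2, 16, series.fps, series.geometry)
        rec = grappa_recon(acq)
        assert rec.frames.shape == (4, 128, 128)


def test_severe_degradation_beyond_r4(moving_series_60):
    """With realistic coil noise, R=4 degrades SENSE and GRAPPA by > 3x R=2."""
    series, _ = moving_series_60
    short = series.copy_with(frames=series.frames[:2])
    maps = make_coil_maps(8, 128)
    ks = multicoil_kspace(coil_images(short, maps, noise_sigma=0.01, seed=3))
    errs_s, errs_g = {}, {}
    for R in (2, 4):
        acq = undersample(ks, R, 40, short.fps, short.geometry)
        errs_s[R] = nrmse(sense_recon(acq, maps).frames, short.frames)
        errs_g[R] = nrmse(grappa_recon(acq).frames, short.frames)
    assert errs_s[4] > 3 * errs_s[2]
    assert errs_g[4] > 3 * errs_g[2]


class TestSosCombine:
    def test_single_coil_magnitude(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=(1, 8, 8)) + 1j * rng.normal(size=(1, 8, 8))
        assert np.allclose(sos_combine(f), np.abs(f[0]))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        f = rng.normal(size=(4, 8, 8)) + 1j * rng.normal(size=(4, 8, 8))
        assert np.allclose(sos_combine(f), sos_combine(f[::-1]))
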