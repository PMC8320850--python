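import numpy as np
import pytest

from vtphantom.anatomy import AnatomyParams, generate_anatomy


@pytest.fixture(scope="session")
def small_anatomy():
    """Moving 64x64 anatomy, 8 frames, one closure cycle."""
    params = AnatomyParams(
        matrix_size=64, fov_mm=300.0, fps=30.0, n_frames=8,
        velum_cycles=1, tongue_excursion_px=3.0, seed=7,
    )
    return params, *generate_anatomy(params)


@pytest.fixture(scope="session")
def static_frame_128():
    """Single static 128x128 phantom frame with ground truth."""
    params = AnatomyParams(
        matrix_size=128, fov_mm=300.0, fps=30.0, n_frames=2,
        velum_cycles=0, tongue_excursion_px=0.0, seed=0,
    )
    series, truth = generate_anatomy(params)
    return series, truth


@pytest.fixture(scope="session")
def moving_series_60():
    """60-frame moving 128x128 phantom at 30 fps (frame-rate sweeps)."""
    params = AnatomyParams(
        matrix_size=128, fov_mm=300.0, fps=30.0, n_frames=60,
        velum_cycles=2, tongue_excursion_px=6.0, seed=1,
    )
    series, truth = generate_anatomy(params)
    return series, truth


def dice(a: np.ndarray, b: np.ndarray) -> float:
    s = a.sum() + b.sum()
    return 2.0 * np.sum(a & b) / s if s else 1.0
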