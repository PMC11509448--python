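import numpy as np
import pytest

from aortaflow import (
    LumenMaskSeries,
    PhantomParams,
    VelocitySeries,
    ground_truth_indices,
    render_phantom,
)


def make_series(velocity, spacing=(1.0, 1.0), rr_ms=None, venc=200.0):
    """VelocitySeries from a raw (frames, rows, cols) array, uniform timing."""
    velocity = np.asarray(velocity, dtype=float)
    n = velocity.shape[0]
    if rr_ms is None:
        rr_ms = 1000.0
    times = np.arange(n) * rr_ms / n
    return VelocitySeries(
        velocity=velocity,
        pixel_spacing_mm=spacing,
        frame_times_ms=times,
        venc_cm_s=venc,
        rr_ms=rr_ms,
    )


def full_masks(velocity):
    return LumenMaskSeries(np.ones_like(np.asarray(velocity), dtype=bool))


@pytest.fixture(scope="session")
def concentric_plug_params():
    """Noise-free concentric plug jet: the symmetric reference phantom."""
    return PhantomParams(
        profile="plug", jet_offset_frac=0.0, retro_frac=0.0, noise_sd_cm_s=0.0
    )


@pytest.fixture(scope="session")
def concentric_plug_phantom(concentric_plug_params):
    return render_phantom(concentric_plug_params, with_noise=False)


@pytest.fixture(scope="session")
def eccentric_params():
    """Noise-free eccentric Gaussian jet with 10% systolic retro fraction."""
    return PhantomParams(
        jet_offset_frac=0.25, retro_frac=0.10, noise_sd_cm_s=0.0
    )


@pytest.fixture(scope="session")
def eccentric_phantom(eccentric_params):
    return render_phantom(eccentric_params, with_noise=False)


@pytest.fixture(scope="session")
def eccentric_ground_truth(eccentric_params):
    return ground_truth_indices(eccentric_params)
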