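"""Shared fixtures: small synthetic scenes built at test time."""

import numpy as np
import pytest

from cardiopiv.synth import (
    AcquisitionParams,
    FlowFieldSpec,
    ParticleCloud,
    make_particle_cloud,
    render_frame,
)

# default calibration used throughout: 1.75 µm/px, 15 ms/frame
PX = 1.75
DT_MS = 15.0
UMS_PER_PXF = PX / (DT_MS / 1000.0)  # µm/s per px/frame


def zncc_direct(frame_a, frame_b, center, w, r, predictor=(0, 0)):
    """Independent correlation oracle: naive double loop over all lags."""
    cx, cy = center
    half = w // 2
    A = frame_a[cy - half: cy - half + w, cx - half: cx - half + w]
    A0 = A - A.mean()
    na = np.sqrt((A0 ** 2).sum())
    out = np.zeros((2 * r + 1, 2 * r + 1))
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            sy = cy - half + predictor[1] + dy
            sx = cx - half + predictor[0] + dx
            B = frame_b[sy: sy + w, sx: sx + w]
            B0 = B - B.mean()
            nb = np.sqrt((B0 ** 2).sum())
            out[dy + r, dx + r] = (A0 * B0).sum() / (na * nb)
    return out


@pytest.fixture(scope="session")
def speckle_pair():
    """A dense noise-free particle image and its exact 3.0-px x-translate."""
    acq = AcquisitionParams(
        image_shape=(96, 96), pixel_size=1.0, frame_interval=10.0,
        n_frames=2, noise_sigma=0.0, background_level=5.0,
    )
    cloud = make_particle_cloud(0.1, (0, 96, 0, 96), seed=42, diameter=3.0)
    shifted = ParticleCloud(
        cloud.positions + np.array([3.0, 1.0]), cloud.diameters, cloud.brightness
    )
    return render_frame(cloud, acq), render_frame(shifted, acq)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def pulsatile_scene(mean_pxf, amp_pxf, *, shape=(96, 192), n_frames=310,
                    period_frames=30, noise_sigma=2.0, density=0.012, seed=1):
    """A lumen-plus-tissue movie spec matching the bundled demo geometry."""
    acq = AcquisitionParams(
        image_shape=shape, pixel_size=PX, frame_interval=DT_MS,
        n_frames=n_frames, noise_sigma=noise_sigma, background_level=10.0,
    )
    h, w = shape
    lumen = (0.0, w * PX, round(0.21 * h) * PX, round(0.79 * h) * PX)
    flow = FlowFieldSpec.pulsatile(
        mean_pxf * UMS_PER_PXF, amp_pxf * UMS_PER_PXF,
        period_frames * DT_MS / 1000.0, lumen,
    )
    return flow, acq, density, seed
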