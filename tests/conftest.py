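import math

import numpy as np
import pytest

from quack.video_io import VideoStack
from quack.synthetic import SimConfig, FilamentTrack, simulate_video


@pytest.fixture
def gradient_stack() -> VideoStack:
    """20-frame smooth grayscale stack with per-frame structure."""
    t, h, w = 20, 32, 40
    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.stack([100 + 50 * np.sin(xx / 5 + k / 3) + 30 * np.cos(yy / 4) for k in range(t)])
    return VideoStack(frames=frames, frame_interval_s=1.0, pixel_size_um=0.1)


@pytest.fixture
def static_filament() -> tuple[VideoStack, list[FilamentTrack], SimConfig]:
    """Noise-free movie with one static vertical filament crossing y=2.2 um."""
    cfg = SimConfig(image_shape=(44, 120), n_frames=60, frame_interval_s=1.0,
                    pixel_size_um=0.1, noise_sd=0.0)
    track = FilamentTrack(center0=(6.0, 2.2), orientation=math.pi / 2, length=3.0,
                          birth_s=0.0, death_s=59.0, drift_velocity=0.0,
                          amplitude=cfg.amplitude)
    stack, tracks = simulate_video(cfg, seed=0, tracks=[track])
    return stack, tracks, cfg
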