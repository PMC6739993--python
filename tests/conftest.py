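"""Shared fixtures.

The expensive artifacts (trained U-net, beamformed ablation images) are
session-scoped and built once; everything downstream reuses them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from ucpwi.bubble import BubbleParams, DrivePulse, build_mother_wavelet
from ucpwi.classifier import TrainConfig, build_unet, train
from ucpwi.pipeline import PipelineConfig, RegionSpec
from ucpwi.rf_sim import (
    ProbeGeometry,
    bubble_tube_phantom,
    make_training_corpus,
    simulate_plane_wave_rx,
)

CORPUS_SEED = 1
MODEL_SEED = 0
FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def default_params():
    return BubbleParams()


@pytest.fixture(scope="session")
def default_drive():
    return DrivePulse()


@pytest.fixture(scope="session")
def mother_wavelet():
    """Mother wavelet at the acquisition sampling rate (25 MHz)."""
    return build_mother_wavelet(BubbleParams(), DrivePulse())


@pytest.fixture(scope="session")
def training_corpus():
    """Seeded 20k-segment corpus, 45/55 balance, frame-level 80/20 split."""
    return make_training_corpus(n_frames=12, seed=CORPUS_SEED, n_segments=20_000)


@pytest.fixture(scope="session")
def trained_unet(training_corpus):
    """U-net trained under the fast profile on the session corpus."""
    model = build_unet(seed=MODEL_SEED)
    model, history = train(model, training_corpus, TrainConfig.fast(seed=MODEL_SEED))
    return model, history


@pytest.fixture(scope="session")
def tube_frame():
    """Bubble tube over a strong tissue layer, 64 elements, 1100 samples."""
    geometry = ProbeGeometry(n_elements=64)
    phantom = bubble_tube_phantom(seed=FIXTURE_SEED, geometry=geometry)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_plane_wave_rx(
            phantom, geometry, DrivePulse(), seed=FIXTURE_SEED, n_samples=1100
        )


def depth_index(z_m: float, decimation: int = 4, fs: float = 25e6, c0: float = 1540.0) -> int:
    """Pixel index of depth z on the decimated default depth grid."""
    return int(round((z_m * 2 * fs / c0 - 1) / decimation))


@pytest.fixture(scope="session")
def tube_regions():
    """UCA rectangle over the tube, tissue rectangle over the strong layer."""
    return RegionSpec(
        uca_region=(10, 54, depth_index(0.018), depth_index(0.020)),
        tissue_region=(10, 54, depth_index(0.009), depth_index(0.011)),
    )


@pytest.fixture(scope="session")
def pipeline_config(trained_unet, mother_wavelet):
    model, _ = trained_unet
    return PipelineConfig(model=model, wavelet=mother_wavelet, depth_decimation=4)
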