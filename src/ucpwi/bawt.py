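"""Bubble-approximated wavelet transform (BAWT) of RF lines.

The continuous wavelet transform against the bubble's scattered-pressure
mother wavelet is a matched filter: bubble echoes correlate strongly with
the dilated wavelet, tissue echoes do not.  In the processing chain, RF
samples classified as bubble are replaced by their wavelet coefficient at
the optimal scale (the dilation placing the wavelet passband on the second
harmonic) and tissue-classified samples are zeroed, suppressing residual
tissue before beamforming.

Conventions: real-valued "same"-mode correlation with zero padding (so
coefficients near line ends are edge-attenuated), L2 normalisation — the
dilated wavelet psi(t/s)/sqrt(s) is renormalised to exactly unit energy, so
a unit-energy input matching the wavelet yields a peak coefficient of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve

from .bubble import BubbleWavelet, dilate_wavelet
from .rf_sim import ChannelData


@dataclass(frozen=True)
class BawtConfig:
    """CWT settings: dilation `scale` and the L2 normalisation flag."""

    scale: float = 1.0
    l2_normalize: bool = True

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def _prepared_kernel(wavelet: BubbleWavelet, scale: float, l2_normalize: bool = True):
    ws = dilate_wavelet(wavelet, scale)
    psi = ws.psi
    dt = 1.0 / ws.fs
    if l2_normalize:
        energy = np.sum(psi**2) * dt
        psi = psi / np.sqrt(energy)
    return psi, dt


def cwt_line(x: np.ndarray, wavelet: BubbleWavelet, scale: float = 1.0,
             l2_normalize: bool = True) -> np.ndarray:
    """Wavelet coefficients of one RF line at a single scale.

    Output has the same length as `x` ("same"-mode correlation, zero-padded
    edges).  Linear in `x`; delaying `x` delays the coefficients equally.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("cwt_line expects a 1-D RF line")
    psi, dt = _prepared_kernel(wavelet, scale, l2_normalize)
    # correlation = convolution with the reversed kernel
    return fftconvolve(x, psi[::-1], mode="same") * dt


def cwt_frame(rf: np.ndarray, wavelet: BubbleWavelet, scale: float = 1.0,
              l2_normalize: bool = True) -> np.ndarray:
    """CWT of every column (element line) of a samples x elements matrix."""
    psi, dt = _prepared_kernel(wavelet, scale, l2_normalize)
    return fftconvolve(rf, psi[::-1, None], mode="same", axes=0) * dt


def apply_bawt(data: ChannelData, mask, cfg: BawtConfig, wavelet: BubbleWavelet) -> ChannelData:
    """Replace bubble-classified samples by wavelet coefficients; zero tissue.

    `mask` is a per-sample binary bubble indicator matching ``data.rf`` (a
    :class:`~ucpwi.classifier.BubbleMask` or a plain array).  Where the mask
    is 1 the RF sample is replaced by the CWT coefficient at ``cfg.scale``;
    everywhere else the output is 0, suppressing tissue and background
    before beamforming.
    """
    m = np.asarray(getattr(mask, "mask", mask))
    if m.shape != data.rf.shape:
        raise ValueError(f"mask shape {m.shape} does not match rf {data.rf.shape}")
    coeffs = cwt_frame(np.asarray(data.rf, dtype=float), wavelet, cfg.scale, cfg.l2_normalize)
    out = np.where(m == 1, coeffs, 0.0)
    return ChannelData(
        rf=out.astype(np.float32),
        geometry=data.geometry,
        f_transmit=data.f_transmit,
        truth_mask=data.truth_mask,
        frame_id=data.frame_id,
    )
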