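"""File formats: HDF5 frames/masks/images, NPZ wavelets, YAML configs."""

from __future__ import annotations

import numpy as np
import h5py
import yaml

from .bubble import BubbleParams, BubbleWavelet, DrivePulse
from .classifier import BubbleMask
from .beamform import BeamformedImage
from .rf_sim import ChannelData, Phantom, ProbeGeometry


def save_channel_data(path, data: ChannelData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=np.asarray(data.rf, dtype=np.float32))
        if data.truth_mask is not None:
            f.create_dataset("truth_mask", data=data.truth_mask.astype(np.int8))
        g = data.geometry
        f.attrs.update(
            {
                "fs": g.fs,
                "c0": g.c0,
                "pitch": g.pitch,
                "n_elements": g.n_elements,
                "f_transmit": data.f_transmit,
                "frame_id": data.frame_id,
            }
        )


def load_channel_data(path) -> ChannelData:
    with h5py.File(path, "r") as f:
        rf = f["rf"][...]
        mask = f["truth_mask"][...] if "truth_mask" in f else None
        a = f.attrs
        geom = ProbeGeometry(
            n_elements=int(a["n_elements"]), pitch=float(a["pitch"]),
            fs=float(a["fs"]), c0=float(a["c0"]),
        )
        return ChannelData(
            rf=rf, geometry=geom, f_transmit=float(a["f_transmit"]),
            truth_mask=mask, frame_id=int(a.get("frame_id", 0)),
        )


def save_wavelet(path, wavelet: BubbleWavelet) -> None:
    np.savez(path, psi=wavelet.psi, fs=wavelet.fs, f_center=wavelet.f_center)


def load_wavelet(path) -> BubbleWavelet:
    with np.load(path) as z:
        return BubbleWavelet(psi=z["psi"], fs=float(z["fs"]), f_center=float(z["f_center"]))


def save_mask(path, mask: BubbleMask) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("mask", data=mask.mask.astype(np.int8))
        f.create_dataset("prob", data=mask.prob.astype(np.float32))


def load_mask(path) -> BubbleMask:
    with h5py.File(path, "r") as f:
        return BubbleMask(mask=f["mask"][...], prob=f["prob"][...])


def save_image(path, image: BeamformedImage) -> None:
    with h5py.File(path, "w") as f:
        for name, arr in image.pixels.items():
            f.create_dataset(f"pixels/{name}", data=arr)
        for name in ("lambda_max", "detect_mask", "envelope", "display", "line_x", "depths"):
            arr = getattr(image, name)
            if arr is not None:
                f.create_dataset(name, data=np.asarray(arr))
        f.attrs["dynamic_range"] = image.dynamic_range


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def bubble_params_from_dict(d: dict) -> BubbleParams:
    return BubbleParams(**d)


def drive_pulse_from_dict(d: dict) -> DrivePulse:
    return DrivePulse(**d)


def probe_geometry_from_dict(d: dict) -> ProbeGeometry:
    return ProbeGeometry(**d)


def phantom_from_dict(d: dict) -> Phantom:
    return Phantom(
        tissue_scatterers=np.asarray(d.get("tissue_scatterers", np.zeros((0, 3)))),
        bubble_scatterers=np.asarray(d.get("bubble_scatterers", np.zeros((0, 3)))),
        noise_sigma=float(d.get("noise_sigma", 0.0)),
    )
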