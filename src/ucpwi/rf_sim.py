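"""Synthetic plane-wave channel-RF generator with per-sample ground truth.

Emulates a linear-array plane-wave acquisition of a contrast-agent scene:
tissue-like point scatterers return linear replicas of the transmit pulse,
while microbubble scatterers return the nonlinear scattered-pressure
waveform of the shell model (:mod:`ucpwi.bubble`), which carries
second-harmonic content the tissue echoes lack.  Every echo is tagged in a
per-sample truth mask, which is what makes supervised segment training and
mask-recall evaluation possible.

The delay law is the standard 0-degree plane-wave two-way time: the transmit
wavefront reaches a scatterer at depth z after z/c0, and the echo returns to
element i after the Euclidean distance over c0.  Echo amplitude falls as the
reciprocal of the return distance.  Element directivity, attenuation and
multiple scattering are deliberately omitted — the post-processing chain
operates on RF statistics, not absolute calibration.

Label codes in truth masks: 0 background, 1 tissue, 2 bubble (bubble takes
precedence where echoes overlap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .bubble import (
    BubbleParams,
    DrivePulse,
    scattered_pressure,
    solve_bubble_dynamics,
    _energy_support,
)

BACKGROUND, TISSUE, BUBBLE = 0, 1, 2


@dataclass(frozen=True)
class ProbeGeometry:
    """Linear-array geometry (defaults: 128 elements, 0.3 mm pitch, 25 MHz
    sampling, 1540 m/s soft-tissue sound speed)."""

    n_elements: int = 128
    pitch: float = 0.3e-3
    fs: float = 25e6
    c0: float = 1540.0

    def __post_init__(self):
        if self.n_elements < 2:
            raise ValueError("need at least 2 elements")
        for name in ("pitch", "fs", "c0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def element_x(self) -> np.ndarray:
        """Lateral element centres, origin at the array centre."""
        return (np.arange(self.n_elements) - (self.n_elements - 1) / 2) * self.pitch


@dataclass(frozen=True)
class Phantom:
    """Scene description: (x, z, strength) triples plus a white-noise level.

    ``tissue_scatterers`` and ``bubble_scatterers`` are (k, 3) arrays of
    lateral position [m], depth [m] (> 0) and echo strength [arbitrary].
    """

    tissue_scatterers: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    bubble_scatterers: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    noise_sigma: float = 0.0

    def __post_init__(self):
        for name in ("tissue_scatterers", "bubble_scatterers"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if arr.size == 0:
                arr = arr.reshape(0, 3)
            if arr.shape[1] != 3:
                raise ValueError(f"{name} must be (k, 3): x, z, strength")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
            if arr.shape[0] and np.any(arr[:, 1] <= 0):
                raise ValueError(f"{name} depths must be positive")
            object.__setattr__(self, name, arr)
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class ChannelData:
    """Channel RF frame: samples x elements, plus geometry and truth."""

    rf: np.ndarray
    geometry: ProbeGeometry
    f_transmit: float
    truth_mask: np.ndarray | None = None
    frame_id: int = 0

    def __post_init__(self):
        self.rf = np.asarray(self.rf)
        if self.rf.ndim != 2 or self.rf.shape[1] != self.geometry.n_elements:
            raise ValueError(
                f"rf must be (samples, {self.geometry.n_elements}); got {self.rf.shape}"
            )
        if self.truth_mask is not None and self.truth_mask.shape != self.rf.shape:
            raise ValueError("truth_mask shape must match rf")

    @property
    def n_samples(self) -> int:
        return self.rf.shape[0]


@dataclass
class SegmentDataset:
    """Labelled sliding-window RF segments.

    `segments` is (n, length) float32; `labels` holds 1 for bubble, 0 for
    tissue; `background_frac` is the fraction of unlabeled samples in each
    window; `provenance` rows are (frame, element, start sample); `subset`
    (optional) assigns each segment to the "train" or "test" side of a
    frame-level split.
    """

    segments: np.ndarray
    labels: np.ndarray
    provenance: np.ndarray
    background_frac: np.ndarray
    label_purity: np.ndarray | None = None
    subset: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.segments)

    def take(self, idx) -> "SegmentDataset":
        return SegmentDataset(
            segments=self.segments[idx],
            labels=self.labels[idx],
            provenance=self.provenance[idx],
            background_frac=self.background_frac[idx],
            label_purity=None if self.label_purity is None else self.label_purity[idx],
            subset=None if self.subset is None else self.subset[idx],
        )

    def filter_background(self, max_frac: float = 0.5) -> "SegmentDataset":
        """Drop windows that are more than `max_frac` background."""
        return self.take(self.background_frac <= max_frac)

    def filter_mixed(self, min_purity: float = 0.7) -> "SegmentDataset":
        """Drop windows whose majority class holds less than `min_purity` of
        the labelled samples.

        Real training corpora are collected from acquisitions that are
        purely bubble or purely tissue; windows straddling both carry
        near-arbitrary majority labels and only inject label noise.
        """
        if self.label_purity is None:
            return self
        return self.take(self.label_purity >= min_purity)

    @property
    def train(self) -> "SegmentDataset":
        if self.subset is None:
            raise ValueError("dataset carries no train/test split")
        return self.take(self.subset == 0)

    @property
    def test(self) -> "SegmentDataset":
        if self.subset is None:
            raise ValueError("dataset carries no train/test split")
        return self.take(self.subset == 1)

    @property
    def bubble_fraction(self) -> float:
        return float(np.mean(self.labels == 1)) if len(self) else 0.0


def bubble_echo_waveform(
    bubble_params: BubbleParams, drive: DrivePulse, fs: float
) -> np.ndarray:
    """Unit-peak scattered-pressure waveform used as the bubble echo.

    Solved once per (params, drive, fs) and trimmed to its 99.9 %-energy
    support; the scatterer strength and 1/distance factors set the scale at
    insertion time.
    """
    traj = solve_bubble_dynamics(bubble_params, drive, fs=fs)
    p = scattered_pressure(traj, d=1.0, rho_l=bubble_params.rho_l)
    i0, i1 = _energy_support(p)
    w = p[i0:i1]
    return w / np.abs(w).max()


def _tissue_echo_waveform(drive: DrivePulse, fs: float) -> np.ndarray:
    w = drive.waveform(fs)
    peak = np.abs(w).max()
    if peak == 0:
        return w
    return w / peak


def _add_delayed(line: np.ndarray, wave: np.ndarray, delay_samples: float, amp: float) -> tuple[int, int]:
    """Add `amp * wave` at fractional sample offset; returns covered range."""
    n = len(line)
    i0 = int(np.floor(delay_samples))
    frac = delay_samples - i0
    # linear-interpolation fractional delay: split between i0 and i0+1
    for off, wgt in ((i0, 1.0 - frac), (i0 + 1, frac)):
        if wgt == 0.0:
            continue
        lo = max(off, 0)
        hi = min(off + len(wave), n)
        if hi <= lo:
            continue
        line[lo:hi] += amp * wgt * wave[lo - off : hi - off]
    return max(i0, 0), min(i0 + len(wave) + 1, n)


def simulate_plane_wave_rx(
    phantom: Phantom,
    geometry: ProbeGeometry | None = None,
    drive: DrivePulse | None = None,
    bubble_params: BubbleParams | None = None,
    seed: int = 0,
    n_samples: int = 2100,
    frame_id: int = 0,
) -> ChannelData:
    """Simulate one 0-degree plane-wave receive frame with ground truth."""
    geometry = geometry or ProbeGeometry()
    drive = drive or DrivePulse()
    bubble_params = bubble_params or BubbleParams()
    if len(phantom.tissue_scatterers) == 0 and len(phantom.bubble_scatterers) == 0 \
            and phantom.noise_sigma == 0.0:
        warnings.warn("empty phantom with zero noise: frame will be all zeros", stacklevel=2)

    fs, c0 = geometry.fs, geometry.c0
    xe = geometry.element_x
    rf = np.zeros((n_samples, geometry.n_elements), dtype=np.float64)
    mask = np.zeros((n_samples, geometry.n_elements), dtype=np.int8)

    tissue_wave = _tissue_echo_waveform(drive, fs)
    bubble_wave = (
        bubble_echo_waveform(bubble_params, drive, fs)
        if len(phantom.bubble_scatterers)
        else None
    )

    truncated = 0
    for scatterers, wave, code in (
        (phantom.tissue_scatterers, tissue_wave, TISSUE),
        (phantom.bubble_scatterers, bubble_wave, BUBBLE),
    ):
        for x, z, strength in scatterers:
            ret_dist = np.hypot(x - xe, z)
            delays = (z + ret_dist) / c0 * fs
            amps = strength / ret_dist
            for e in range(geometry.n_elements):
                if delays[e] >= n_samples:
                    truncated += 1
                    continue
                lo, hi = _add_delayed(rf[:, e], wave, delays[e], amps[e])
                if delays[e] + len(wave) > n_samples:
                    truncated += 1
                if code == BUBBLE:
                    mask[lo:hi, e] = BUBBLE
                else:
                    seg = mask[lo:hi, e]
                    seg[seg != BUBBLE] = TISSUE
    if truncated:
        warnings.warn(
            f"{truncated} echo(es) extended beyond the {n_samples}-sample window and "
            "were truncated",
            stacklevel=2,
        )
    if phantom.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        rf += rng.normal(0.0, phantom.noise_sigma, size=rf.shape)
    return ChannelData(
        rf=rf.astype(np.float32),
        geometry=geometry,
        f_transmit=drive.f0,
        truth_mask=mask,
        frame_id=frame_id,
    )


def segment_rf(data: ChannelData, length: int = 60, step: int = 5) -> SegmentDataset:
    """Slide length-`length` windows with stride `step` along every line.

    A window's label is the majority of its tissue/bubble-tagged samples
    (ties go to bubble); `background_frac` records the untagged fraction so
    training corpora can drop mostly-empty windows while inference keeps
    every window.
    """
    if length > data.n_samples:
        raise ValueError("segment length exceeds line length")
    rf = np.asarray(data.rf, dtype=np.float32)
    n_samples, n_elem = rf.shape
    starts = np.arange(0, n_samples - length + 1, step)
    windows = np.lib.stride_tricks.sliding_window_view(rf, length, axis=0)[::step]
    # windows: (n_starts, n_elem, length) -> flatten element-major
    segs = windows.transpose(1, 0, 2).reshape(-1, length)

    if data.truth_mask is not None:
        mask_w = np.lib.stride_tricks.sliding_window_view(data.truth_mask, length, axis=0)[::step]
        n_bub = (mask_w == BUBBLE).sum(axis=2)
        n_tis = (mask_w == TISSUE).sum(axis=2)
        n_bg = length - n_bub - n_tis
        labels = (n_bub >= n_tis).astype(np.int8)  # ties -> bubble
        labels[(n_bub == 0) & (n_tis == 0)] = 0    # pure background -> tissue
        bg_frac = n_bg / float(length)
        n_lab = np.maximum(n_bub + n_tis, 1)
        purity = np.maximum(n_bub, n_tis) / n_lab
        labels = labels.T.reshape(-1)
        bg_frac = bg_frac.T.reshape(-1).astype(np.float32)
        purity = purity.T.reshape(-1).astype(np.float32)
    else:
        labels = np.full(len(segs), -1, dtype=np.int8)
        bg_frac = np.zeros(len(segs), dtype=np.float32)
        purity = np.ones(len(segs), dtype=np.float32)

    elems = np.repeat(np.arange(n_elem), len(starts))
    start_col = np.tile(starts, n_elem)
    prov = np.column_stack(
        [np.full(len(segs), data.frame_id, dtype=np.int64), elems, start_col]
    )
    return SegmentDataset(
        segments=np.ascontiguousarray(segs),
        labels=labels,
        provenance=prov,
        background_frac=bg_frac,
        label_purity=purity,
    )


def _random_phantom(rng: np.random.Generator, geometry: ProbeGeometry,
                    n_samples: int = 2100) -> Phantom:
    """Randomised scene mimicking varied acquisition conditions.

    Tissue is dense (speckle-like overlapping echoes); bubbles come in small
    clusters, the way contrast agent fills a vessel or tube rather than
    appearing as isolated scatterers.
    """
    half_ap = geometry.element_x[-1]
    n_tissue = int(rng.integers(40, 80))
    n_cluster = int(rng.integers(3, 6))
    z_lo, z_hi = 5e-3, 0.9 * geometry.c0 * n_samples / (2 * geometry.fs)
    tissue = np.column_stack(
        [
            rng.uniform(-half_ap, half_ap, n_tissue),
            rng.uniform(z_lo, z_hi, n_tissue),
            rng.uniform(0.5, 2.0, n_tissue),
        ]
    )
    clusters = []
    for _ in range(n_cluster):
        cx = rng.uniform(-half_ap, half_ap)
        cz = rng.uniform(z_lo, z_hi)
        k = int(rng.integers(4, 8))
        clusters.append(
            np.column_stack(
                [
                    cx + rng.uniform(-1e-3, 1e-3, k),
                    np.maximum(cz + rng.uniform(-1.5e-3, 1.5e-3, k), z_lo),
                    # contrast agent scatters several-fold stronger than tissue
                    rng.uniform(1.5, 6.0, k),
                ]
            )
        )
    bubbles = np.concatenate(clusters)
    return Phantom(tissue_scatterers=tissue, bubble_scatterers=bubbles, noise_sigma=0.2)


def bubble_tube_phantom(seed: int = 11, geometry: ProbeGeometry | None = None) -> Phantom:
    """Evaluation scene: a contrast-filled tube over a strong tissue layer.

    Mimics the wall-less-tube phantom topped with pork: dense tissue speckle
    throughout, three strong scatterers near 10 mm (the pork interface), and
    a band of bubble clusters at 18-20 mm depth (the contrast-filled tube).
    """
    geometry = geometry or ProbeGeometry(n_elements=64)
    rng = np.random.default_rng(seed)
    n_t = 50
    tissue = np.column_stack(
        [
            rng.uniform(-9e-3, 9e-3, n_t),
            rng.uniform(5e-3, 28e-3, n_t),
            rng.uniform(0.5, 1.5, n_t),
        ]
    )
    strong = np.array(
        [[0.0, 0.010, 8.0], [-3e-3, 0.0105, 6.0], [3e-3, 0.0095, 6.0]]
    )
    nb = 40
    tube = np.column_stack(
        [
            rng.uniform(-4e-3, 4e-3, nb),
            rng.uniform(18e-3, 20e-3, nb),
            rng.uniform(1.5, 6.0, nb),
        ]
    )
    return Phantom(
        tissue_scatterers=np.vstack([tissue, strong]),
        bubble_scatterers=tube,
        noise_sigma=0.2,
    )


def make_training_corpus(
    n_frames: int = 12,
    class_balance: float = 0.45,
    seed: int = 0,
    n_segments: int = 20_000,
    geometry: ProbeGeometry | None = None,
    n_samples: int = 2100,
    train_fraction: float = 0.8,
    drive_frequencies: tuple[float, ...] = (3e6, 4e6, 5e6),
    min_purity: float = 0.7,
) -> SegmentDataset:
    """Build a labelled segment corpus from randomised synthetic frames.

    Frames vary scatterer placement, strength and transmit frequency (the
    acquisition-parameter sweeps used to enrich real training data).  The
    corpus is split 80/20 at *frame* level — heavily overlapping windows
    from one frame never straddle the split — then each side is subsampled
    to the requested bubble fraction (default 45 % bubble / 55 % tissue).
    Deterministic given `seed`.
    """
    if not 0 < class_balance < 1:
        raise ValueError("class_balance must be in (0, 1)")
    geometry = geometry or ProbeGeometry(n_elements=32)
    rng = np.random.default_rng(seed)
    datasets = []
    for f in range(n_frames):
        drive = DrivePulse(f0=float(rng.choice(drive_frequencies)))
        phantom = _random_phantom(rng, geometry)
        frame = simulate_plane_wave_rx(
            phantom,
            geometry,
            drive,
            seed=int(rng.integers(2**31)),
            n_samples=n_samples,
            frame_id=f,
        )
        datasets.append(segment_rf(frame).filter_background().filter_mixed(min_purity))

    pooled = SegmentDataset(
        segments=np.concatenate([d.segments for d in datasets]),
        labels=np.concatenate([d.labels for d in datasets]),
        provenance=np.concatenate([d.provenance for d in datasets]),
        background_frac=np.concatenate([d.background_frac for d in datasets]),
        label_purity=np.concatenate([d.label_purity for d in datasets]),
    )

    frame_order = rng.permutation(n_frames)
    n_train_frames = max(1, int(round(train_fraction * n_frames)))
    train_frames = set(frame_order[:n_train_frames].tolist())
    in_train = np.isin(pooled.provenance[:, 0], list(train_frames))

    n_train_target = int(round(train_fraction * n_segments))
    parts = []
    for is_train, n_target in ((True, n_train_target), (False, n_segments - n_train_target)):
        side = pooled.take(in_train == is_train)
        n_bub_target = int(round(class_balance * n_target))
        n_tis_target = n_target - n_bub_target
        idx_bub = np.flatnonzero(side.labels == 1)
        idx_tis = np.flatnonzero(side.labels == 0)
        if len(idx_bub) < n_bub_target or len(idx_tis) < n_tis_target:
            raise ValueError(
                f"corpus too small: need {n_bub_target} bubble / {n_tis_target} tissue "
                f"segments on the {'train' if is_train else 'test'} side, have "
                f"{len(idx_bub)} / {len(idx_tis)}; increase n_frames"
            )
        pick = np.concatenate(
            [
                rng.choice(idx_bub, n_bub_target, replace=False),
                rng.choice(idx_tis, n_tis_target, replace=False),
            ]
        )
        pick = rng.permutation(pick)
        chosen = side.take(pick)
        chosen.subset = np.full(len(chosen), 0 if is_train else 1, dtype=np.int8)
        parts.append(chosen)

    return SegmentDataset(
        segments=np.concatenate([p.segments for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        provenance=np.concatenate([p.provenance for p in parts]),
        background_frac=np.concatenate([p.background_frac for p in parts]),
        label_purity=np.concatenate([p.label_purity for p in parts]),
        subset=np.concatenate([p.subset for p in parts]),
    )
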