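"""Plane-wave beamforming: DAS, minimum variance, and eigenspace MV.

Pixels live on a grid of scan lines (one per element lateral position by
default) and depth samples.  For a 0-degree plane wave, the two-way travel
time to a pixel at (x, z) seen by element i at x_i is

    tau_i = z / c0 + sqrt((x - x_i)^2 + z^2) / c0,

sampled with linear interpolation.  The delayed element vector x_d(k) feeds

* DAS — the plain mean over elements;
* MV (Capon) — w = R~^{-1} d / (d^H R~^{-1} d) with d = 1 (delays already
  applied), output averaged over the M - L + 1 sliding subarrays;
* ESBMV — the MV weight projected onto the signal subspace spanned by the
  eigenvectors whose eigenvalues reach alpha * lambda_1.

R(k) is the mean of sliding length-L subarray outer products, stabilised by
diagonal loading R~ = R + delta * trace(R) * I (delta <= 1/L).  The largest
eigenvalue lambda_1 is far higher over bubble pixels than tissue pixels,
which the per-line threshold detector exploits: a pixel is flagged bubble
when lambda_1 >= c * max(lambda_1 over its scan line).

One weight vector is computed per pixel and shared across subarrays, which
is how the subarray-sum output definitions read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .rf_sim import ChannelData, ProbeGeometry

DEFAULT_L = 32
DEFAULT_ALPHA = 0.4
DEFAULT_C = 0.15
DEFAULT_DYNAMIC_RANGE = 60.0


def default_delta(L: int) -> float:
    """Default diagonal-loading fraction: one tenth of the 1/L bound."""
    return 1.0 / (10.0 * L)


@dataclass
class DelayedArraySignal:
    """Per-pixel vector of delayed element samples."""

    x_d: np.ndarray
    out_of_window: bool = False

    @property
    def M(self) -> int:
        return len(self.x_d)


@dataclass
class CovarianceEstimate:
    """Loaded subarray covariance with (optionally) its eigenstructure."""

    R: np.ndarray
    L: int
    epsilon: float = 0.0
    eigvals: np.ndarray | None = None  # descending
    eigvecs: np.ndarray | None = None  # columns match eigvals
    N: int | None = None               # signal-subspace dimension


@dataclass
class BeamformedImage:
    """Per-pixel beamformer outputs on a (lines x depths) grid."""

    pixels: dict
    lambda_max: np.ndarray | None = None
    detect_mask: np.ndarray | None = None
    envelope: np.ndarray | None = None
    display: np.ndarray | None = None
    line_x: np.ndarray | None = None
    depths: np.ndarray | None = None
    dynamic_range: float = DEFAULT_DYNAMIC_RANGE
    stages: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# delays


def delay_table(geometry: ProbeGeometry, line_x: float, depths: np.ndarray) -> np.ndarray:
    """Two-way delays in samples, shape (n_depths, n_elements)."""
    xe = geometry.element_x
    z = np.asarray(depths, dtype=float)[:, None]
    tau = (z + np.hypot(line_x - xe[None, :], z)) / geometry.c0
    return tau * geometry.fs


def gather_line(data: ChannelData, line_x: float, depths: np.ndarray) -> np.ndarray:
    """Delayed element samples for every depth of one scan line.

    Linear interpolation between samples; times beyond the recorded window
    contribute zeros.  Returns (n_depths, M).
    """
    rf = np.asarray(data.rf, dtype=float)
    n = rf.shape[0]
    pos = delay_table(data.geometry, line_x, depths)
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    valid0 = (i0 >= 0) & (i0 <= n - 1)
    valid1 = (i0 + 1 >= 0) & (i0 + 1 <= n - 1)
    i0c = np.clip(i0, 0, n - 1)
    i1c = np.clip(i0 + 1, 0, n - 1)
    cols = np.arange(rf.shape[1])[None, :]
    s0 = rf[i0c, cols]
    s1 = rf[i1c, cols]
    return np.where(valid0, s0 * (1 - frac), 0.0) + np.where(valid1, s1 * frac, 0.0)


def delay_and_gather(data: ChannelData, pixel: tuple[float, float]) -> DelayedArraySignal:
    """Delayed element vector for a single (line_x, depth) pixel in metres."""
    line_x, depth = pixel
    if depth <= 0:
        raise ValueError("pixel depth must be positive")
    pos = delay_table(data.geometry, line_x, np.array([depth]))[0]
    oow = bool(np.any(pos >= data.n_samples - 1) or np.any(pos < 0))
    x_d = gather_line(data, line_x, np.array([depth]))[0]
    return DelayedArraySignal(x_d=x_d, out_of_window=oow)


def default_depth_grid(data: ChannelData, decimation: int = 1) -> np.ndarray:
    """Depths z_k = c0 * k / (2 fs) for every `decimation`-th sample."""
    g = data.geometry
    k = np.arange(1, data.n_samples, decimation, dtype=float)
    return g.c0 * k / (2.0 * g.fs)


# ---------------------------------------------------------------------------
# covariance and eigenstructure


def subarray_covariance(x_d: np.ndarray | DelayedArraySignal, L: int) -> CovarianceEstimate:
    """Mean of the M - L + 1 sliding length-L subarray outer products."""
    v = x_d.x_d if isinstance(x_d, DelayedArraySignal) else np.asarray(x_d, dtype=float)
    M = len(v)
    if not 1 <= L <= M:
        raise ValueError(f"subarray length L={L} must satisfy 1 <= L <= M={M}")
    sub = np.lib.stride_tricks.sliding_window_view(v, L)  # (M-L+1, L)
    R = sub.T @ sub / (M - L + 1)
    return CovarianceEstimate(R=R, L=L)


def diagonal_load(R: np.ndarray | CovarianceEstimate, delta: float | None = None) -> CovarianceEstimate:
    """R~ = R + epsilon I with epsilon = delta * trace(R), 0 < delta <= 1/L."""
    est = R if isinstance(R, CovarianceEstimate) else None
    Rm = est.R if est is not None else np.asarray(R, dtype=float)
    L = Rm.shape[0]
    if delta is None:
        delta = default_delta(L)
    if not 0 < delta <= 1.0 / L:
        raise ValueError(f"delta must lie in (0, 1/L] = (0, {1.0 / L:.4g}]")
    eps = delta * float(np.trace(Rm))
    return CovarianceEstimate(R=Rm + eps * np.eye(L), L=L, epsilon=eps)


def eigendecompose(R: np.ndarray | CovarianceEstimate, alpha: float = DEFAULT_ALPHA) -> CovarianceEstimate:
    """Descending eigendecomposition with alpha-rule signal subspace.

    The signal subspace keeps every eigenvector whose eigenvalue is at least
    `alpha * lambda_1`; its dimension N is always >= 1.
    """
    est = R if isinstance(R, CovarianceEstimate) else None
    Rm = est.R if est is not None else np.asarray(R, dtype=float)
    if not np.allclose(Rm, Rm.conj().T, atol=1e-10 * max(1.0, np.abs(Rm).max())):
        raise ValueError("covariance matrix must be Hermitian")
    vals, vecs = np.linalg.eigh(Rm)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    N = int(np.sum(vals >= alpha * vals[0])) if vals[0] > 0 else len(vals)
    N = max(N, 1)
    return CovarianceEstimate(
        R=Rm,
        L=Rm.shape[0],
        epsilon=est.epsilon if est is not None else 0.0,
        eigvals=vals,
        eigvecs=vecs,
        N=N,
    )


# ---------------------------------------------------------------------------
# single-pixel beamformers (reference implementations)


def das(x_d: np.ndarray | DelayedArraySignal) -> float:
    v = x_d.x_d if isinstance(x_d, DelayedArraySignal) else np.asarray(x_d, dtype=float)
    return float(np.mean(v))


def _mv_weight(R_loaded: np.ndarray, d: np.ndarray) -> np.ndarray:
    y = np.linalg.solve(R_loaded, d)
    denom = d @ y
    if denom == 0:
        raise np.linalg.LinAlgError("degenerate steering denominator")
    return y / denom


def _subarray_mean(v: np.ndarray, L: int) -> np.ndarray:
    sub = np.lib.stride_tricks.sliding_window_view(v, L)
    return sub.mean(axis=0)


def mv(x_d: np.ndarray | DelayedArraySignal, R_loaded: CovarianceEstimate | np.ndarray,
       d: np.ndarray | None = None) -> float:
    """Minimum-variance output: shared weight, subarray-summed."""
    v = x_d.x_d if isinstance(x_d, DelayedArraySignal) else np.asarray(x_d, dtype=float)
    Rm = R_loaded.R if isinstance(R_loaded, CovarianceEstimate) else np.asarray(R_loaded)
    L = Rm.shape[0]
    d = np.ones(L) if d is None else np.asarray(d, dtype=float)
    if np.trace(Rm) == 0:
        w = d / L  # silent pixel: fall back to uniform (DAS) weights
    else:
        try:
            w = _mv_weight(Rm, d)
        except np.linalg.LinAlgError:
            import warnings

            warnings.warn("singular loaded covariance; falling back to DAS weights", stacklevel=2)
            w = d / L
    return float(w @ _subarray_mean(v, L))


def esbmv(x_d: np.ndarray | DelayedArraySignal, R_loaded, d: np.ndarray | None = None,
          alpha: float = DEFAULT_ALPHA) -> float:
    """Eigenspace MV: the MV weight projected onto the signal subspace."""
    v = x_d.x_d if isinstance(x_d, DelayedArraySignal) else np.asarray(x_d, dtype=float)
    est = R_loaded if isinstance(R_loaded, CovarianceEstimate) else CovarianceEstimate(
        R=np.asarray(R_loaded, dtype=float), L=np.asarray(R_loaded).shape[0]
    )
    if est.eigvecs is None:
        est = eigendecompose(est, alpha)
    L = est.L
    d = np.ones(L) if d is None else np.asarray(d, dtype=float)
    if np.trace(est.R) == 0:
        w = d / L
    else:
        w = _mv_weight(est.R, d)
        Us = est.eigvecs[:, : est.N]
        w = Us @ (Us.T @ w)
    return float(w @ _subarray_mean(v, L))


# ---------------------------------------------------------------------------
# whole-image engines (vectorised over depths)


def _line_covariances(X: np.ndarray, L: int, delta: float):
    """Loaded covariances for all depths of one line. X: (nz, M)."""
    nz, M = X.shape
    P = M - L + 1
    sub = np.lib.stride_tricks.sliding_window_view(X, L, axis=1)  # (nz, P, L)
    R = np.einsum("npl,npk->nlk", sub, sub) / P
    tr = np.trace(R, axis1=1, axis2=2)
    Rl = R + (delta * tr)[:, None, None] * np.eye(L)
    xm = sub.mean(axis=1)  # (nz, L) subarray-mean vectors
    return Rl, tr, xm


def _line_mv_esbmv(X: np.ndarray, L: int, delta: float, alpha: float):
    """MV and ESBMV outputs plus lambda_1 for all depths of one line."""
    nz, M = X.shape
    Rl, tr, xm = _line_covariances(X, L, delta)
    ones = np.ones(L)
    silent = tr <= 0
    Rl_safe = Rl.copy()
    Rl_safe[silent] = np.eye(L)
    y = np.linalg.solve(Rl_safe, np.broadcast_to(ones[:, None], (nz, L, 1)).copy())[:, :, 0]
    denom = y.sum(axis=1)
    w = y / denom[:, None]
    w[silent] = 1.0 / L
    out_mv = np.einsum("nl,nl->n", w, xm)

    vals, vecs = np.linalg.eigh(Rl_safe)      # ascending
    lam1 = vals[:, -1]
    keep = vals >= alpha * lam1[:, None]      # signal subspace (alpha rule)
    coef = np.einsum("nlk,nl->nk", vecs, w)   # eigvec coefficients of w
    w_es = np.einsum("nlk,nk->nl", vecs, coef * keep)
    w_es[silent] = 1.0 / L
    out_es = np.einsum("nl,nl->n", w_es, xm)
    lam1 = np.where(silent, 0.0, lam1)
    return out_mv, out_es, lam1


def beamform_image(
    data: ChannelData,
    method: str = "esbmv",
    L: int = DEFAULT_L,
    delta: float | None = None,
    alpha: float = DEFAULT_ALPHA,
    line_x: np.ndarray | None = None,
    depths: np.ndarray | None = None,
    depth_decimation: int = 1,
) -> BeamformedImage:
    """Beamform a whole frame with one of {das, mv, esbmv}.

    Returns pixel values (lines x depths) and, for the adaptive methods,
    the per-pixel largest eigenvalue map.
    """
    if method not in ("das", "mv", "esbmv"):
        raise ValueError("method must be das, mv or esbmv")
    g = data.geometry
    if delta is None:
        delta = default_delta(L)
    if not 0 < delta <= 1.0 / L:
        raise ValueError(f"delta must lie in (0, 1/L]")
    line_x = g.element_x if line_x is None else np.asarray(line_x, dtype=float)
    depths = default_depth_grid(data, depth_decimation) if depths is None else np.asarray(depths)

    n_lines, nz = len(line_x), len(depths)
    out = np.zeros((n_lines, nz))
    lam = np.zeros((n_lines, nz))
    for i, lx in enumerate(line_x):
        X = gather_line(data, lx, depths)
        if method == "das":
            out[i] = X.mean(axis=1)
        else:
            out_mv, out_es, lam1 = _line_mv_esbmv(X, L, delta, alpha)
            out[i] = out_mv if method == "mv" else out_es
            lam[i] = lam1
    return BeamformedImage(
        pixels={method: out},
        lambda_max=None if method == "das" else lam,
        line_x=line_x,
        depths=depths,
    )


def max_eigenvalue_map(
    data: ChannelData,
    L: int = DEFAULT_L,
    delta: float | None = None,
    line_x: np.ndarray | None = None,
    depths: np.ndarray | None = None,
    depth_decimation: int = 1,
) -> np.ndarray:
    """Per-pixel largest eigenvalue of the loaded subarray covariance."""
    img = beamform_image(
        data, "mv", L=L, delta=delta, line_x=line_x, depths=depths,
        depth_decimation=depth_decimation,
    )
    return img.lambda_max


def threshold_detect(lambda_max: np.ndarray, c: float = DEFAULT_C) -> np.ndarray:
    """Per-scan-line maximum-eigenvalue threshold.

    A pixel is flagged bubble when lambda_1 >= c * (line maximum); a line
    that is identically zero yields no detections.
    """
    if not 0 < c < 1:
        raise ValueError("threshold fraction c must lie in (0, 1)")
    lam = np.asarray(lambda_max, dtype=float)
    line_max = lam.max(axis=1, keepdims=True)
    mask = lam >= c * line_max
    mask[line_max[:, 0] <= 0] = False
    return mask


# ---------------------------------------------------------------------------
# envelope and display


def envelope_detect(pixels: np.ndarray) -> np.ndarray:
    """Analytic-signal magnitude along the depth axis of each line."""
    return np.abs(hilbert(pixels, axis=1))


def log_compress(envelope: np.ndarray, dynamic_range: float = DEFAULT_DYNAMIC_RANGE) -> np.ndarray:
    """20 log10(envelope / max), clipped to [-dynamic_range, 0] dB."""
    peak = envelope.max()
    if peak <= 0:
        return np.full_like(envelope, -dynamic_range)
    db = 20.0 * np.log10(np.maximum(envelope, peak * 10 ** (-dynamic_range / 20.0 - 2)) / peak)
    return np.clip(db, -dynamic_range, 0.0)
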