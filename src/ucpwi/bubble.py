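"""Shelled-microbubble radial dynamics and the bubble-matched mother wavelet.

A SonoVue-like microbubble driven by a short ultrasound pulse oscillates
nonlinearly; the scattered pressure it radiates carries harmonic content that
tissue echoes lack.  This module solves the Doinikov shell model for the
radial trajectory R(t), evaluates the far-field scattered pressure, and turns
that pressure waveform into a compactly supported, zero-mean, unit-energy
mother wavelet.  Correlating raw RF against this wavelet acts as a matched
filter for bubble echoes (see :mod:`ucpwi.bawt`).

The shell model is a Rayleigh–Plesset-type second-order ODE

    rho_l (R R'' + 3/2 R'^2) = (P0 + 2 sigma(R0)/R0) (R0/R)^{3 gamma}
                               - 2 sigma(R0)/R - 4 chi (1/R0 - 1/R)
                               - P0 - P_drive(t) - 4 eta_l R'/R
                               - 4 (k0 / (1 + alpha_t |R'/R|) + k1 R'/R) R'/R^2

with initial condition R(0) = R0, R'(0) = 0.  The k0/k1 terms model the
nonlinear shell viscosity responsible for the "compression-only" behaviour
of phospholipid-shelled agents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp


class BubbleCollapseError(RuntimeError):
    """Raised when the integrated radius reaches zero (non-physical collapse)."""


class DegenerateWaveletError(ValueError):
    """Raised when the scattered pressure is identically zero."""


@dataclass(frozen=True)
class BubbleParams:
    """Physical constants of the shell model (SI units).

    Defaults are the SonoVue-calibrated values used throughout: liquid density
    1000 kg/m^3, ambient pressure 101 kPa, polytropic exponent 1.07, rest
    radius 1.7 um, surface tension 0.072 N/m, shell elasticity 0.25 N/m,
    liquid viscosity 2 mPa s, shell viscosity components k0 = 4e-8 kg and
    k1 = 7e-15 kg/s with characteristic time 4 us.
    """

    rho_l: float = 1000.0
    P0: float = 101_000.0
    gamma: float = 1.07
    R0: float = 1.7e-6
    sigma_R0: float = 0.072
    chi: float = 0.25
    eta_l: float = 0.002
    k0: float = 4e-8
    k1: float = 7e-15
    alpha_t: float = 4e-6

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"BubbleParams.{name} must be strictly positive")


@dataclass(frozen=True)
class DrivePulse:
    """Transmit pulse: an `n_cycles`-cycle sinusoid at `f0`.

    `envelope` is "hann" (default) or "rect".  The Hann taper models the
    band-limited acoustic pulse a real transducer radiates when excited by a
    hard-gated two-cycle sine; "rect" is the raw gated excitation.  The
    default 58 kPa peak sits just below the shell model's runaway-collapse
    threshold (about 60 kPa for a two-cycle 4 MHz drive), maximising the
    second-harmonic content of the bubble echo while keeping the mechanical
    index MI = peak_pressure[MPa] / sqrt(f0[MHz]) = 0.029, well under the
    0.1 bubble-destruction limit; a warning is emitted if MI >= 0.1.
    """

    f0: float = 4e6
    n_cycles: int = 2
    peak_pressure: float = 58e3
    fs: float = 25e6
    envelope: str = "hann"

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.fs < 4 * self.f0:
            raise ValueError("fs must be at least 4*f0")
        if self.peak_pressure < 0:
            raise ValueError("peak_pressure must be non-negative")
        if self.envelope not in ("rect", "hann"):
            raise ValueError("envelope must be 'rect' or 'hann'")
        if self.mechanical_index >= 0.1:
            warnings.warn(
                f"mechanical index {self.mechanical_index:.3f} >= 0.1; "
                "microbubbles may be destroyed",
                stacklevel=2,
            )

    @property
    def duration(self) -> float:
        """Pulse length in seconds."""
        return self.n_cycles / self.f0

    @property
    def mechanical_index(self) -> float:
        return (self.peak_pressure / 1e6) / np.sqrt(self.f0 / 1e6)

    def pressure(self, t):
        """Drive pressure P_drive(t) in Pa; zero outside [0, duration]."""
        t = np.asarray(t, dtype=float)
        gate = (t >= 0.0) & (t <= self.duration)
        p = self.peak_pressure * np.sin(2 * np.pi * self.f0 * t)
        if self.envelope == "hann":
            p = p * np.sin(np.pi * t / self.duration) ** 2
        return np.where(gate, p, 0.0)

    def waveform(self, fs: float | None = None):
        """Sampled pulse at rate `fs` (defaults to self.fs)."""
        fs = self.fs if fs is None else fs
        n = int(np.ceil(self.duration * fs)) + 1
        return self.pressure(np.arange(n) / fs)


@dataclass
class RadialTrajectory:
    """Solved radial dynamics: R(t) and its first two time derivatives."""

    t: np.ndarray
    R: np.ndarray
    Rdot: np.ndarray
    Rddot: np.ndarray

    @property
    def fs(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])


@dataclass
class BubbleWavelet:
    """Mother wavelet sampled at `fs`, zero-mean and unit-energy.

    `f_center` is the frequency of the spectral peak of `psi`.
    """

    psi: np.ndarray
    fs: float
    f_center: float
    norm: str = "l2"

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    def energy(self) -> float:
        return float(np.sum(self.psi**2) * self.dt)


def _rhs_acceleration(params: BubbleParams, drive: DrivePulse, t, R, Rdot):
    """R'' from the shell model, vectorised over samples."""
    p = params
    ratio = Rdot / R
    p_gas = (p.P0 + 2 * p.sigma_R0 / p.R0) * (p.R0 / R) ** (3 * p.gamma)
    shell_visc = 4 * (p.k0 / (1 + p.alpha_t * np.abs(ratio)) + p.k1 * ratio) * Rdot / R**2
    rhs = (
        p_gas
        - 2 * p.sigma_R0 / R
        - 4 * p.chi * (1 / p.R0 - 1 / R)
        - p.P0
        - drive.pressure(t)
        - 4 * p.eta_l * ratio
        - shell_visc
    )
    return (rhs / p.rho_l - 1.5 * Rdot**2) / R


def solve_bubble_dynamics(
    params: BubbleParams,
    drive: DrivePulse,
    t_span: tuple[float, float] | None = None,
    fs: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    max_step: float = 1e-9,
) -> RadialTrajectory:
    """Integrate the shell model with an adaptive Runge–Kutta scheme.

    Parameters
    ----------
    t_span
        Integration interval in seconds.  Defaults to the drive pulse plus a
        ring-down tail of ten drive periods.
    fs
        Output sampling rate (defaults to ``drive.fs``).  The adaptive solver
        chooses its own internal steps; ``fs`` only sets the output grid.

    The second derivative is recovered by evaluating the ODE right-hand side
    on the solution, not by finite differencing.
    """
    if t_span is None:
        t_span = (0.0, drive.duration + 10.0 / drive.f0)
    fs = drive.fs if fs is None else fs
    t_eval = np.arange(t_span[0], t_span[1], 1.0 / fs)

    # Guard against adaptive trial steps probing R <= 0; the terminal event
    # below decides whether the *solution* actually collapses.
    R_floor = 1e-3 * params.R0

    def rhs(t, y):
        R, Rdot = y
        return [Rdot, _rhs_acceleration(params, drive, t, max(R, R_floor), Rdot)]

    def collapse(t, y):
        return y[0] - 10 * R_floor

    collapse.terminal = True
    collapse.direction = -1

    sol = solve_ivp(
        rhs,
        t_span,
        [params.R0, 0.0],
        method="RK45",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        max_step=max_step,
        events=collapse,
        dense_output=False,
    )
    if sol.status == 1:
        raise BubbleCollapseError(
            f"bubble radius reached zero at t = {sol.t_events[0][0]:.3e} s; "
            "drive amplitude is non-physical for this shell model"
        )
    if not sol.success:
        # The shell-viscosity bracket k0/(1+alpha_t|R'/R|) + k1 R'/R changes
        # sign at large compression shear, so above ~60 kPa (two-cycle 4 MHz
        # drive, default constants) the compression phase runs away and the
        # step size underflows between output samples.  Report that as a
        # collapse, not a solver bug.
        if "step size" in sol.message.lower() or (
            len(sol.y[1]) and np.abs(sol.y[1]).max() > 1e3
        ):
            raise BubbleCollapseError(
                f"runaway collapse near t = {sol.t[-1] if len(sol.t) else t_span[0]:.3e} s; "
                "reduce the drive amplitude (the shell model is anti-damped at "
                "high compression shear)"
            )
        raise RuntimeError(f"ODE solver did not converge: {sol.message}")
    R, Rdot = sol.y
    if np.any(R <= 0):
        raise BubbleCollapseError("non-physical collapse: R <= 0 in solution")
    Rddot = _rhs_acceleration(params, drive, sol.t, R, Rdot)
    return RadialTrajectory(t=sol.t, R=R, Rdot=Rdot, Rddot=Rddot)


def scattered_pressure(traj: RadialTrajectory, d: float, rho_l: float = 1000.0) -> np.ndarray:
    """Far-field scattered pressure P(d) = rho_l (R/d)(2 R'^2 + R R'').

    `d` is the bubble-to-transducer distance in metres; the waveform scales
    exactly as 1/d.
    """
    if d <= 0:
        raise ValueError("distance d must be positive")
    return rho_l * (traj.R / d) * (2.0 * traj.Rdot**2 + traj.R * traj.Rddot)


def spectral_peak(x: np.ndarray, fs: float, nfft: int | None = None) -> float:
    """Frequency of the power-spectrum maximum (zero-padded FFT)."""
    n = len(x)
    if nfft is None:
        nfft = max(4096, 8 * n)
    spec = np.abs(np.fft.rfft(x, nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    return float(freqs[int(np.argmax(spec))])


def _energy_support(p: np.ndarray, keep: float = 0.999) -> tuple[int, int]:
    """Smallest symmetric-tail window holding `keep` of the energy."""
    e = np.cumsum(p**2)
    total = e[-1]
    if total == 0:
        raise DegenerateWaveletError("degenerate wavelet: scattered pressure is zero")
    tail = (1.0 - keep) / 2.0
    i0 = int(np.searchsorted(e, tail * total))
    i1 = int(np.searchsorted(e, (1.0 - tail) * total)) + 1
    return i0, min(i1, len(p))


def build_mother_wavelet(
    params: BubbleParams | None = None,
    drive: DrivePulse | None = None,
    fs: float | None = None,
) -> BubbleWavelet:
    """Construct the bubble-matched mother wavelet.

    Solves the shell model under `drive`, evaluates the scattered pressure,
    trims it to the window holding 99.9 % of its energy, removes the mean
    (admissibility), and normalises to unit energy (sum psi^2 * dt = 1).
    """
    params = BubbleParams() if params is None else params
    drive = DrivePulse() if drive is None else drive
    fs = drive.fs if fs is None else fs
    if drive.peak_pressure == 0:
        raise DegenerateWaveletError("degenerate wavelet: zero-amplitude drive")
    traj = solve_bubble_dynamics(params, drive, fs=fs)
    p = scattered_pressure(traj, d=1.0, rho_l=params.rho_l)
    i0, i1 = _energy_support(p)
    psi = p[i0:i1].astype(float)
    psi = psi - psi.mean()
    dt = 1.0 / fs
    energy = np.sum(psi**2) * dt
    if energy == 0:
        raise DegenerateWaveletError("degenerate wavelet: zero energy after trimming")
    psi = psi / np.sqrt(energy)
    return BubbleWavelet(psi=psi, fs=fs, f_center=spectral_peak(psi, fs))


def optimal_scale(wavelet: BubbleWavelet, f_transmit: float) -> float:
    """Dilation factor placing the wavelet's passband at the second harmonic.

    The dilated wavelet psi(t/s) has spectral peak f_center / s; choosing
    s = f_center / (2 f_transmit) puts that peak at 2 f_transmit, where the
    microbubble second harmonic lives.
    """
    if f_transmit <= 0:
        raise ValueError("f_transmit must be positive")
    return wavelet.f_center / (2.0 * f_transmit)


def dilate_wavelet(wavelet: BubbleWavelet, scale: float) -> BubbleWavelet:
    """Resample psi(t) to psi(t/s)/sqrt(s) on the same sampling grid.

    The 1/sqrt(s) factor keeps the dilated wavelet at (approximately) unit
    energy, the L2 CWT convention.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    n = len(wavelet.psi)
    n_new = int(round(n * scale))
    if n_new < 4:
        raise ValueError(f"scale {scale} dilates the wavelet below 4 samples")
    t_old = np.arange(n) / wavelet.fs
    t_new = np.arange(n_new) / wavelet.fs
    psi_s = np.interp(t_new / scale, t_old, wavelet.psi) / np.sqrt(scale)
    return BubbleWavelet(
        psi=psi_s,
        fs=wavelet.fs,
        f_center=spectral_peak(psi_s, wavelet.fs),
        norm=wavelet.norm,
    )
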