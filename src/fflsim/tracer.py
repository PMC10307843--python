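"""Nanoparticle signal formation and harmonic (sideband) analysis.

Signal model: the equilibrium magnetization of a superparamagnetic tracer
ensemble follows the Langevin function ``L(xi) = coth(xi) - 1/xi`` of the
local applied field (static model -- Neel/Brownian relaxation is out of
scope).  As the field-free line transits a tracer voxel its magnetization
flips, and the induced receive voltage is ``s = -dM/dt``.  Receive
sensitivity is a homogeneous scalar over the FOV; gradiometric suppression of
the drive feedthrough is emulated by a frequency-domain notch
(:func:`filter_fundamental`).

Because the drive frequencies are commensurate with the acquisition window,
the signal spectrum is supported on bins ``n*f3 + k*f1``: harmonics of the
deflection frequency with sidebands spaced at the traveling-wave frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .scanner import ScannerConfig, Trajectory, wave_field

__all__ = [
    "TracerModel",
    "NoiseModel",
    "SignalFrame",
    "HarmonicComponent",
    "Spectrum",
    "langevin",
    "simulate_frame",
    "harmonic_freq",
    "spectrum_of",
    "pick_harmonics",
    "filter_fundamental",
    "sideband_energy_fraction",
]


@dataclass
class TracerModel:
    """Langevin tracer parameters.

    ``beta`` (1/T) maps the applied field B to the Langevin argument
    ``xi = beta * B``.  The default is calibrated so the FFL must approach
    within ~2 mm of a voxel at a 0.25 T/m gradient before its magnetization
    leaves saturation, consistent with a ~5 mm scanner resolution; it is a
    free parameter, not a measured Perimag property.  ``m_sat`` is the
    saturation signal moment per mol Fe (arbitrary receive units).
    """

    beta: float = 1.0e4          # 1/T
    m_sat: float = 1.0           # signal units per mol Fe
    name: str = "Perimag"
    c_stock: float = 8.5         # mg Fe / ml
    molar_mass_fe: float = 55.845  # g/mol

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.m_sat <= 0 or self.c_stock <= 0:
            raise ValueError("beta, m_sat and c_stock must be positive")


@dataclass
class NoiseModel:
    """White receive noise plus optional narrowband interference lines."""

    sigma_white: float = 0.0
    interference_lines: list = field(default_factory=list)  # (freq Hz, amplitude)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_white < 0:
            raise ValueError("sigma_white must be non-negative")

    def sample(self, n: int, fs: float, t0: float = 0.0) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        noise = rng.normal(0.0, self.sigma_white, size=n) if self.sigma_white else np.zeros(n)
        if self.interference_lines:
            t = t0 + np.arange(n) / fs
            for freq, amp in self.interference_lines:
                noise = noise + amp * np.sin(2 * math.pi * freq * t)
        return noise


@dataclass
class SignalFrame:
    """One induced-voltage record (one acquisition window)."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def copy(self) -> "SignalFrame":
        return SignalFrame(self.samples.copy(), self.fs, self.t0)


@dataclass
class HarmonicComponent:
    n: int
    k: int
    frequency: float
    amplitude: complex
    snr: float


@dataclass
class Spectrum:
    """Sideband decomposition of a frame: components at ``n*f3 + k*f1``."""

    components: list
    noise_floor: float

    def amplitude(self, n: int, k: int) -> complex:
        for c in self.components:
            if c.n == n and c.k == k:
                return c.amplitude
        raise KeyError(f"no component (n={n}, k={k})")


def langevin(xi):
    """Langevin function ``L(xi) = coth(xi) - 1/xi``.

    Odd, strictly increasing, bounded by +-1; the removable singularity at 0
    evaluates to 0 (series ``xi/3 - xi^3/45 + ...`` used for small arguments).
    """
    xi = np.asarray(xi, dtype=float)
    if not np.all(np.isfinite(xi)):
        raise ValueError("langevin argument must be finite")
    small = np.abs(xi) < 1e-4
    safe = np.where(small, 1.0, xi)
    out = np.where(small, xi / 3.0 - xi ** 3 / 45.0,
                   1.0 / np.tanh(safe) - 1.0 / safe)
    return out if out.ndim else float(out)


def simulate_frame(phantom, traj: Trajectory, tracer: TracerModel,
                   noise: NoiseModel | None = None,
                   _chunk: int = 4096) -> SignalFrame:
    """Simulate one induced-voltage frame for a phantom on a trajectory.

    The local field is the smooth traveling-wave model
    (:func:`fflsim.scanner.wave_field`); each voxel's magnetization is the
    Langevin fraction of the field magnitude projected on the receive axis
    (z), ``M_z = c m_sat L(beta |B|) B_z/|B|``, and the induced voltage is
    ``s = -dM_z/dt`` by central finite differences along the sample axis,
    with homogeneous receive sensitivity over the FOV.  A zero phantom yields
    an all-zero (noise-free) signal; the map is linear in the phantom.

    The static background field ``config.B_background`` is added to the FFL
    field.  It matters: at the stock frequency ratio (f3/f1 = 124/3) the
    ideal FFL field is exactly antiperiodic over half the acquisition window,
    so with a perfectly odd magnetization response every even-index band --
    including the 5*f3 + 2*f1 detection band -- would vanish identically.
    The environmental offset field breaks that polarity symmetry, as it does
    in hardware.
    """
    config = traj.config
    if len(traj) > 1:
        dt = float(traj.t[1] - traj.t[0])
        if abs(dt * config.fs - 1.0) > 1e-9:
            raise ValueError(
                f"phantom/trajectory sampling mismatch: trajectory step "
                f"{dt:.3e} s vs 1/fs = {1.0 / config.fs:.3e} s")
    xs, zs, amounts = phantom.nonzero_points()
    n = len(traj)
    M = np.zeros(n)
    if xs.size:
        weights = amounts * tracer.m_sat
        for start in range(0, n, _chunk):
            sl = slice(start, min(start + _chunk, n))
            Bx, Bz = wave_field(config, xs, zs, traj.t[sl])
            Bz = Bz + config.B_background
            Bmag = np.hypot(Bx, Bz)
            xi = tracer.beta * Bmag
            # receive-axis (z) projection: M_z = L(xi) Bz / |B| = [L(xi)/xi] beta Bz
            small = xi < 1e-4
            ratio = np.where(small, 1.0 / 3.0 - xi ** 2 / 45.0,
                             langevin(np.where(small, 1.0, xi)) / np.where(small, 1.0, xi))
            M[sl] = (ratio * tracer.beta * Bz) @ weights
    s = -np.gradient(M, 1.0 / config.fs)
    if noise is not None:
        s = s + noise.sample(n, config.fs, t0=float(traj.t[0]))
    return SignalFrame(samples=s, fs=config.fs, t0=float(traj.t[0]))


def harmonic_freq(config: ScannerConfig, n: int, k: int) -> float:
    """Frequency (Hz) of sideband ``k`` of deflection harmonic ``n``: n*f3 + k*f1."""
    if n < 1:
        raise ValueError("harmonic order n must be >= 1")
    return n * config.f3 + k * config.f1


def _bin_of(freq: float, df: float, n_bins: int):
    b = freq / df
    bi = int(round(b))
    return bi if (abs(b - bi) < 1e-6 and 0 <= bi < n_bins) else None


def _sideband_bins(config: ScannerConfig, df: float, n_bins: int,
                   n_max: int, k_max: int) -> set:
    bins = set()
    for n in range(1, n_max + 1):
        for k in range(-k_max, k_max + 1):
            bi = _bin_of(n * config.f3 + k * config.f1, df, n_bins)
            if bi is not None:
                bins.add(bi)
    return bins


def _check_commensurate(frame: SignalFrame, config: ScannerConfig) -> float:
    df = 1.0 / frame.duration
    for f in (config.f1, config.f3):
        offset = f / df - round(f / df)
        if abs(offset) > 1e-6:
            raise ValueError(
                f"frame duration not commensurate with {f} Hz: sideband falls "
                f"{offset:+.4f} bins off an FFT bin (bin width {df:.4g} Hz)"
            )
    return df


def spectrum_of(frame: SignalFrame, config: ScannerConfig,
                n_max: int = 8, k_max: int = 12,
                n_noise_bins: int = 20) -> Spectrum:
    """Read the complex amplitude of each ``n*f3 + k*f1`` band off the FFT.

    Per-band SNR is amplitude divided by a local noise floor: the median
    magnitude of the ``n_noise_bins`` nearest bins that belong to no sideband.
    Requires the frame duration to be commensurate with f1 (bins exact).
    """
    df = _check_commensurate(frame, config)
    X = np.fft.rfft(frame.samples)
    amp = 2.0 * np.abs(X) / frame.samples.size
    n_bins = amp.size
    lattice = _sideband_bins(config, df, n_bins, max(n_max, config.n_harmonics),
                             max(k_max, 40))
    lattice.add(0)
    non_sideband = np.setdiff1d(np.arange(n_bins), np.fromiter(lattice, dtype=int))
    components = []
    for n in range(1, n_max + 1):
        for k in range(-k_max, k_max + 1):
            freq = n * config.f3 + k * config.f1
            bi = _bin_of(freq, df, n_bins)
            if bi is None or freq <= 0:
                continue
            near = non_sideband[np.argsort(np.abs(non_sideband - bi))[:n_noise_bins]]
            floor = float(np.median(amp[near])) if near.size else 0.0
            a = complex(2.0 * X[bi] / frame.samples.size)
            snr = float(np.abs(a) / floor) if floor > 0 else math.inf
            components.append(HarmonicComponent(n=n, k=k, frequency=freq,
                                                amplitude=a, snr=snr))
    global_floor = float(np.median(amp[non_sideband])) if non_sideband.size else 0.0
    return Spectrum(components=components, noise_floor=global_floor)


def pick_harmonics(spec: Spectrum, snr_min: float = 2.0) -> Spectrum:
    """Keep only components whose SNR reaches ``snr_min`` (default 2)."""
    kept = [c for c in spec.components if c.snr >= snr_min]
    return Spectrum(components=kept, noise_floor=spec.noise_floor)


def filter_fundamental(frame: SignalFrame, config: ScannerConfig,
                       guard_bins: int = 1) -> SignalFrame:
    """Notch the drive components (f1/f2, f3 fundamental) and DC.

    Emulates the gradiometric receive coil plus software filtering: the
    excitation feedthrough is removed in the frequency domain; all other bins
    are untouched.
    """
    df = _check_commensurate(frame, config)
    X = np.fft.rfft(frame.samples)
    n_bins = X.size
    X[0] = 0.0
    for f in {config.f1, config.f2, config.f3}:
        bi = _bin_of(f, df, n_bins)
        if bi is not None:
            lo = max(bi - guard_bins, 0)
            X[lo:bi + guard_bins + 1] = 0.0
    out = np.fft.irfft(X, n=frame.samples.size)
    return SignalFrame(samples=out, fs=frame.fs, t0=frame.t0)


def sideband_energy_fraction(frame: SignalFrame, config: ScannerConfig,
                             n_max: int = 20, k_max: int = 40) -> float:
    """Fraction of spectral energy on the ``n*f3 + k*f1`` lattice.

    Evaluated after removing DC; bins above ``n_max*f3 + k_max*f1`` are
    excluded from the denominator (out-of-band energy beyond the retained
    harmonic set is not part of the analysis window).
    """
    df = _check_commensurate(frame, config)
    X = np.fft.rfft(frame.samples)
    power = np.abs(X) ** 2
    power[0] = 0.0
    n_bins = power.size
    f_top = n_max * config.f3 + k_max * config.f1
    top = min(n_bins, int(round(f_top / df)) + 1)
    power = power[:top]
    lattice = _sideband_bins(config, df, top, n_max, k_max)
    total = power.sum()
    if total == 0:
        return 1.0
    in_band = sum(power[b] for b in lattice)
    return float(in_band / total)
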