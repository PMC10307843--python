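"""Scanner geometry, drive parameters, and the traveling field-free-line trajectory.

The scanner encodes a 2D projection (x-z plane) with a field-free line (FFL)
oriented along y.  Two saddle-coil pairs (CH1/CH2) driven at ``f1 = f2`` with a
90-degree phase shift generate a traveling wave whose zero crossings -- the
FFLs -- move along the symmetry axis z.  A solenoid pair (CH3) at ``f3 >> f1``
deflects the whole pattern sinusoidally in x, so the in-plane FFL position
traces a dense sinusoidal trajectory over the field of view (FOV).

The field model is an idealized analytic FFL: the field magnitude is zero on
the line and grows linearly with perpendicular in-plane distance, with slope
equal to the operating gradient.  Coil windings are not modelled.

Coordinate convention: FOV-centered Cartesian, x = deflection axis,
z = travel axis, y = FFL/projection axis.  Continuous coordinates in meters;
images are indexed row = z, column = x.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, fields, asdict

import numpy as np

__all__ = [
    "ScannerConfig",
    "FFLState",
    "Trajectory",
    "ffl_position",
    "field_at",
    "gradient_at_fraction",
    "make_sequence",
]

_COMMENSURATE_TOL = 1e-9


@dataclass
class ScannerConfig:
    """Drive and geometry parameters of the scanner.

    Parameters mirror the hardware operating point: drive frequencies
    ``f1 = f2`` (traveling wave, Hz) and ``f3`` (deflection, Hz), channel
    currents relative to full power (the gradient scales linearly with
    current), FOV extents, peak-to-peak drive amplitude, and the acquisition
    timing (50 ms window inside a 60 ms burst).
    """

    f1: float = 60.0
    f2: float = 60.0
    f3: float = 2480.0
    phase12: float = math.pi / 2
    gradient_full: float = 0.36      # T/m at full current
    I_ch12_full: float = 165.0       # A
    I_ch3_full: float = 110.0        # A
    I_ch12: float = 110.0            # operating current, A
    I_ch3: float = 75.0              # operating current, A
    fov_x: float = 0.11              # m
    fov_z: float = 0.12              # m
    ffl_spacing: float | None = None  # m; default fov_z (one FFL per half period)
    x_max: float | None = None        # m; default fov_x / 2
    B_pp: float = 0.070              # T, peak-to-peak drive amplitude
    T_acq: float = 0.050             # s, acquisition window
    dt_burst: float = 0.060          # s, burst duty cycle
    fs: float = 496_000.0            # S/s
    ramp_time: float = 0.010         # s, settle delay before acquisition
    n_harmonics: int = 25            # highest f3 harmonic retained in analysis
    B_background: float = 5e-5       # T, static background field (earth-scale)

    def __post_init__(self) -> None:
        if self.ffl_spacing is None:
            self.ffl_spacing = self.fov_z
        if self.x_max is None:
            self.x_max = self.fov_x / 2.0
        self.validate()

    def validate(self) -> None:
        if self.f1 != self.f2:
            raise ValueError(f"f1 must equal f2 (got f1={self.f1}, f2={self.f2})")
        if not self.f3 > self.f1:
            raise ValueError(f"f3 must exceed f1 (got f3={self.f3}, f1={self.f1})")
        for name in ("f1", "f3", "gradient_full", "I_ch12_full", "I_ch3_full",
                     "fov_x", "fov_z", "ffl_spacing", "B_pp", "T_acq",
                     "dt_burst", "fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.x_max > self.fov_x / 2 + 1e-12:
            raise ValueError("x_max cannot exceed fov_x/2")
        if self.fs <= 2 * self.n_harmonics * self.f3:
            raise ValueError(
                f"fs={self.fs} violates Nyquist for harmonic {self.n_harmonics}"
                f" of f3 ({2 * self.n_harmonics * self.f3} S/s required)"
            )

    # ------------------------------------------------------------------ derived
    @property
    def gradient(self) -> float:
        """Operating FFL gradient (T/m), linear in CH1/2 current."""
        return self.gradient_full * self.I_ch12 / self.I_ch12_full

    @property
    def n_samples(self) -> int:
        return int(round(self.T_acq * self.fs))

    @property
    def n_lines(self) -> int:
        """Number of complete 1/f3 lines in the acquisition window."""
        return int(round(self.T_acq * self.f3))

    def is_commensurate(self) -> bool:
        """True when the acquisition window holds whole periods of f1 and f3.

        Then the trajectory repeats exactly with period ``T_acq`` and every
        harmonic sideband lands on an FFT bin.
        """
        for f in (self.f1, self.f3):
            cycles = self.T_acq * f
            if abs(cycles - round(cycles)) > _COMMENSURATE_TOL * max(1.0, cycles):
                return False
        return True

    # ---------------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ScannerConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown scanner config keys: {sorted(unknown)}")
        return cls(**data)

    def fingerprint(self) -> str:
        """Stable hash of the configuration (used to tag derived artifacts)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class FFLState:
    """Instantaneous in-FOV FFL: in-plane position, gradient polarity, slope."""

    x: float
    z: float
    sign: int
    G: float
    t: float


@dataclass
class Trajectory:
    """Time-resolved FFL trajectory over one acquisition window.

    Arrays are sampled at ``config.fs``; ``line_index`` labels the 1/f3 period
    and ``pass_index`` the z-sweep (FFL polarity alternates between passes).
    """

    t: np.ndarray
    x: np.ndarray
    z: np.ndarray
    sign: np.ndarray
    line_index: np.ndarray
    pass_index: np.ndarray
    config: ScannerConfig
    repeating: bool = True

    def __len__(self) -> int:
        return self.t.size

    @property
    def fs(self) -> float:
        return self.config.fs

    def state(self, i: int) -> FFLState:
        return FFLState(
            x=float(self.x[i]), z=float(self.z[i]), sign=int(self.sign[i]),
            G=self.config.gradient, t=float(self.t[i]),
        )


# ---------------------------------------------------------------------- kinematics

def _ffl_arrays(config: ScannerConfig, t: np.ndarray):
    """Vectorized in-FOV FFL position/sign for absolute times ``t``."""
    t = np.asarray(t, dtype=float)
    x = config.x_max * np.sin(2 * math.pi * config.f3 * t)
    # traveling-wave phase: one FFL crosses the scan span per half period of f1
    passes = np.floor(2 * config.f1 * t).astype(np.int64)
    frac = 2 * config.f1 * t - passes
    z = (frac - 0.5) * config.ffl_spacing
    sign = np.where(passes % 2 == 0, 1, -1).astype(np.int8)
    return x, z, sign, passes


def ffl_position(config: ScannerConfig, t: float) -> FFLState:
    """In-FOV FFL state at time ``t``.

    ``x(t) = x_max sin(2 pi f3 t)``; z advances linearly with the traveling
    wave phase, restarting at the span edge each half period of f1 with
    alternating gradient polarity.
    """
    if not np.isfinite(t):
        raise ValueError("time must be finite")
    if t < 0:
        raise ValueError("time must be non-negative")
    x, z, sign, _ = _ffl_arrays(config, np.asarray([t]))
    return FFLState(x=float(x[0]), z=float(z[0]), sign=int(sign[0]),
                    G=config.gradient, t=float(t))


def signed_field(config: ScannerConfig, xq, zq, t):
    """Signed field magnitude (T) at points ``(xq, zq)`` for times ``t``.

    Broadcasts to shape ``(len(t), len(xq))``.  The field is the operating
    gradient times the in-plane distance to the *nearest* FFL, signed by that
    FFL's polarity; exactly zero on the line.
    """
    xq = np.atleast_1d(np.asarray(xq, dtype=float))
    zq = np.atleast_1d(np.asarray(zq, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    x_ffl, z_in, sign_in, _ = _ffl_arrays(config, t)
    dx = xq[None, :] - x_ffl[:, None]              # (T, P)
    G = config.gradient
    best = None
    best_sign = None
    # neighbouring zeros of the traveling wave, alternating polarity
    for j in range(-2, 3):
        zj = z_in + j * config.ffl_spacing
        sj = sign_in * (1 if j % 2 == 0 else -1)
        d2 = dx * dx + (zq[None, :] - zj[:, None]) ** 2
        if best is None:
            best, best_sign = d2, np.broadcast_to(sj[:, None], d2.shape).copy()
        else:
            closer = d2 < best
            best = np.where(closer, d2, best)
            best_sign = np.where(closer, sj[:, None], best_sign)
    return best_sign * G * np.sqrt(best)


def wave_field(config: ScannerConfig, xq, zq, t):
    """Smooth in-plane field components ``(Bx, Bz)`` of the traveling FFL.

    ``Bz`` is the traveling wave (zeros at the FFLs, slope = +-G, peak
    ``G * ffl_spacing / pi`` between them); ``Bx`` is the deflection-displaced
    transverse component ``G (x - x_ffl) cos(...)`` so that near every FFL the
    field is the quadrupole-like ``+-G (dx, dz)`` of the local polarity.
    Broadcasts to shape ``(len(t), len(xq))``.  Unlike the piecewise
    nearest-line magnitude of :func:`field_at`, these components are smooth
    everywhere, which is what the induced-signal simulation needs.
    """
    xq = np.atleast_1d(np.asarray(xq, dtype=float))
    zq = np.atleast_1d(np.asarray(zq, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    x_ffl, z_in, sign_in, _ = _ffl_arrays(config, t)
    # reference positive-polarity zero
    z0p = z_in + np.where(sign_in > 0, 0.0, config.ffl_spacing)
    k = math.pi / config.ffl_spacing
    G = config.gradient
    phase = k * (zq[None, :] - z0p[:, None])
    Bz = (G / k) * np.sin(phase)
    Bx = G * (xq[None, :] - x_ffl[:, None]) * np.cos(phase)
    return Bx, Bz


def field_at(config: ScannerConfig, r, t: float) -> float:
    """Signed field (T) at point ``r = (x, z)`` and time ``t``.

    Idealized FFL model: zero on the line, linear in perpendicular in-plane
    distance with slope equal to the operating gradient, sign from the polarity
    of the nearest FFL.
    """
    x, z = r
    half_x = config.fov_x  # bounding box 2x the FOV
    half_z = config.fov_z
    if abs(x) > half_x or abs(z) > half_z:
        raise ValueError(f"point {r} outside 2x FOV bounding box")
    return float(signed_field(config, [x], [z], [t])[0, 0])


def gradient_at_fraction(config: ScannerConfig, fraction: float) -> float:
    """FFL gradient (T/m) at a given fraction of full current (linear scaling)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    return config.gradient_full * fraction


# ---------------------------------------------------------------------- sequence

def make_sequence(config: ScannerConfig):
    """Build the acquisition trajectory and the three drive waveforms.

    The acquisition window of ``T_acq`` starts ``ramp_time`` after waveform
    start (transient-free field amplitude).  Returns ``(trajectory, waveforms)``
    where ``waveforms`` contains the CH1/CH2/CH3 current waveforms over the
    full burst, sampled at ``fs``, with a linear ramp envelope.
    """
    config.validate()
    n = config.n_samples
    # time origin = acquisition start; the ramp precedes it at negative times
    t = np.arange(n) / config.fs
    x, z, sign, passes = _ffl_arrays(config, t)
    line_index = np.floor(config.f3 * t * (1 - 1e-15)).astype(np.int64)
    pass_index = passes - passes[0]
    repeating = config.is_commensurate()

    n_total = int(round((config.ramp_time + config.T_acq) * config.fs))
    t_all = np.arange(n_total) / config.fs - config.ramp_time
    envelope = np.clip(1.0 + t_all / config.ramp_time, 0.0, 1.0)
    w = 2 * math.pi
    waveforms = {
        "t": t_all,
        "ch1": config.I_ch12 * envelope * np.sin(w * config.f1 * t_all),
        "ch2": config.I_ch12 * envelope * np.sin(w * config.f2 * t_all - config.phase12),
        "ch3": config.I_ch3 * envelope * np.sin(w * config.f3 * t_all),
    }
    traj = Trajectory(t=t, x=x, z=z, sign=sign, line_index=line_index,
                      pass_index=pass_index, config=config, repeating=repeating)
    return traj, waveforms
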