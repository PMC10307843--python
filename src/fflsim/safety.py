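"""Safety and operations budget: PNS, SAR, channel power, coil heating, cooling.

Peripheral nerve stimulation (magnetostimulation) is the dominant safety
limit for drive frequencies below ~42 kHz.  The fundamental law of
magnetostimulation gives the peak-to-peak field threshold as a function of
frequency,

    B_th,pp(f) = dB_min,pp * (1 + 1 / (2 tau_c f)),

where ``dB_min,pp`` is the asymptotic threshold and ``tau_c`` the nerve
chronaxie.  With the published leg parameters (47.5 mT, 295 us) the
threshold at the 2480 Hz deflection frequency evaluates to ~80 mT pp, just
above the 70 mT pp the hardware drives.

Tissue heating (SAR) scales with f^2 B^2 and is anchored at the published
operating point (2480 Hz, 35 mT -> 0.15 W/kg); the typical regulatory limit
is 4 W/kg.  The thermal chain is a lumped copper model: effective channel
power 1/2 R I^2, per-burst heating P dt / (m c), and convective cooling
alpha A dT / (m c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

from .scanner import ScannerConfig
from .phantoms import dose_limit

__all__ = [
    "PnsParams",
    "CoilSpec",
    "SafetyReport",
    "pns_threshold",
    "sar_scaled",
    "channel_power",
    "copper_mass",
    "heat_per_frame",
    "cooling_rate",
    "duty_cycle_plan",
    "safety_report",
    "default_coils",
]

SAR_REFERENCE = (2480.0, 35.0, 0.15)   # (f Hz, B mT, SAR W/kg) published anchor
SAR_LIMIT = 4.0                        # W/kg, typical regulatory limit
ALPHA_FREE = 10.0                      # W/(m^2 K), free convection
ALPHA_FORCED = 30.0                    # W/(m^2 K), forced air flow


@dataclass
class PnsParams:
    """Magnetostimulation parameters (leg, ~6 cm radius)."""

    delta_B_min_pp: float = 47.5   # mT, asymptotic peak-to-peak threshold
    tau_c: float = 295e-6          # s, chronaxie
    f: float = 2480.0              # Hz, drive frequency

    def __post_init__(self) -> None:
        if self.delta_B_min_pp <= 0 or self.tau_c <= 0:
            raise ValueError("PNS parameters must be positive")


@dataclass
class CoilSpec:
    """Lumped electrical/thermal description of one transmit coil channel."""

    name: str = "CH1/2"
    R: float = 0.5                         # Ohm
    I: float = 165.0                       # A, peak current
    l_wire: float = 90.0                   # m
    A_wire: float = math.pi * 1e-6         # m^2 (litz 400 x 0.1 mm -> pi mm^2)
    rho_cu: float = 8960.0                 # kg/m^3
    c_cu: float = 383.0                    # J/(kg K)
    A_surface: float = 0.168               # m^2
    alpha_free: float = ALPHA_FREE
    alpha_forced: float = ALPHA_FORCED

    def __post_init__(self) -> None:
        for name in ("R", "A_wire", "rho_cu", "c_cu", "A_surface"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.l_wire < 0:
            raise ValueError("l_wire must be non-negative")


def default_coils() -> list:
    """The two transmit channels at their published electrical parameters."""
    return [
        CoilSpec(name="CH1/2", R=0.5, I=165.0, l_wire=90.0, A_surface=0.168),
        CoilSpec(name="CH3", R=0.6, I=110.0, l_wire=105.0, A_surface=0.171),
    ]


def pns_threshold(p: PnsParams) -> float:
    """Peak-to-peak PNS field threshold (mT) at frequency ``p.f``.

    Strictly decreasing in f; tends to ``delta_B_min_pp`` as f -> infinity.
    """
    if p.f <= 0:
        raise ValueError("frequency must be positive")
    return p.delta_B_min_pp * (1.0 + 1.0 / (2.0 * p.tau_c * p.f))


def sar_scaled(f: float, B: float, ref=SAR_REFERENCE) -> float:
    """SAR (W/kg) scaled as f^2 B^2 from a reference operating point.

    ``B`` in mT.  Default reference: 0.15 W/kg at 2480 Hz and 35 mT.
    """
    f_ref, B_ref, sar_ref = ref
    if f < 0 or B < 0 or f_ref <= 0 or B_ref <= 0 or sar_ref <= 0:
        raise ValueError("frequencies, fields and reference SAR must be positive")
    return sar_ref * (f / f_ref) ** 2 * (B / B_ref) ** 2


def channel_power(R: float, I: float) -> float:
    """Effective channel power (W) for a sinusoidal drive: 1/2 R I^2."""
    if R <= 0:
        raise ValueError("resistance must be positive")
    if not math.isfinite(I):
        raise ValueError("current must be finite")
    return 0.5 * R * I * I


def copper_mass(spec: CoilSpec) -> float:
    """Copper mass (kg) of the winding: A_wire * l_wire * rho."""
    return spec.A_wire * spec.l_wire * spec.rho_cu


def heat_per_frame(P: float, dt: float, m: float, c: float) -> float:
    """Adiabatic coil temperature rise (K) of one burst: P dt / (m c)."""
    if m <= 0 or c <= 0:
        raise ValueError("mass and heat capacity must be positive")
    return P * dt / (m * c)


def cooling_rate(alpha: float, A_surface: float, delta_T: float,
                 m: float, c: float) -> float:
    """Convective cooling rate (K/s): alpha A dT / (m c)."""
    if alpha <= 0 or A_surface <= 0 or m <= 0 or c <= 0:
        raise ValueError("alpha, area, mass and heat capacity must be positive")
    if delta_T < 0:
        raise ValueError("temperature difference must be non-negative")
    return alpha * A_surface * delta_T / (m * c)


def duty_cycle_plan(frame_rate: float, heat_frame: float, cool_rate: float,
                    delta_T_limit: float = 50.0):
    """Continuous-operation budget at a given frame rate.

    Net heating rate is ``frame_rate * heat_frame - cool_rate``; operation is
    sustainable iff that is <= 0, otherwise the scanner can run for
    ``delta_T_limit / net`` seconds before reaching the temperature budget.
    Returns ``(max_continuous_s, sustainable)``.
    """
    if frame_rate <= 0 or heat_frame < 0 or cool_rate < 0 or delta_T_limit <= 0:
        raise ValueError("invalid duty-cycle inputs")
    net = frame_rate * heat_frame - cool_rate
    if net <= 0:
        return math.inf, True
    return delta_T_limit / net, False


@dataclass
class SafetyReport:
    """Aggregated safety/thermal budget for one operating point."""

    pns_threshold_pp: float          # mT
    operating_B_pp: float            # mT
    pns_margin: float                # threshold / operating
    pns_flag: bool                   # True if operating exceeds threshold
    sar: float                       # W/kg
    sar_limit: float                 # W/kg
    channels: list = field(default_factory=list)   # per-channel dicts
    dose_limit_mg: float = 200.0
    dose_reference: str = "2.5 mg Fe/kg x 80 kg"

    def as_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        lines = [
            "Safety / thermal budget",
            f"  PNS threshold    : {self.pns_threshold_pp:7.2f} mT pp",
            f"  operating field  : {self.operating_B_pp:7.2f} mT pp"
            f"  (margin {self.pns_margin:.2f}x, "
            f"{'EXCEEDED' if self.pns_flag else 'within limit'})",
            f"  SAR              : {self.sar:7.3f} W/kg (limit {self.sar_limit} W/kg)",
            f"  dose limit       : {self.dose_limit_mg:.0f} mg Fe ({self.dose_reference})",
        ]
        for ch in self.channels:
            lines += [
                f"  {ch['name']:<6} power     : {ch['power_W'] / 1e3:6.2f} kW"
                f"  (copper {ch['copper_kg']:.2f} kg)",
                f"  {ch['name']:<6} heating   : {ch['heat_per_frame_K']:6.3f} K/frame"
                f"  cooling {ch['cooling_free_K_s']:.3f}..{ch['cooling_forced_K_s']:.3f} K/s",
                f"  {ch['name']:<6} 4 fps     : "
                + ("sustainable" if ch['sustainable_at_4fps']
                   else f"max {ch['max_continuous_4fps_s']:.0f} s continuous"),
            ]
        return "\n".join(lines)


def safety_report(config: ScannerConfig, coils: list | None = None,
                  pns: PnsParams | None = None, frame_rate: float = 4.0,
                  delta_T_limit: float = 50.0) -> SafetyReport:
    """Compose the full safety/thermal budget for a scanner configuration."""
    if coils is None:
        coils = default_coils()
    if pns is None:
        pns = PnsParams(f=config.f3)
    threshold = pns_threshold(pns)
    operating = config.B_pp * 1e3  # T -> mT
    sar = sar_scaled(config.f3, operating / 2.0)
    channels = []
    for coil in coils:
        P = channel_power(coil.R, coil.I)
        m = copper_mass(coil)
        dT = heat_per_frame(P, config.dt_burst, m, coil.c_cu)
        cool_free = cooling_rate(coil.alpha_free, coil.A_surface, delta_T_limit,
                                 m, coil.c_cu)
        cool_forced = cooling_rate(coil.alpha_forced, coil.A_surface,
                                   delta_T_limit, m, coil.c_cu)
        max_cont, sustainable = duty_cycle_plan(frame_rate, dT, cool_forced,
                                                delta_T_limit)
        channels.append({
            "name": coil.name,
            "power_W": P,
            "copper_kg": m,
            "heat_per_frame_K": dT,
            "cooling_free_K_s": cool_free,
            "cooling_forced_K_s": cool_forced,
            "max_continuous_4fps_s": max_cont,
            "sustainable_at_4fps": sustainable,
        })
    return SafetyReport(
        pns_threshold_pp=threshold,
        operating_B_pp=operating,
        pns_margin=threshold / operating,
        pns_flag=operating > threshold,
        sar=sar,
        sar_limit=SAR_LIMIT,
        channels=channels,
        dose_limit_mg=dose_limit(2.5, 80.0),
    )
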