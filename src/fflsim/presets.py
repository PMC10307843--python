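"""Ready-made scanner configurations.

``full_scale`` is the hardware operating point (496 kS/s sampling, 1 mm
phantoms).  ``desk_scale`` keeps every physical parameter of the operating
point but samples at 124 kS/s (50 samples per deflection period, harmonics to
order 20 alias-free) with 2 mm phantom pixels and a 4 mm reconstruction grid
-- small enough that a full simulate/grid/fold/reconstruct chain runs in
seconds on one CPU while preserving the encoding physics.
"""

from __future__ import annotations

from .scanner import ScannerConfig

__all__ = ["full_scale", "desk_scale", "DESK_PHANTOM_PIXEL", "DESK_RECON_PIXEL"]

DESK_PHANTOM_PIXEL = 2e-3   # m
DESK_RECON_PIXEL = 4e-3     # m


def full_scale() -> ScannerConfig:
    """The published operating point at full sampling rate."""
    return ScannerConfig()


def desk_scale() -> ScannerConfig:
    """Operating point with reduced sampling for fast desk-scale runs."""
    return ScannerConfig(fs=124_000.0, n_harmonics=20)
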