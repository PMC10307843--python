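"""End-to-end experiment runners: the scanner's studies as reproducible recipes.

Each runner wires phantom generation, sequence/trajectory, signal simulation,
and the gridding/reconstruction chain together and (optionally) writes the
artifact files.  The CLI is a thin wrapper around these functions; they are
equally usable from scripts and tests.

A ``RunConfig`` fully determines a run: scanner + tracer + noise parameters,
the named phantom with its parameters, reconstruction settings, output
directory and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as fio
from .scanner import ScannerConfig, make_sequence
from .tracer import TracerModel, NoiseModel, simulate_frame, spectrum_of
from .phantoms import (Phantom, point_sample, vessel_phantom, bolus_sequence,
                       instrument_phantom, lettering_phantom, dilution_to_mol,
                       VesselSpec)
from .recon import (ReconGrid, ReconParams, default_recon_params, band_filter,
                    grid_raw, fold, build_system_matrix, reconstruct)
from .safety import safety_report
from .presets import desk_scale, DESK_PHANTOM_PIXEL, DESK_RECON_PIXEL

__all__ = [
    "RunConfig", "make_phantom", "run_simulate", "run_reconstruct",
    "run_demo", "run_dilution_series", "make_fixtures", "DILUTION_STEPS",
]

log = logging.getLogger("fflsim")

DILUTION_STEPS = (50, 100, 200, 400, 800)
DILUTION_NOISE_SIGMA = 2e-5   # receive units; highest dilution near detection limit


@dataclass
class RunConfig:
    """Complete, serializable description of one simulation/reconstruction run."""

    scanner: ScannerConfig = field(default_factory=desk_scale)
    tracer: TracerModel = field(default_factory=TracerModel)
    noise: NoiseModel | None = None
    phantom_name: str = "lettering"
    phantom_params: dict = field(default_factory=dict)
    recon: ReconParams | None = None
    oversample_margin: float = 0.15
    recon_pixel: float = DESK_RECON_PIXEL
    phantom_pixel: float = DESK_PHANTOM_PIXEL
    output_dir: str = "fflsim_out"
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "scanner": self.scanner.to_dict(),
            "tracer": asdict(self.tracer),
            "noise": None if self.noise is None else asdict(self.noise),
            "phantom_name": self.phantom_name,
            "phantom_params": self.phantom_params,
            "recon": None if self.recon is None else asdict(self.recon),
            "oversample_margin": self.oversample_margin,
            "recon_pixel": self.recon_pixel,
            "phantom_pixel": self.phantom_pixel,
            "output_dir": self.output_dir,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["scanner"] = ScannerConfig.from_dict(d["scanner"])
        d["tracer"] = TracerModel(**d["tracer"])
        if d.get("noise"):
            d["noise"] = NoiseModel(**d["noise"])
        if d.get("recon"):
            d["recon"] = ReconParams(**d["recon"])
        return cls(**d)


_PHANTOM_REGISTRY = {}


def _register(name):
    def deco(fn):
        _PHANTOM_REGISTRY[name] = fn
        return fn
    return deco


@_register("point")
def _point(params, pixel_size):
    defaults = dict(position=(0.0, 0.0), volume=1.0,
                    iron_mol=dilution_to_mol(8.5, 100, 1.0))
    defaults.update(params)
    return [point_sample(pixel_size=pixel_size, **defaults)]


@_register("vessel")
def _vessel(params, pixel_size):
    params = dict(params)
    fill = params.pop("fill_concentration", 8.5 / 100)
    return [vessel_phantom(VesselSpec(**params), fill, pixel_size=pixel_size)]


@_register("bolus")
def _bolus(params, pixel_size):
    params = dict(params)
    spec = VesselSpec(**params.pop("vessel", {}))
    dyn = bolus_sequence(spec, pixel_size=pixel_size, **params)
    return list(dyn.frames)


@_register("instrument")
def _instrument(params, pixel_size):
    defaults = dict(kind="guidewire", tip_position=(0.0, 0.0))
    defaults.update(params)
    return [instrument_phantom(pixel_size=pixel_size, **defaults)]


@_register("lettering")
def _lettering(params, pixel_size):
    return [lettering_phantom(pixel_size=pixel_size, **params)]


def make_phantom(name: str, params: dict, pixel_size: float) -> list:
    """Instantiate the named phantom; returns a list of frames (usually one)."""
    if name not in _PHANTOM_REGISTRY:
        raise ValueError(f"unknown phantom {name!r}; "
                         f"known: {sorted(_PHANTOM_REGISTRY)}")
    return _PHANTOM_REGISTRY[name](params, pixel_size)


def _prepare_outdir(run: RunConfig) -> Path:
    out = Path(run.output_dir)
    if not out.exists():
        out.mkdir(parents=True)
        log.info("created output directory %s", out)
    (out / "run_config.json").write_text(json.dumps(run.to_dict(), indent=2))
    return out


def run_simulate(run: RunConfig, write: bool = True):
    """Simulate the configured phantom: trajectory + one signal frame per phantom frame.

    Returns ``(trajectory, frames, phantoms)``; with ``write=True`` the
    trajectory, each signal frame and each phantom are written under
    ``run.output_dir`` (CSV for signals/trajectory, TIFF+JSON for phantoms).
    """
    t0 = time.time()
    noise = run.noise
    if noise is not None:
        noise = NoiseModel(noise.sigma_white, noise.interference_lines,
                           seed=run.seed)
    traj, _ = make_sequence(run.scanner)
    phantoms = make_phantom(run.phantom_name, run.phantom_params,
                            run.phantom_pixel)
    frames = [simulate_frame(ph, traj, run.tracer, noise) for ph in phantoms]
    if write:
        out = _prepare_outdir(run)
        fio.trajectory_to_csv(traj, out / "trajectory.csv")
        for i, (ph, fr) in enumerate(zip(phantoms, frames)):
            fio.signal_to_csv(fr, out / f"signal_{i:03d}.csv", run.scanner)
            fio.phantom_to_tiff(ph, out / f"phantom_{i:03d}.tiff")
        log.info("simulated %d frame(s) in %.1f s -> %s",
                 len(frames), time.time() - t0, out)
    return traj, frames, phantoms


def run_reconstruct(run: RunConfig, frames=None, traj=None, sm=None,
                    write: bool = True):
    """Grid, fold and reconstruct the given (or freshly simulated) frames.

    Builds the system matrix if not supplied; refuses a supplied matrix whose
    fingerprint does not match the scanner config.  Returns
    ``(raws, foldeds, recons, sm)``.
    """
    if frames is None or traj is None:
        traj, frames, _ = run_simulate(run, write=False)
    params = run.recon or default_recon_params(run.scanner)
    if sm is None:
        grid = ReconGrid.cover(run.scanner.fov_x, run.scanner.fov_z,
                               run.recon_pixel, run.oversample_margin)
        sm = build_system_matrix(run.scanner, run.tracer, grid,
                                 run.oversample_margin, params=params)
    elif sm.fingerprint != run.scanner.fingerprint():
        raise ValueError("system matrix fingerprint does not match scanner config")
    raws, foldeds, recons = [], [], []
    for fr in frames:
        filtered = band_filter(fr, run.scanner, params)
        raw = grid_raw(filtered, traj)
        folded = fold(raw, sm.folded_shape, sm.extent)
        rec = reconstruct(folded, sm, params.lambda_reg, params.n_iter)
        raws.append(raw)
        foldeds.append(folded)
        recons.append(rec)
    if write:
        out = _prepare_outdir(run)
        meta = {"config_fingerprint": run.scanner.fingerprint()}
        for i, (raw, folded, rec) in enumerate(zip(raws, foldeds, recons)):
            fio.image_to_tiff(np.abs(raw.grid), out / f"raw_{i:03d}.tiff", meta)
            fio.image_to_tiff(np.abs(folded.grid), out / f"folded_{i:03d}.tiff", meta)
            fio.image_to_tiff(rec.grid, out / f"recon_{i:03d}.tiff", meta)
        log.info("reconstructed %d frame(s) -> %s", len(recons), out)
    return raws, foldeds, recons, sm


def run_dilution_series(scanner: ScannerConfig | None = None,
                        tracer: TracerModel | None = None,
                        steps=DILUTION_STEPS, position=(0.012, -0.018),
                        noise_sigma: float = DILUTION_NOISE_SIGMA,
                        seed: int = 0, pixel_size: float = DESK_PHANTOM_PIXEL):
    """Sensitivity study: 1-ml point samples of a tracer dilution series.

    Returns ``(iron_mol, amplitudes)`` of the first sideband of the 5th
    deflection harmonic (5 f3 + 2 f1), the scanner's detection band, one
    amplitude per dilution step.
    """
    scanner = scanner or desk_scale()
    tracer = tracer or TracerModel()
    traj, _ = make_sequence(scanner)
    irons, amps = [], []
    for i, step in enumerate(steps):
        iron = dilution_to_mol(tracer.c_stock, step, 1.0, tracer.molar_mass_fe)
        ph = point_sample(position, 1.0, iron, pixel_size=pixel_size)
        noise = (NoiseModel(noise_sigma, seed=seed + i)
                 if noise_sigma > 0 else None)
        frame = simulate_frame(ph, traj, tracer, noise)
        spec = spectrum_of(frame, scanner, n_max=6, k_max=4)
        irons.append(iron)
        amps.append(abs(spec.amplitude(5, 2)))
    return np.asarray(irons), np.asarray(amps)


def run_demo(output_dir: str = "fflsim_demo", write: bool = True):
    """Full chain on the block-lettering phantom; returns (phantom, recon, ncc).

    Deterministic (noise off).  ``ncc`` is the normalized cross-correlation
    between the reconstruction and the phantom projected on the recon grid.
    """
    from .recon import project_phantom

    run = RunConfig(phantom_name="lettering", output_dir=output_dir)
    traj, frames, phantoms = run_simulate(run, write=False)
    raws, foldeds, recons, sm = run_reconstruct(run, frames, traj, write=False)
    ph, rec = phantoms[0], recons[0]
    truth = project_phantom(ph, sm.recon_grid)
    a = rec.grid.ravel() - rec.grid.mean()
    b = truth.ravel() - truth.mean()
    ncc = float(a @ b / np.sqrt((a @ a) * (b @ b)))
    if write:
        out = _prepare_outdir(run)
        fio.phantom_to_tiff(ph, out / "demo_phantom.tiff")
        fio.image_to_tiff(np.abs(raws[0].grid), out / "demo_raw.tiff")
        fio.image_to_tiff(np.abs(foldeds[0].grid), out / "demo_folded.tiff")
        fio.image_to_tiff(rec.grid, out / "demo_recon.tiff")
        _demo_panel(ph, raws[0], foldeds[0], rec, truth, out / "demo_panel.png")
        (out / "demo_metrics.json").write_text(
            json.dumps({"ncc": ncc, "config_fingerprint":
                        run.scanner.fingerprint()}, indent=2))
        log.info("demo ncc=%.3f -> %s", ncc, out)
    return ph, rec, ncc


def _demo_panel(phantom, raw, folded, rec, truth, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 4, figsize=(13, 3.2))
    for ax, (img, title) in zip(axes, [
            (phantom.grid, "phantom (projected iron)"),
            (np.abs(raw.grid), "raw image (|gridded signal|)"),
            (np.abs(folded.grid), "folded (4 sub-images)"),
            (rec.grid, "reconstruction")]):
        ax.imshow(img, origin="lower", aspect="auto", cmap="inferno")
        ax.set_title(title, fontsize=9)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def make_fixtures(seed: int = 0, output_dir: str = "fflsim_fixtures"):
    """Miniature test assets, fully regenerated from the seed.

    Quarter-resolution phantoms (4 mm pixels), one noisy point-source frame,
    and a small prebuilt system matrix (8 mm recon pixels).
    """
    scanner = desk_scale()
    tracer = TracerModel()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj, _ = make_sequence(scanner)
    ph = point_sample((0.01, 0.0), 1.0, dilution_to_mol(8.5, 100, 1.0),
                      pixel_size=4e-3)
    frame = simulate_frame(ph, traj, tracer, NoiseModel(2e-5, seed=seed))
    fio.phantom_to_tiff(ph, out / "mini_point.tiff")
    fio.signal_to_csv(frame, out / "mini_frame.csv", scanner)
    grid = ReconGrid.cover(scanner.fov_x, scanner.fov_z, 8e-3, margin=0.15)
    sm = build_system_matrix(scanner, tracer, grid, 0.15,
                             params=default_recon_params(scanner))
    fio.system_matrix_to_hdf5(sm, out / "mini_system_matrix.h5")
    fio.save_scanner_config(scanner, out / "mini_scanner.yaml")
    return out


def run_safety(scanner: ScannerConfig | None = None):
    """Safety/thermal budget for the configured operating point."""
    return safety_report(scanner or desk_scale())
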