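"""File I/O: configs (YAML), signals/trajectories (CSV + HDF5), images (TIFF/PNG).

Every exported artifact carries provenance: the scanner-config fingerprint
and the package version, either as HDF5 attributes, a JSON sidecar, or a
header comment in delimited text.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml
from PIL import Image

from . import __version__
from .scanner import ScannerConfig, Trajectory
from .tracer import SignalFrame
from .phantoms import Phantom
from .recon import ReconGrid, SystemMatrix

__all__ = [
    "load_scanner_config", "save_scanner_config",
    "trajectory_to_csv", "trajectory_to_hdf5",
    "signal_to_csv", "signal_from_csv", "signal_to_hdf5", "signal_from_hdf5",
    "phantom_to_tiff", "phantom_from_tiff", "phantom_from_csv", "phantom_to_csv",
    "image_to_tiff", "image_to_png",
    "system_matrix_to_hdf5", "system_matrix_from_hdf5",
]


def _provenance(config: ScannerConfig | None = None) -> dict:
    meta = {"package": "fflsim", "version": __version__}
    if config is not None:
        meta["config_fingerprint"] = config.fingerprint()
    return meta


# ------------------------------------------------------------------------ configs

def save_scanner_config(config: ScannerConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_scanner_config(path) -> ScannerConfig:
    """Load a flat YAML/JSON scanner config; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"scanner config {path} is not a mapping")
    return ScannerConfig.from_dict(data)


# --------------------------------------------------------------------- trajectory

def trajectory_to_csv(traj: Trajectory, path) -> None:
    header = (f"fflsim trajectory v{__version__} "
              f"config={traj.config.fingerprint()} fs={traj.fs}\n"
              "t,x,z,sign,line_index,pass_index")
    data = np.column_stack([traj.t, traj.x, traj.z, traj.sign,
                            traj.line_index, traj.pass_index])
    np.savetxt(path, data, delimiter=",", header=header,
               fmt=["%.9f", "%.6e", "%.6e", "%d", "%d", "%d"])


def trajectory_to_hdf5(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as f:
        for name in ("t", "x", "z", "sign", "line_index", "pass_index"):
            f.create_dataset(name, data=getattr(traj, name))
        for k, v in _provenance(traj.config).items():
            f.attrs[k] = v
        f.attrs["fs"] = traj.fs
        f.attrs["repeating"] = traj.repeating


# ------------------------------------------------------------------------ signals

def signal_to_csv(frame: SignalFrame, path,
                  config: ScannerConfig | None = None) -> None:
    header = (f"fflsim signal v{__version__} fs={frame.fs} t0={frame.t0}"
              + (f" config={config.fingerprint()}" if config else "")
              + "\nt,value")
    t = frame.t0 + np.arange(frame.samples.size) / frame.fs
    np.savetxt(path, np.column_stack([t, frame.samples]), delimiter=",",
               header=header, fmt=["%.9f", "%.9e"])


def signal_from_csv(path, fs: float | None = None) -> SignalFrame:
    data = np.loadtxt(path, delimiter=",", comments="#")
    t, v = data[:, 0], data[:, 1]
    if fs is None:
        dt = np.diff(t)
        if dt.size == 0 or np.any(dt <= 0):
            raise ValueError("cannot infer sampling rate from time column")
        fs = 1.0 / float(np.median(dt))
    return SignalFrame(samples=v, fs=fs, t0=float(t[0]))


def signal_to_hdf5(frame: SignalFrame, path,
                   config: ScannerConfig | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=frame.samples)
        f.attrs["fs"] = frame.fs
        f.attrs["t0"] = frame.t0
        for k, v in _provenance(config).items():
            f.attrs[k] = v


def signal_from_hdf5(path) -> SignalFrame:
    with h5py.File(path, "r") as f:
        return SignalFrame(samples=f["samples"][...], fs=float(f.attrs["fs"]),
                           t0=float(f.attrs["t0"]))


# ----------------------------------------------------------------------- phantoms

def _to_uint16(grid: np.ndarray):
    peak = float(grid.max())
    scaled = (grid / peak * 65535.0) if peak > 0 else grid
    return np.round(scaled).astype(np.uint16), peak


def phantom_to_tiff(phantom: Phantom, path) -> None:
    """16-bit grayscale TIFF plus a JSON sidecar with scale/pixel metadata."""
    raster, peak = _to_uint16(phantom.grid)
    tifffile.imwrite(path, raster)
    sidecar = {
        "pixel_size_m": phantom.pixel_size,
        "origin_m": list(phantom.origin),
        "label": phantom.label,
        "total_iron_mol": phantom.total_iron,
        "peak_mol_per_pixel": peak,
        **_provenance(),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def phantom_from_tiff(path) -> Phantom:
    raster = tifffile.imread(path).astype(float)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    grid = raster / 65535.0 * sidecar["peak_mol_per_pixel"]
    return Phantom(grid=grid, pixel_size=sidecar["pixel_size_m"],
                   origin=tuple(sidecar["origin_m"]), label=sidecar["label"])


def phantom_to_csv(phantom: Phantom, path) -> None:
    header = (f"fflsim phantom v{__version__} pixel_size={phantom.pixel_size} "
              f"origin={phantom.origin[0]},{phantom.origin[1]} label={phantom.label}")
    np.savetxt(path, phantom.grid, delimiter=",", header=header)


def phantom_from_csv(path, pixel_size: float | None = None) -> Phantom:
    header = Path(path).read_text().splitlines()[0]
    if pixel_size is None:
        for token in header.replace("#", "").split():
            if token.startswith("pixel_size="):
                pixel_size = float(token.split("=", 1)[1])
        if pixel_size is None:
            raise ValueError("pixel_size not given and absent from header")
    grid = np.loadtxt(path, delimiter=",", comments="#")
    return Phantom(grid=grid, pixel_size=pixel_size)


# ------------------------------------------------------------------------- images

def image_to_tiff(image: np.ndarray, path, meta: dict | None = None) -> None:
    raster, peak = _to_uint16(np.asarray(image, dtype=float))
    tifffile.imwrite(path, raster)
    sidecar = {"peak_value": peak, **(meta or {}), **_provenance()}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def image_to_png(image: np.ndarray, path, meta: dict | None = None) -> None:
    raster, peak = _to_uint16(np.asarray(image, dtype=float))
    Image.fromarray(raster, mode="I;16").save(path)
    sidecar = {"peak_value": peak, **(meta or {}), **_provenance()}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


# ------------------------------------------------------------------ system matrix

def system_matrix_to_hdf5(sm: SystemMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=sm.A)
        g = sm.recon_grid
        f.attrs.update({
            "nx": g.nx, "nz": g.nz, "pixel_size": g.pixel_size,
            "x0": g.x0, "z0": g.z0,
            "folded_shape": sm.folded_shape, "extent": sm.extent,
            "fingerprint": sm.fingerprint,
            "build_params": json.dumps(sm.build_params),
        })
        for k, v in _provenance().items():
            f.attrs[k] = v


def system_matrix_from_hdf5(path, expect_config: ScannerConfig | None = None
                            ) -> SystemMatrix:
    """Load a persisted system matrix, refusing a config-fingerprint mismatch."""
    with h5py.File(path, "r") as f:
        fingerprint = str(f.attrs["fingerprint"])
        if expect_config is not None and fingerprint != expect_config.fingerprint():
            raise ValueError(
                f"system matrix fingerprint {fingerprint} does not match the "
                f"scanner config ({expect_config.fingerprint()})")
        grid = ReconGrid(nx=int(f.attrs["nx"]), nz=int(f.attrs["nz"]),
                         pixel_size=float(f.attrs["pixel_size"]),
                         x0=float(f.attrs["x0"]), z0=float(f.attrs["z0"]))
        return SystemMatrix(A=f["A"][...], recon_grid=grid,
                            folded_shape=tuple(int(v) for v in f.attrs["folded_shape"]),
                            extent=tuple(float(v) for v in f.attrs["extent"]),
                            fingerprint=fingerprint,
                            build_params=json.loads(str(f.attrs["build_params"])))
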