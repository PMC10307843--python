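"""Deterministic 2D phantom generators emulating the scanner's test objects.

All phantoms are projected iron-amount maps (mol Fe per pixel) on a
FOV-centered grid (row = z, column = x).  3D tube geometry enters through an
analytic chord-thickness projection: a filled cylinder of local diameter D
projects to thickness ``2 sqrt((D/2)^2 - d^2)`` at perpendicular distance d
from its axis.  Generators are deterministic (no RNG) and conserve the
requested iron totals.

Covered phantom classes: 1-ml point samples of a tracer dilution series,
vessel tubes with adjustable stenosis grade and aneurysm bulges, a traveling
bolus under pulsatile flow, point-like instrument markers (guidewire tip,
two balloon markers), and block lettering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Phantom",
    "DynamicPhantom",
    "VesselSpec",
    "dilution_to_mol",
    "dose_limit",
    "point_sample",
    "vessel_phantom",
    "bolus_sequence",
    "instrument_phantom",
    "lettering_phantom",
]

DEFAULT_FOV_X = 0.11   # m
DEFAULT_FOV_Z = 0.12   # m
DEFAULT_PIXEL = 1e-3   # m


@dataclass
class Phantom:
    """Projected iron-amount map: ``grid[iz, ix]`` in mol Fe per pixel."""

    grid: np.ndarray
    pixel_size: float = DEFAULT_PIXEL
    origin: tuple = (0.0, 0.0)   # (x, z) offset of grid center, m
    label: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("phantom grid must be 2D")
        if np.any(self.grid < 0):
            raise ValueError("phantom grid must be non-negative")

    @property
    def x_centers(self) -> np.ndarray:
        nx = self.grid.shape[1]
        return (np.arange(nx) - (nx - 1) / 2) * self.pixel_size + self.origin[0]

    @property
    def z_centers(self) -> np.ndarray:
        nz = self.grid.shape[0]
        return (np.arange(nz) - (nz - 1) / 2) * self.pixel_size + self.origin[1]

    @property
    def total_iron(self) -> float:
        return float(self.grid.sum())

    def nonzero_points(self):
        """(x, z, amount) arrays of the nonzero pixels, for signal simulation."""
        iz, ix = np.nonzero(self.grid)
        return (self.x_centers[ix], self.z_centers[iz], self.grid[iz, ix])

    def scaled(self, factor: float) -> "Phantom":
        return Phantom(self.grid * factor, self.pixel_size, self.origin, self.label)


@dataclass
class DynamicPhantom:
    """Ordered phantom frames plus the pulsatile flow profile that drove them."""

    frames: list
    frame_rate: float = 4.0            # 1/s
    flow_profile: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        shapes = {f.grid.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError("all frames must share grid geometry")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class VesselSpec:
    """Geometry of a vessel-tube phantom.

    ``path`` is a polyline of (x, z) vertices in meters (default: straight
    along the travel axis z through the FOV center).  ``stenosis_grade`` is
    the fractional *diameter* reduction (clinical convention), applied as a
    smooth cosine-tapered narrowing of length ``stenosis_length`` centered at
    ``stenosis_position`` (fraction of arclength).  ``aneurysm_diameter``
    adds a disc bulge; ``branch`` an optional perpendicular side segment
    ``(position_fraction, length)``.
    """

    parent_diameter: float = 0.010           # m (8-10 mm lumen; parent 10 mm)
    path: list | None = None
    stenosis_grade: float = 0.0              # 0..1 diameter reduction
    stenosis_length: float = 0.030           # m
    stenosis_position: float = 0.5           # fraction of arclength
    aneurysm_diameter: float = 0.0           # m, 0 = none
    aneurysm_position: float = 0.5           # fraction of arclength
    branch: tuple | None = None              # (position_fraction, length m)

    def __post_init__(self) -> None:
        if not 0.0 <= self.stenosis_grade <= 1.0:
            raise ValueError("stenosis_grade must lie in [0, 1]")
        if self.parent_diameter <= 0:
            raise ValueError("parent_diameter must be positive")
        if self.path is None:
            half = DEFAULT_FOV_Z / 2
            self.path = [(0.0, -half), (0.0, half)]

    def path_array(self) -> np.ndarray:
        return np.asarray(self.path, dtype=float)

    def path_length(self) -> float:
        p = self.path_array()
        return float(np.sum(np.hypot(*np.diff(p, axis=0).T)))


# ------------------------------------------------------------------- arithmetic

def dilution_to_mol(c_stock: float, dilution_factor: float, volume: float,
                    molar_mass: float = 55.845) -> float:
    """Iron amount (mol) in ``volume`` ml of a ``1:dilution_factor`` dilution.

    ``c_stock`` in mg/ml, ``molar_mass`` in g/mol.  Example: a 1:100 dilution
    of an 8.5 mg/ml stock in 1 ml holds 1.52 umol Fe.
    """
    if c_stock <= 0 or dilution_factor <= 0 or molar_mass <= 0:
        raise ValueError("concentration, dilution factor and molar mass must be positive")
    if volume < 0:
        raise ValueError("volume must be non-negative")
    mg = c_stock / dilution_factor * volume
    return mg * 1e-3 / molar_mass


def dose_limit(mg_per_kg: float, body_mass: float) -> float:
    """Total iron dose limit (mg): ``mg_per_kg * body_mass`` (e.g. 2.5 x 80 = 200)."""
    if mg_per_kg < 0 or body_mass < 0:
        raise ValueError("dose rate and body mass must be non-negative")
    return mg_per_kg * body_mass


# -------------------------------------------------------------------- grid setup

def _empty_grid(fov_x: float, fov_z: float, pixel_size: float):
    nx = int(round(fov_x / pixel_size)) + 1
    nz = int(round(fov_z / pixel_size)) + 1
    return np.zeros((nz, nx))


def _grid_coords(grid: np.ndarray, pixel_size: float):
    nz, nx = grid.shape
    x = (np.arange(nx) - (nx - 1) / 2) * pixel_size
    z = (np.arange(nz) - (nz - 1) / 2) * pixel_size
    return np.meshgrid(x, z)


# ---------------------------------------------------------------------- phantoms

def point_sample(position, volume: float, iron_mol: float,
                 sample_diameter: float = 0.010,
                 fov_x: float = DEFAULT_FOV_X, fov_z: float = DEFAULT_FOV_Z,
                 pixel_size: float = DEFAULT_PIXEL) -> Phantom:
    """Point-like sample (Eppendorf cap): a uniform disc holding ``iron_mol``.

    Total iron over the grid equals ``iron_mol`` exactly; integer-pixel
    translations of ``position`` shift the pattern without changing it.
    """
    x0, z0 = position
    if abs(x0) > fov_x / 2 or abs(z0) > fov_z / 2:
        raise ValueError(f"position {position} outside FOV")
    grid = _empty_grid(fov_x, fov_z, pixel_size)
    nz, nx = grid.shape
    # integer-pixel disc (center snapped to the nearest pixel) so that
    # integer-pixel translations are exactly equivariant
    ix0 = int(round(x0 / pixel_size + (nx - 1) / 2))
    iz0 = int(round(z0 / pixel_size + (nz - 1) / 2))
    jx, jz = np.meshgrid(np.arange(nx) - ix0, np.arange(nz) - iz0)
    mask = jx ** 2 + jz ** 2 <= (sample_diameter / (2 * pixel_size)) ** 2
    if not mask.any():
        mask[min(max(iz0, 0), nz - 1), min(max(ix0, 0), nx - 1)] = True
    grid[mask] = iron_mol / mask.sum()
    return Phantom(grid, pixel_size, label=f"point({volume} ml, {iron_mol:.3g} mol)")


def _polyline_distance(X: np.ndarray, Z: np.ndarray, path: np.ndarray):
    """Per-pixel distance to a polyline and arclength of the nearest point."""
    dmin = np.full(X.shape, np.inf)
    smin = np.zeros(X.shape)
    s0 = 0.0
    for (xa, za), (xb, zb) in zip(path[:-1], path[1:]):
        seg = math.hypot(xb - xa, zb - za)
        if seg == 0:
            continue
        tx, tz = (xb - xa) / seg, (zb - za) / seg
        proj = np.clip((X - xa) * tx + (Z - za) * tz, 0.0, seg)
        d = np.hypot(X - (xa + proj * tx), Z - (za + proj * tz))
        closer = d < dmin
        dmin = np.where(closer, d, dmin)
        smin = np.where(closer, s0 + proj, smin)
        s0 += seg
    return dmin, smin


def _lumen_diameter(s: np.ndarray, spec: VesselSpec, total_len: float) -> np.ndarray:
    """Local lumen diameter along arclength with the cosine-tapered stenosis."""
    D = np.full(s.shape, spec.parent_diameter)
    if spec.stenosis_grade > 0:
        # flat-bottom narrowing (the vessel clip compresses an extended
        # length) with smooth cosine-tapered shoulders
        s_c = spec.stenosis_position * total_len
        u = np.abs(s - s_c) / spec.stenosis_length
        w = np.where(u <= 0.25, 1.0,
                     np.where(u <= 0.5,
                              0.5 * (1 + np.cos(4 * math.pi * (u - 0.25))),
                              0.0))
        D = spec.parent_diameter * (1 - spec.stenosis_grade * w)
    return D


def _chord_thickness(dist: np.ndarray, diameter) -> np.ndarray:
    r = np.asarray(diameter) / 2
    h2 = r ** 2 - dist ** 2
    return 2.0 * np.sqrt(np.clip(h2, 0.0, None))


def _point_on_path(path: np.ndarray, frac: float):
    seg = np.hypot(*np.diff(path, axis=0).T)
    total = seg.sum()
    target = frac * total
    s0 = 0.0
    for (xa, za), (xb, zb), L in zip(path[:-1], path[1:], seg):
        if target <= s0 + L and L > 0:
            u = min(max((target - s0) / L, 0.0), 1.0)
            return ((xa + u * (xb - xa), za + u * (zb - za)),
                    ((xb - xa) / L, (zb - za) / L))
        s0 += L
    (xa, za), (xb, zb), L = path[-2], path[-1], seg[-1]
    return (tuple(path[-1]), ((xb - xa) / L, (zb - za) / L))


def vessel_phantom(spec: VesselSpec, fill_concentration: float = 8.5,
                   fov_x: float = DEFAULT_FOV_X, fov_z: float = DEFAULT_FOV_Z,
                   pixel_size: float = DEFAULT_PIXEL) -> Phantom:
    """Projected thickness map of a tracer-filled vessel tube.

    ``fill_concentration`` in mg Fe/ml.  The stenosis narrows the lumen
    diameter to ``parent * (1 - grade)`` over ``stenosis_length``; an
    aneurysm adds a disc bulge; ``branch`` adds a perpendicular side segment.
    """
    path = spec.path_array()
    half_x, half_z = fov_x / 2 + pixel_size, fov_z / 2 + pixel_size
    if np.any(np.abs(path[:, 0]) > half_x) or np.any(np.abs(path[:, 1]) > half_z):
        raise ValueError("vessel path exits the grid")
    grid = _empty_grid(fov_x, fov_z, pixel_size)
    X, Z = _grid_coords(grid, pixel_size)
    dist, s = _polyline_distance(X, Z, path)
    D = _lumen_diameter(s, spec, spec.path_length())
    thickness = _chord_thickness(dist, D)

    if spec.aneurysm_diameter > 0:
        (cx, cz), _ = _point_on_path(path, spec.aneurysm_position)
        d_an = np.hypot(X - cx, Z - cz)
        thickness = np.maximum(thickness,
                               _chord_thickness(d_an, spec.aneurysm_diameter))
    if spec.branch is not None:
        frac, length = spec.branch
        (bx, bz), (tx, tz) = _point_on_path(path, frac)
        nx_, nz_ = -tz, tx  # perpendicular
        bpath = np.asarray([[bx, bz], [bx + nx_ * length, bz + nz_ * length]])
        bdist, _ = _polyline_distance(X, Z, bpath)
        thickness = np.maximum(thickness,
                               _chord_thickness(bdist, spec.parent_diameter))

    # mg/ml == kg/m^3; mol per pixel = thickness * area * conc / molar mass
    mol_per_m3 = fill_concentration / 55.845e-3
    grid = thickness * pixel_size ** 2 * mol_per_m3
    return Phantom(grid, pixel_size, label=f"vessel(grade={spec.stenosis_grade})")


def pulsatile_velocity(t, peak_velocity: float, pulse_freq: float = 1.0):
    """Rectified-sinusoid pulsatile velocity profile (m/s), exact stated peak.

    ``pulse_freq = 0`` degenerates to constant (non-pulsatile) flow.
    """
    t = np.asarray(t, dtype=float)
    if pulse_freq == 0:
        return np.full(t.shape, peak_velocity)
    return peak_velocity * np.abs(np.sin(math.pi * pulse_freq * t))


def bolus_sequence(spec: VesselSpec, bolus_volume: float = 1.0,
                   bolus_iron: float | None = None,
                   peak_velocity: float = 0.5, frame_rate: float = 4.0,
                   n_frames: int = 20, pulse_freq: float = 1.0,
                   start_fraction: float = 0.0,
                   fov_x: float = DEFAULT_FOV_X, fov_z: float = DEFAULT_FOV_Z,
                   pixel_size: float = DEFAULT_PIXEL) -> DynamicPhantom:
    """Traveling tracer bolus in a vessel under pulsatile flow.

    The bolus (default 1 ml of 8.5 mg/ml stock) occupies a slug of length
    ``volume / lumen_area`` along the path; its head advances by the time
    integral of the rectified-sinusoid velocity between frames.  Total iron
    is conserved while the slug is fully inside the path, then decreases as
    it exits.
    """
    if peak_velocity <= 0:
        raise ValueError("peak_velocity must be positive")
    if bolus_iron is None:
        bolus_iron = dilution_to_mol(8.5, 1.0, bolus_volume)
    path = spec.path_array()
    total_len = spec.path_length()
    area = math.pi * spec.parent_diameter ** 2 / 4
    slug_len = bolus_volume * 1e-6 / area
    lam = bolus_iron / slug_len  # mol per meter of slug

    # head position per frame by integrating the velocity profile
    t_fine = np.linspace(0, n_frames / frame_rate, max(2, n_frames * 200 + 1))
    v_fine = pulsatile_velocity(t_fine, peak_velocity, pulse_freq)
    s_fine = np.concatenate([[0.0], np.cumsum(np.diff(t_fine) * 0.5 *
                                              (v_fine[1:] + v_fine[:-1]))])
    frame_times = np.arange(n_frames) / frame_rate
    heads = start_fraction * total_len + np.interp(frame_times, t_fine, s_fine)

    grid0 = _empty_grid(fov_x, fov_z, pixel_size)
    X, Z = _grid_coords(grid0, pixel_size)
    dist, s_near = _polyline_distance(X, Z, path)
    thickness = _chord_thickness(dist, _lumen_diameter(s_near, spec, total_len))

    frames = []
    for head in heads:
        tail = head - slug_len
        overlap = max(0.0, min(head, total_len) - max(tail, 0.0))
        grid = np.where((s_near >= tail) & (s_near <= head), thickness, 0.0)
        tot = grid.sum()
        grid = grid * (lam * overlap / tot) if tot > 0 else grid
        frames.append(Phantom(grid, pixel_size, label=f"bolus(head={head:.3f} m)"))
    profile = pulsatile_velocity(np.linspace(0, n_frames / frame_rate,
                                             n_frames * 100 + 1),
                                 peak_velocity, pulse_freq)
    return DynamicPhantom(frames=frames, frame_rate=frame_rate, flow_profile=profile)


def instrument_phantom(kind: str, tip_position, marker_iron: float = 2e-6,
                       marker_spacing: float = 0.037, direction=(0.0, 1.0),
                       marker_diameter: float = 0.004,
                       fov_x: float = DEFAULT_FOV_X, fov_z: float = DEFAULT_FOV_Z,
                       pixel_size: float = DEFAULT_PIXEL) -> Phantom:
    """Point-marker phantom for labeled endovascular instruments.

    ``guidewire``: a single marker at the tip.  ``balloon``: two markers
    separated by ``marker_spacing`` (default 37 mm) along the device axis,
    the second trailing the tip opposite to ``direction``.
    """
    if kind not in ("guidewire", "balloon"):
        raise ValueError(f"unknown instrument kind {kind!r}")
    dx, dz = direction
    norm = math.hypot(dx, dz)
    if norm == 0:
        raise ValueError("direction must be non-zero")
    dx, dz = dx / norm, dz / norm
    positions = [tuple(tip_position)]
    if kind == "balloon":
        positions.append((tip_position[0] - marker_spacing * dx,
                          tip_position[1] - marker_spacing * dz))
    grid = _empty_grid(fov_x, fov_z, pixel_size)
    acc = Phantom(grid, pixel_size, label=kind)
    for pos in positions:
        p = point_sample(pos, 0.0, marker_iron, sample_diameter=marker_diameter,
                         fov_x=fov_x, fov_z=fov_z, pixel_size=pixel_size)
        acc = Phantom(acc.grid + p.grid, pixel_size, label=kind)
    return acc


# 5x7 block glyphs for the lettering phantom (deterministic, no font engine)
_GLYPHS = {
    "I": ["11111", "00100", "00100", "00100", "00100", "00100", "11111"],
    "M": ["10001", "11011", "10101", "10001", "10001", "10001", "10001"],
    "P": ["11110", "10001", "11110", "10000", "10000", "10000", "10000"],
    "i": ["00100", "00000", "01100", "00100", "00100", "00100", "01110"],
    " ": ["00000"] * 7,
}


def lettering_phantom(text: str = "iMPI", total_iron: float = 2e-6,
                      coverage: float = 0.6,
                      fov_x: float = DEFAULT_FOV_X, fov_z: float = DEFAULT_FOV_Z,
                      pixel_size: float = DEFAULT_PIXEL) -> Phantom:
    """Binary block-lettering map, scaled to ``coverage`` of the FOV width.

    Uniform concentration over the glyph pixels; deterministic across calls.
    """
    try:
        rows = ["0".join(_GLYPHS[c][r] for c in text) for r in range(7)]
    except KeyError as exc:
        raise ValueError(f"no glyph for character {exc.args[0]!r}") from None
    bitmap = np.array([[int(b) for b in row] for row in rows], dtype=float)
    target_w = coverage * fov_x
    scale = max(1, int(round(target_w / (bitmap.shape[1] * pixel_size))))
    bitmap = np.kron(bitmap, np.ones((scale, scale)))
    grid = _empty_grid(fov_x, fov_z, pixel_size)
    nz, nx = grid.shape
    bz, bx = bitmap.shape
    if bz > nz or bx > nx:
        bitmap = bitmap[:nz, :nx]
        bz, bx = bitmap.shape
    z0, x0 = (nz - bz) // 2, (nx - bx) // 2
    grid[z0:z0 + bz, x0:x0 + bx] = bitmap
    total = grid.sum()
    if total > 0:
        grid *= total_iron / total
    return Phantom(grid, pixel_size, label=f"lettering({text!r})")
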