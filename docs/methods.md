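# Models and methods

This note documents the physical models in `fflsim`, the parameter choices
that matter, the numerical decisions, and what the synthetic experiments do
and do not demonstrate about a real scanner.

## Encoding model

The scanner produces a field-free line (FFL) oriented along the projection
axis *y*. Two phase-shifted 60 Hz saddle-coil pairs create a traveling wave
whose zeros — the FFLs, of alternating gradient polarity — move along the
bore axis *z*; a 2480 Hz solenoid pair deflects the whole pattern
sinusoidally along *x*. In the trajectory parameterization, the in-FOV FFL
position is

- x(t) = x_max · sin(2π f₃ t), with x_max = FOV_x/2 = 5.5 cm,
- z(t) advancing linearly across the scan span once per half period of f₁,
  restarting at the opposite edge with flipped gradient polarity.

At the stock frequencies f₃/f₁ = 2480/60 = 124/3, so one 50 ms acquisition
contains exactly 124 deflection lines, three f₁ periods (six z passes), and
repeats itself sample-for-sample — every harmonic sideband n·f₃ + k·f₁ falls
exactly on an FFT bin of the window.

Two field models coexist deliberately:

- `field_at` is the simple accessor: field magnitude = gradient × in-plane
  distance to the nearest FFL (exactly zero on the line), signed by that
  FFL's polarity. It is the natural "how strong is the field here" query,
  but the *signed* value is discontinuous midway between two
  opposite-polarity FFLs.
- `wave_field` is the smooth model the signal simulation uses: the traveling
  wave component B_z = (G/k)·sin(k(z − z₊)) (zeros at the FFLs, slope ±G,
  k = π/spacing) plus the deflection-displaced transverse component
  B_x = G·(x − x_ffl)·cos(k(z − z₊)). Near every FFL this reduces to the
  quadrupole-like ±G·(dx, dz) and it is continuous everywhere. Simulating
  with the nearest-line signed scalar instead produces spurious full
  magnetization flips at the mid-planes and mirror ghosts displaced by one
  FFL spacing — which is why the vector model is the default.

No coil geometry (Biot–Savart) is modeled; FFL rotation and 3D encoding are
out of scope.

## Tracer signal

Tracer magnetization is the static Langevin equilibrium
L(ξ) = coth ξ − 1/ξ of ξ = β|B|; Néel/Brownian relaxation is deliberately
not modeled (static response only — relaxation would lag and asymmetrize
the response at these sweep rates). The receive coil measures the *z*
component with homogeneous sensitivity over the FOV:

    s(t) = − d/dt Σᵢ cᵢ m_sat L(β|B(rᵢ,t)|) · B_z/|B| ,

with the derivative by central finite differences at the sampling rate.

Parameters:

- **β = 10⁴ T⁻¹** (free calibration, not a measured tracer property): the
  magnetization leaves saturation only when the FFL comes within
  ξ≈5 ⇒ ~2 mm at a 0.25 T/m gradient, consistent with the scanner-class
  ~5 mm resolution. Larger β sharpens the point response and spreads signal
  energy to higher harmonics.
- **m_sat = 1** (arbitrary receive units per mol Fe); all amplitudes are
  relative, which suffices because every characterization here is a ratio.
- **B_background = 50 µT** (earth-scale static field added to B_z). This is
  not cosmetic: with f₃/f₁ = 124/3 the ideal drive field is exactly
  antiperiodic over half the acquisition window, B(t + 25 ms) = −B(t), so a
  perfectly odd magnetization response puts *zero* energy at every even
  multiple of the 20 Hz bin spacing — including the 12,520 Hz
  (5f₃ + 2f₁) detection band. Real scanners sit in static background
  fields that break the polarity symmetry; the model includes one for the
  same reason. Setting it to zero reproduces the extinction exactly (this
  is a regression test).
- **Noise**: white Gaussian receive noise plus optional narrowband
  interference lines, fully seeded. The study noise level σ = 2×10⁻⁵
  (receive units) was chosen so that the most dilute point sample of the
  dilution series (1:800, 0.19 µmol Fe) sits near the detection limit at
  the 5th-harmonic sideband, emulating the sensitivity regime the scanner
  operates in.

The spectrum analyzer reads complex amplitudes directly off the FFT bins
(exact by commensurability), estimates a per-band SNR against the median of
the nearest bins off the sideband lattice, and supports SNR ≥ 2 peak
picking.

## Phantoms

All phantoms are 2D projected iron-amount maps (mol Fe per pixel, 1 mm
pixels at full scale, 2 mm at desk scale) on the FOV-centered grid. 3D tube
geometry enters via the analytic chord projection: a filled cylinder of
local diameter D projects to thickness 2√((D/2)² − d²).

- *Dilution series*: 1 ml point samples (1 cm disc) of the 8.5 mg Fe/ml
  stock at 1:50 … 1:800 (3.04, 1.52, 0.761, 0.381, 0.190 µmol Fe by
  c·V/M with M = 55.845 g/mol).
- *Vessels*: 10 mm parent lumen along a polyline; stenosis as a flat-bottom
  narrowing to D·(1 − grade) with smooth cosine shoulders over 30 mm (a
  vessel clip compresses an extended length, hence the plateau); optional
  aneurysm disc bulge and a perpendicular branch segment. The *grade* is a
  diameter ratio (clinical convention), so the projected, across-vessel
  integrated signal scales with the lumen *area* ∝ D².
- *Bolus*: a 1 ml slug (length = volume/lumen area) advancing by the time
  integral of a rectified-sinusoid velocity profile (1 Hz pulse rate,
  peak 0.5 m/s; only the pump's peak velocity is specified, the profile
  shape is a modeling choice). Iron is conserved until the slug leaves the
  path.
- *Instruments*: guidewire = one point marker at the tip; balloon = two
  markers 37 mm apart along the device axis.
- *Lettering*: 5×7 block glyphs (hand-coded bitmaps, no font engine, hence
  bit-deterministic) scaled to ~60 % of the FOV width.

All generators are deterministic and conserve requested iron totals to
machine precision.

## Signal-to-image chain

**Gridding.** Each sample is accumulated (nearest neighbor, hit-count
normalized) at (row = deflection-period index, column = phase bin). After
each f₁ period the registration continues phase-exactly at the offset given
by the f₃/f₁ ratio. Per-pixel mean FFL coordinates and polarity are kept.

**Folding.** The raw image holds the FOV information four times
(rising/falling sweep × FFL polarity). Folding maps every raw pixel through
its FFL coordinates onto the unique FOV grid and averages with hit-count
weights. The default accumulates *signed*, polarity-corrected values: this
keeps the whole chain exactly linear in the tracer map (superposition holds
to machine precision), which the system-matrix inversion relies on.
Magnitude folding (available as `signed=False`) is nonlinear under
superposition (|a+b| ≠ |a|+|b|) and produced midpoint and corner ghosts for
multi-source scenes. On independent white noise the four-fold average
suppresses the noise standard deviation by ≈ 1/√4 either way.

**Harmonic band.** The default reconstruction band keeps deflection
harmonics n = 2 … (n_harmonics − 2) with |k| ≤ 40 sidebands. Starting at
n = 2 emulates the receive chain's suppression of the low-frequency region
and discards the smooth whole-structure transit burst that carries no
deflection encoding; it is also what makes the orientation artifact (below)
behave like the hardware's.

**System matrix.** One column per reconstruction pixel: the folded response
of a unit point source simulated through the identical chain. Columns keep
their relative physical scale (a single global constant normalizes the
matrix); per-column L1 sums are exposed as the position-dependent
sensitivity map, and a unit-L1 normalized view exists. Normalizing each
column individually equalizes sensitivity but amplifies the weakly-observed
FOV corners into ghost sites, so it is not the default. The reconstruction
grid covers the FOV at 4 mm pixels (desk scale) with a 15 % overscan margin
*along x only*: the encoding is periodic in z with the FFL spacing, so
z-overscan would add exactly degenerate columns (a source at z ± spacing is
indistinguishable), and it measurably mirrored edge sources. The x-margin's
purpose is absorbing tracer just outside the FOV: with it, an out-of-FOV
source misattributes ~30 % less energy into the image. For sources *inside*
the FOV the idealized twin shows no benefit from overscan (there is no
model mismatch to absorb).

**Inversion.** Regularized Kaczmarz row-action sweeps in fixed row order
with a non-negativity projection after each sweep; λ is relative to the
largest row norm (default 10⁻³), deterministic throughout. The iteration is
*semi-convergent*: at the real-time display depth (10 sweeps) faint
extended structures are still strongly attenuated; by ~50 sweeps they are
recovered; far beyond that, noise and leakage re-amplify. Two presets
encode this: `default_recon_params` (10 sweeps, real-time behavior,
artifact-faithful) and `quantitative_recon_params` (50 sweeps, used for
profile quantification).

**Multicontrast.** One data set, two parameter sets (harmonic bands and/or
regularization), same system matrix — mirroring practice, where a single
pre-calculated matrix is reused while different harmonic subsets are
collected. Point-like markers keep a far larger share of their energy in
high deflection harmonics (n ≥ 6) than an extended tracer fill (which
concentrates at n = 2, 4), so the high-band image emphasizes markers, the
low-band image the fill, and the clamped difference of the max-normalized
pair isolates one contrast.

**Stenosis grading.** The along-vessel profile integrates the
reconstruction perpendicular to the path over a band of 2× the parent
diameter (ends trimmed 12 %). Because the projected signal scales with the
lumen area, the diameter grade is estimated as 1 − √(min/median) of the
profile. On the desk-scale chain a true 70 % stenosis reads ≈0.70
(ideal-profile value 0.65 after discretization), a uniform vessel < 0.1,
and a full occlusion ≈0.9 (a ~1 % reconstruction-leakage floor keeps it
below 1.0).

**Orientation (pseudo-stenosis) artifact.** A homogeneous segment aligned
with the travel axis generates almost no interior signal — the traveling
wave slides along it and the total magnetization is nearly
translation-invariant; only the deflection harmonics weakly encode its
interior. At the real-time iteration depth such a segment reconstructs
visibly dimmer than the same segment rotated 90°, reproducing the
perpendicular-segment pseudo-stenosis artifact class of this scanner
family. A sufficiently converged noise-free inversion can undo the artifact
by amplifying the faint interior encoding, which is precisely why it is a
real-time phenomenon.

## Safety and thermal budget

All formulas are closed-form; anchors are the published operating values.
PNS: B_th,pp = ΔB_min,pp (1 + 1/(2 τ_c f)) with leg parameters 47.5 mT /
295 µs → 79.96 mT pp at 2480 Hz vs the 70 mT pp operating amplitude. SAR
scales as f²B², anchored at 0.15 W/kg for (2480 Hz, 35 mT), limit 4 W/kg.
Channel power ½RI²; note that with R = 0.5/0.6 Ω and I = 165/110 A the
formula gives 6.81/3.63 kW, whereas the published effective powers are
rounded to 6.6/3.5 kW — the per-burst temperature rises 0.41/0.18 K follow
from the *published* powers with the litz-wire copper masses
(π mm² × 90/105 m × 8.96 g/cm³) and c = 0.383 J/(g·K) over the 60 ms burst.
Convective cooling α·A·ΔT/(mc) with α = 10/30 W/(m²K) (free/forced) and a
50 K coil-air difference. The duty-cycle planner reports the sustainable
frame rate or the time to the temperature budget (e.g. ≈35 s at 4 fps for
CH1/2 with forced cooling — the same order as the published ~45 s figure,
which is not exactly recoverable from the stated constants).

## Problem sizes and determinism

The desk-scale preset keeps every physical parameter of the operating point
and reduces only the numerics: 124 kS/s sampling (50 samples per deflection
period, harmonics to order 20 alias-free), 2 mm phantom pixels, 4 mm
reconstruction pixels, 30×28 folded images. A full system-matrix build is
~1500 simulated point responses (seconds on one CPU); every stochastic
element draws from an explicitly seeded generator, and all pipelines are
bit-reproducible given (config, seed).

## What the synthetic experiments do not show

- Absolute signal amplitudes and SNR of real hardware (receive units are
  arbitrary; the noise level is a calibrated emulation, not a measurement).
- Relaxation effects (static Langevin only), coil-geometry field
  inhomogeneity, receive-coil sensitivity profiles, and EMI structure of an
  unshielded environment.
- Real-time latency and frame-rate engineering claims.
- 3D anatomy: phantoms are analytic projections, not CT-derived meshes; an
  elastic vessel's mechanical response to balloon dilation is not modeled.
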