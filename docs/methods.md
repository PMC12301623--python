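# Methods

## Scope and measurement model

`catheter_psoct` simulates and inverts catheter-based polarization-sensitive
OCT (PS-OCT) of deep-brain tissue along a straight, vertical insertion
trajectory, the acquisition geometry used for deep-brain-stimulation-style
probes: a fiber probe rotating inside a transparent protective sheath
(2.3 mm outer diameter) performs a helical scan while being pulled back at
5 mm/s with 25 rotations/s, i.e. a 0.2 mm helical pitch, 115 frames over a
23 mm pullback, at a 1300 nm center wavelength.

Polarization is handled in the Stokes/Poincaré formalism. Tissue is assumed
purely linearly retarding (no diattenuation or depolarization), so every
one-pixel tissue layer is an SO(3) rotation about an equatorial Poincaré
axis `(cos 2θ, sin 2θ, 0)`, where θ is the optic-axis orientation (degrees,
mod 180) in the plane transverse to the beam and the rotation angle is the
double-pass retardance of that pixel, `δ = 2π·Δn·|f⊥|²·(2Δz)/λ₀`. `|f⊥|²` is
the squared transverse component of the fiber direction: fibers orthogonal
to the beam produce the full birefringence, fibers along the beam none.

Per A-line at azimuth α the one-way stack is `P(z) = L₁···L_z` (sheath
retarder first, then tissue pixels); the round trip is
`C(z) = P(z)·dT(P(z))` with the reciprocity operator
`dT(R) = D Rᵀ D, D = diag(1, 1, −1)`. The catheter and system transmission
conjugates the measurement: `R_meas(z) = dT(T(α))·C(z)·T(α)`. The simulator
lifts `R_meas` to SU(2) (half-angle lift, global phase fixed to zero — Stokes
processing is phase-insensitive) and applies it to the two alternating input
Jones states (horizontal and +45°, orthogonal on the Poincaré sphere),
scaling by class-dependent scattering amplitude with exponential attenuation,
one circular-Gaussian speckle factor per (depth pixel, A-line pair) shared by
both detection channels — speckle randomizes amplitude and phase but not the
polarization state, which is exactly the structure the Gaussian filtering
stage averages over — plus additive circular-Gaussian detector noise.

A useful identity: `dT(T)·C·T` is D-transpose symmetric for *any* rotation
T, because `dT` reverses products and fixes `C`. Consequently (a) the
symmetry-restoration stage cannot identify T from the asymmetry alone (the
objective is flat along conjugations by linear retarders), and (b) the full
effect of a circular transmission component `T = R_v(2φ)` is a rigid
orientation offset −φ on every reported layer, sheath included. That is why
the sheath "guide star" — a retarder of known orientation in the probe
frame — recovers absolute orientation: its apparent-minus-known orientation
per A-line *is* the offset.

## Reconstruction chain

1. **Stokes estimation** (`compute_stokes`): per detection-channel pair,
   `q = (|h|²−|v|²)/I`, `u = 2Re(h v̄)/I`, `v = −2Im(h v̄)/I`; adjacent
   A-lines are paired into the two probing states. Intensity-weighted Stokes
   components are smoothed with a separable Gaussian — axial σ = 3 depth
   pixels, lateral σ = 2 A-line pairs (wrapping in azimuth) — then
   renormalized; the ratio of the filtered polarized magnitude to the
   filtered intensity is the degree of polarization (DOP).
   *Why axial σ = 3:* the layer-peeling derivative below differentiates the
   cumulative rotation over a single 4.8 μm pixel, whose true WM rotation
   angle is only ≈ 0.5°; with realistic speckle/detector noise the per-pixel
   angular error is of the same order, and because an estimated angle is
   non-negative the noise *inflates* retardance in non-birefringent tissue
   until the WM/GM contrast disappears. Three pixels of axial correlation
   (14 μm, comparable to the ~9 μm axial resolution) restore the contrast
   without measurably biasing the recovered plateau values.
2. **Cumulative rotation** (`estimate_cumulative`): the unique rotation
   mapping the known input-state triad to the measured (Gram-Schmidt
   orthogonalized) output triad; pixels with DOP < 0.7 or intensity below
   the noise floor (10× the detector-noise intensity) are masked.
3. **Transmission compensation** (`compensate_transmission`): a correction
   rotation V̂ per coarse (A-line-pair, frame) block minimizes
   `‖dT(Ĉ)−Ĉ‖²_F` over the depths of a window, `Ĉ = dT(V̂)⁻¹·C_meas·V̂⁻¹`,
   with a small ridge penalty toward the identity because of the flat
   directions noted above. In this measurement model the stage is a
   symmetry/quality gate (residual asymmetry is stored); rotation angles —
   hence retardance — are invariant under the conjugation by construction.
4. **Layer peeling** (`peel_layers`): with `P(0) = I`,
   `N(z+1) = Ĉ(z+1)·Ĉ(z)⁻¹ = P(z)·L²·P(z)⁻¹`; half the rotation angle of N
   is the local double-pass retardance (reported in deg/100 μm), and
   `P(z)⁻¹` applied to its axis, projected to the equator, gives the
   apparent orientation (halved azimuth). `P` is advanced by the estimated
   layer; masked depths carry `P` forward unchanged so signal-free gaps do
   not accumulate error. Orientation is additionally masked below a local
   retardance floor of 5 deg/100 μm (orientation of a near-identity rotation
   is meaningless).
5. **Guide star** (`guide_star_correct`): per A-line, the
   retardance-weighted circular mean (period 180°) of orientation over the
   sheath band minus the known sheath orientation gives the offset φ(α),
   circularly smoothed along azimuth (default window 15 pairs; reduced-scale
   runs shrink it proportionally, since a window spanning a large fraction
   of the rotation averages the offset away). A-lines without a detectable
   sheath (mean band retardance < 1 deg/100 μm) are filled from azimuthal
   neighbors and flagged. Absolute orientation = apparent − φ(α) mod 180°.
6. **Sign convention**: brain white matter is negatively birefringent, so
   the measured optic axis is perpendicular to the fiber. The simulator adds
   90° to the retarder axis when the phantom sign is −1, and the
   reconstruction's `negative_birefringence` flag (default on) folds the
   reported orientation back, so 0° always means *fiber oriented
   circumferentially* in the probe frame — matching the colormap convention
   (hue = orientation with 0° = blue, brightness = retardance). Toggling
   only the reconstruction flag shifts every reported orientation by
   exactly 90°.

## Synthetic phantom and MRI rendering

The phantom is a stack of slabs transverse to the trajectory (anatomy is
deliberately simplified; the acceptance surface is parameter recovery):
cortical GM 0–2 mm, subcortical WM 2–10 mm, deep GM 10–23 mm containing a
2 mm tract at 13–15 mm standing in for the internal capsule. Defaults:
Δn = 2·10⁻⁴ (WM), 5·10⁻⁴ (tract), 0 (GM) — configurable placeholders on the
order of reported brain-WM birefringence; WM fibers run circumferentially
around the trajectory (evaluated analytically at sample positions, so the
response is azimuth-independent — the configuration in which the forward
model is exactly invertible at any azimuth sampling), while the tract fiber
is lab-fixed horizontal, producing the characteristic two-lobe en-face
signature (beam ⊥ fiber at exactly two azimuths 180° apart).

The matched MRI-like volume is a 0.57 mm isotropic T1-weighted-style
rendering: each MRI voxel is the *exact* volume-weighted average of class
intensities (WM 1.0, tract 1.0, cortex 0.55, deep GM 0.5) over the phantom
voxels it covers — the partial-volume mixing that limits boundary
localization to about one voxel — plus seeded Gaussian noise (σ = 0.02).

Noise defaults (chosen once as realistic study conditions): detector noise
σ = 0.02 per field quadrature (≈34 dB SNR at the tissue surface, decaying
with the 0.5 mm⁻¹ attenuation default), fully developed speckle,
transmission offset 40° amplitude (one cycle per rotation) plus a 10° slow
drift across the pullback, evaluated at pair-center azimuth because the
offset varies slowly compared with the 50 kHz A-line rate. The sheath
retarder: 200 μm thick, 0.3 rad total retardance spread uniformly over its
band, orientation 0° in the probe frame.

What the generator does **not** emulate: Fourier-domain interferogram
synthesis, dispersion and k-clock effects, non-uniform rotational
distortion, diattenuation/depolarization and multiple scattering,
crossing or sub-resolution interwoven fibers, out-of-plane optic-axis
components (the projection is purely in-plane), and anatomically shaped
tissue. Passing recovery tests therefore demonstrate the correctness of the
algebraic inversion chain under its stated assumptions, not robustness to
every artifact of real catheter data.

## Co-registration and barcodes

The en-face carpet samples the reconstruction 300 μm outside the sheath,
averaging a ±2 pixel depth band (validity-weighted mean for retardance and
intensity, circular mean for orientation). Rows are frames (0.2 mm pitch),
columns azimuth. The MRI ROI is a 5×5-voxel cube along the trajectory — 9
central pixels covering the catheter track, 16 perimeter pixels whose
9.12 mm ring path approximates the carpet circumference — unfolded by a
fixed counterclockwise walk starting at the +x ring pixel; the 9 central
pixels are extracted but feed no statistic. Carpet row j maps to MRI slice
`floor(j·pitch / 0.57)` (slice k covers `[k·h, (k+1)·h)`), nearest-neighbor
with no resampling. Exact azimuthal registration of carpet columns to
anatomical directions is out of scope; the unfolding order is a convention.

Barcodes: per-row means over unmasked columns (rows with <25% valid columns
are flagged; empty rows are interpolated), exact 1-D 2-means on the profile
(optimal 2-partitions of scalars are contiguous in sorted order, so a
threshold scan with prefix sums finds the global optimum deterministically —
randomized Lloyd iterations are not guaranteed to), binary threshold at the
midpoint of the two cluster centers (ties to the low class), high cluster =
WM-like for both modalities. The comparison reports row-wise agreement
through the longitudinal map, per-class Dice, and transition positions.

## Numerical choices

- SO(3) logs/exps go through `scipy.spatial.transform.Rotation`; at rotation
  angle π the axis sign is fixed by making the first component of magnitude
  > 1e−9 positive. The zero rotation maps to axis (1,0,0) by convention.
- Orthogonalization of measured state pairs: normalize state 1, Gram-Schmidt
  state 2 against it; degenerate pairs are masked, not raised.
- Circular statistics on orientations always use angle doubling (period
  180°).
- The compensation optimizer is Levenberg–Marquardt on a 3-parameter
  rotation vector, ridge weight 1e−3, warm-started from the previous
  A-line, with depth subsampling beyond 64 valid depths; non-convergence
  falls back to the previous estimate.
- All randomness flows from one seed through named per-stage
  `numpy.random.SeedSequence` substreams.

## Problem sizes

Desk-scale runs keep the full printed geometry where it is the point (115
frames over 23 mm; ROI geometry at 0.57 mm) and reduce what is free:
noise-free oracle checks use 32 A-lines/frame on 6 mm pullbacks with filter
widths 0 (no speckle to average); the speckle guide-star check keeps the
default 512 A-lines/frame — the offset gradient per A-line pair must stay
small relative to the lateral filter — on a 2 mm WM pullback over 10 seeds;
the barcode check runs the full 23 mm phantom at 64 A-lines/frame over 10
seeds. The full 2048 A-lines/frame acquisition is available via
configuration (`--full-scale`).

## Known limitations

- With the spec's conjugation-form transmission model the compensation
  stage cannot (and need not) estimate T; a measurement model with distinct
  illumination/detection paths would give it independent work.
- Orientation accuracy degrades when the azimuthal offset gradient is large
  relative to the lateral filter width (coarse A-line sampling); the
  default sampling keeps this negligible.
- The local-retardance estimator is positively biased in low-birefringence
  tissue at low SNR; the axial filter width controls this trade-off.
- Only grid-axis-aligned trajectories are supported; oblique trajectories
  and real MRI-to-MRI registration are out of scope.
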