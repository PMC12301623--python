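# catheter-psoct

Simulation and reconstruction pipeline for **catheter-based
polarization-sensitive OCT (PS-OCT) of deep-brain tissue**, aimed at the
instrumentation/neurophotonics setting where a rotating fiber probe is
inserted along a deep-brain-stimulation-style trajectory and pulled back
through cortex, white matter and deep nuclei. White matter's densely packed
fibers are birefringent; depth-resolved PS-OCT therefore maps both a scalar
birefringence (local retardance) and the in-plane fiber orientation
(optic axis) along the insertion path, at micrometer resolution that MRI
cannot match. The package provides:

- a physics-based synthetic pullback simulator (layered GM/WM phantom with
  per-voxel birefringence and 3-D fiber direction, rotating 2.3 mm catheter
  with a birefringent sheath, per-A-line transmission offsets, speckle, and
  a matched 0.57 mm T1-like MRI rendering with partial-volume mixing);
- the full inversion chain: Stokes estimation with spectral binning and
  Gaussian filtering, cumulative retardance/rotation retrieval,
  catheter/system transmission compensation, one-pixel layer peeling, and
  **guide-star** absolute optic-axis correction using the catheter sheath;
- en-face *carpet views* (rows = pullback position, columns = azimuth), the
  unfolded 5×5-voxel MRI ROI along the trajectory, their longitudinal
  co-registration, and binary WM/GM **tissue barcodes** from 2-means
  clustering of the longitudinal profiles.

Because no real pullback is required, every stage is verified by
forward-simulate-then-invert parameter recovery against ground truth.

## The model in brief

Stokes vectors live on the Poincaré sphere; a linearly retarding tissue
pixel is a rotation by the double-pass retardance
δ = 2π·Δn·|f⊥|²·(2Δz)/λ₀ about the equatorial axis (cos 2θ, sin 2θ, 0).
With the one-way stack P(z) = L₁···L_z, the measured round trip is

    R_meas(z) = dT(T(α)) · P(z)·dT(P(z)) · T(α),     dT(R) = D Rᵀ D,  D = diag(1,1,−1)

where T(α) is the rotating catheter's transmission. Layer peeling inverts
the cumulative rotations depth by depth,
N(z+1) = Ĉ(z+1)·Ĉ(z)⁻¹ = P(z)·L²·P(z)⁻¹, and the sheath — a retarder of
known orientation in the probe frame — acts as a guide star: its apparent
minus known orientation per A-line is exactly the offset φ(α) that the
rotating catheter imposes on all reported orientations, which is then
subtracted to obtain the absolute optic axis. Conventions: orientation is
reported mod 180° with 0° = circumferential fiber; brain WM is treated as
negatively birefringent (the measured axis is fiber + 90°, folded back at
reporting time). See `docs/methods.md` for the complete account.

## Worked example

The numbered scripts under `analysis/` run the whole study at desk scale
(64 A-lines/frame; outputs under `results/pipeline/`):

```bash
python analysis/01_simulate_pullback.py
python analysis/02_reconstruct_birefringence.py
python analysis/03_carpet_views_and_mri_roi.py
python analysis/04_tissue_barcodes.py
```

which prints, for the default 23 mm phantom (cortex 0–2 mm, subcortical WM
2–10 mm, deep GM with a 13–15 mm internal-capsule-like tract):

```
frames: 115 (pitch 0.20 mm over 23 mm)
sheath band: depth pixels 0..42
guide-star offset range: -45.7 .. 36.0 deg (periodic catheter-rotation term + slow drift)
median local retardance over birefringent pixels: 10.1 deg/100um
carpet: 115 rows x 32 azimuth columns (pitch 0.20 mm, depth offset 300 um outside the sheath)
unfolded MRI ROI: 37 slices x 16 perimeter pixels (9.12 mm ring path)
PS-OCT/MRI barcode agreement: 0.972 over 106 rows
transitions (mm from cortical entry):
  PS-OCT: [2.0, 10.2, 13.2, 15.2]
  MRI:    [1.71, 10.26, 13.11, 14.82]
```

Reading this: the reconstruction recovered the catheter's azimuth-varying
orientation offset (the ±40-ish° guide-star series), WM reads ≈10 deg/100 μm
local retardance while GM stays near zero, the 115-row carpet co-registers
with 37 MRI slices over 21 mm, and the two tissue barcodes place all four
GM/WM transitions within one MRI voxel (0.57 mm) of each other — the
partial-volume-limited agreement expected at MRI resolution.

The same pipeline is scriptable via the CLI, e.g.:

```bash
catheter-psoct run phantom --out results/run --seed 1
catheter-psoct pipeline --seed 1 --out results/run   # all stages
```

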