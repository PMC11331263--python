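# Methods

`holoqpi` simulates and reconstructs common-path off-axis lensless digital
holograms and derives quantitative-phase observables from them.  This note
records the model, the numerical choices, and what the synthetic scenes do
and do not establish about real recordings.

## Optical model

The instrument is a point-source (divergent illumination) lensless
microscope with spatial multiplexing.  A grating upstream of the sample
splits the beam into laterally separated point sources (separation
`d = N·λ·f_FL′`); the sample plane is divided into three horizontal bands —
blocked (x), object (o), and reference (r) — so light through the empty r
band reaches the sensor as a tilted reference wave and interferes with the
Fresnel diffraction pattern of the o band, writing a carrier fringe onto a
single-shot hologram.  The system constants are

* magnification `M = (z1 + z2)/z1` — 11× at the reference geometry
  (z1 = 1.0 mm, z2 = 10.0 mm);
* object-plane field of view `L·p/M` per side — 446.84 µm (displayed
  rounded to 447 µm) for L = 1024 pixels of 4.8 µm pitch;
* diffraction-limited resolution `ρ = 2·λ·z2/(L·p)` — 2.0955 µm at
  λ = 515 nm.  (Published descriptions of this geometry quote
  ρ = 2.16 ± 0.02 µm; the stated parameter set evaluates to 2.0955 µm, and
  the package returns the formula value.  The parameter set producing 2.16
  is not stated anywhere we could verify, so the discrepancy is documented
  rather than reproduced.)

Divergent illumination is handled throughout by the Fresnel-scaling
equivalence: recording over (z1, z2) with a point source equals collimated
recording over `z_eff = z1·z2/(z1+z2) = z2/M` on a grid of pitch `p/M`.
This avoids sampling a steep spherical phase on the grid and is exact for
the on-axis beam.

## Propagation

Free-space propagation uses the exact (non-paraxial) angular-spectrum
transfer function `exp(i·2π·z·sqrt(λ⁻² − f²))` with evanescent components
truncated.  Propagation conserves power to 1e−10 (relative) while all
content propagates, inverts to 1e−8, and composes additively — these are
asserted as property tests.  A guard band (default L/8 pixels,
edge-replicated) suppresses the FFT propagator's periodic wrap-around;
edge replication continues the unit background rather than creating an
artificial aperture.

## Recording model

The simulator multiplies the object transmittance by the multiplexed band
layout (blocked band zeroed), propagates `z_eff`, and interferes with an
analytic tilted plane reference, optionally multiplied by a Zernike
primary-coma phase `coeff·(3ρ³ − 2ρ)·cos θ` (ρ normalised to the grid
half-diagonal) standing for the aberration the reference picks up by
crossing the focusing lens off-axis.  Shot noise is Poisson with a mean
photon budget per pixel; quantisation is uniform (8/16 bit) with the frame
maximum at full scale and the scale recorded so reconstruction stays
gain-aware.  No read noise is modelled.

**Carrier frequency.**  The experimental carrier is not stated in published
descriptions, but the grating geometry implies one: sources separated by
0.51 mm at z1 + z2 = 11 mm give a fringe period of ≈2.3 sensor pixels —
near Nyquist.  The passband available to the demodulator is the filter
radius, by default half the carrier→DC distance; a carrier of (L/8, L/8)
cycles per field would cap the usable passband at periods ≳5 µm, below
what the instrument demonstrably resolves (a 4.38 µm three-bar group).
The default carrier is therefore (L/4, L/4) cycles per field — a ≈2.8-px
diagonal fringe, in the near-Nyquist regime the physical grating produces —
giving a demodulation cutoff of ≈0.41 cycles/µm (period ≈2.5 µm),
consistent with both the resolved 4.38 µm element and the ≈2.1 µm
diffraction estimate.  Carrier and filter radius remain explicit knobs.

## Reconstruction chain

1. centred FFT of the hologram;
2. carrier detection: strongest upper-half-plane peak outside a DC
   exclusion disk, refined by a 3×3 magnitude centroid (the refinement can
   absorb the centroid of an aberrated sideband into a sub-bin offset; the
   resulting linear ramp is common to object and blank and cancels in the
   division);
3. Fourier filtering: hard-edged disk (cosine taper optional) of radius
   half the carrier distance, integer-bin roll to baseband plus a residual
   sub-bin ramp; the upper sideband holds the conjugate cross term
   `O*·R`, so the filtered wave is conjugated to give the object wave;
4. numerical refocusing by `−z_eff` (or autofocus);
5. compensation: complex division by the blank-hologram wave with the
   blank amplitude floored at 5 % of its maximum;
6. background removal: least-squares plane over background pixels (by
   default: object-band pixels below the Otsu threshold of |phase|), then
   median-zeroing;
7. optional 2-D unwrapping (reliability-sorted).

**Compensation plane.**  The classical order divides at the sensor plane
and then refocuses.  Band-pass filtering does not commute with complex
division, and the blank of a multiplexed field carries a sharp structure —
the blocking edge — inside the frame.  Sensor-plane division then leaves
≈0.09 rad RMS of residual fringes across the field and a +0.2 rad bias at
a bead apex (measured, noise-free); dividing the two *refocused* fields
instead leaves 0.006 rad RMS and a −0.05 rad apex bias.  The default is
therefore image-plane compensation; `compensation="sensor_plane"` restores
the classical order, appropriate when the blank holds only smooth
aberrations.  The `compensate` operation itself is plane-agnostic complex
division and is exact for identical inputs.

**Autofocus.**  Focus metrics are evaluated on the central half of the
field, normalised by mean amplitude (hence gain-invariant).  The default
`contrast` metric *maximises* the amplitude standard deviation: steep
phase objects (beads, suspended cells) diffract a dark rim exactly at
focus, so their amplitude contrast peaks there — measured profiles confirm
this, and minimising (the classical weak-phase criterion, retained as
`amplitude_std`) diverges to the scan edge for such objects.  A coarse
scan brackets the optimum and bounded scalar minimisation refines it to
10⁻³ of the scan range; flat or edge-sitting profiles return a warning.

**Accuracy.**  Against the raw ground truth a noise-free 9.8 µm bead
reconstructs with ≈0.12 rad RMS inside its support — dominated by the
demodulation passband acting on the bead's sub-resolution rim, as shown by
comparing with the band-limited truth, against which the chain is accurate
to 0.020 rad RMS.  A smooth phase object (correlation length ≥ 2ρ)
reconstructs to 0.007 rad RMS against raw truth.  Tests assert both
figures at a 0.05 rad bound.

## Quantitative phase analysis

Thickness follows `d = Δθ·λ/(2π·Δn)`.  The bead validation converts the
reconstructed phase of a simulated 9.8 µm PMMA sphere (n = 1.494) in
90/10 glycerol-water (n = 1.458) and reports the mean ± SD of the 10
thickest pixels inside the largest segmented component; at 10⁴
photons/pixel this yields 9.65–9.68 µm across seeds, inside the
9.7 ± 0.2 µm band measured on the physical instrument.

Per-cell features over a segment of projected area S with mean phase Δφ̄:
`R = sqrt(S/π)`; dry mass `DM = 10·λ·Δφ̄·S/(2π·β)` with β = 0.002 m³/kg
(together equivalent to the conventional refractive-index increment
0.2 ml/g); mean thickness `h̄ = 4R/3` (sphere volume over projected area);
integral refractive index `n = n_medium + Δφ̄·λ/(2π·h̄)`.  The radius
definition takes the square root of S/π as the evident intent of the
area-to-radius conversion for a disk of area S.

**Segmentation and the cap-fit refinement.**  Detection uses Otsu's
threshold on the phase map (object band only — the blocked band carries no
light).  For a spherical cell the Otsu threshold has a closed-form
location: in the small-foreground limit the between-class variance is
maximised at u = τ/φ_peak solving 2u³ − 3u + 1 = 0, i.e. u = (√3 − 1)/2 ≈
0.366.  Cutting a hemispherical phase profile at 0.37 of its peak discards
the outer ≈7 % of the projected radius, which propagates to ≈+0.005 in the
integral RI — measured: R −7.0 %, n +0.0045 on a noise-free cell.  Since
the downstream formulas assume the full projected disk, the flow pipeline
by default refines each detected cell's support by a least-squares fit of
the spherical-cap model `φ0·sqrt(1 − ρ²/R²)` (the same spherical-shape
assumption behind h̄ = 4R/3) and feeds the fitted disk to the feature
formulas; measured recovery is then R −0.1 %, n −0.0003, DM −1.4 %.
`refine="none"` restores raw-Otsu features.

**Flow pipeline.**  The blank is demodulated and refocused once and reused
across the stack.  Per frame: reconstruct → segment → flag (border within
2 px of the frame edge; clustered when solidity < 0.9 or equivalent radius
exceeds a gate — two disks merging at ≈2R separation drop below 0.9
solidity, while moderate overlaps are caught by the radius gate) →
features.  Detections in consecutive frames within one cell radius are
linked into tracks; tracks shorter than 3 detections are dropped as noise;
each accepted track contributes the record of its maximal-solidity
unflagged frame.  A per-frame counting mode is available instead of
linking.  Summary statistics are mean ± standard error over accepted
cells.

## Synthetic scenes

* **Sphere** — phase-only chord-thickness transmittance; ground truth is
  the thickness map.
* **Three-bar targets** — binary amplitude bars (duty 1/2) at USAF-chart
  periods; resolution is scored by Michelson contrast between bar and
  inner-gap windows of a profile averaged along the bars, resolved at
  C ≥ 0.2.  The smallest resolved period in the noise-free sweep is
  2.19 µm; contrast at the finest periods is genuine finite-target
  diffraction (the sinc-broadened fundamental of a 3-bar group partially
  enters the passband), not autocorrelation-term leakage (verified by
  varying the reference amplitude).
* **Adherent blob** — Gaussian-correlated texture (autocorrelation 1/e
  radius = the requested correlation length) under a smooth confinement
  envelope, rectified and scaled to a peak phase; ground truth is the
  phase map.
* **Flow scene** — spherical cells with clipped-Gaussian radii
  (8.64 ± 0.4 µm) and integral RIs (1.366 ± 0.002) in medium n = 1.339,
  advected along a hydrodynamically focused single-file lane (±3 µm
  lateral jitter) at 10 object-pixels/frame; arrivals are Poisson
  (0.25/frame) thinned to a 3-radius headway, as sheath focusing enforces
  physically.  Every cell's radius, RI, entry frame and per-frame position
  are recorded as ground truth.  The parameter-recovery experiment uses
  470 frames (≈12 s at the 40 fps the instrument records), yielding ≥50
  fully transited cells.

What these scenes do not emulate: speckle from out-of-plane scatterers,
read noise, grating higher orders, illumination-amplitude structure,
non-spherical or internally structured cells, and cell deformation in
flow.  Passing tests therefore establish the correctness and calibration
of the processing chain, not the biological fidelity of the scene.

## Temporal stability

For a stack of phase maps of a static scene the package computes the
frame-mean drift `Δφ̄(t) = φ̄(t) − φ̄(0)` and the per-pixel statistic
`σt = sqrt((1/T)·Σ_t [φ(t) − φ(0)]²)` — the frame-0-referenced RMS with
divisor T, matching the form in which this figure is conventionally
printed for such instruments.  For i.i.d. noise it converges to σ√2, and
under shot noise it scales as photons^(−1/2) (both asserted).  A
conventional temporal standard deviation (about the temporal mean,
divisor T−1) is available as `mode="temporal"`.  The default ROI is a
centred 300×300 px window.  The absolute σ̄t of a physical bench is
hardware-dependent and is not a target of the synthetic tests; only the
estimator's statistical behaviour is validated.

## Numerical choices and degenerate inputs

* All lengths SI metres internally; configuration values may carry unit
  suffixes and are normalised on load.
* Grid: pixel-centred, origin at the centre pixel; spectra centred.
* Amplitude floor in compensation: 5 % of the blank maximum (exposed).
* Filter radius default: half the carrier→DC distance, guaranteeing DC
  exclusion; the disk must not touch DC or the spectrum edge (errors).
* Carrier detection requires the peak to exceed 3× the half-plane median;
  an in-line hologram (no carrier) raises rather than demodulating noise.
* Constant images cannot be Otsu-thresholded (error); near-constant phase
  maps fall back to whole-field background fitting.
* Sub-Nyquist bar periods and spheres below two object pixels are scene
  errors; objects must fit inside the object band.
* Reproducibility: every stochastic draw derives from an integer seed
  (frames seeded as (seed, frame index)); identical seeds give
  bit-identical holograms, tables and files.

## Known limitations

* The multiplexed layout devotes one third of the field to the object;
  scenes wider than the o band are rejected rather than wrapped.
* Image-plane compensation assumes the blank and object share the focus
  distance; strongly defocus-dependent aberrations would favour
  sensor-plane mode.
* The cap-fit refinement assumes near-spherical cells, as does the
  h̄ = 4R/3 thickness model; both bias adherent, spread cells, for which
  the raw-Otsu mode and thickness maps are the appropriate outputs.
* At fields below ≈512 px the 9.8 µm bead's scatter cone outgrows the
  frame and reconstruction accuracy degrades; accuracy figures are quoted
  at L = 1024.
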