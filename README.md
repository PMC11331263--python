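# holoqpi

Simulation, reconstruction and quantitative phase analysis for **lensless
common-path off-axis digital holographic microscopy**.

Lensless holographic microscopes record the Fresnel diffraction pattern of
a sample illuminated by a point source, with no imaging lens between
sample and sensor.  The classical in-line arrangement suffers from the
*twin image*: the out-of-focus conjugate term overlaps the focused
reconstruction and corrupts quantitative phase.  A common-path off-axis
variant fixes this with a single diffraction grating: the grating creates
laterally separated point sources, the sample plane is spatially
multiplexed into an object band and an empty reference band, and light
through the reference band arrives at the sensor tilted — writing a
carrier fringe that separates the object term in the Fourier domain.  One
shot then yields twin-image-free quantitative phase imaging (QPI), fast
enough for imaging flow cytometry of living cells.

`holoqpi` provides, as a library and a CLI:

* **geometry** — the closed-form system relations: magnification
  `M = (z1+z2)/z1`, field of view `L·p/M`, diffraction-limited resolution
  `ρ = 2λz2/(Lp)`, grating source separation `N·λ·f′`, and the
  Fresnel-scaling equivalent geometry (`z_eff = z2/M`, pitch `p/M`);
* **wavefield** — exact angular-spectrum propagation, tilted plane waves,
  Zernike primary coma;
* **simulate** — synthetic scenes with full ground truth (PMMA
  microspheres, USAF-style three-bar targets, adherent-cell phase blobs,
  suspended cells in microfluidic flow) recorded as off-axis or in-line
  holograms with shot noise and quantisation;
* **reconstruct** — Fourier filtering and carrier demodulation,
  blank-hologram aberration compensation, numerical refocusing with
  autofocus, background-plane removal, 2-D phase unwrapping;
* **qpi** — phase→thickness maps, Otsu segmentation, per-cell biophysics
  (projected radius `R = sqrt(S/π)`, dry mass `DM = 10λΔφ̄S/(2πβ)`,
  integral refractive index `n = n_medium + Δφ̄λ/(2πh̄)` with `h̄ = 4R/3`),
  maximum-intensity projection, and a batch flow-cytometry pipeline with
  cell tracking;
* **stability** — temporal phase-stability statistics (frame-mean drift
  and the per-pixel frame-0-referenced RMS map σt).

See `docs/methods.md` for the model, numerical choices and limitations.

## Worked example

Simulate a 9.8 µm PMMA microsphere (n = 1.494) immersed in 90/10
glycerol-water (n = 1.458), record an off-axis hologram at the reference
geometry (λ = 515 nm, z1 = 1 mm, z2 = 10 mm, 1024² px of 4.8 µm), and
recover its thickness:

```python
import holoqpi as h
from holoqpi.qpi import PMMA_IN_GLYCEROL_WATER, measure_bead_thickness

cfg = h.default_geometry()
print(cfg.magnification, cfg.fov_side_um_rounded)   # 11.0 447

mat = PMMA_IN_GLYCEROL_WATER
obj, truth = h.sphere_transmittance(cfg, radius=4.9e-6, delta_n=mat.delta_n)
holo  = h.record_hologram(obj, cfg, photons=1e4, bits=16, seed=1)
blank = h.blank_hologram(cfg, photons=1e4, bits=16, seed=2)

q = h.reconstruct_hologram(holo, blank=blank, unwrap=True)
d_mean, d_std = measure_bead_thickness(q.phase, cfg, mat, k=10)
print(f"d_max = {d_mean*1e6:.2f} ± {d_std*1e6:.2f} µm")
```

which prints

```
11.0 447
d_max = 9.68 ± 0.05 µm
```

— the magnification and rounded field of view of the reference geometry,
and the bead's maximum thickness (mean ± SD of the ten thickest pixels
inside the segmented bead), recovering the 9.8 µm diameter through the
full holographic chain at a realistic photon budget.

The same chain drives the CLI:

```bash
holoqpi simulate --scene sphere --photons 10000 --bits 16 --seed 1 --out run/
holoqpi reconstruct --hologram run/holograms.tiff --blank run/blank.tiff --out run/rec/
holoqpi flow --stack flow.tiff --blank blank.tiff --material cells --out run/flow/
holoqpi stability --stack series.tiff --blank blank.tiff --out run/stab/
```

Every run writes a `manifest.json` with content hashes and the fully
resolved configuration; identical seeds reproduce outputs byte for byte.

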