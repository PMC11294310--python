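# phantomiq

Tube-phantom simulation and edge-profile image-quality metrics for
photon-counting-detector CT angiography (PCD-CTA) reconstructions.

Lower-leg CT angiography lives or dies on whether sub-millimetre vessel walls
and plaques survive the reconstruction: a soft kernel blurs the contrast-filled
lumen over the wall ("blooming"), an ultrasharp kernel drowns it in noise, and
iterative reconstruction (QIR) trades noise against possible smoothing.
`phantomiq` is for imaging physicists and methodologists who want to study
that trade-off quantitatively: it simulates axial slices of a silicone-tube
vessel phantom (inner diameter 1–5 mm, 1 mm wall, iodine dilutions
0–37 mg I/mL) under any reconstruction kernel, QIR level and dose, and
measures them with an edge-profile analysis chain whose endpoint is a 0–8
**slope score** — the number of water↔wall and wall↔lumen boundaries that
produce their own slope maximum above the noise level.

The core models:

- **Kernel MTF** from its two printed anchors:
  `MTF(ρ) = 1/(1 + (ρ/ρ₅₀)^b)`, `b = ln 9 / ln(ρ₁₀/ρ₅₀)` — closed form,
  monotone, flat quantitative passband.  Nyquist limit of the 0.4 mm grid:
  ρ_max = 12.5 Lp/cm.
- **Noise**: SD = anchor(sharpness; QIR-3, 3 mGy) × QIR ratio × √(3/CTDI),
  synthesised as a stationary field with power spectrum ∝ ρ·MTF(ρ)².
- **Slope analysis**: 128² crop → corner-ROI noise SD → 64² crop → 4-pixel
  averaged profiles → 3-point regression slopes (≡ central difference) →
  directional slope maxima at the eight nominal boundaries → amplitude, mean
  slope maximum, slope score.
- **Reader statistics**: exact paired Wilcoxon signed-rank (tie-safe, zeros
  discarded) with Bonferroni correction, ordinal Krippendorff's α with the
  0.2/0.4/0.6/0.8 interpretation bands, and a latent-Gaussian simulator of
  3 readers × 20 patients × 9 reconstructions Likert sessions.

## Worked example

```python
from phantomiq import (AcquisitionSpec, PhantomSpec, analyze_image,
                       kernel_from_table, simulate_slice)

phantom = PhantomSpec(inner_diameter=3.0, iodine_concentration=37.0)
kernel  = kernel_from_table("Qr60")              # rho50 8.8, rho10 11.2 Lp/cm
acq     = AcquisitionSpec(ctdi=30.0, qir_level=4)

image  = simulate_slice(phantom, kernel, acq, seed=1)
result = analyze_image(image, phantom)
print(f"noise {result.noise_sd:.1f} HU, amplitude {result.amplitude:.0f} HU, "
      f"mean slope max {result.mean_slope_maximum:.0f} HU/mm, "
      f"score {result.slope_score}/8")
```

prints

```
noise 7.8 HU, amplitude 2083 HU, mean slope max 1857 HU/mm, score 8/8
```

The 2000 HU lumen stands 2083 HU above water (slight edge overshoot is
physical for band-limited kernels), the wall edges slope at ~1860 HU/mm, and
all eight boundaries are individually resolved — at 30 mGy and QIR-4 the
sharp kernel separates a 1 mm wall from a fully opacified 3 mm lumen.  Rerun
with `kernel_from_table("Qr36")` and the score drops to 4: the soft kernel
blooms the lumen over the wall.  Fill with `iodine_concentration=9.25` — the
dilution that iso-attenuates with silicone — and every kernel scores 4,
because the wall-lumen boundary has no contrast to detect.

The `examples/` scripts walk each capability: `01_kernel_mtf.py` (MTF fits,
Nyquist, noise model), `02_simulate_and_analyze.py` (the example above with
the full transition table), `03_parameter_sweep.py` (factorial sweep, noise
and plateau summaries, per-dose score grids), `04_reader_agreement.py`
(synthetic Likert session, α per criterion, Bonferroni-corrected Wilcoxon
comparisons).  Slices export to TIFF/DICOM via `phantomiq.image_io`, and any
2D TIFF/DICOM slice with known pixel spacing can be loaded and analysed.

## Layout

```
src/phantomiq/
  kernel_model.py    MTF fits, Nyquist, noise & slope-difference models
  phantom_sim.py     rasterization, MTF blurring, shaped noise, slice synthesis
  edge_metrics.py    crops, ROI noise, profiles, slopes, transitions, score
  sweep_pipeline.py  factorial runner, plateau summary, score grids
  reader_stats.py    Wilcoxon, Krippendorff's alpha, Likert simulator
  image_io.py        TIFF/DICOM export-import, provenance manifests
  data/              kernel table and Likert score-profile CSVs
docs/methods.md      models, assumptions, numerical choices, limitations
```
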