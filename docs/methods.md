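# Methods

`phantomiq` models how the reconstruction kernel, the strength of quantum
iterative reconstruction (QIR) and the radiation dose shape image quality in
photon-counting-detector CT angiography of small vessels, using a digital
silicone-tube phantom, and implements the statistics used to validate such
protocol choices with human readers.  This note describes the models, the
choices behind them, and what the simulator does and does not emulate.

## Kernel model

A reconstruction kernel is summarised by the spatial frequencies at which its
modulation transfer function (MTF) falls to 50% and 10% (ρ50, ρ10, in line
pairs per cm).  From these two anchors we fit the Butterworth-type family

    MTF(ρ) = 1 / (1 + (ρ/a)^b),   a = ρ50,   b = ln 9 / ln(ρ10/ρ50),

which passes through both anchors exactly, is strictly decreasing, and — the
property that matters — has a *flat* low-frequency passband, as a quantitative
kernel must to preserve HU values of extended structures.  A
generalized-Gaussian family `exp(-(ρ/a)^b)` through the same anchors droops
much earlier in the passband; its line-spread function is wide enough that the
1 mm tube wall no longer produces a separate slope maximum at the
sharpness-60 kernel, contradicting the resolvability the phantom measurements
show there.  The Butterworth knee reproduces it.

Two caveats follow from the anchor data themselves and are not defects of the
family: kernels Qr60 and Qr64 share ρ10 = 11.2 Lp/cm, so their curves
necessarily cross just above that frequency, and Qr64's very narrow
ρ50→ρ10 gap (knee exponent ≈ 21) lets it graze ~6·10⁻⁴ below Qr68 in the
mid-band.  Cross-kernel ordering therefore holds on (0, 11.2] Lp/cm to a
1e-3 tolerance, not exactly.

The Nyquist limit of the 0.4 mm isotropic reconstruction grid is
1/(2·0.04 cm) = 12.5 Lp/cm; kernels whose ρ10 exceeds it (sharpness ≥ 68)
mostly amplify noise rather than add resolvable detail.

### Noise model

Background noise is calibrated at one point — QIR-3, 3 mGy — by three anchors
(16, 38, 77 HU for sharpness 44, 60, 72), interpolated log-linearly in
sharpness (the simplest monotone model through all three), scaled by the
measured QIR ratios at sharpness 60 (51/38, 1, 25/38 for QIR-2/3/4, applied
multiplicatively to every kernel), and by the quantum-noise dose law
√(3 mGy/CTDI).  Predictions outside sharpness 36–76 carry an extrapolation
warning.  QIR is modelled *only* as this scale factor; the nonlinear,
locally-adaptive behaviour of real iterative reconstruction is out of scope,
which is why the noise-free image is exactly QIR-independent here.

## Phantom simulator

The phantom is a silicone tube (inner diameter 1–5 mm, wall 1 mm) in water,
lumen filled with an iodine dilution.  Attenuation calibration at 55 keV:
water 0 HU, silicone 500 HU, and an iodine enhancement slope of
500/9.25 ≈ 54.05 HU·mL/mg, so that the 9.25 mg I/mL dilution iso-attenuates
with the wall *exactly* and 37 mg I/mL maps to 2000 HU.  The iso-attenuation
choice is forced by the phantom observation it reproduces: at 9.25 mg I/mL no
wall-lumen slope maximum is separable at any kernel or dose, which bounds the
lumen-wall contrast below the detectability of the quietest setting
(~5 HU noise at 30 mGy).  Both constants are configurable per `PhantomSpec`.

A reconstructed slice is modelled as the continuous object convolved with the
kernel PSF and *point-sampled* at the pixel centres: the measured MTF of a CT
reconstruction already contains the detector aperture, so rasterizing onto
0.4 mm pixels by area-averaging and then blurring would count a 0.4 mm box
aperture twice (and visibly erases the wall's slope dip).  Implementation:
anti-aliased rasterization (8×8 sub-pixel area sampling in boundary pixels) on
a 5× finer grid covering the tube plus a 9 mm water margin, radially
symmetric MTF multiplication in the frequency domain, then decimation back to
the pixel grid (odd factor, centres aligned).  The 5× factor leaves the
wall-edge slope dip within 6% of its converged (S→∞) depth; naive
point-sampled rasterization instead leaves aliasing that makes the dip
oscillate with the supersampling factor.

Noise is stationary, zero-mean, with power spectrum ∝ ρ·MTF(ρ)² — the
classical ramp-filtered back-projection noise shaped by the kernel — scaled so
the full-field SD equals the calibrated target exactly.  Identical seeds give
bitwise-identical fields.  Real PCD-CT noise at high QIR is neither stationary
nor exactly ramp-shaped; only the SD is calibrated here, the texture is the
standard analytic model.

Not rendered: container walls, table, the second water bath, beam hardening,
projection-domain or spectral (multi-bin) physics, 3D structure.  The analysis
regions only ever see water, wall and lumen.

## Edge-profile analysis

From a slice (512×512 or any central crop): crop to 128×128; noise SD = mean
of the sample SDs in the two bottom 44×44 corner ROIs; crop to 64×64;
horizontal and vertical profiles through the tube centre as the mean of the 4
central rows/columns (an even band cannot centre on one pixel, so it straddles
the midline, indices 30–33); profile amplitude = mean over the two profiles of
(maximum − water level from the outer 8 points per end); slope at each
interior point = least-squares line through 3 neighbouring points, which on a
uniform grid is the central difference over 2h = 0.8 mm.

**Transitions.**  Each profile crosses the tube on two sides, each side
having an outer (water↔wall) and inner (wall↔lumen) boundary.  Each boundary
has a known contrast direction — water→wall is positive, wall→lumen follows
the sign of (lumen − wall) — and its transition is assigned the strongest
local maximum of the *directional* slope within ±0.8 mm of the nominal
boundary radius (2 pixels: wide enough for blur shift of soft kernels, narrow
enough to separate the two wall boundaries at diameters ≥ 2 mm; ties break
toward the nominal position).  A transition is **visible** when such a peak
exists, its height is at least c·σ_slope (default c = 2), and it is not the
same peak as the neighbouring boundary's — when both boundaries of one side
collapse onto a single peak the edges are not individually resolved and the
nearer boundary keeps it.  A boundary with zero nominal contrast has no edge
to detect.  The **slope score** (0–8) counts visible transitions; the
**mean slope maximum** averages, over the four sides of the tube, each side's
strongest boundary slope (this reading of "the mean of these four maxima"
matches the published magnitudes; averaging all eight boundary values instead
gives ~30% lower numbers).

**σ_slope.**  For white pixel noise the 4-pixel averaging and central
difference give σ_slope = σ/(2h·√2).  The simulator's shaped noise
concentrates power at mid frequencies, which the averaging/differencing
filters pass more efficiently: exact spectral propagation of the
ρ·MTF² spectrum through both transfer functions gives up to 1.4× the white
value (sharpness-dependent).  The spectral value is used whenever the image
provenance carries the MTF; the white formula is the fallback for images of
unknown origin.  c is configurable and reported in every result.

An earlier design gated visibility on peak *prominence* as well; it was
dropped because the directional-slope rule already rejects wrong-direction
shoulder artefacts, while prominence of the genuine sharp-kernel outer peak
sits close to 2σ thresholds and only made the high-contrast endpoint flaky.

## Factorial sweep

`run_sweep` iterates the factor grid, caching the noise-free blurred slice per
(kernel, diameter, concentration) so extra seeds and doses only cost a noise
synthesis plus analysis (~50 ms per cell).  Desk-scale default:
3 kernels × 3 QIR × 2 doses × 2 diameters × 3 concentrations × 5 seeds;
`full_study_config()` exposes the complete 10×3×6×5×5 design.  With an output
directory, finished cells persist as JSON keyed by a parameter hash and reruns
skip them.  Seeds default to several per cell with medians reported — a single
physical scan per cell, as in a real phantom session, carries unreported
sampling error that medians over seeds average out.

Simulated behaviours that mirror the measured ones: noise rises monotonically
with sharpness and falls with QIR; log-noise vs log-dose regresses to −0.5;
soft kernels (≤ 48) lose amplitude on ≤ 2 mm tubes while sharpness ≥ 60 does
not; the noise-free mean slope maximum rises with sharpness and the
sharpness ≥ 60 kernels plateau — the simulated Qr60–Qr76 spread is ~10%
(10.3% noise-free at 5 mm; the published column puts it at 9%), asserted in
tests at ≤ 12%.  At full contrast, soft kernels bloom: the bright lumen
overruns the 1 mm wall, the outer boundary loses its own slope maximum, and
scores drop to 4 — while at 9.25 mg I/mL every kernel scores 4 because the
inner boundary has no contrast.  One sampling artefact is worth knowing: at
the 5 mm geometry the outer radius (3.5 mm) falls exactly between profile
samples, and Qr60 — unlike Qr72/76 — does not retain a separate outer local
maximum there even noise-free; resolvability endpoints are therefore defined
on the 3 mm geometry.

## Reader-study statistics

**Wilcoxon.**  Paired, two-sided, zeros discarded.  Likert differences are
heavily tied, so for n ≤ 25 the exact conditional null (all 2ⁿ sign
assignments, computed by convolution over doubled midranks) is used — this is
exact under ties, which scipy's exact path refuses; above 25 the
tie-corrected normal approximation.  Bonferroni: p_adj = min(1, m·p) with the
comparison-family size m a caller argument, since which pairings form a family
is a design choice, not a constant.

**Krippendorff's α** with ordinal distances on the coincidence matrix
(δ²(c,k) = (Σ n_g − (n_c+n_k)/2)² summed over categories between c and k);
missing ratings supported; α undefined (NaN, flagged) when all ratings share
one category.  Interpretation bands: ≤ 0.2 poor (negative values included),
then fair, moderate, substantial, excellent in 0.2 steps, half-open upward.

**Likert simulator.**  Each of the 54 cells (9 reconstructions × 3 criteria ×
2 anatomic levels) has a target median and IQR from the packaged summary
table.  A score is clip(round(μ + bias_r + ε), 1, 5) with μ the cell median,
bias_r ~ N(0, 0.15) per reader (persistent reader strictness), and
ε ~ N(0, σ_cell), σ_cell = residual_scale·max(IQR/1.349, 0.25) — the latent
SD whose quartiles match the target IQR, floored so zero-width IQRs still
leave minority scores.  With residual_scale = 0 and no bias every cell
reproduces its target median exactly; agreement rises monotonically toward
α = 1 as the residual shrinks.  The simulator emulates marginal cell
distributions and reader bias only — not per-patient anatomy effects, reader ×
reconstruction interactions, or ordinal cut-point asymmetries — so synthetic
α and p-values characterise the statistics pipeline, not the clinical data.

## What passing tests show — and what they do not

The simulator is calibrated to the *printed summary numbers* of a physical
phantom session (MTF anchors, three noise anchors, QIR ratios, score
endpoints) and reproduces the relationships between them.  It does not model
the scanner's actual reconstruction chain, spectral physics, or QIR
nonlinearity, and real reader data are not deposited; clinical p-values and
agreement coefficients are therefore checked only against the synthetic
generator's own ground truth.  Tests passing mean the analysis chain measures
what it claims on data whose truth is known — not that the simulator predicts
a particular scanner.

## Reference problem sizes

Default test and acceptance runs use: 20 seeds for the high-contrast
worked example (3 mm, 37 mg I/mL, Qr60, QIR-4, 30 mGy); 150 cells
(3 kernels × 5 diameters × 10 seeds) for the iso-attenuation endpoint;
20 seeds for the noise round-trip and 12 for the dose-law regression — sizes
at which the medians and means reported are stable to well inside the
tolerances asserted.
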