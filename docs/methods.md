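# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `avicontrast`. It is the package's own
account of its science; every empirical statement here is one the test
suite or `scripts/acceptance.py` computes.

## Visual system model

The observer is an average UVS passerine with four single cones (U, S_U, M,
L) and a double cone (D). Spectral sensitivities are area-normalized
Gaussians on a 300–700 nm grid (peaks/FWHM: U 370/40, S_U 445/50, M 508/60,
L 565/70, D 560/110 nm). These are configurable stand-ins, not measured
curves: only the scene generator consumes them, and none of the
contrast-level conclusions depend on their exact shape. The double cone is
modeled as a single direct channel rather than a weighted combination of
other filters.

Receptor noise follows the standard receptor-noise-limited (RNL)
convention: each chromatic channel's Weber fraction is

    e_i = ν / √η_i

with single-cone noise ν = 0.1 and relative abundances
η = (1, 1.9, 2.7, 2.7) for (U, S_U, M, L), the blue tit's ratios. The
√η scaling is the convention of the RNL literature; sources reporting these
noise values do not always state the scaling explicitly, so it is exposed
as a documented assumption (override `abundances`/`weber_single` to probe
it). The double cone carries its own Weber fraction ω_D = 0.34 and no
abundance.

## Processing chain

Order is enforced (each stack records its provenance and out-of-order or
repeated steps raise):

1. **Dark subtraction.** The per-channel mean over the flagged
   unilluminated sensor rows is subtracted from every pixel; negative
   results are clipped to zero (the underlying quantity is a photon count).
2. **Normalization.** Either gray-standard normalization (divide by the
   mean over the standard mask; the standard region maps to p ≈ 1) or von
   Kries chromatic adaptation (divide each channel by its mean over the
   illuminated frame). The adaptation mean *includes* the target pixels by
   default — the documented reading of "mean across all pixels" — with an
   optional adaptation mask to exclude them; the synthetic dark rows are a
   sensor artifact, not scene content, and are always excluded from the
   mean.
3. **Naka–Rushton nonlinearity.** E = p/(p+1), mapping catches to
   excitations in [0, 1). Negative catches raise (they indicate a missing
   dark correction).

ROI statistics are *channelwise* (marginal) medians, robust to the odd
specular pixel. Background comparison patches are 3×3 px squares on a
uniform grid over the background mask's bounding box; the grid pitch is
searched coarse-to-fine until the number of fully-inside, disjoint patches
reaches 20 ± 3 (a seeded subsample trims overshoot), which realizes "evenly
spaced, programmatically selected" without an arbitrary placement
heuristic.

## RNL distances

Chromatic distance is implemented in the generalized form
ΔS² = min_a Σ (Δf_i − a)²/e_i² — the noise-weighted distance after removing
the best-fitting uniform signal shift. The minimizer is the
precision-weighted mean of Δf, so the computation is closed-form; the
published di-/tri-/tetrachromat formulas are kept only as independent test
oracles. Receptor signals default to the Naka–Rushton excitations E
(matching the processing order above); a log-quantum-catch mode
(f = ln p, the classic RNL signal) is available via `signal="log"` since
the convention genuinely varies between studies. Achromatic distance is
|Δf_D|/ω_D.

The excitation-boost robustness re-analysis multiplies a target's ROI
excitations by a factor (1.186 for the field paint's measured brightness
excess, up to 1.29 as a bound), clipped below 1; boosting p instead of E is
available for sensitivity analysis.

## Acuity simulation

One object-plane pixel of pitch *s* mm at distance *d* cm subtends
arctan(s/10d) degrees. A viewer of acuity A cpd applies a Gaussian MTF
exp(−c (ν/A)²) per channel in the 2-D FFT domain, ν in cycles/degree. The
constant c = 3.56 leaves e^{−3.56} ≈ 2.8% of contrast at the cutoff
frequency; it is configurable because the value comes from a cited
acuity-simulation method rather than first principles. MTF(0) = 1, so
channel means are preserved; the Gaussian kernel is non-negative, so no
ringing occurs and the [0, 1) clip is a no-op in practice. Edges are
periodic (plain FFT) by default with a mirrored-pad option; the synthetic
scenes have statistically uniform borders, so the choice is benign. Only
the illuminated sub-image is filtered. Composing two blurs equals one blur
with summed c α² (Gaussian closure) — asserted numerically in the tests.

## Synthetic scenes

The generator emulates the structure of field photographs of a posed
spider on leaf litter: a 256×256 px frame at 0.05 mm/px (a ~4 mm leg spans
~80 px), 8 dark sensor rows, a 20%-reflective gray-standard square, an
elongated leg target with a red patch and an adjoining simulated black
ornament (flat 1.5% reflectance), and litter background everywhere else.
Noise-free pixel values are ∝ ∫R(λ)I(λ)S_c(λ)dλ (trapezoidal, 1-nm grid)
with per-channel exposure placing the gray standard at half scale, plus a
constant 2%-of-full-scale dark offset (any positive constant exercises the
correction, since the pipeline estimates it from the dark rows).
Multiplicative mean-one lognormal noise (sd 0.02) models photon/gain noise.
Rendering is a pure, seeded function of its configuration.

Material spectra are plausible stand-ins chosen once and documented, not
measurements:

- **Litter**: template rising 0.05 (400 nm) → 0.35 (700 nm) — the
  desaturated, long-wavelength-rich shape of dry oak litter. Each scene's
  leaf perturbs the template with a seeded brightness offset and spectral
  tilt (sd 0.15 each, bounded to ±30% of the template); real dead leaves
  range from gray-brown to strongly reddish, and this between-leaf
  diversity is what gives group comparisons realistic cluster-level
  variance. Within a scene the background is a mosaic of leaf fragments
  (32 px blocks) with their own smaller brightness/tilt jitter, so
  background patches differ both achromatically and chromatically.
- **Red ornament**: a sigmoid ramp, low below ~580 nm rising to a plateau
  above ~620 nm (base 0.02, plateau 0.40, inflection 615 nm,
  perpendicular). The plateau was calibrated so the red ornament's mean
  chromatic distance to the litter background matches the simulated black
  ornament's — the chromatic *equivalence* of red and black against litter
  is part of the measured structure the generator is built to emulate —
  and then frozen. The oblique pose shifts the inflection to 575 nm and
  lowers the plateau to 0.30, reproducing the orange/yellow appearance and
  reduced darkness of legs angled away from the viewer; angle is a spectral
  label, not a 3-D model.
- **Black ornament / gray standard**: spectrally flat at 1.5% and 20%.
- **Illuminant**: flat by default (standing in for a daylight-like source);
  any `SpectrumCurve` can be supplied.

What passing tests on these scenes show — and what they do not: the
pipeline's arithmetic is exact (closed-form ROI checks at 1e-9 on
noise-free scenes), and the *directional* structure of the imaging
experiment (red below black achromatically, robust to excitation boosts up
to 1.29×; chromatic equivalence; contrast loss at predator resolution for
20–40 cm; lower achromatic contrast at oblique angles) is reproduced under
realistic noise. The synthetic materials do not reproduce the absolute JND
values of any particular field dataset, and the generator has no specular
reflections, shadows, 3-D geometry, or UV iridescence.

## Experiment orchestration and comparison

The default experiment renders 13 spiders × 3 leaves (39 scenes; 7 spiders
also posed obliquely), processes each via background adaptation, samples
20 ± 3 patches, and computes contrasts at native resolution and through an
11-cpd viewer at 20/30/40 cm. All stage seeds derive from one master seed;
the run manifest records them, making every CSV row traceable.

Group effects (color, angle, acuity) are estimated as mean differences
with a leaf-cluster percentile bootstrap (2000 replicates, 95% CI):
clusters are leaves because contrasts sharing a background are correlated.
This is a deliberate, assumption-light substitution for robust
mixed-effects estimation, whose random-effects structures are
data-dependent and poorly transportable to synthetic data; spider-level
random variation is left at zero variance in the generator, consistent
with spider-ID variance components being negligible in this setting.

## Survival analysis

Single-covariate Cox partial likelihood (treatment: black vs. red
baseline), Newton–Raphson with step-halving, convergence at |Δβ| < 1e-8 or
50 iterations, SE from the observed information. Breslow tie handling is
the default (minute-rounded times create modest ties; tests show the
estimate moves < 0.01 vs. continuous times), Efron optional. A monotone
partial likelihood (all events in one group) drifts the estimate; at
|β| > 10 the fit warns and returns unconverged, and
`require_converged()` blocks downstream use. The implementation is
cross-checked against `lifelines` on tie-free data, where Breslow and
Efron coincide.

The paired-trial simulator draws exponential event times with baseline
rate ln 2 / 720 per minute (a 50% 12-h predation probability for the red
baseline — field-realistic pressure), multiplies the hazard by e^{log HR}
for black, censors administratively at 720 min, and rounds to the nearest
minute. With log HR = −0.98 (hazard ratio 0.375) the black group's event
probability is ≈ 23%, and the recovery study (200 replicates × 300 pairs)
recovers the mean log HR within ±0.15 with model SEs calibrated to the
empirical spread within 25%. The field fit's raw data are not public, so
only its derived quantities (Wald −2.39; 63% hazard reduction) are exactly
reproducible; the mixed-effects (frailty) extension is out of scope, the
fixed-effect fit targeting the same marginal treatment effect.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
complete in well under a minute on a single CPU: 256×256 scenes, 39 scenes
per experiment, 2000 bootstrap replicates, 200×300-pair recovery study.
All are configuration parameters.

## Known limitations

- Gaussian sensitivities and a flat illuminant are stand-ins; absolute
  quantum-catch scales are arbitrary (contrasts are scale-free by
  construction).
- Opponent mechanisms beyond the RNL noise model (categorical perception,
  pop-out, object categorization) are outside the model class.
- The oblique pose is spectral, not geometric; no shadows or speculars.
- The Cox model is fixed-effect only; no frailty terms or
  proportional-hazards diagnostics beyond the design.
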