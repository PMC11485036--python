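# avicontrast

Avian-vision multispectral contrast modeling for camouflage research.

Small prey animals are often colored in ways that look conspicuous to us but
not to their actual predators. Deciding whether a color patch is camouflage
or a signal requires modeling the *predator's* visual system: its cone
complement, its receptor noise, and its spatial acuity at realistic viewing
distances. `avicontrast` implements that pipeline for a UVS (ultraviolet-
sensitive) passerine observer viewing a small spider-like target against
leaf litter, together with the survival analysis of a paired field predation
experiment. Because raw field photographs are rarely redistributable, the
package includes a first-class synthetic scene generator that emulates the
statistical structure of such photographs and makes every stage testable
end to end.

## What it computes

**Cone excitations.** Multichannel stacks (one grayscale image per cone
class: U, S_U, M, L and the double cone D) are processed as calibrated
multispectral photographs: dark noise, estimated from unilluminated sensor
rows, is subtracted from every pixel; pixels are converted to relative
quantum catches *p* either by normalizing to a 20%-reflective gray standard
or by von Kries chromatic adaptation (dividing each channel by its mean
across the scene); and catches become receptor excitations through the
Naka–Rushton nonlinearity *E = p/(p+1)*.

**Receptor-noise-limited (RNL) contrasts.** The chromatic distance between
a target and a background patch with receptor signals *f* and channel noise
*e_i* is

    ΔS² = min_a Σ_i (Δf_i − a)² / e_i²,

the noise-weighted distance after projecting out the best-fitting uniform
(achromatic) component; for 2–4 cone classes this equals the published
closed forms. Channel noise follows the Weber/abundance scaling
*e_i = ν/√η_i* with blue-tit cone ratios 1 : 1.9 : 2.7 : 2.7 (U : S_U : M : L)
and ν = 0.1. Achromatic contrast uses the double cone with Weber fraction
ω_D = 0.34: ΔS = |Δf_D| / ω_D. Distances are in just-noticeable differences
(JND).

**Acuity-limited viewing.** A predator with acuity *A* cycles/degree at
distance *d* sees the scene through a Gaussian modulation transfer function
MTF(ν) = exp(−c (ν/A)²) with c = 3.56 (≈2.8% residual contrast at the
cutoff), applied per channel in the Fourier domain. The default viewer is
the median bird: 11 cpd at 5–40 cm.

**Survival analysis.** Paired 12-h predation trials (black-painted vs.
red-legged targets, censoring at 720 min, times rounded to the minute) are
fit with a Cox proportional-hazards model (Newton–Raphson on the Breslow
partial likelihood; Efron optional), with the Wald statistic β/SE and the
hazard reduction 100 (1 − e^β) as derived quantities, plus a paired-trial
simulator for parameter-recovery studies.

## Worked example

```python
from avicontrast import simulate_predation, cox_fit, hazard_reduction

records = simulate_predation(n_pairs=300, log_hr=-0.98, seed=42)
fit = cox_fit(records).require_converged()
print(f"log HR  = {fit.beta:.3f} +/- {fit.se:.3f}")
print(f"hazard reduction (black vs red) = {hazard_reduction(fit.beta):.1f}%")
```

```
log HR  = -0.922 +/- 0.146
hazard reduction (black vs red) = 60.2%
```

The fitted log hazard ratio recovers the simulated −0.98 within one
standard error; the hazard-reduction transform expresses it as the percent
drop in instantaneous predation risk for black-legged targets.

```python
from avicontrast.workflow import (
    ExperimentConfig, run_imaging_experiment, cluster_bootstrap_diff,
)

config = ExperimentConfig()  # 13 spiders x 3 leaves, predator at 20/30/40 cm
table, manifest = run_imaging_experiment(config, seed=7)
native = table[(table.resolution_class == "native")
               & (table.angle_class == "perpendicular")
               & (table.boost_factor == 1.0)]
for value in ("chromatic", "achromatic"):
    r = cluster_bootstrap_diff(native, value, "color_class",
                               ("red", "black_simulated"), seed=7)
    print(f"{value:10s} red-black = {r.difference:+.3f} JND, "
          f"95% CI [{r.ci_low:+.3f}, {r.ci_high:+.3f}]")
```

```
chromatic  red-black = +0.002 JND, 95% CI [-0.021, +0.024]
achromatic red-black = -0.578 JND, 95% CI [-0.592, -0.565]
```

Against the default litter scenes the red ornament is chromatically
indistinguishable from a simulated black one (CI straddles 0) but offers
substantially *less* achromatic contrast — the pattern expected if red
functions as luminance camouflage against long-wavelength-rich litter.

A command-line interface mirrors the stages
(`avicontrast synth | excite | blur | contrast | survival | run | compare`).

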