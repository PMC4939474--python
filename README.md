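# protonfcs

Quantitative tools for studying **protonation dynamics at lipid membrane
surfaces** with fluorescence correlation spectroscopy (FCS), built around the
proton-collecting-antenna effect on lipid nanodiscs: small (9–12 nm) bilayer
patches whose membrane surface funnels protons to an anchored pH-sensitive
fluorophore far faster than direct diffusion from bulk water would allow.

The package is aimed at biophysicists analyzing FCS blinking data of
pH-sensitive dyes (fluorescein on lipids or on membrane proteins such as
cytochrome *c* oxidase) and at modellers exploring how membrane size and
external buffers shape local proton exchange.

## What it computes

**Correlation model.** The autocorrelation of a diffusing fluorophore with
three independent dark states — protonation (P, τ_prot), triplet (T, τ_T) and
a slower redox state (R, τ_R):

```
G(τ) = 1 + [1/(N(1−P−T−R))] (1+τ/τ_D)^−1 (1+τ/(β²τ_D))^−1/2
         × (1−P−T−R + P e^(−τ/τ_prot) + T e^(−τ/τ_T) + R e^(−τ/τ_R))
```

**Global fitting.** Levenberg–Marquardt least squares (via lmfit) of single
curves and of pH/buffer series with shared diffusion/photophysics parameters
(τ_D, β, T, τ_T, R, τ_R) and per-curve protonation parameters (N, P, τ_prot),
with stage-wise initialization, multi-start, and optional per-point weights.

**Kinetics analysis.** For a reversible one-step protonation,
`k_prot = k_off + κ_on·[H+]`: a linear regression of fitted relaxation rates
versus proton concentration yields the on-rate constant κ_on (M⁻¹s⁻¹, slope)
and off-rate k_off (s⁻¹, intercept). Also: the two-pKa titration fit of the
normalized molecular brightness, the antenna radius relation
`R_PCA = √(2 D_s τ_s / π)`, and disc/annulus membrane-area arithmetic.

**Three-pathway Monte Carlo.** A kinetic simulator of proton exchange at a
nanodisc surface: (I) bulk↔surface adsorption/desorption, with desorption
enhanced by buffer; (II) 2D surface diffusion of protons with capture by the
central dye; (III) direct bulk/buffer↔dye exchange. It reproduces both the
saturation of the antenna effect with disc diameter and the non-monotonic
buffer-concentration dependence of k_prot (decrease up to a few mM, then
increase).

**Synthetic data.** A seeded generator of correlation curves and titration
series at the bundled per-sample rate constants, with ground-truth manifests —
the benchmark bed for every recovery test in the package.

## Worked example

```python
import numpy as np
from protonfcs import (SAMPLES, FitSpec, apply_triplet_bounds, fit_global,
                       generate_ph_series, detectable_kprot_points,
                       fit_protonation)
from protonfcs.fitting import amplitude_weights

# synthetic pH series for lipid-anchored fluorescein on a 12-nm disc
curves, truth = generate_ph_series(SAMPLES["ND12-flu"], np.linspace(6, 9, 10),
                                   noise_eps=0.02, seed=1)
spec = apply_triplet_bounds(FitSpec(weights=amplitude_weights(curves)))
result = fit_global(curves, spec)

points = detectable_kprot_points(result.per_curve, curves)
kin = fit_protonation(points, h_max=1e-8)        # pH >= 8 regime
print(f"kappa_on = {kin.kappa_on:.3g} M^-1 s^-1, k_off = {kin.k_off:.3g} s^-1")
```

prints

```
kappa_on = 8.02e+12 M^-1 s^-1, k_off = 4.2e+04 s^-1
```

i.e. the regression recovers the generating on-rate constant 7.35×10¹²
M⁻¹s⁻¹ within ~9% at 2% curve noise — about 200-fold above the free-dye
value of 4×10¹⁰ M⁻¹s⁻¹, which is the antenna enhancement itself.

The same pipeline is available from the shell:

```sh
protonfcs synth --sample ND12-flu --ph 6:9:10 --noise 0.02 --seed 1 --out data/
protonfcs fit data/ --out fits.tsv
protonfcs kinetics fits.tsv
```

and the simulator via `protonfcs simulate / sweep-buffer / sweep-size /
calibrate` with a TOML config (see `docs/methods.md`).

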