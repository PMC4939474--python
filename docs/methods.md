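# Methods

This note records the models, parameter choices and numerical decisions
behind `protonfcs`, and what the synthetic benchmarks do and do not show.

## Correlation model

Fluorescence fluctuations are modelled as 3D-Gaussian translational diffusion
(amplitude 1/N, diffusion time τ_D, axial/lateral ratio β) multiplied by
three independent exponential blinking terms: protonation (fraction P,
relaxation time τ_prot), triplet (T, τ_T) and a slower, most likely redox,
dark state (R, τ_R). The model is the additive dark-state form

    G(τ) = 1 + [1/(N(1−P−T−R))] G_D(τ) (1−P−T−R + Σ_k F_k e^(−τ/τ_k)),

valid for P+T+R < 1; parameters are validated eagerly. The blinking
exponents use the correlation lag τ throughout. The protonated form of
fluorescein is dark, so for a reversible one-step reaction P and τ_prot are
tied to bulk pH by the two-state equilibrium

    τ_prot = 1/(k_off + κ_on[H+]),   P = κ_on[H+] / (κ_on[H+] + k_off).

β defaults to 5 (typical confocal aspect ratio) and is always fittable.

Units: seconds, s⁻¹, molar in all fitting modules; nm, s, M in the
simulator (1 cm²/s = 10¹⁴ nm²/s).

## Global fitting

A pH or buffer series shares its diffusion and photophysics: {τ_D, β, T,
τ_T, R, τ_R} are fitted jointly, {N, P, τ_prot} per curve; any parameter can
be moved between groups or fixed. The optimizer is Levenberg–Marquardt
(lmfit/MINPACK) with box bounds via lmfit's parameter transformation,
tolerance 1e-10 on the relative cost change.

Three exponentials on a single curve are label-degenerate, so initialization
is staged the way practitioners fit such series:

1. per-curve fits with the shared block pinned, multi-started over
   τ_prot ∈ {1, 10, 100 µs} (and τ_D if per-curve);
2. a shared-block fit with per-curve values pinned; two alternations;
3. one joint fit per shared-τ_D branch (τ_D₀ ∈ {10 µs, 100 µs, 1 ms}),
   lowest final cost wins;
4. a rescue pass: a fitted τ_prot outside a curve's lag window means the
   protonation term collapsed into a dead amplitude; such curves are refit
   alone with the shared values pinned and the joint solution polished once.

Default bounds encode weak physical priors that remove pathological basins
(β ∈ [1.5, 20]; τ_T ∈ [0.1, 10] µs; τ_R ∈ [2 µs, 10 ms]); the empirical
triplet window observed on fluorescein calibration samples (τ_T 1.4–1.5 µs,
T 24–28%) is installed by `apply_triplet_bounds` and is what anchors the
triplet term — no ordering constraint between the dark states is imposed.

Weighting defaults to uniform. Correlator noise grows with the correlation
amplitude, so `amplitude_weights` provides per-point standard-deviation
estimates ∝ (G−1+0.05)·G computed from the data; the end-to-end pipelines
use them, and they markedly improve recovery at realistic noise.

Linearized standard errors come from the MINPACK covariance; they are
per-fit quantities, distinct from the across-experiment standard deviations
a study would report, and are never asserted against the latter.

## Rate-constant analysis

k_prot = 1/τ_prot points are regressed against [H+] by ordinary least
squares; the slope is κ_on, the intercept k_off. The fit is restricted to
the high-pH regime ([H+] ≤ h_max, default 10 nM) where the membrane antenna
is fully active; negative intercepts are reported with a warning flag, not
clamped. `detectable_kprot_points` additionally drops curves whose fitted
protonated fraction is below 0.08 or whose τ_prot lies outside the sampled
lag window — on such curves the relaxation rate is not measurable, the same
reason low-P samples are excluded from this regression in practice.

The two-pKa titration of the normalized molecular brightness is fitted by
bounded least squares; results follow the pKa₁ ≤ pKa₂ convention with an
a ↔ 1−a swap if the optimizer crosses. Flat data and optimizer failures are
flagged, never silently returned. With a → 0 the site split is degenerate;
only the function values and the upper pKa are identifiable.

Antenna geometry uses the 2D mean-square-displacement relation
R_PCA = √(2 D_s τ_s/π); with D_s = 2×10⁻⁷ cm²/s and R_PCA = 4–5 nm this
gives τ_s ≈ 1.3–2.0 µs, the ~1 µs order the simulator adopts (k_des0 =
1/τ_s = 10⁶ s⁻¹).

## Three-pathway Monte Carlo

A single protonatable dye sits at the center of a circular disc of diameter
d (capture radius a_f = 0.5 nm, the order of a lipid headgroup); the disc
edge reflects (the scaffold belt blocks lateral escape) and desorption is
the only surface exit. Protons adsorb uniformly over the disc as a Poisson
process with rate k_ads·[H+] and desorb at k_des0 + k_scav·[buffer]
(pathway I); they diffuse on the surface with D_s = 2×10⁻⁷ cm²/s and
protonate the dye on entering a_f while it is deprotonated (pathway II); the
dye also exchanges directly with bulk water and buffer (pathway III):
protonation at κ_on,bulk·[H+] + κ_BH·[BH], deprotonation at
k_off + κ_B·[B⁻], with [BH] = c/(1+10^(pH−pKa)). A proton released on dye
deprotonation goes to bulk, not back to the surface, keeping pathway II
unidirectional — consistent with the absence of a membrane effect on the
measured off-rates. The buffer's pathway-I role is funnelled entirely into
desorption (k_scav); buffer-assisted adsorption is not modelled.

Numerics: surface protons advance with fixed steps dt = 1 ns (per-axis
variance 2·D_s·dt, radial reflection at the rim, per-step Bernoulli
desorption with probability k_des·dt, guarded by dt·k_des < 0.1); dye
transitions and adsorption arrivals are event-driven exponential waiting
times superimposed on the stepping, and the simulation jumps directly
between events whenever no surface proton is alive. Kernels are
numba-compiled and seeded; identical configurations give bit-identical
results.

Estimators: k_on_eff = 1/mean(deprotonated dwell), k_off_eff =
1/mean(protonated dwell), k_prot = k_on_eff + k_off_eff — exact for a
telegraph process — with standard errors from a 200-resample per-dwell
bootstrap. Runs stop after `min_events` protonation events (default 1000;
relative SE ≈ 1/√n) or at `t_max`, flagged under-converged.

Calibrated constants (procedure in `scripts/calibrate_buffers.py`):

* k_ads(12 nm) = 1.94×10¹³ M⁻¹s⁻¹ — fixed by requiring the buffer-free
  simulation to reproduce the measured κ_on = 7.35×10¹² M⁻¹s⁻¹ of
  lipid-anchored fluorescein on a 12-nm disc; `calibrate_adsorption`
  automates this (capture-probability oracle for the starting point,
  proportional iteration on the nearly linear k_ads → κ_on map,
  deterministic seed schedule, 5% tolerance). Disc-size sweeps scale k_ads
  with disc area (constant adsorption flux density).
* Phosphate: pKa 7.2, κ_BH = 3×10⁷, κ_B = 1.7×10⁶, k_scav = 5.5×10⁸
  M⁻¹s⁻¹ — chosen once so that the free-dye simulation shows a clear linear
  k_prot rise already at sub-mM phosphate and the 12-nm-disc sweep minimum
  falls at ~3 mM. HEPES: pKa 7.5, rates 0.3× phosphate (larger molecule:
  lower collisional rates, poorer access to the membrane–water interface).

The buffer minimum is shallow (the k_prot curve varies by ~1% between
neighbouring grid points around it), so `sweep_minimum` locates it by a
quadratic fit in log-concentration through the points around the raw argmin;
sweep-grid argmins are quoted from runs with ≥20000 events per point, where
the grid argmin is stable across seeds.

## Synthetic data and what the benchmarks show

The generator emulates semi-log correlator exports: 128 log-spaced lags from
0.1 µs to 1 s, model curves at the bundled per-sample rate constants, and
multiplicative noise ε_i ~ N(0, noise_eps·(G_i−1+0.05)) truncated at ±5σ —
amplitude-proportional with a floor so tail lags stay noisy. Real correlator
noise is lag-correlated; the independent-noise model is a declared
simplification, so passing recovery tests demonstrate correctness of the
estimation pipeline under the assumed noise structure, not performance on
real detector artefacts (afterpulsing, baseline drift are out of scope).

Sample table defaults not fixed by the measured rate constants: N = 4
(within the 1–10 occupancy window used experimentally), τ_D = 30 µs for free
dye, 150 µs for solubilized protein, 300–350 µs for nanodiscs (typical
confocal values for these species), T = 0.26 / τ_T = 1.45 µs (middle of the
calibration window), R = 0.08 / τ_R = 40 µs. The redox relaxation time is
deliberately placed between the slowest protonation relaxation in the fitted
pH window (~17 µs) and the disc diffusion time (~350 µs): if it overlaps
either, the three-exponential decomposition of a noisy series is genuinely
ill-posed — a property of the model, not of the optimizer.

At pH well below the effective pK the equilibrium protonated fraction drives
P+T+R ≥ 1 where the additive model's amplitude diverges (such curves are not
measurable in practice either); the generator clips P so the total dark
fraction stays ≤ 0.95 and records the clipped value as ground truth. τ_prot
is never altered by the clip, so rate-law recovery is unaffected.

## Known limitations

* The additive dark-state model requires P+T+R < 1; strongly protonated
  samples need the multiplicative blinking form, which is out of scope.
* Single-curve fits cannot separate protonation from the redox term without
  pinned photophysics; only series fits carry that information.
* The simulator's bulk is a reservoir (no 3D diffusion field, no proton
  depletion) and surface diffusion is ordinary Brownian motion; anomalous
  (time- and length-scale-dependent) diffusion and Grotthuss-level detail
  are not modelled.
* Monte Carlo standard errors assume independent dwells, which holds for
  this model but would not for externally correlated noise.
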