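# Methods

## The minimal model

Seven concentrations (nM) evolve under mass-action kinetics in two
compartments:

| variable | pool |
|---|---|
| x1 (CB) | free cytoplasmic CTNNB1 |
| x2 (DC) | free destruction complex |
| x3 (CB\*-DC) | destruction-complex-bound phosphorylated CTNNB1 |
| x4 (DC\*) | DVL-inactivated destruction complex |
| x5 (NB) | free nuclear CTNNB1 |
| x6 (TCF) | free TCF/LEF |
| x7 (NB-TCF) | TCF-bound nuclear CTNNB1 |

Reactions: CB+DC ⇌ CB\*-DC (k1, k2); CB\*-DC → DC + CB\* with CB\* degraded
and not tracked (k3); DC ⇌ DC\* (k4, k5), active only when the binary WNT
input w = 1; CB ⇌ NB shuttling (k6, k7); NB+TCF ⇌ NB-TCF (k8, k9);
constant synthesis b. Receptor-level detail (FZD/LRP/DVL kinetics) is
collapsed into w; there is no spatial or stochastic resolution.

Two exact invariants — x2+x3+x4 (total destruction complex) and x6+x7
(total TCF) — are monitored along every trajectory (tolerance 1e-6
relative, solver LSODA at rtol 1e-8 / atol 1e-10 nM).

### Identifiability and baseline magnitudes

Equilibrium data constrain only the ratios K1 = k2/k1, k3, b, k6/k7,
K2 = k9/k8 and k5/k4, plus a global time-scale factor. Fixed points are
invariant under joint rescaling of all rates and b, and depend on the
absolute magnitudes only through k3/k1 ≪ K1. The baseline magnitudes
k1 = 0.05 nM⁻¹min⁻¹, k7 = 0.03 min⁻¹, k4 = 0.01 min⁻¹, k8 = 0.01 nM⁻¹min⁻¹
(all pre-scaling, all overridable) satisfy that condition with two orders
of margin; the factor `rate_scale = 20` places equilibration at the
observed ≈4.5 h. `fit_rate_factor` recomputes this factor from a target
convergence time by bisection on simulated trajectories; with the default
magnitudes it lands at order 20, but its exact value trades off against
the unconstrained baseline magnitudes and is treated as tunable, not as a
verifiable quantity.

### The OFF → ON transition

The stimulated condition differs in three ratios (k5/k4 effective-off → 1.7,
k6/k7 0.96 → 1.17, K2 320 → 33.6 nM). The transition is modeled as: w
switches 0 → 1 at onset; the shuttling and retention ratios interpolate
linearly in time, completing `steep = 150` min after onset; inactivation
ramps in by scaling k4 from 0 (so k5/k4 descends monotonically from its
no-inactivation limit to the fitted ON value). Linear interpolation is
the simplest monotone form consistent with a "gradual, complete by
*steep*" transition; the functional form is otherwise unconstrained.

### Steady states

`steady_state(method="integrate")` integrates until every |dx/dt| <
1e-8 nM min⁻¹ (horizon 1e5 min), from a caller-seeded random state on the
conservation manifold — results are verified independent of the start.
`method="algebraic"` evaluates the closed form (x3 = b/k3; the DC pool
split by conservation and, under WNT, by k5/k4; x1 from the CB\*-DC
balance including the exact k3/k1 correction; x5 = (k6/k7)x1; x7 from the
TCF binding isotherm) and serves as the independent cross-check. With
w = 0 the inactivated pool x4 is pinned to 0: w = 0 freezes x4 at its
initial value, and the unstimulated condition is defined by x4 = 0.

### Parameter derivation

With conserved totals DC⁰ = 82.4+62.5 = 144.9 nM and TCF⁰ = 103 nM
(86 nM bound after stimulation plus a fifth of that still free, committed
at reporting precision), the equilibrium conditions give closed forms:
k6/k7 = x5/x1, k3 = b/x3, x2 = K1·x3/x1, K2 = x5(TCF⁰−x7)/x7. The free-DC
formula uses the small-b approximation (b ≪ the binding fluxes); an exact
variant x2 = (K1·x3 + b/k1)/x1 is available behind a flag and differs by
<1%. All values are carried at full precision internally and rounded only
at reporting (0.96, 0.0068 min⁻¹, 82.4 nM, 320 nM, 1.17, 33.6 nM).

k5/k4 is not identifiable from concentrations alone: `fit_dc_inactivation`
minimises the squared relative error of the steady-state (x1, x7) against
the stimulated measurements over log₁₀(k5/k4) ∈ [−3, 3], returning 1.69
(reported 1.7). Carrying k3 at full precision matters here: with the
rounded 0.0068 the fit would return 1.65.

The degradation-rate scans model constitutive activation (S45F mutation,
GSK3 inhibition) as a reduction of k3 with the destruction complex still
active (w = 0), crossed with the unstimulated/stimulated values of k6/k7
and K2. The cytoplasmic total x1+x3 is analytically independent of the
nuclear ratios in this regime, which the scan report asserts (<1% spread).

## FCS

The autocorrelation estimator is the definitional one: for integer lag k,
g(k·Δt) = 1 + [Σ_t δI(t)δI(t+k)/(n−k)]/⟨I⟩², with δI taken against the
analysis-window mean, evaluated exactly (no multi-tau coarse-graining) on
a quasi-logarithmic integer grid (8 points per octave, from 2 bins to a
tenth of the window). It matches a brute-force double-loop oracle to
1e-10. Finite windows bias g downward by roughly twice the correlation
area over the window length — an offset absorbed by the free G∞ term in
fits (this motivates the default 10 s synthetic traces; at 8 s the bias
begins to leak into the slow fraction).

The fit model is the standard triplet × 3D-diffusion form with one
transverse factor and one axial square-root factor per component (the
axial-power variant is available behind a flag for sensitivity checks;
both agree in the fitted regimes). Default bounds follow established
practice for these traces: G∞ ∈ [0.5, 1.5], N ∈ [0.001, 500],
τ_trip ∈ [1e-6, 0.05] ms, τ_diff2 ∈ [10, 150] ms; the first component is
fixed to the Einstein–Stokes monomer value converted through the day's
calibration (never a hard-coded time), or free in [0.5, 10] ms. Fits are
unweighted by default (per-lag weights optional); misfit detection is a
sign-runs test on residuals (p < 0.01) plus reduced χ² > 5 when weights
exist, and active-bound warnings — all advisory flags, never silent drops.

QC selects the longest ~1 s-coarse-grained window whose linear-trend
relative change stays below 10%, rejecting traces without a compliant
30 s window ("bleaching" when the overall trend is monotone decreasing).
For short synthetic traces the batch processor scales the minimum window
down explicitly.

Calibration anchors the geometry to Alexa488 (D = 435 µm²/s at 22.5 °C):
ω_xy = √(4Dτ_diff), cylinder volume V = 2πω_xy³·sp, C = N/(V·N_A). The
default synthetic volume is 0.74 fl (back-solved from the measured
80 molecules ↔ 180 nM correspondence; ω_xy = 0.287 µm, sp = 5).

## Number & Brightness

Photon-counting estimators (APD in counting mode; analog S-factor
calibration is out of scope): ε = (σ²−⟨I⟩)/⟨I⟩ and n = ⟨I⟩²/(σ²−⟨I⟩) per
pixel across 50 frames, unbiased variance, pixels without fluctuation
excess masked. Brightness is normalised to a same-compartment monomer
control, making oligomer size read directly (dimer ≈ 2). Bright static
structures are excluded when the pixel mean exceeds the ROI median by
more than 3 MAD (an explicit, reproducible stand-in for manual
thresholding); no frame detrending is applied by default (a moving-average
option exists for bleaching stacks).

Number conventions: the estimator n is the "apparent" number, directly
comparable to an FCS-fitted N (both equal c·π^{3/2}ω²ω_z for a 3D-Gaussian
detection profile). N&B software instead reports the count inside the
Gaussian PSF volume, which is γ = 2^{−3/2} = 0.3536 of the apparent
number; `roi_summary` reports that convention as `number_raw` and
`number_raw/γ` as the FCS-comparable, γ-corrected number.

## Synthetic data

The trace simulator advances independent Brownian walkers in a periodic
box and draws per-bin Poisson counts from summed 3D-Gaussian detection
weights (peak rate per particle in kHz), plus optional flat background
and an optional two-state dark-state telegraph (valid when τ_trip is not
far below the bin width; at default binning the study's ~µs dark states
are sub-bin and only attenuate the mean, so the default dark fraction is
0 and the telegraph is exercised with finer binning). Detector
afterpulsing is not simulated separately — in the fitting model the
triplet term absorbs both.

Numerical design, validated against the analytic model curve:

* positions advance by Gaussian jumps of variance 2DΔt per axis, which
  makes the sampled autocorrelation *exact* at integer multiples of the
  update interval (no time-discretisation error at the fitted lags);
* very slow species use a coarser update stride (RMS transverse jump
  ≤ ω_xy/15 — stride 1 for the monomer at default binning), and the axial
  coordinate advances on a schedule resolving the axial diffusion time
  with ≥10 points, since the axial weight factor varies that slowly;
* the box is 6ω_xy wide and 6ω_z tall: smaller lateral boxes let wrapped
  walkers generate spurious long-lag correlation (measured +0.05..+0.11
  bias on the recovered slow fraction at 3–4ω_xy);
* the planted "particle number" is defined in the FCS effective volume
  π^{3/2}ω²ω_z, which is what an unbiased amplitude fit reports.

Default regime (the measured cytoplasmic condition): two species at 14.9
and 0.3 µm²/s (monomer prediction; middle of the measured 0.1–0.6 µm²/s
complex range — the mid value also keeps τ_diff2 ≈ 69 ms safely inside
the [10, 150] ms fit bounds, where a value near a bound would make
recovery studies degenerate), fractions 0.65/0.35, 80 particles ≈ 180 nM
in 0.74 fl, 3 kHz per particle, 80 µs bins, 10 s duration. Real
acquisitions run ~120 s; 10 s (~145 slow-complex transits) is the
smallest duration at which recovery is unbiased, and keeps a 50-trace
study within minutes.

The frame-stack simulator places emitters uniformly in a ±1.5ω_z slab
(truncating <0.3% of the axial weight), redrawing positions every frame in the
fast-diffusion limit or propagating persistent walkers in slow mode, and
sums separable Gaussian PSF contributions into per-pixel Poisson rates.
Measurement-noise replicates apply median-unbiased multiplicative
log-normal noise (σ² = ln(1+CV²)) to the four fluctuation-measured pools,
holding literature constants fixed.

### What the generators do not emulate

Photon-arrival (time-tagged) statistics, detector dead time and
afterpulsing, optical aberrations, cellular heterogeneity and
autofluorescence structure, anomalous subdiffusion, and photobleaching of
the emitter pool. Passing recovery tests therefore demonstrate estimator
and fitting correctness under the assumed physics — free 3D diffusion in
a Gaussian volume with ideal counting statistics — not robustness to
every artifact of live-cell data; the QC and correction stages address
those artifacts on the real-data path and are tested on constructed
fixtures (drift, steps, bleaching, static structures).

## Degenerate inputs and tie-breaks

Scan values and rates must be positive; b/k3 ≥ DC⁰ has no steady state
and raises; w = 1 with k5 = 0 drives the free DC pool to zero and raises;
fit targets equal to the unstimulated equilibrium make k5/k4 unbounded
and raise an infeasibility error. QC window ties resolve to the earliest
window; solver overshoot below zero is clipped at 1e-9 nM. Reports carry
a provenance block (config hash, seeds, package version) and never drop
a trace or pixel silently — every exclusion appears with a reason code.

## Sizes used by the test and benchmark studies

FCS recovery: 50 traces × 10 s (seeds 1–50), fixed-first-component fits.
N&B: 64×64 px × 50 frames (monomer/dimer), 32×32 px for the
FCS-matched concentration cross-check. Measurement-noise recovery: 200
replicates at 10% CV. These sizes put the Monte-Carlo error of each
checked statistic several-fold below its acceptance band.
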