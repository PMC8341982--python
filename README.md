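# wntquant

Quantitative analysis of WNT/CTNNB1 (β-catenin) signaling in live cells:
fluorescence fluctuation spectroscopy to measure absolute CTNNB1
concentrations and complex states, and a minimal ODE model of the pathway
whose parameters derive directly from those measurements.

The package is aimed at quantitative cell biologists and modelers who work
with confocal point-FCS and Number & Brightness (N&B) data, or who want a
small, fully-parameterised compartment model of CTNNB1 turnover and
nucleocytoplasmic distribution.

## What it does

**FCS chain** (`wntquant.fcs`): drift/bleach QC of photon-count traces,
exact autocorrelation on a quasi-logarithmic lag grid,

G(τ) = G<sub>∞</sub> + (1/N) · (1 + F<sub>trip</sub>/(1−F<sub>trip</sub>) e<sup>−τ/τ<sub>trip</sub></sup>) · Σ<sub>i</sub> F<sub>i</sub> (1+τ/τ<sub>i</sub>)<sup>−1</sup> (1+τ/(τ<sub>i</sub>sp²))<sup>−1/2</sup>

bounded least-squares fitting of this triplet × two-component diffusion
model (first component fixable to the Einstein–Stokes monomer prediction
D = D<sub>ref</sub>(m<sub>ref</sub>/m)<sup>1/3</sup>), autofluorescence/bleaching correction
N<sub>corr</sub> = N<sub>apa</sub>(1−I<sub>auto</sub>/I<sub>total</sub>)²·(I<sub>start</sub>/I<sub>ana</sub>), reference-dye
calibration ω<sub>xy</sub> = √(4Dτ<sub>diff</sub>), V = 2πω<sub>xy</sub>³·sp, and conversion to
concentrations C = N/(V·N<sub>A</sub>) and diffusion coefficients D = ω<sub>xy</sub>²/(4τ).

**N&B** (`wntquant.nandb`): per-pixel photon-counting estimators
ε = (σ²−⟨I⟩)/⟨I⟩ and n = ⟨I⟩²/(σ²−⟨I⟩) on frame stacks, monomer-normalised
brightness, static-structure exclusion, and the γ = 0.3536 volume-factor
bookkeeping that makes N&B particle numbers comparable with FCS.

**Minimal model** (`wntquant.model`): seven species — free and
destruction-complex-bound cytoplasmic CTNNB1 (CB, CB*-DC), free and
DVL-inactivated destruction complex (DC, DC*), free and TCF-bound nuclear
CTNNB1 (NB, NB-TCF) and free TCF — under mass-action kinetics with a binary
WNT input *w* gating destruction-complex inactivation. Steady states by
stiff ODE integration or closed form; time courses with a gradual OFF→ON
transition of the shuttling (k6/k7), retention (k9/k8) and inactivation
(k5/k4) ratios; parameter scans.

**Parameter derivation** (`wntquant.derive`): the equilibrium conditions
invert measured concentrations into rate ratios — k6/k7 = x5/x1,
k3 = b/x3, x2 = K1·x3/x1, K2 = k9/k8 = x5(TCF⁰−x7)/x7 — plus model fits
for the non-identifiable pieces (k5/k4, global time-scale factor).

**Synthetic data** (`wntquant.synthetic`): Brownian-dynamics photon traces
(Gaussian detection volume, periodic box, optional dark-state telegraph),
N&B frame stacks with oligomeric emitters, and noisy equilibrium
measurement replicates — all seeded, with ground-truth sidecars.

## Worked example

```python
import numpy as np
from wntquant.pipeline import build_reference_parameters
from wntquant.model import steady_state

params_off, params_on, info = build_reference_parameters()
off = steady_state(params_off, w=0, dc_total=info["dc_total"],
                   tcf_total=info["tcf_total"], method="integrate",
                   rng=np.random.default_rng(0))
on = steady_state(params_on, w=1, dc_total=info["dc_total"],
                  tcf_total=info["tcf_total"], method="integrate",
                  rng=np.random.default_rng(0))
print(f"free cytoplasmic CTNNB1: {off.x1:.1f} -> {on.x1:.1f} nM")
print(f"free nuclear CTNNB1:     {off.x5:.1f} -> {on.x5:.1f} nM")
print(f"TCF-bound nuclear:       {off.x7:.1f} -> {on.x7:.1f} nM")
print(f"N/C ratio:               {off.nc_ratio:.2f} -> {on.nc_ratio:.2f}")
```

prints

```
free cytoplasmic CTNNB1: 91.1 -> 145.0 nM
free nuclear CTNNB1:     87.1 -> 170.0 nM
TCF-bound nuclear:       22.0 -> 86.0 nM
N/C ratio:               0.71 -> 1.23
```

i.e. WNT stimulation shifts CTNNB1 from nuclear exclusion (N/C ≈ 0.7) to
nuclear accumulation (N/C ≈ 1.2), with the TCF-bound transcriptional pool
rising almost fourfold — all of it emerging from the measured equilibrium
concentrations plus two literature rate constants (b, K1).

The numbered scripts under `analysis/` run the full chains and write tidy
CSV tables under `results/`:

```bash
python analysis/01_derive_parameters.py          # rate-ratio table
python analysis/02_steady_states_and_timecourse.py
python analysis/03_perturbation_scans.py         # k3 scans (oncogenic regime)
python analysis/04_fcs_synthetic_benchmark.py 6  # FCS recovery on 6 traces
python analysis/05_nandb_synthetic_benchmark.py
```

For example, `03_perturbation_scans.py` reports that reducing the
degradation rate k3 from 0.0068 to ≈0.0043 min⁻¹ reproduces the measured
cytoplasmic concentration of the degradation-resistant S45F mutant
(351 nM), that this prediction is insensitive to the nuclear
shuttling/retention regimes, and that nuclear accumulation (N/C > 1)
additionally requires the stimulated shuttling ratio.

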