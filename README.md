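# memkin

Single-molecule membrane-binding and lipid-kinase kinetics, as a tested,
reusable Python package.

`memkin` implements the quantitative analysis chain used to study a lipid
kinase (PIP5K-type) that phosphorylates PI(4)P to PI(4,5)P₂ on supported
lipid bilayers and whose activity is potentiated by membrane-mediated
dimerization: single-particle dwell-time and step-size mixture fits,
molecular-brightness and photobleaching-step analysis of oligomeric state,
surface-density calibration and cooperative binding isotherms, feedback-order
decomposition of reaction kinetics, and a deterministic/stochastic model of
the bistable kinase–phosphatase competition in micrometer-scale membrane
corrals. A synthetic-data generator emulates every observable (TIRF
single-particle tracks, intensity traces, titrations, reaction time series),
so the whole pipeline is testable end to end without microscopy data.

It is aimed at single-molecule biophysicists and quantitative membrane
biologists who have spot-tracking exports (TrackMate-style CSV), per-particle
intensity traces, titration tables, or sensor kinetics, and want the
field-standard fits with explicit models and reproducible statistics.

## Models at the core

**Dwell times.** The survival of membrane residence times is fit in
log₁₀(1 − CDF) space to one or two exponentials,
`f(t) = α e^(−t/τ₁) + (1−α) e^(−t/τ₂)` (τ₁ ≤ τ₂; α = fast fraction), with
Poisson-weighted least squares, nested-model F-test escalation, and the
competing-exponentials photobleaching correction
`1/τ_true = 1/τ_obs − 1/τ_bleach`.

**Step sizes.** Per-frame 2D displacements follow the Brownian density
`f(r) = r/(2Dτ) e^(−r²/4Dτ)`; one- or two-species mixtures are fit to the
0.01 µm-binned probability density, giving state-resolved diffusion
coefficients (monomer vs membrane dimer).

**Brightness.** Particles above a fixed intensity threshold are classified
dimeric; chromophore maturation p limits the detectable two-fluorophore
fraction to `p²/(1−(1−p)²)`; change-point segmentation counts discrete
photobleaching steps.

**Cooperative binding.** Fluorescence is converted to molecules/µm² via a
lipid-standard calibration line and a dye-brightness scaling factor;
isotherms are fit with the concerted (Hill) model
`ρ(c) = Bmax·cⁿ/(Kdⁿ + cⁿ)`. Lipid mole fractions convert to absolute
densities with a 0.72 nm² lipid footprint (4 mol% → 55,555 lipids/µm²).

**Feedback kinetics.** Sensor traces are normalized to the reaction
coordinate x ∈ [0, 1]; `dx/dt = k(x)(1−x)` with `k(x) = k0 + k1·x + k2·x²`
is decomposed by local-regression derivatives plus a trace-level refinement.
The polynomial order of k(x) is the feedback order: first order from simple
product binding, second order from product-driven dimerization. Per-enzyme
velocities `v = (dP/dt)/E(t)` against remaining substrate `S = S0 − P` give
Michaelis-style per-molecule rates.

**Bistable corrals.** The competition
`dx/dt = (k0+k1x+k2x²)(1−x) − (p0+p1(1−x))x` is analyzed exactly
(polynomial steady states and stability, bistable parameter ranges) and
simulated stochastically by an exact event-driven scheme over
{kinase arrival, departure, single-lipid (de)phosphorylation}, reproducing
trajectory heterogeneity and system-size-dependent outcomes
(stochastic geometry sensing).

## Worked example

```python
from memkin import (SimConfig, simulate_tracks, tracks_from_frame,
                    filter_tracks, extract_dwells, extract_steps,
                    fit_dwell, fit_steps, correct_bleaching)

cfg = SimConfig(seed=5, frame_interval=0.05, n_frames=4000,
                arrival_rate=0.035, dwell_taus=(0.453,),
                diff_coeffs=(0.148,), bleach_tau=26.7,
                maturation_prob=1.0, localization_sigma=0.01)
table, truth = simulate_tracks(cfg)
kept, report = filter_tracks(tracks_from_frame(table),
                             cfg.n_frames, cfg.field_size)
dwells = extract_dwells(kept, cfg.frame_interval)
fit = correct_bleaching(fit_dwell(dwells, cfg.frame_interval), 26.7)
steps, _ = extract_steps(kept)
sfit = fit_steps(steps, cfg.frame_interval)
print(f"tau = {fit.tau_corrected[0]:.3f} s ({fit.n_components} component)")
print(f"D   = {sfit.D1:.3f} um^2/s from {sfit.n_steps} steps")
```

prints

```
tau = 0.448 s (1 component)
D   = 0.150 um^2/s from 71412 steps
```

the bleach-corrected membrane dwell time and diffusion coefficient of the
dilute (monomeric) kinase, recovered from ~7,000 simulated molecules whose
generating parameters were τ = 0.453 s and D = 0.148 µm²/s (D is reported
with the expected localization-noise inflation σ²/τ_frame ≈ 0.002 µm²/s).

The numbered scripts under `analysis/` run the full studies: single-molecule
binding at dilute vs dense kinase (01), brightness and photobleaching (02),
binding isotherms (03), feedback decomposition (04), and bistable corrals
(05). Each writes its tables under `results/`.

A `memkin` CLI wraps the same operations
(`memkin simulate tracks`, `memkin filter`, `memkin fit-dwell`,
`memkin hill`, `memkin bistable range`, ...); see `memkin --help`.

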