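# Methods

This note records the models behind each module, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## The system

A lipid kinase binds PI(4,5)P₂-containing supported bilayers, diffuses in
2D, and phosphorylates PI(4)P to PI(4,5)P₂, creating positive feedback
through product binding. The kinase exists in a monomer–dimer equilibrium:
at low membrane density it binds and acts as a monomer; rising surface
density drives membrane-mediated dimerization, which lengthens the
membrane dwell, slows diffusion, and sharply increases catalytic rate.
Against an opposing 5-phosphatase whose own feedback is driven by the
substrate-regenerating product, the composition dynamics can be bistable,
and in small membrane corrals molecular noise makes the outcome
system-size dependent.

## Synthetic observables (`synthgen`)

`simulate_tracks` generates a single-particle-tracking movie: arrivals are
Poisson in time and uniform in space; membrane dwell is drawn from a one-
or two-component exponential mixture; each frame the particle takes a
Gaussian step with per-axis SD √(2D·Δt), with D keyed to a two-state
(monomer/dimer) Markov chain switching at `dimer_on_rate`/`dimer_off_rate`;
per-particle photobleaching competes with unbinding (observed lifetime is
the minimum); each chromophore is mature with probability
`maturation_prob` (immature particles are undetected); localization noise
(default σ = 0.02 µm per axis) and Gaussian camera noise are added per
frame. The observed mean-squared displacement per frame is therefore
4DΔt + 4σ². The initial oligomer state defaults to the switching
equilibrium (steady-state imaging); `initial_dimer_prob=0` models
attachment-style experiments where molecules arrive from solution as
monomers. Dimerization is a per-particle state switch, not an explicit
pair-collision simulation: the downstream analyses consume only
state-dependent dwell and mobility.

Key defaults and their provenance as study conditions: frame interval
0.05 s (the dwell-histogram bin), photobleaching τ = 26.7 s (the stable
dye), maturation 0.8 (fluorescent-protein tags), monomer D = 0.148 µm²/s,
monomer dwell τ = 0.453 s, dimer D = 0.043 µm²/s, camera intensities
centered at 5,500 A.U. per fluorophore so the 8,200 A.U. dimer threshold
sits between the one- and two-fluorophore levels. Membrane dimer on/off
rates are not experimentally quantified (membrane dimers persist only
on the order of a second);
defaults (on 0.85 /s, off 0.5 /s where two states are enabled) are
illustrative and chosen to reproduce the observed slow-state occupancy.

What the generator does **not** emulate: raw TIRF images and spot
detection (tracks are born perfect, no false linking), EMCCD noise physics
beyond additive Gaussians, fluorophore blinking, spatial coincidence of
two independent particles in one diffraction-limited spot, membrane
hydrodynamics, and explicit pairwise encounter kinetics. Passing tests
therefore validate the statistical estimators and pipelines, not
detection or linking robustness on real images.

`simulate_reaction` integrates dx/dt = k(x)(1−x) − (p0 + p1(1−x))·x
(LSODA, rtol 1e−9), or runs an exact Gillespie simulation in a corral:
discrete lipids S = round(S₀·area), kinase copies arriving at
kon·[kinase]·area and departing at 1/τ_dwell each, phosphorylation
propensity (N/N_ss)·k(x)·(S − n_P), dephosphorylation
(p0 + p1(1−x))·n_P, with N_ss = arrival·τ_dwell. The N/N_ss scaling makes
the mean-field limit equal the ODE while kinase copy-number fluctuations
modulate the rate; the phosphatase is treated mean-field (its copy
numbers are not experimentally resolved). An optional
`recruitment_coupling` multiplies arrivals by (1 + c·x) for exploratory
product-enhanced recruitment; it is off by default and goes beyond the
stated rate law. All propensities are constant between events, so the
direct method is exact; the kernel is numba-compiled.

## Trajectory hygiene (`trajectory`)

Filters are applied in a fixed order: tracks beginning in frame 1
(arrival unobserved), tracks present in the last movie frame (departure
unobserved), tracks ≤ 2 frames, immobile tracks, and tracks near the
field edge. The immobile criterion — maximum excursion from the track's
own start below 2× the default localization σ (0.04 µm) — is a package
choice: such filters are usually documented only by the 1–5% of
particles they remove, not by a threshold. The edge rule is a configurable
margin, default 5% of the field width. Dwell = (frame span, inclusive) ×
frame interval, so detection gaps do not shorten dwells; steps are taken
only across consecutive frames, with gapped pairs counted and excluded.

## Mixture fits (`mixture_fits`)

Dwell survival is binned at the frame interval and fit in log₁₀(1−CDF)
space, the field's standard transform. Numerical choices that matter:

- **Weights.** Points carry Poisson counting errors propagated into log
  space, σᵢ = √((1−Sᵢ)/(n·Sᵢ))/ln 10. Uniform weights let the long tail
  dominate and degrade the fast component ~27% (measured); weighted fits
  recover well-separated mixture parameters to ~3–4% at n = 10⁴.
- **Truncation.** Dwells shorter than one frame are unobservable and a
  minimum-track-length filter truncates further; the fit starts one bin
  past the first bin where survival < 1, and a free amplitude absorbs the
  truncation, leaving the decay constants unbiased (the binned survival
  of a frame-discretized exponential decays exactly as e^(−Δt/τ) per bin).
- **Model selection.** Both models are always fit; the two-component
  model is accepted only if the nested F-test is significant (p < 0.01)
  *and* the mixture is non-degenerate: minor fraction > 0.10 and
  component ratio ≥ 2. An R²-threshold short-circuit was rejected because
  the log-survival R² of a straight line through a well-separated mixture
  stays above 0.99 (the tail carries most of the variance), so it never
  escalates. The degeneracy guards absorb the F-test's anti-conservatism
  on correlated binned data; selection is 100/100 correct in both
  directions at n = 10⁴ (measured). Components are reported in canonical
  order (τ₁ ≤ τ₂, D₁ ≤ D₂) with α the fraction of the first-listed
  component — fast-dissociating for dwells, slow-diffusing for steps.
- **Survival cut.** Bins below survival 10⁻³ (or fewer than two counts)
  are dropped; three decades of decay bound the information content.
- **MLE cross-check.** An EM exponential-mixture fit on the raw sample
  (`fit_dwell_mle`) serves as an independent oracle in tests; it is not
  the default because the log-survival fit is the field's standard.

Two-component dwell fits at component ratio ~2.6 (the dense-kinase
condition) scatter 10–15% per realization even at n ≈ 8,000; reported
values for that condition are means over four independently simulated
replicates, as single-molecule binding parameters are conventionally
reported (means with SD across technical replicates).

The bleach correction treats unbinding and photobleaching as competing
exponentials, τ_true = 1/(1/τ_obs − 1/τ_bleach), and refuses
τ_obs ≥ τ_bleach. Reported dwell times in this field do not always say
whether they are bleach-corrected, so the correction is optional and off
by default.

Step-size histograms (bin 0.01 µm, density = frequency/bin width) are fit
to the Brownian one- or two-species density with trust-region least
squares, multi-start over α ∈ {0.2, 0.5, 0.8}, Poisson weights, and the
same selection rule. Fits pinned at parameter bounds are flagged. The
fitted D includes the localization-noise inflation σ²/Δt (≈ 0.008 µm²/s
at the default σ), exactly as experimental step-size fits do.

## Brightness (`brightness`)

The dimer threshold (default 8,200 A.U.) is instrument-specific and
configurable; an automatic alternative places the threshold at the
antimode of a two-Gaussian mixture whose second mean is constrained to
twice the first. Step counting segments the trace into piecewise-constant
levels by binary splitting with a BIC stopping rule, then gates steps at
magnitude ≥ 3× the noise SD and ≥ 2 frames separation; this is robust on
short traces and needs no training. The time-resolved dimer fraction uses
non-overlapping windows (default 1 s), classifying particles visible in
each window; with full maturation and no arrivals it follows
s²/(2s − s²), s = e^(−t/τ_b). A dimerization-deficient species' apparent
equilibrium dimer fraction in the generator is only the camera-noise tail
(≲ 0.1%); the ~1% coincidence rate seen on real membranes arises from
optical overlap of independent particles, which the generator does not
model. A related open point is surfaced, not resolved: an observed ~80%
initial two-visible fraction equals the quoted ~80% maturation
probability, whereas independent maturation arithmetic gives
p²/(1−(1−p)²) = 67% at p = 0.8; the package reports the conditional
(two-visible among detectable) statistic.

## Calibration and isotherms (`cooperativity`)

Mole fraction converts to density as fraction/0.72 nm² per lipid with no
leaflet factor-of-two — the total-composition-per-membrane-area
convention under which 4 mol% is 55,555 lipids/µm². The calibration line
is fit with a free intercept (background fluorescence exists); the
scaling factor is the ratio of probe to standard solution-brightness
slopes. Hill fits use lmfit with inverse-variance weights when replicate
SDs are provided; fits whose data never reach 70% of the fitted Bmax are
flagged extrapolated. Reference Hill coefficients are not printed for the
binding curves, so n_H is reported without an external check;
log-spaced concentration designs spanning ~20× below to ~20× above Kd
are recommended.

## Feedback decomposition (`feedback`)

The reaction coordinate normalizes start intensity to 0 and the plateau
mean (final 10% of points, required to vary < 2% of amplitude) to 1,
assuming sensor intensity linear in product density between the 0 and S₀
anchors. Derivatives are local linear-regression slopes over ±2 s
(one-sided at the ends, flagged); no additional smoothing is applied.
The decomposition dx/dt = (k0 + k1·x [+ k2·x²])(1−x) is linear in the
coefficients and solved by least squares over x ∈ (0.02, 0.98), where
(1−x) does not amplify noise; order escalates 1 → 2 by F-test (p < 0.01).
Because the ±2 s window derivative carries an O(width²) curvature bias
(~5% in the fast phase at 2 s sampling), the selected-order coefficients
are then refined by integrating the rate law and least-squares matching
x(t) itself, anchored at x = 0 (the normalization makes that the true
start; anchoring at the noisy first point biases the lag-phase
coefficients). Noise-free recovery is then exact to ≲10⁻⁴ relative. For
noisy data, the Fisher information of a single 2 s-sampled trace bounds
k1 recovery at ~21% relative SD per 1% trace noise, so recovery studies
use the mean of four replicate traces, matching typical replicate counts
for these kinetics. A fitted second-order term contributing < 1% of
k0 + k1 demotes to first order.

## Bistable corrals (`bistable`)

g(x) is a polynomial of degree ≤ 3, so steady states are its real roots
in [0, 1] with stability from sign(g′); an identically-zero g (perfectly
matched linear kinase and phosphatase) is flagged as a degenerate
continuum. `bistable_range` brackets the bistable window of any single
rate coefficient by coarse scan plus bisection to the saddle-node edges.
The phosphatase feedback form (p0 + p1(1−x))·x is the minimal first-order
form consistent with product-binding regulation; no quantitative
phosphatase constants exist to fit, so all its coefficients are free
parameters and the demonstration values here are package choices read off
the deterministic phase diagram.

Design of the stochastic comparisons:

- **Problem sizes.** Ensembles use S_total = 5,000 lipids/µm² rather than
  the full 55,555, keeping 100-corral ensembles at 25 µm² to ~10⁵–10⁶
  events each; lipid-number noise is slightly overestimated as a result,
  which is conservative for every "noise decreases with size" claim.
- **Heterogeneity at matched mean rate.** The dimerization-deficient
  (linear-feedback) kinase is matched to the dimerizing kinase's mean
  completion time by raising its solution concentration (4×), as done
  experimentally when balancing the weaker mutant against a phosphatase.
  The resulting higher copy number is precisely why its trajectories are
  more uniform (CV ≈ 0.18 vs 0.33 at 1 µm²). Matching instead by
  rescaling k(x) at equal copy number concentrates the same conversion
  into fewer kinase visits and makes the linear model *noisier* — the
  copy-number route is the faithful one.
- **Geometry sensing.** The demonstration model scales all rate
  constants 10× (identical steady-state structure; per-kinase-visit
  composition jumps scale with k·τ_dwell/N_ss) so that outcome flips of a
  just-outside-bistable, phosphatase-favored reaction occur at observable
  frequency in sub-µm² corrals; the outcome fraction then decays toward
  the deterministic outcome with increasing area.
- Per-corral RNG streams derive from one root seed; outcomes are
  classified at x = 0.5 at t_end (default 30 simulated minutes).

## Known limitations

Dwell and step analyses assume memoryless state kinetics and ignore
state-switching within the dwell of a single molecule when fitting
mixtures (each step is treated as drawn from the occupancy-weighted
mixture — accurate when switching is slow relative to the frame but an
approximation in between). The corral model resolves kinase copy number
but not phosphatase copies or spatial pattern formation; sensor-binding
nonlinearity, ATP/Mg²⁺ dependence, and temperature are out of scope.
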