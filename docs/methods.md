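# Methods

## Study structure emulated by the generator

The synthetic study reproduces a paired soil-warming experiment in a
southern Great Plains tallgrass prairie: four replicate blocks, each
with one infrared-warmed and one ambient control plot, sampled monthly
for one calendar year (96 samples), with daily soil temperature,
volumetric moisture and GPP forcing. Condition presets follow the
emulated site: monthly mean air temperature from 3.5 °C (January) to
28.1 °C (July); soil warming offsets of +3.6 / +4.5 / +4.1 °C in the
early cool, warm and late cool seasons; cool-season moisture reduced
multiplicatively (10.7 → 5.9 %V early, 7.5 → 5.3 %V late; warm season
unchanged); GPP a growing-season pulse peaking near day 150 at
8 g C m⁻² d⁻¹, identical between treatments.

All randomness flows from one master seed through per-generator
`SeedSequence` splits, so identical configurations are bit-identical.

### Site temperature climatology

The monthly air-temperature preset is anchored at the January/July
extremes above and encodes a concentrated late-winter warm-up and a
sharp early-autumn cool-down. This shape matters: the season
segmentation fits a single degree-5 polynomial to the 12 monthly values
and partitions the year at the extrema of its first derivative, and a
smooth sinusoid-like annual cycle puts the steepest fitted rise in
April. The preset was selected (from monotone-up/monotone-down
candidate shapes) so the fitted derivative extrema fall in the
February–March and September–October intervals — the transition timing
characteristic of the emulated site — yielding the
Jan–Feb / Mar–Sep / Oct–Dec partition used throughout.

### Community generator

ASV copy numbers are lognormal (median ≈ 2.5, clipped to [1, 15]).
Counts are Dirichlet-multinomial: a Dirichlet(0.3) base composition per
block-month shared by both treatments, resampled multinomially at a
fixed depth of 21 567 reads (the rarefaction depth of the emulated
study). The warming trait effect is an exponential tilt of the warmed
composition toward high-copy ASVs, with the tilt parameter solved (by
bracketed root finding) so the true community-aggregate log-ratio
equals the configured effect exactly; the default cool-season effect is
+0.10 on the log scale, zero in warm months. The taxonomy/lookup pair
is constructed so the rank-fallback assignment recovers each ASV's true
copy number: 80% of ASVs have species-level entries, 15% resolve
through the genus (child-species mean or genus entry) and 5% through
the family (genus-entry mean).

What the generator does not emulate: phylogenetic correlation of copy
numbers, compositional autocorrelation between months, classifier
confidence miscalibration, and chimeric/denoising artifacts. Passing
tests therefore demonstrate correctness of the estimators under the
assumed sampling model, not robustness to those real-data features.

### Probe-signal generator

Log-normal probe signals with: per-probe baseline ~ N(ln 800, 0.5);
hybridization batches by month half-year with ±0.25 log-scale offsets
(standards carry the same offsets, so standard-probe normalization can
remove them); block effects (sd 0.10); i.i.d. log-scale noise
(sd 0.45); and a warming effect of ln 2 added to warmed cool-month
samples on 85% of the C-decomposition probes, which make up 15% of the
array. Effect size, noise and composition were set so the cool-season
fraction of significantly stimulated C-decomposition probes lands near
the ~80% characteristic of the emulated study while the warm season
stays in single digits. QC fields (spot CV, SNR) are drawn in passing
ranges; QC-rule behavior is tested with hand-built violations.

Mean-normalization against functional probes introduces a small
compositional bias in response ratios when a nonnegligible fraction of
probes shifts in one direction (the array mean absorbs part of the
effect); with 2% of probes affected the bias is ln(1.02) ≈ 0.02, which
is why effect-recovery checks configure small affected sets.

### Respiration observations

Monthly Rh observations are calendar-month means of a forward model run
plus relative Gaussian noise truncated at zero (default 5%). Companion
enzyme "gene-abundance" series are the simulated enzyme pools times an
arbitrary scale with lognormal noise — they enter the objective only
through the correlation of logs, so the scale is irrelevant. Total soil
respiration is emulated as a fixed multiple of Rh so that the
autotrophic component satisfies Ra = Rs − Rh exactly.

## Microbial-enzyme model

Pools (mg C g⁻¹ soil): oxidatively and hydrolytically decomposed
particulate C (P_O, P_H), mineral-associated C (M), adsorbed C (Q),
dissolved C (D), active and dormant biomass (B_A, B_D), oxidative,
hydrolytic and mineral-pool enzymes (EP_O, EP_H, EM).

Fluxes (all biological rates scaled by an Arrhenius factor
f_T = exp(−Ea/R (1/T − 1/T_ref)), Ea = 47 kJ mol⁻¹ ≈ Q10 1.9, and a
saturating moisture factor f_W = min(1, W/30)^½):

* decomposition: V_P·EP_X·P_X/(K_P+P_X) for each particulate pool and
  V_M·EM·M/(K_M+M); a fraction f_D of decomposed P goes to D, the rest
  to M; decomposed M goes to D;
* adsorption/desorption: k_ads·D·(1−Q/Q_max) and k_des·Q;
* uptake: V_g·B_A·D/(K_D+D), split Yg(T) to growth and 1−Yg(T) to
  growth respiration, with Yg(T) = Yg_ref + kYg (T−T_ref) clamped to
  [0.01, 0.99];
* maintenance: α·V_g·B_A (dormant biomass at 1% of that rate);
* enzyme production: p_EP·V_g·B_A split evenly between EP_O and EP_H,
  plus fp_EM·p_EP·V_g·B_A to EM; first-order turnover r_E;
* mortality: 5×10⁻⁴ d⁻¹ (dormant at 10%); dead biomass and spent
  enzymes split g_D to D and 1−g_D to P_H (EM turnover residue to M);
* dormancy: below the moisture threshold ψ_A2D the active pool converts
  to dormant at rate β, above it the reverse.

External input is the daily GPP times a soil-allocation fraction
(default 0.30), split f_INP to the particulate pools and 1−f_INP to D.
Rh = growth + maintenance respiration. Internal units are
mg C g⁻¹ soil d⁻¹, converted to chamber units (µmol CO₂ m⁻² s⁻¹)
through a 0–15 cm soil mass of 1.95×10⁵ g m⁻² (bulk density
1.3 g cm⁻³).

The governing equations of the model family this implements are
conventionally published in supplementary material; the flux forms
above are this package's own transcription of that structure, chosen to
honor the calibrated-parameter list and to keep every flux individually
testable. Fixed kinetic constants (activation energy, V_P, K_P, V_M,
K_M, adsorption/desorption, mortality) are not calibrated, consistent
with a calibration set containing no such terms.

**Integrator.** Explicit Euler at one day with adaptive step halving
whenever a pool would go negative (up to 2²⁰ subdivisions), which makes
the scheme deterministic and exactly conservative: over any window,
Δ(total C) = inputs − cumulative Rh to round-off (verified at 10⁻⁶ of
throughput on multi-year runs). Halving the substep changes cumulative
Rh by ~10⁻⁵ relative on the default scenario. Under constant forcing
the system approaches input–output balance; the mineral pool
equilibrates over centuries, so the steady-state check runs 200 years
and accepts a 5% residual gap.

## Calibration

Objectives: J₁ = 1 − R² on monthly Rh; J₂, J₃ = 1 − r between
log-transformed observed and simulated enzyme series (gene abundances
are proportional, not absolute, hence correlation of logs); weights
(3/5, 1/5, 1/5), normalized at construction. Failed or invalid
simulations score a fixed penalty of 10⁶ (excluded from COFI).

SCE-UA defaults: 2·⌈√p⌉ complexes of 2p+1 points, p+1 competitive
simplex steps (reflection → contraction → random replacement) per
complex per shuffling loop, uniform initialization within bounds,
convergence when the population objective spread falls below 10⁻⁸.
The full evaluation trace feeds COFI: J_cr = J_opt(1 + p/(n−p)
F_{0.95;p,n−p}) with the upper-tail F quantile, the feasible set being
all evaluated vectors with J ≤ J_cr, summarized by per-parameter
coefficients of variation.

**Recovery experiment.** The parameter-recovery protocol frees
(V_g, K_D, Yg_ref, kYg) with the other seven process parameters held at
truth, on a two-year daily window (24 monthly observations) with 5%
observation noise and a 5000-evaluation budget. Freeing more parameters
at this observation density leaves the CUE parameters practically
non-identifiable (compensation through the biomass feedback); the
two-year window mirrors the multi-year assimilation the analysis
emulates while keeping a 20-dataset experiment inside a few minutes.

## First-order baseline

Three serial pools (litter → fast SOM → slow SOM) with first-order
turnover, transfer fractions 0.45 and 0.30, remainder respired;
ξ = Q10^((T−T_ref)/10) · min(1, W/w_opt). The integrator uses the exact
exponential outflow propagator per day, so single-pool decay matches
X₀e^(−ξkt) to machine precision. M-H calibration uses Gaussian
random-walk proposals with reflection at the uniform prior bounds and a
Gaussian likelihood whose variance is marginalized under a Jeffreys
prior (log-likelihood −n/2·ln SSR), giving t-like credible intervals
without a noise hyperparameter.

## CUE analytics

Intrinsic CUE series are Yg(T(t)) on each treatment's own temperature
forcing; sensitivity slopes are OLS regressions of CUE on temperature
(equal to kYg on clamp-free series); the warming effect on sensitivity
is reported as the percent change in slope magnitude. The crossover
temperature solves Yg_w(T*) = Yg_c(T*) in closed form,
T* = T_ref + (Yg_ref,c − Yg_ref,w)/(k_w − k_c), returned only when the
lines are non-parallel, the intersection lies in the queried range and
neither line is clamped there. CUE differences are diagnosed against
the control-plot temperature series. Note that T* depends on a small
intercept difference divided by a small slope difference, so crossover
estimates from independently calibrated parameter sets are
ill-conditioned at demonstration budgets; the study-condition presets
give the exact reference value.

## Condition presets

Control intrinsic CUE: Yg_ref = 0.43 at T_ref = 15 °C with
kYg = −0.0025 °C⁻¹, spanning ≈ 0.39–0.47 over 0–30 °C. Warmed preset:
slope magnitude reduced by 28.7% (kYg = −0.0017825) with the intercept
set so the warmed and control CUE lines cross at 15.7 °C — below that
temperature warming lowers CUE (and raises respiration potential per
unit uptake), above it the difference reverses.

## Numerical choices and edge cases

* Confidence ties at the 50% floor fail the strict "> 50%" rule.
* ASVs with no resolvable copy number are dropped from both sums of the
  community aggregate (logged, never imputed).
* Copy numbers are real-valued means, never rounded.
* Season boundaries are rounded to month resolution; derivative extrema
  are located on a 0.01-month grid of the analytic polynomial
  derivative (no root finding).
* Response-ratio detection grouping defaults to treatment × month
  (options: treatment-wide or global); sub-category ratios default to
  per-sample sums (option: mean of probe-level ratios); significance
  uses the normal CI.
* Degenerate trait distributions (single support point) are flagged and
  exempt from tilting; constant temperature series are flagged and
  refuse partitioning.
* The objective treats missing enzyme observations as satisfied
  (component 0), so Rh-only calibration degenerates gracefully.

## Problem sizes

Defaults are desk-scale: 300 ASVs, 400–1000 probes, one- to two-year
daily forcing windows, SCE budgets of a few thousand evaluations and
MCMC chains of a few thousand steps. These sizes keep the full test
suite and the acceptance script in the minutes range on a single CPU
while exercising every code path; all are parameters, and nothing in
the implementation assumes them.

## Known limitations

* No nitrogen coupling, vertical soil structure or freeze–thaw physics
  in the carbon model.
* Enzyme-pool observations are linked to gene abundances only through
  rank/shape (log correlation), not absolute concentration.
* The delta-method response-ratio CI is approximate at n = 4; its ~5%
  null exclusion rate is verified at the warm-season grouping (n = 28
  per arm), where the approximation is accurate.
* The generator's probe noise is i.i.d. on the log scale; real arrays
  show spatially and chemically structured noise.
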