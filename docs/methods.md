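# Methods

## The system being modelled

The package models a serial-transfer evolution experiment with two
heterotrophic bacteria that differ in resource-use strategy: a copiotroph
(*Serratia marcescens*) that grows fast when resource is abundant, and an
oligotroph (*Novosphingobium capsulatum*) that grows comparatively well
when resource is scarce.  Microcosms hold a single limiting resource
(cereal-leaf extract, 1 g L⁻¹ fresh loading) and are pulsed weekly: a
volumetric fraction *f* of the old culture is carried into fresh medium.
Two regimes are represented, a large pulse (99.9 % of the volume renewed,
*f* = 150 µl/150 ml = 0.001) and a small pulse (70 % renewed,
*f* = 45 ml/150 ml = 0.30).  Clone-level fitness assays are week-long
plate-reader growth curves sampled every 5 minutes, from which four traits
are computed: maximum growth rate, yield, mortality and biofilm
production.

## Batch dynamics (`serialpulse.batch`)

Within one inter-pulse period a microcosm follows Monod resource-limited
batch dynamics,

    mu_i(R) = r_max_i · R / (K_s_i + R)
    dR/dt   = − Σ_i mu_i(R) · N_i / Y_i
    dN_i/dt = (mu_i(R) − d_i) · N_i

with biomass N_i in OD-equivalent units and yield coefficient Y_i in
OD-equivalents per g L⁻¹ of resource.  Species parameters default to the
hay-extract Monod estimates (r_max 0.418 h⁻¹, K_s 1.72 g L⁻¹ for the
copiotroph; 0.103 h⁻¹, 0.29 g L⁻¹ for the oligotroph).  Yield
coefficients and death rates are not published for the original strains;
the batch-level defaults are Y = 1 and d = 0, which keeps the mass balance
N + Y·R exactly conserved and testable.  Biomass is continuous and
deterministic: population sizes stay above ~10⁴ CFU ml⁻¹ in both regimes,
so demographic noise is negligible at the scale of these dynamics.
CFU-per-OD conversion factors are exposed as display constants only.

Integration uses `scipy.integrate.solve_ivp` (LSODA, rtol 1e−8,
atol 1e−11) with a dense interpolant; a fixed-step classical RK4
integrator (`calibration.rk4_reference`) serves as an independent
cross-check and agrees with the adaptive solution to well below 0.1 %.
The weekly transfer operator is exact arithmetic — N → f·N,
R → f·R + (1−f)·R_fresh — so it is linear in biomass and preserves
inter-species ratios to machine precision.

A note on the original inoculation volumes: the starting populations are
described both as percentages of maximum yield (0.1 % vs 30 %) and as
volumes (210 µl vs 6.3 ml), which differ by a factor of 30, not 300.  The
simulator follows the volumetric carryover fractions of the *weekly
transfers* (150 µl and 45 ml of 150 ml), which do reproduce the stated
99.9 %/70 % renewal, and leaves the inoculation-day discrepancy
unresolved.

## Synthetic clone assays (`serialpulse.growth_curves`)

Each simulated clone grows alone in assay medium (R₀ = 1 g L⁻¹) in three
phases: a flat lag of `lag_h` hours; Monod-limited growth integrated with
the batch core until the resource falls below 10⁻⁶ g L⁻¹ (growth
cessation, time t_c); then exponential decline of live biomass at the
clone's death rate d.  Observed OD is

    OD(t) = blank + N_live(t) + φ · N_dead(t),

multiplied by lognormal measurement noise exp(σ·Z).  The dead-cell
opacity φ (default 0.5) reflects that turbidity cannot distinguish live
from dead biomass, so OD-based mortality underestimates cell death: in
closed form the proportional OD mortality is (1−φ)·(1−e^{−d·Δt}) with
Δt the time from growth cessation to the end of the assay — a relation
the tests verify against the extractor.

Defaults (per-well): blank OD 0.05, multiplicative noise σ = 0.01
(typical plate-reader magnitudes), inoculum 0.005 OD-equivalents,
5-minute sampling for 168 h (2017 samples).  Ancestral clone phenotypes
reproduce the ancestral ordering of the two species: the oligotroph has
higher yield (Y 1.1 vs 0.9), lower death rate (0.002 vs 0.008 h⁻¹) and
less biofilm (0.3 vs 0.8 absorbance units) than the copiotroph.

Clone-to-clone variation is lognormal and mean-preserving
(x = m·e^{σZ−σ²/2}), so treatment-cell means are exact regardless of
spread, and treatment effects are multiplicative shifts of those means.
Default spread: CV 0.08 for most parameters (clonal variation is
generally low in this system), with species-specific growth-rate spread —
CV 0.30 for the oligotroph, the magnitude implied by its reported week-1
clonal SD of ≈0.033 on a ≈0.1 h⁻¹ trait, doubling to 0.60 by week 13;
and CV 0.10 for the copiotroph, consistent with its clearly separable
ancestor-vs-evolved growth contrasts.  The default effect table encodes
the qualitative outcome structure of the study system (evolved copiotroph:
death rate ×0.5, growth ×0.85, biofilm ×1.3 in monoculture; oligotroph:
growth ×1.15 after co-culture with a further ×1.10 under large pulses by
week 13, biofilm up at week 1 and partly back down by week 13).  These
effects are *imposed*, not evolved: the generator emulates the outcome of
selection, not the mutational process.

Seeding is hierarchical: every population and clone derives its own
32-bit seed from the master seed and its identifiers via SHA-256, so any
subset of the experiment can be regenerated independently and the whole
dataset is byte-reproducible.

What the generator does *not* emulate: plate effects and well-position
bias, autocorrelated reader drift, evaporation late in the week,
condensation spikes (the extractor's despiking is still exercised by
synthetic spikes in tests), biofilm growing during the OD assay itself,
and any genetic structure below the clone level.  Passing tests therefore
show that the estimators and statistics behave correctly for curves with
the assumed rise–peak–decline structure and noise scale — not that they
are robust to every artefact of real plate data.

## Trait extraction (`serialpulse.traits`)

*Maximum growth rate* is the slope of the steepest regression over any
contiguous window of 30 measurement points, reported with the
30 × 5 min = 2.5 h window convention.  The regression is on
ln(OD − blank) by default, because the trait is a per-capita rate in h⁻¹
comparable to the Monod r_max; a linear-OD mode exists for sensitivity
analysis.  Blank-corrected OD is floored at 10⁻⁴ (detection limit) before
the log and windows entirely at the floor are skipped; a curve that never
leaves the floor reports rate 0 with a degenerate flag.  Ties are broken
by the earliest window, with a 10⁻⁹ relative tolerance so that exactly
log-linear data deterministically report their first window.

The per-window fit is variance-weighted: measurement noise is
proportional to total OD, so by the delta method the standard deviation
of ln(OD − blank) scales as OD/(OD − blank), and each point receives
weight ((OD − blank)/OD)².  Without this, windows in the near-blank
region — where log-noise is amplified roughly tenfold — occasionally win
the max-slope scan and bias the estimator upward; with it, recovery of
the generating r_max is ≲1 % on noiseless curves (the residual being the
Monod factor R₀/(K_s+R₀)) and the 95th-percentile error is ≈9 % at the
default noise level.  Weights are uniform when the blank is zero, and on
noiseless log-linear data weighted and unweighted fits coincide exactly.
For a slow-growing, low-inoculum clone the steepest-window statistic
remains upward-biased at default noise (a max over many noisy windows);
this bias is common to all groups in a comparison and largely cancels in
contrasts.

*Yield* is the maximum of the blank-corrected series after a centred
running-median despike filter (width 5, edge-padded; width 1 disables
it), preventing single condensation spikes from defining the trait.

*Mortality* is total = max − end and proportional = total/max, with end
biomass the mean of the final 12 smoothed samples (the last hour) rather
than the literal last reading, for robustness to endpoint noise.  Using
the same smoothed series for max and end guarantees total ≥ 0.  Curves
whose peak never exceeds the detection floor have undefined mortality and
are flagged.

*Biofilm* is summarised as the time-averaged mean of the 20 h
crystal-violet dissolution read (the original statistic is unstated; the
maximum is available as an option), with point-wise blank subtraction
when a blank series is supplied.

## Statistics (`serialpulse.stats`)

Populations (microcosms) are summarised by the clone mean and the sample
SD (n−1 denominator; the original denominator is unstated) of each trait;
the SD is the estimate of clonal variation.  Ancestor-vs-evolved
contrasts use a two-tailed Welch-type statistic,
t = (m₁−m₂)/√(se₁²+se₂²), with Satterthwaite degrees of freedom — the
exact unequal-n correction used originally (a textbook formula cited by
page number) is not reproduced in the source, and Welch/Satterthwaite is
the standard choice consistent with fractional dfs like 6.4 and 7.1.  Two
modes exist: a summary mode comparing a clone list to a model-estimated
mean ± SE, and a plain two-sample mode on clone lists (with a
pooled-variance Student option for sensitivity).  Degenerate zero-variance
inputs are flagged; equal means give an undefined t, unequal means follow
the infinite-t convention with p = 0.

The multiple-testing family is the four treatment contrasts per trait per
time point: `bonferroni(0.05, 4)` gives the per-test threshold 0.0125 and
family-wise error rates 1−0.95⁴ = 18.55 % uncorrected and
1−0.9875⁴ = 4.91 % corrected.  Significance decisions are pure functions
of (p, adjusted α) and can be re-flagged for a different family size
without refitting.

Changes in clonal variation are tested by the two-sample mode on the
per-population SDs of week 1 vs week 13, reporting mean ± SE of SD per
week.  Trait–trait correlations are Pearson r with the two-tailed
t-transform p-value (`scipy.stats.pearsonr`), restricted in the analysis
scripts to week-13 clones.

`fit_repeated_model` approximates the original repeated-measures analysis
(SPSS GLMM with unstructured within-subject covariance, whose exact
F/df/p output is out of scope) with a linear mixed model: week as
within-subject factor, pulse and diversity as fixed factors, a random
intercept per microcosm, REML fit via `statsmodels` MixedLM, and
fixed-effect p-values from a t distribution with residual degrees of
freedom (better calibrated than the default normal approximation at
n ≈ 24 populations).  Microcosms missing a week are dropped listwise and
reported.  Type-I calibration and power of this approximation are
exercised in the test suite on null and effect-injected summaries.

## Monte-Carlo problem sizes

The calibration studies (`serialpulse.calibration`) are pure functions of
their seed.  The acceptance script runs them at their nominal sizes —
500 clones for noisy growth-rate recovery, 10⁴ null replicates for
two-sample calibration (n₁ = 10, n₂ = 9), 200 replicate experiments for
the mortality-effect power (ancestor vs 2-fold reduced death rate, 10
clones per group, week-long assays) and 200 for the clonal-variation
detection (the full oligotroph arm: 2 pulses × 2 diversities × 3
microcosms × 10 clones per week, growth-rate spread doubled at week 13).
The test suite runs the same studies at reduced replicate counts
(50–120 replicates) with unchanged thresholds, as a fast regression
check.  Clone-assay simulations inside these studies use 48 h assays
where only the growth phase matters (the growth window closes well before
48 h); mortality studies keep the full 168 h assay because the trait
accrues until the end of the week.

## Known limitations

- Treatment effects are imposed multiplicative shifts; there is no
  mutation, selection or demographic stochasticity during the long-term
  phase, and no cross-feeding or interference terms (discussed
  qualitatively in the source system but never parameterised).
- The growth-cessation threshold (resource < 10⁻⁶ g L⁻¹) truncates a
  negligible residual of Monod growth; death begins exactly at t_c.
- Doubling the growth-rate spread at week 13 also inflates the spread of
  extracted yield and mortality (slow clones fail to exhaust the resource
  within the assay), so the synthetic week-13 oligotroph shows variation
  increases in correlated traits, not only in growth rate; likewise the
  generator produces a positive growth–mortality correlation in both
  species, whereas only the copiotroph showed one in the original system.
- OD-based mortality conflates death with lysis/opacity via the single φ
  parameter; CFU-based survival is out of scope.
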