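# Methods

This note documents the models behind `cb1pet`, the defaults it ships, the
numerical choices that matter, and what the synthetic-data tests do and do
not demonstrate.

## Kinetic model and ground truth

Tissue kinetics follow the two-tissue compartment model for a reversible
tracer: free/non-specific concentration C₁ and specifically bound C₂ obey

    dC₁/dt = K1·C_p − (k2 + k3)·C₁ + k4·C₂
    dC₂/dt = k3·C₁ − k4·C₂

with K1 [mL·cm⁻³·min⁻¹] delivery, k2 [min⁻¹] efflux, k3/k4 [min⁻¹]
binding/dissociation, and C_p the metabolite-corrected plasma input.  The
total volume of distribution is V_T = (K1/k2)(1 + k3/k4) (k3 = 0 reduces to
one-tissue K1/k2), and this closed form is the simulator's ground truth.
The ODE system is integrated with LSODA at rtol 1e-8 together with the
running tissue integral as an auxiliary state, so framed activities are
exact frame averages rather than midpoint samples.  A blood-volume fraction
vB is supported but defaults to 0.

Simulated time-activity curves use 33 frames over 120 min (6×30 s, 3×60 s,
2×120 s, 22×300 s); only the frame count and total duration are anchored to
the acquisition protocol, so the inner split is a package choice and is
configurable.  TAC noise is additive Gaussian with SD =
noise_scale·sqrt(activity/frame duration), the standard count-statistics
surrogate in which longer frames are proportionally less noisy; true PET
noise is Poisson-driven and spatially correlated, which this deliberately
does not model.

## Arterial input model

The total plasma curve is a Feng-type model — linear upslope times a fast
exponential plus two slower exponentials, delayed by 0.5 min — with
amplitudes scaled to a peak of ~50 kBq/mL and a terminal clearance of
0.012 min⁻¹, plausible for a ~500 MBq bolus.  The measured study does not
publish its plasma curve shape, so these constants are simulator defaults,
not estimates.  The parent fraction is p(t) = p∞ + (1 − p∞)·Q(α, t/θ) with
Q the regularized upper incomplete gamma (survival function of a gamma
law): p(0) = 1, monotone non-increasing, asymptote p∞.  Defaults
p∞ = 0.12, α = 1.5, θ = 20 min give ~35% parent at 30 min and ~14% at
120 min, a typical profile for a rapidly metabolized arylpyrazole tracer.
"Inverted gamma" fits of parent fractions are not standardized in the
literature; this survival-function parameterization was chosen because it
enforces the three properties above, and a monotone PCHIP spline is the
logged fallback when the parametric fit fails.  Plasma is total/whole-blood
ratio 1.3, treated as constant and, when missing, re-estimated as the
median ratio over samples carrying both measurements.

The corrected input is plasma × p(t) on the sample grid, with an explicit
interpolation contract: zero before the first sample, piecewise linear
between samples, mono-exponential tail fitted to the last three points
beyond the last sample (integration more than twice past the last sample
warns).  Running integrals are computed exactly under that contract.  When
the sample grid is only the 13 discrete draws (first at 3 min), the early
peak is unrepresented and MA1 V_T is biased low by several percent; the
pipeline therefore includes the continuous early segment (10-s sampling to
7 min) by default, mirroring the acquisition protocol.

## MA1, Logan and the composite

MA1 regresses frame activity on the running plasma and tissue integrals
over frames with midpoint > t* = 30 min (weighted least squares, weights ∝
frame duration by default, configurable to uniform):
C_T(t) = −(V_T/b)·∫C_p + (1/b)·∫C_T, V_T = −β₁/β₂.  The tissue integral
uses the trapezoid rule on frame midpoints with C_T(0) = 0.  |β₂| < 1e−12
raises a degenerate-fit error; fewer than 3 usable frames raises an
insufficient-frames error.  Non-positive V_T estimates are retained with an
invalid flag and excluded from composites and regressions.  Logan graphical
analysis (slope of ∫C_T/C_T on ∫C_p/C_T beyond t*) exists purely as an
internal cross-check.

On noiseless simulations MA1 and Logan agree with the closed form to within
1% and 2% respectively across kinetics that approach equilibrium within the
120-min scan.  This is a real validity boundary, not a tolerance artifact:
for slowly equilibrating parameter sets (k4 ≲ 0.03 min⁻¹ combined with slow
k2) both linearized estimators acquire a genuine negative bias of several
percent at this scan length, which is why the validation grid spans the
tracer-like regime the method assumes.

The whole-brain score is Σwᵢ·V_Tᵢ/Σwᵢ over the four cortical lobes and
cerebellum.  The exact atlas volumes used by the study are not published
with it; the shipped weights (frontal 0.30, temporal 0.23, parietal 0.16,
occipital 0.13, cerebellum 0.18) are atlas-plausible relative volumes and
are overridable in configuration.

## Cohort generator

Group sizes default to 19 PTSD / 27 TC / 16 HC with group-specific male
fractions (10/19, 25/27, 9/16), ages (42.6±13.0, 45.8±13.9, 29.4±8.2 y) and
BMI (30.1±5.8, 29.7±6.0, 25.8±4.9 kg/m²).  CAPS-5 totals are 38.4±9.3
(PTSD) and 8.7±6.9 (TC); HC carry no CAPS, and two TC subjects are marked
CAPS-missing so the symptom-analysis subset is n = 44 (19 PTSD, 25 TC), as
in the study.  The published table reports only totals, so the eight factor
clusters (internal/external intrusion, avoidance, negative affect,
anhedonia/emotional numbing, externalizing, anxious and dysphoric arousal)
are generated as an equicorrelated (ρ = 0.6) truncated multivariate normal
with locations proportional to item counts, rounded to integers and capped
at 4 points per item; DSM-5 clusters are sums of factor clusters, so
cluster/total sum-consistency holds by construction.

True regional V_T is baseline + Σ effect·predictor + a shared subject
residual, floored at 0.05 (V_T is a physical ratio).  The residual is
Student-t (df 5) with scale 0.25 V_T units and 5% gross-outlier
contamination (±4 scales) — the kind of heavy-tailed between-subject spread
that motivates the Student-t likelihood downstream.  The 0.25 scale was
calibrated so that a whole-brain symptom-model slope on the default cohort
has a posterior SD of ≈0.007 V_T per CAPS point, matching the precision
scale of the reported symptom models.  The default effect map plants an
anhedonia slope of 0.014 V_T units per CAPS point, the study's headline
association; all other effects default to zero.  Baseline V_T by region
(cerebellum 1.0 … amygdala 1.4) reflects the relative CB1R densities seen
with this tracer class.

What passing generator-based tests shows: the estimation chain is unbiased
and calibrated *under its own assumptions* (known input model, matched
kinetic model, Gaussian count noise, linear effects).  What it does not
show: robustness to model mismatch — dispersion/delay in the arterial line,
motion, partial-volume effects, non-linear symptom relationships — none of
which the generator emulates.

## Robust regression and inference

All three model families share the likelihood V_T ~ Student-t(μ, ν, ε) with
μ = Xβ, priors β_j ~ Normal(0, 1), ν ~ InverseGamma(3, 1),
ε ~ Exponential(1), exactly as displayed in the study.  The InverseGamma
prior concentrates on small degrees of freedom; with realistic residuals
the likelihood dominates and ν posteriors land in the 3–10 range.  Age and
BMI are z-scored (population SD) within each model's analysis subset — the
study is ambiguous between whole-sample and subset standardization, and the
subset choice keeps each model self-contained.  Sex is coded 0 = male,
1 = female, forced by the healthy-control-male reference level; the group
family uses TC and PTSD dummies plus Sex×TC and Sex×PTSD products (8
coefficients).  Cluster scores enter raw, so slopes are V_T units per CAPS
point — forced by the magnitude of the reported anhedonia slope (0.014 per
point).

Sampling uses Hamiltonian Monte Carlo with analytic gradients of the joint
log density (ν, ε on the log scale with Jacobians), leapfrog integration,
dual-averaging step-size adaptation to an 80% target acceptance, jittered
path length ≈2.5, and two windowed diagonal mass-matrix updates during the
1000-step tuning phase; 1000 draws per chain, 4 chains, no thinning.
Divergences (ΔH > 1000 or non-finite) are counted and rejected.  Chain
count is a package choice (the study reports draws/tune/acceptance but not
chains); 4 chains make split-R̂ well defined.  ESS/R̂ come from arviz; a
fit is `converged` only when every split-R̂ < 1.01, every ESS > 1000, and
the divergent fraction ≤ 2% — otherwise the summary is returned with a
warning rather than discarded.  An alternative Gamma-type prior on ν was
considered as a sensitivity switch and deliberately not included: the
displayed priors are the contract, and sensitivity analysis belongs in user
code.

The 89% HPD interval is the narrowest contiguous window containing
⌈0.89·n⌉ sorted draws (exhaustive window scan; ties resolved to the first
minimal window; at least 100 draws required).  `robust` is exactly
"interval excludes 0".  Under a null study-sized cohort the rule excludes
zero in ≈11% of replicates — the expected behaviour of an 89% interval with
priors this weak, and a reminder that "robust" is a decision rule, not a
multiplicity-corrected error rate.  Because HPD endpoints are themselves
Monte-Carlo estimates, very short chains inflate the exclusion rate by a
point or two; the calibration checks therefore use ≥2000 pooled draws per
replicate.

The exact-linear-outcome check adds residual noise of 1e−3 rather than
exactly zero: with a perfectly linear outcome the ε posterior degenerates
(the log-density is unbounded as ε → 0), so "noiseless" is approximated at
the smallest scale that keeps the posterior proper.

## Summary-statistic tests

ANOVA F is reconstructed from (n, mean, sd) triples via SSB = Σnᵢ(mᵢ−m̄)²,
SSW = Σ(nᵢ−1)sᵢ²; Pearson χ² uses no continuity correction; the t tests use
the Welch unequal-variance form because the printed degrees of freedom (10
and 16 for the trauma-count and first-trauma rows) match Welch–Satterthwaite
and not the pooled form.  Checks compare at |Δ| ≤ max(0.02, 1% of printed),
absorbing the rounding of the printed means/SDs.  Four printed statistics
(CAPS-5 t, age-at-presenting-trauma t, race χ², injected-mass F) are not
reproducible from the printed summaries under either t/F variant — most
plausibly different analysis subsets — and are transcribed in the fixture
with `check = False` rather than guessed at.

## Problem sizes and runtime choices

The validation suite uses desk-scale sizes chosen to keep each check sharp
but cheap: the kinetic grid has 10 parameter sets; slope-recovery cohorts
use n = 500 (posterior SE ≈ 0.001, an order below the 0.004 check); the
OLS effect-recovery check uses n = 2000 with a 3-standard-error band; null
calibration uses 200 replicates of the study-sized cohort (binomial SE
≈ 0.022 against the ±0.04 band) with 2 chains × 500 draws per replicate;
Monte-Carlo noisy-MA1 bias uses 100 seeds.  The full pipeline on the
62-subject default (7 regions × 33 frames, 21 models) runs in a few
minutes on one core.

## Known limitations

* MA1/Logan bias for slowly equilibrating kinetics at 120 min (above).
* The arterial model has no dispersion or delay error, so input-function
  round-trip accuracy is an upper bound on real-data performance.
* Composite weights and lobe definitions are surrogates for the study's
  unpublished atlas volumes.
* The generator's regional V_T values share one subject-level residual
  (regions are perfectly correlated up to optional jitter), which is
  adequate for per-region models but would understate multi-region joint
  uncertainty.
* The CLI's `bayes` subcommand exits non-zero when a fit fails the
  convergence gate; with reduced draw counts that is the expected outcome,
  not an error in the model.
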