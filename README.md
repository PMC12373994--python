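# cb1pet

Quantification and inference pipeline for PET studies of cannabinoid
receptor type 1 (CB1R) availability, built around the [¹¹C]OMAR radiotracer
and its application to posttraumatic stress disorder (PTSD).

Brain CB1R availability is indexed by the tracer's total volume of
distribution V_T — the equilibrium ratio of tissue to metabolite-corrected
plasma tracer concentration.  Estimating it from a dynamic PET scan needs a
chain of steps, each of which this package implements as a tested library
module with a thin CLI on top:

1. **Arterial input function** (`cb1pet.input_function`).  Discrete arterial
   blood samples are corrected for radiometabolites: the unmetabolized
   parent fraction measured by HPLC at 5, 15, 30, 60, 90 and 120 min is
   fitted with an inverted-gamma curve p(t) = p∞ + (1 − p∞)·Q(α, t/θ)
   (Q the regularized upper incomplete gamma function, so p(0) = 1 and p is
   monotone), and the total plasma activity curve is multiplied by p(t)
   point by point.
2. **Kinetic modelling** (`cb1pet.kinetics`).  Regional V_T is estimated by
   multilinear analysis-1 (MA1) with t* = 30 min:
   C_T(t) = −(V_T/b)·∫₀ᵗC_p + (1/b)·∫₀ᵗC_T for frames beyond t*, fitted by
   weighted linear least squares, so V_T = −β₁/β₂.  Logan graphical
   analysis is included as an internal cross-check, and whole-brain
   availability is a volume-weighted composite of the four cortical lobes
   and the cerebellum.
3. **Bayesian robust regression** (`cb1pet.bayes`).  Subject-level V_T is
   modelled with a Student-t likelihood, V_T ~ t(μ, ν, ε) with μ = Xβ,
   β_j ~ Normal(0, 1), ν ~ InverseGamma(3, 1), ε ~ Exponential(1) — three
   model families (confounds; group with HC-male reference and group×sex
   interactions; one model per PTSD symptom cluster).  A slope is called
   *robust* when its 89% highest-posterior-density interval excludes zero;
   fits are gated on split-R̂ < 1.01 and effective sample sizes > 1000.
4. **Summary-statistic tests** (`cb1pet.tablestats`).  One-way ANOVA F,
   Pearson χ² and Welch t statistics recomputed from printed group
   means/SDs and counts.
5. **Synthetic study generator** (`cb1pet.synthetic`).  A full ground-truth
   simulator — three-group cohort (19 PTSD / 27 TC / 16 HC) with CAPS-5
   symptom-cluster scores, Feng-type arterial input model, two-tissue
   compartment tissue kinetics on a 33-frame 120-min schedule, and
   configurable linear effects of demographics and symptoms on true V_T —
   so the entire chain is testable without any scanner data.

## Worked example

```python
import numpy as np
from cb1pet import (
    InputFunctionModel, FrameSchedule, KineticParams, analytic_vt,
    simulate_blood, simulate_tac, fit_parent_fraction, build_input_function,
    ma1_vt,
)

model = InputFunctionModel()                   # ground-truth arterial model
blood = simulate_blood(model, seed=1,          # 13 draws, 6 HPLC samples,
                       continuous_dt=1 / 6)    # + 10-s early arterial segment
pf = fit_parent_fraction(blood)                # inverted-gamma fit
input_fn = build_input_function(blood, pf)     # metabolite-corrected input

params = KineticParams(K1=0.3, k2=0.15, k3=0.05, k4=0.05)
tac = simulate_tac(params, model.to_input_function(), FrameSchedule.default())
est = ma1_vt(tac, input_fn, t_star=30.0)
print(f"analytic V_T = {analytic_vt(params):.3f}")
print(f"MA1 V_T      = {est.vt:.3f} ({est.n_frames_used} frames)")
```

prints

```
analytic V_T = 4.000
MA1 V_T      = 3.924 (18 frames)
```

i.e. MA1 applied to a noiseless simulated time-activity curve, using an
input function rebuilt from the sampled blood table, recovers the
closed-form V_T = (K1/k2)(1 + k3/k4) = 4 to ~2% (the residual error comes
from rebuilding the input from finitely many blood samples; with the
densely sampled true input the agreement is better than 1%).

Fitting a symptom-cluster model on a synthetic cohort with a planted
anhedonia/emotional-numbing slope of 0.014 V_T units per CAPS point:

```python
from cb1pet import CohortConfig, generate_cohort, RegressionModelSpec, \
    MCMCSettings, build_design, fit_model

cohort = generate_cohort(CohortConfig(seed=7))
spec = RegressionModelSpec("whole_brain", "symptom", cluster="cl_anhedonia",
                           mcmc=MCMCSettings(seed=11))
summary = fit_model(build_design(cohort, spec), spec)
print(summary.coefficients.loc["cl_anhedonia"].round(4))
```

reports the posterior mean, SD, the 5.5%/94.5% HPD bounds and the
robustness flag for the slope, alongside split-R̂/ESS diagnostics.

The same chain is available from a shell:

```bash
cb1pet simulate --outdir sim --seed 1
cb1pet inputfn fit sim/blood.csv --out sim/input.json
cb1pet bayes symptoms sim/cohort.csv --cluster cl_anhedonia --seed 1
cb1pet tablestats
cb1pet run-all --outdir run --seed 1          # full pipeline + manifest
```

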