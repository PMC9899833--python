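# fcn159pk

Population pharmacokinetics of **FCN-159**, an oral MEK1/2 inhibitor studied
in adults with advanced melanoma and with neurofibromatosis type 1 (NF1), and
the model-informed selection of a pediatric posology.  The package is for
pharmacometricians who want the adult model, its estimation and qualification
machinery, and the pediatric dose-banding simulation as tested, scriptable
Python.

## The model

Drug amount moves through a depot with first-order absorption (rate `KA`,
lag `ALAG`) into a central compartment with first-order elimination and
exchange with a peripheral compartment.  All parameters are apparent
(oral-bioavailability scaled).  The covariate submodel on subject *i*:

```
CL/F_i = 13.2  * exp(eta1) * (BSA_i/1.66)^1.11            L/h
Vc/F_i = 48.7  * exp(eta2) * (BSA_i/1.66)^2.41 * (TP_i/68.95)^-3.1   L
Q/F_i  = 35.1  * exp(eta3) * (BSA_i/1.66)^2.20            L/h
Vp/F_i = 314   * exp(eta4) * (BSA_i/1.66)^3.84 * (1 + 0.751*[female])  L
F1_i   = 1 (melanoma) | 1.29 (NF1)
KA = 0.5 1/h,  ALAG = 0.211 h
```

with `eta_k ~ N(0, omega_k^2)` (omegas 0.19, 0.694, 0.26, 0.265) and a 25.8%
proportional residual error.  Estimation is FOCE with interaction: each
subject's empirical Bayes eta maximizes the conditional density (damped
Newton with complex-step sensitivities through the closed-form
tri-exponential solution), and the marginal -2 log-likelihood is assembled
from the eta-linearized covariance at that mode.

Pediatric extrapolation (2–17 y, BSA 0.55–2.15 m²) carries the allometric BSA
terms, IIV and residual error over unchanged; dose bands map BSA intervals to
fixed integer-mg doses whose simulated steady-state AUC0–24 matches the adult
NF1 exposure at the recommended 8 mg QD dose.

## Worked example

```python
from fcn159pk import (CovariateVector, FixedEffects, Regimen,
                      apply_covariates, exposure)

fe = FixedEffects()                       # shipped final-model estimates
cov = CovariateVector(bsa=1.66, tp=68.95, sex="male", cancer_type="nf1")
p = apply_covariates(fe, cov)             # typical NF1 adult
m = exposure(p, Regimen(dose=8.0))        # 8 mg once daily, steady state
print(m.auc24_ss, m.cmax_ss, m.tmax_ss)
```

prints

```
781.8181818181819 72.78231387241743 1.6895936034562034
```

— the adult reference exposure: AUC0–24,ss ≈ 781.8 ng·h/mL (the analytic
F·Dose/CL), Cmax,ss ≈ 72.8 ng/mL reached 1.69 h after dosing.  A subject at
the population 5th BSA percentile (1.42 m²) has `(1.42/1.66)^-1.11 ≈ 1.19` —
19% higher AUC — which `covariate_effects(fe)` tabulates for every covariate.

The `examples/` directory holds one short script per capability: the typical
profile, the covariate forest table, a small simulated-study fit, pediatric
band construction/refinement, and VPC + bootstrap qualification.  A thin CLI
(`fcn159 generate | fit | simulate | vpc | bootstrap | dose-bands | data
summarize`) wraps the same functions for shell use.

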