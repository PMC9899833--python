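# Methods

## Structural and statistical model

FCN-159 plasma kinetics follow a two-compartment disposition with first-order
elimination from the central compartment and first-order absorption delayed
by a lag time.  The closed-form tri-exponential solution is the only
evaluation path used in production code: the disposition exponents
`alpha > beta` are the roots of `x^2 - (k10+k12+k21)x + k10*k21`, and the
single-dose curve is `C(t) = (F*D*ka/Vc) * sum_j c_j exp(-lambda_j (t-ALAG))`
with the standard partial-fraction coefficients (which sum to zero).
Numerical ODE integration exists only as an independent oracle in the test
suite, where the two paths agree to a relative 1e-6.

Repeated dosing is superposition.  Internally, runs of equal, equally spaced
doses are collapsed to "dose trains" so the superposition becomes a geometric
sum written entirely in non-positive exponents; this is exact, cannot
overflow for arbitrarily long histories, and makes the multi-subject
evaluator a handful of vectorized array operations.  Steady state uses the
analytic accumulation factor `1/(1-exp(-lambda*tau))` rather than long-run
simulation; the finite-superposition profile after 30 daily doses agrees with
it to well under 0.5%.

Units: doses mg, concentrations ng/mL, volumes L, clearances L/h, times h.
The single conversion (mg -> ug, so ug/L = ng/mL) lives in one constant,
`model.MG_TO_UG`.

Between-subject variability is lognormal on CL/F, Vc/F, Q/F and Vp/F with a
diagonal covariance (the final model reports no covariances); none is placed
on KA, ALAG or F.  The published percentage IIVs are interpreted as
`omega x 100` (0.19, 0.694, ...), not as lognormal CVs; at these magnitudes
the two readings differ by <2% except for Vc (69.4%), so the loader exposes
`iiv_as_cv=True` for the alternative reading.  Residual error is proportional
with SD 0.258; an additive component exists as a base-model option only.

## Exposure metrics

AUC0-24,ss is the linear-PK identity `F*Dose/CL` (cross-checked against
trapezoidal integration at 0.001 h within 0.5%).  Cmax,ss/Tmax,ss come from a
0.001 h grid over one interval plus bounded scalar refinement; the batched
simulators use a 0.002 h grid with one parabolic refinement step, which
agrees with the scalar path to ~1e-6 relative and is orders of magnitude
faster for thousands of subjects.

## FOCE-I estimation

The inner problem finds, per subject, the eta maximizing the conditional
joint density.  It is solved for all subjects simultaneously by a damped
(Levenberg-Marquardt) Newton method: sensitivities of the prediction with
respect to eta come from complex-step differentiation through the closed
form (exact to machine precision); the curvature uses the exact second
derivative of the per-observation loss with respect to the prediction
(clamped positive), dropping only the second-derivative-of-the-model term in
Gauss-Newton style.  Rejected steps raise a per-subject damping factor
instead of moving.  Convergence: per-subject gradient below
`1e-8 * max(1, |h|)` with an absolute floor of 1e-5 (below that, improvements
are smaller than double-precision resolution of the objective); maximum 100
iterations; modes are warm-started across outer iterations and clamped to
|eta| <= 12.

The marginal objective is the standard FOCE-I expression: with `G` the eta
sensitivities at the mode, `V = diag(sigma^2 f(etahat)^2) + G Omega G'` (the
interaction: residual variance at the individual prediction) and
`r = y - f(etahat) + G etahat`,

    OFV = sum_i [ log det V_i + r_i' V_i^{-1} r_i ] + N log 2pi,

evaluated with the matrix-determinant lemma and Woodbury identity so all
per-subject linear algebra is K x K (K = number of IIVs).

The residual-variance prediction is floored at 0.1 ng/mL (half the assay
LLOQ).  This bounds the weight of grossly mispredicted points during early
optimization; since BQL observations are excluded before fitting, no
analyzed observation sits below the LLOQ, and at convergence the floor is
inactive for essentially all points.  Gradient and curvature terms arising
from the variance's dependence on the prediction are switched off below the
floor so the gradient is exactly consistent with the objective.

The outer optimizer is L-BFGS-B on transformed parameters (log for
positives, log1p for categorical fractions, identity for power/linear/
exponential coefficients) inside wide physiological sanity boxes (e.g. CL/F
in [0.05, 500] L/h, proportional residual SD <= 1.0).  The absorption lag is
additionally bounded below 95% of the smallest observed time-after-dose:
past that point a sample would predate absorption entirely, the likelihood
is cliff-edged, and the lag is unidentifiable.  Forward-difference gradients
use a 3e-5 step, large enough to dominate the ~1e-6 noise left by the inner
solver.  Because a conditional-likelihood surface far from the optimum is
rugged (a degenerate "all variance" mode exists with inflated sigma), `fit`
is staged by default: a naive-pooled fit (eta = 0, exact objective, <1 s)
first localizes the fixed effects — ordinary initial-estimate practice —
and the full conditional fit starts there.  Convergence follows the
optimizer's relative-reduction criterion (ftol 1e-9).

Standard errors come from a central finite-difference Hessian (step 0.01 on
the transformed scale), covariance `2 H^{-1}` mapped to the natural scale by
the transform Jacobian.  The condition number is the eigenvalue ratio of the
correlation-scaled covariance of the fixed effects (scale-invariant); the
raw-covariance reading is available as a switch.  CWRES standardizes
`y - (f(etahat) - G etahat)` by the same marginal covariance; eta shrinkage
is `1 - sd(etahat)/omega`.

Covariate search: forward inclusion accepts the candidate with the largest
OFV drop exceeding the chi-square 0.05 quantile (3.84 for one parameter),
refitting after each addition; backward elimination removes terms whose
removal raises OFV by less than the 0.01 quantile (6.63).  The allometric
BSA terms are locked (included by default, never tested).  Categorical
candidates whose minority level covers <10% of subjects are excluded up
front with a logged reason.  After the search, `reassess_iiv` drops random
effects estimated below 1e-3 or with RSE > 200% and refits once.  AIC is
`OFV + 2 * n_parameters`.

## Qualification

The VPC bins observations by time after dose with quantile-spaced edges
(8 bins by default; bins under 5 observations merge leftward, logged),
stratified by study population, and overlays observed 5th/50th/95th
percentiles on the 2.5–97.5 percentile band of the same quantities across
model-simulated replicates of the identical design.  Plain (not
prediction-corrected) VPC, matching the original analysis.  On data
simulated from the checked model, ~95% of percentile cells fall inside their
bands; the acceptance suite requires >= 90% at 200 replicates.

The bootstrap resamples subjects with replacement stratified by study
population, because cancer type drives the relative-bioavailability term and
an unstratified resample can produce single-type sets that make F1
unidentifiable.  "Converged" means optimizer success (a positive-definite
covariance is not required), and percentile intervals use converged runs
only.

## Synthetic studies

The generator emulates the two adult trials: 33 melanoma patients across
nine QD dose arms 0.2–15 mg (21-day dosing for 0.2–4 mg, 28-day for 6–15 mg)
each with a single-dose PK run-in and a 72 h washout before continuous
dosing; and 12 NF1 adults at 4–12 mg QD for 28 days.  Covariates: BSA
truncated normal (mean 1.66, SD 0.20, bounds 1.33–2.16 m²; the SD is chosen
so the 5th/95th percentiles land near the reported 1.42/2.01), age uniform
20–71 y, total protein normal with SD 4.83 g/L (placing the 95th percentile
near the 76.89 g/L perturbation point — an inference, not a reported value),
albumin N(40, 4) g/L, 60% male, and a weight back-calculated from BSA through
the Livingston relation for consistency.  Covariates are drawn independently;
real joint structure (BSA-sex-weight correlation) is not emulated, so tests
passing here say nothing about covariate-correlation robustness on real data.

Sampling schedules are a design choice (none are published): the melanoma
run-in samples 14 times over 0.25–72 h, plus a rich last-dosing-day profile;
the NF1 study samples the first dosing day, pre-dose troughs on days 8/15/22,
and a rich day-28 profile.  That yields 1089 observations for 45 subjects;
`fixture_mode` appends one deterministic late trough to reach the published
1090 and then deterministically nudges borderline values across the 0.2
ng/mL LLOQ so exactly 60 rows are BQL (the natural count varies by seed).
Nudged rows are BQL and therefore excluded before any estimation; the
analysis set is untouched.  Every random draw flows through named
substreams `(seed, replicate, subject)`, so outputs are bit-reproducible and
stable under changes of replicate or subject counts.

## Pediatric dose banding

The extrapolation to 2–17 y (BSA 0.55–2.15 m²) keeps bioavailability, IIV
and residual error at adult values and applies no maturation function (the
relevant CYPs are essentially adult from age 2); the module refuses BSA below
0.55 m² rather than extrapolate.  Virtual children are NF1, sex Bernoulli
(0.5), total protein fixed at the adult median 68.95 g/L (no pediatric TP
distribution is available and the TP effect is not clinically meaningful);
all of these defaults are arguments.

Two dose rules are implemented: linear 4 mg/m² (the selected starting rule)
and exposure-matched power `8 * (BSA/1.66)^1.11` mg.  Initial band cutoffs
are the exact BSA preimages of half-integer doses, clipped to the pediatric
range, doses capped at the 8 mg adult RP2D and floored at the 1 mg tablet.
Refinement replaces the published manual tuning with a deterministic
coordinate search: interior cutoffs move on a 0.005 m² lattice to minimize
the summed absolute difference between each band's median simulated
AUC0-24,ss and the adult median, with common random numbers so the objective
is a deterministic function of the cutoffs.  Cmax,ss is reported per band
but deliberately excluded from the objective (AUC is the primary matching
metric).

## Problem sizes and numerical choices

Default problem sizes used by the tests and the acceptance script: 45
subjects / ~1030 analyzed samples per estimation dataset (the study's own
size), three seeds for parameter recovery, 200 VPC replicates, a 20-run
bootstrap of a 16-subject reduced-model trial, and 500 simulated subjects
per dose band.  The full-size options (1000 replicates, 1000 bootstrap runs)
are plain arguments.  Degenerate inputs are handled explicitly: `ka` equal
to a disposition root raises with a perturbation hint; omega = 0 collapses
the objective to the pooled extended-least-squares limit; shrinkage is
reported absent when omega is zero; a single replicate collapses VPC bands.

## Known limitations

The estimator is FOCE-I only (no SAEM or importance sampling), BQL handling
is exclusion only (no M3 likelihood), there is no inter-occasion variability
and no infusion/steady-state dosing records.  Forest-table Cmax ratios are
reported but not asserted anywhere: the published construction for those
percentages is under-specified and could not be reproduced by independent
hand computation.  Observed-vs-model-typical terminal half-life differences
are likewise out of scope.
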