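# Methods

## The interest parameter

For a binary treatment A and binary outcome Y in a fixed context (a
population located in time and space), the average causal effect (ACE) is

    psi = Pr(Y^1 = 1) - Pr(Y^0 = 1) = mu_1 - mu_0,

where Y^a is the Neyman potential outcome under treatment set to a. The
axioms of probability place psi in the parameter space [-1, 1]. Only one
potential outcome per unit is observed, so psi must be *identified* —
re-expressed in terms of available information — before it can be computed
or estimated. The package implements two routes to (partial) identification
and keeps them deliberately parallel: a statistical route driven by sampled
data, and a mechanistic route driven by component functions and parameter
ranges.

## Statistical identification (`statistical_id`)

**Nonparametric bounds.** Decomposing mu_a by the received treatment and
applying causal consistency (Y = Y^A) leaves a single unidentified term,
Pr(Y^a=1 | A != a), known only to lie in [0, 1]. Imputing its extremes
gives per-arm bounds

    mu_a in [ Pr(Y=1,A=a),  Pr(Y=1,A=a) + Pr(A != a) ]

and, differencing arms in opposite directions, ACE bounds

    psi in [ -Pr(Y=0,A=1) - Pr(Y=1,A=0),  Pr(Y=1,A=1) + Pr(Y=0,A=0) ].

Two structural facts follow algebraically and are enforced by tests: the
interval width is exactly 1 (half of the parameter space), and the interval
always contains 0 — observed (Y, A) data alone can never certify an effect.
The upper bound is implemented as the *sum* Pr(Y=1,A=1) + Pr(Y=0,A=0);
a difference in that position would contradict both the width-1 identity
and null containment, and does not follow from differencing the per-arm
bounds. The brute-force cross-check (enumerating the four extreme
imputations) lives in the test suite, independent of the closed forms.

**Randomization.** Unconditional randomization gives marginal
exchangeability with positivity by design, so psi is point-identified by
the contrast of weighted observed arm means. A missing arm raises a
positivity error rather than returning a value.

**G-formula.** Under conditional exchangeability given covariates W with
positivity, mu_a = E_W[ Pr(Y=1 | A=a, W) ]. The estimator fits an outcome
model m(A, W; gamma), predicts m(a, W_i; gamma_hat) for every record with
the treatment *set* to a, and averages the predictions with the sampling
weights. The estimator is the weighted mean of the set-treatment
predictions — a plain sum over records evaluated at the received treatment
would estimate neither mu_1 nor mu_0 and is not what the identification
expression calls for. Two model kinds are supported: a saturated
stratification (exact weighted cell means; correct specification holds by
construction for discrete W, and empty (a, w) cells raise positivity
errors while zero-weight strata are dropped with a warning) and a logistic
regression (statsmodels GLM/Binomial, IRLS to tolerance 1e-8, at most 100
iterations, sampling weights as case weights). With a single binary
covariate and a treatment-by-covariate product term the logistic model is
saturated, which the tests exploit as an equivalence oracle.

## Mechanistic models (`mechanistic`)

A mechanistic model for the mediator structure A -> M -> Y needs no data:
a mediator law g(a; theta) = Pr(M=1 | set A=a) and an outcome law
h(a, m; lambda) = Pr(Y=1 | set A=a, M=m), with treatment set
deterministically (Pr(A=a) := 1 under intervention). The computed arm mean
marginalizes the binary mediator with its probability mass,

    mu_bar_a = h(a,1;lambda) g(a;theta) + h(a,0;lambda) (1 - g(a;theta)),

i.e. the mediator mass enters as g^m (1-g)^(1-m); and
psi_bar = mu_bar_1 - mu_bar_0.

**Bounds over parameter boxes.** Point identification corresponds to an
oracle handing over the true (theta*, lambda*). Short of that, the
*model-capture* assumption — the true mechanism probabilities lie within
the images of g and h over declared ranges Theta* x Lambda* (a parameter
box) — yields partial identification: psi lies between the minimum and
maximum of psi_bar over the box. Two search strategies are provided:

* `grid` — a full product grid, default 25 points per free dimension,
  endpoints included. 25 keeps a 3-parameter box at 15,625 evaluations
  (well under a second) while making discretization error negligible for
  the smooth models shipped here.
* `corners` — only the 2^k box vertices. Exact when psi_bar is monotone in
  every free parameter; therefore the strategy refuses to run unless every
  free parameter carries a declared monotonicity direction. Degenerate
  (fixed) entries never need declarations.

Shrinking a box can never widen the resulting bounds; the property tests
check this directly.

**Vacuousness.** A model is *vacuous* when its achievable psi_bar values,
together with the closure points {-1, 0, 1}, span the whole space [-1, 1]:
the functional form then imposes nothing, and every structural assumption
lives in the parameter choices (e.g. "A has no direct effect on Y" is
lambda1 = lambda3 = 0 in the logistic example, not a different function).
Set equality is not decidable by finite computation, so
`vacuousness_diagnostic` is explicitly a *numerical probe*: for each
magnitude c in a schedule (default 10, 20, 40) it searches psi_bar over
parameter vectors whose entries are capped at |c| (intersected with the
declared spaces) and records the achieved envelope. The verdict is
"vacuous-compatible" when the envelope reaches within tol (default 0.01)
of both endpoints at the largest magnitude, else "non-vacuous-evidence"
with the achieved envelope; it is evidence, never proof. The search
combines a 5-level lattice per dimension ({-c, -c/2, 0, c/2, c}, clipped
to the space) with seeded uniform draws and an L-BFGS-B polish of the best
candidates. Pure +/-c corner search is insufficient — the logistic
example's extremes need mixed-magnitude points such as theta = (-c/2, c) —
which is why the lattice includes half-magnitudes and zero. Only the
psi_bar envelope decides the verdict; per-component envelopes of g and h
are reported as supplementary output because one can also ask whether each
component's image covers [0, 1].

## The amlodipine case study (`pharmacodynamic`)

The question: among US adults (18+) with systolic blood pressure (SBP) of
at least 140 mm Hg, the difference in risk of hypertension 24 h after
10 mg amlodipine versus placebo. Components:

* **f(b)** — the baseline SBP density, represented nonparametrically as a
  weighted cohort with the hard support constraint f(b) = 0 for b < 140.
  The filter is the strict exclusion b < 140 (a reading exactly at 140 is
  kept), the literal form of the constraint.
* **g(theta) = theta0 * theta1** — effective concentration at 24 h: dose
  (mg) times the fraction of active drug remaining, theta0 >= 0,
  theta1 in [0, 1]. Placebo means theta0 = 0.
* **Hill (E-max) response** — predicted SBP at 24 h is
  ybar = b - (lambda0 + a lambda1 m/(lambda2 + m) + a lambda3), with
  lambda0 a constant shift (mm Hg), lambda1 the maximum response (mm Hg),
  lambda2 >= 0 the concentration at half-maximal response (mg; the
  half-max identity ybar = b - lambda1/2 at m = lambda2 is a unit test),
  and lambda3 a direct effect not through concentration. The binary
  outcome is h = 1{ybar < 140}, strict at the boundary.

**Outcome coding.** h = 1 means hypertension *resolved* (SBP below 140 at
24 h), exactly as the indicator is written; a positive psi_bar therefore
means benefit. This is stated prominently because "risk of hypertension"
phrasing would suggest the opposite sign.

**Negative predictions.** ybar can go negative for extreme parameters.
Values are not clamped — the indicator is evaluated on the raw prediction —
but the first occurrence per process logs a warning (subsequent
occurrences log at debug level to keep grid searches readable).

Arm means are cohort-weighted averages of the indicator; the integral over
f is computed exactly as a finite weighted sum because f is empirical.
With lambda0 = lambda3 = 0 the placebo arm mean is identically zero on any
supported cohort — the untreated prediction is b itself, never below 140 —
so psi_bar reduces to the treated arm mean. The code still computes the
placebo arm rather than assuming it away, and the identity is an
acceptance-level test.

**Boxes.** The literature-informed default boxes are theta1 in
[0.25, 0.40] (24 h pharmacokinetics), lambda1 in [16.3, 36.3] mm Hg and
lambda2 in [0.1, 13.0] mg (pharmacodynamic dose-response studies), with
lambda0 = lambda3 = 0 fixed. psi_bar is nondecreasing in theta1 and
lambda1 and nonincreasing in lambda2 (a larger half-max concentration
weakens the response at fixed m), so the corner strategy needs only the
two extreme vertices (theta1 low, lambda1 low, lambda2 high) and (theta1
high, lambda1 high, lambda2 low); grid and corners agreeing to 1e-9 is an
acceptance-level test.

**NHANES reconstruction.** The cohort for the headline numbers is NHANES
2017-2018: first measured SBP (BPXSY1) >= 140, age (RIDAGEYR) >= 18,
two-year examination weights (WTMEC2YR), files BPX_J.XPT / DEMO_J.XPT
merged on SEQN. The survey names the cohort but not the exact variable
mapping; this mapping is a documented reconstruction, every name is
overridable, and records with missing SBP/age/weight or nonpositive weight
are dropped with logged counts. The >= 140 inclusion (rather than strictly
above) follows the support constraint's boundary semantics. No
survey-design variance estimation is attempted; weights enter point
computations only, and the sampling uncertainty of the empirical f is not
propagated. The package builds and tests without these files; only the
one reproduction test needs them, reading from `data/nhanes/`.

## Synthetic generators (`synthetic`)

**Observational DGP.** W ~ Bernoulli(pw); A | W ~
Bernoulli(expit(alpha0 + alpha1 W)); potential outcomes Y^a | W ~
Bernoulli(expit(beta0 + beta1 a + beta2 W)); Y = Y^A. Each unit draws one
uniform per arm shared across the two expit thresholds, which fixes a
joint law for (Y^0, Y^1) — more than identification needs, but it makes
the empirical ACE from attached potential outcomes computable and stable;
the marginals are unaffected. Defaults (pw = 0.4, alpha = (-0.4, 1.2),
beta = (-1.0, 0.7, 0.9), n = 1000) encode a moderately confounded
observational study in which W raises both treatment uptake and outcome
probability. `true_ace` gives the closed-form psi by summing the stratum
contrasts over the W distribution, and `population_joint` the exact
population (Y, A) table, so containment and recovery are testable without
Monte-Carlo error in the truth.

**SBP cohort.** SBP = location + Gamma(shape, scale), right-skewed,
rejection-sampled above the truncation point; weights are Gamma with unit
mean and coefficient of variation `weight_dispersion`. Defaults (location
120, shape 4, scale 8, truncation 140, dispersion 0.5) give mean ~152 and
SD ~16 mm Hg before truncation with roughly three quarters of draws
surviving the cutoff — a plausible hypertensive-clinic shape with
survey-style weight heterogeneity. These are documented fixtures chosen
for shape, not calibrated to NHANES or any survey: passing tests show the
pipeline's algebra and monotonicity on realistic-looking inputs, not
fidelity to US blood-pressure data. The generators emulate neither survey
design (strata, clustering, nonresponse) nor measurement error.

All generators run off a single integer seed through named
`numpy.random.Generator` instances; there is no global RNG state.

## Numerical choices and degenerate inputs

* Joint tables validate nonnegativity and unit sum to 1e-12; weighted
  proportions are computed from unnormalized weights in one division.
* Bounds objects enforce space_lower <= lower <= upper <= space_upper at
  construction (tolerance 1e-12), so impossible intervals fail loudly.
* Empty samples, all-zero weights, single-arm samples, empty saturated
  strata, non-convergent logistic fits, cohorts entirely below support,
  inverted boxes, and the undefined Hill point lambda2 + m = 0 each raise
  a distinct, typed error rather than returning a value.
* The case-study vacuousness probe floors its lambda2 search space at
  1e-6 to stay off that undefined point; the envelope is insensitive to
  the floor. Its magnitude schedule (50, 100, 200) exceeds the generic
  default because reaching psi_bar = -1 requires |lambda0| and |lambda3|
  beyond max(b) - 140.
* Grid searches include interval endpoints; ties between equal extremes
  are irrelevant since only min/max are reported.

## Problem sizes

Default verification sizes were chosen so the whole suite runs in well
under a minute: 1,000 random joints for the bound identities, 100 random
parameter points on a 1,000-person synthetic cohort for the placebo
identity, 500 random DGPs for containment, one n = 50,000 draw for
g-formula recovery (tolerance 0.02, comfortably above the ~0.004
Monte-Carlo standard error), and 10^6 draws for the mechanism Monte-Carlo
oracle (3-standard-error agreement).

## Known limitations

* Bounds are point computations; no sampling uncertainty for bounds, the
  g-formula, or the empirical f is provided.
* No interference between units, no time-varying treatments, no
  differential-equation mechanisms, no continuous mediators in the generic
  mechanistic module (the case study handles its continuous baseline by
  direct summation over the cohort).
* The vacuousness verdict is a bounded numerical search; a
  "non-vacuous-evidence" verdict can in principle be overturned by a
  larger magnitude schedule.
* The corner strategy trusts the declared monotonicity; declaring a wrong
  direction silently yields corner bounds that a grid run would contradict
  (the cross-strategy tests exist for exactly that reason).
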