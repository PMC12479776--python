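# Methods

## The choice model

Each trial of the 216-trial session offers a fixed low option (low
incentive, effort level E0) against a high option defined by valence
(gain/loss), incentive level *I* ∈ {1,2,3} and effort level *E* ∈
{1,2,3}.  The decision variable is the subjective value of accepting
the high option,

    SV = bias + kR·I                      (gain trials)
       = bias + kP·I                      (loss trials; value of the avoided loss)
       −  (kEp + kFp·fatigue)·E           (physical trials)
       −  (kEm − kLm·learning)·E          (mental trials)

and P(high) = 1/(1+e^(−SV)).  `fatigue` is cumulative chosen physical
effort normalized by the session maximum (108 physical trials × E3), so
it grows only when effortful physical options are accepted; `learning`
is the fraction of mental trials already completed, growing by 1/108
per mental trial regardless of the choice.  Incentives and efforts
enter as level indices rather than monetary/force units because levels
are calibrated per subject — indices are the comparable scale.
Confidence is described as 2·|p − 0.5| and excluded from the
likelihood.  Learning may drive the instantaneous mental cost negative
for extreme kLm; no floor is applied (the fitting prior makes that
region improbable).

Because fatigue and learning are rolled forward from observed choices,
SV is linear in the natural parameters given the data.  The likelihood
is therefore a sign-constrained logistic regression, and gradients and
Hessians are exact.

## Fitting

Per-subject inversion is MAP estimation with a Laplace posterior.  The
six sensitivities are positive by construction through an exponential
latent mapping (natural = exp(latent)); the bias is identity-mapped.
Priors are independent N(0, 1) on the latent scale — weakly
informative, mirroring variational-Bayes toolbox defaults.  The
optimizer is L-BFGS-B with analytic gradients, latent bounds ±15, and
multi-start (prior mean plus prior draws; 5 starts by default, fewer in
large simulation sweeps where the objective is well-behaved).  Per-trial
probabilities are floored at 1e-10 in the likelihood to avoid −∞ under
saturated parameters.

The posterior covariance is the inverse exact Hessian of the negative
log-posterior at the mode (ridge-regularized and flagged when
indefinite).  The reported free energy is the standard Laplace value,
log-posterior(mode) + ½·log det(2πΣ) — identical to what iterative
variational schemes reach at convergence in the Laplace limit, and used
here for model comparison alongside AIC/BIC (computed from the
likelihood at the MAP).  Fit quality is summarized by the median
absolute error between predicted choice probabilities and 0/1 choices
and by the squared Pearson correlation between them; the latter is one
of several possible readings of a "goodness-of-fit R²" and is the one
this package commits to.

Fitted sensitivity parameters are strongly right-skewed, so cohort
tables are Box–Cox transformed per column (λ by profile maximum
likelihood, +1e-6 shift when zeros occur); the bias column is left
untransformed.

### Known estimator bias

On data simulated from the prior, recovered latents are unbiased for
the bias term, but the six sensitivity latents carry a small upward
mean shift (~0.1–0.2 latent SD at 216 trials).  With an exponential
link the likelihood is flat as the latent goes to −∞, so strongly
negative generative latents are recovered at a finite prior/likelihood
balance point.  This is intrinsic to MAP under a positivity link, does
not depend on optimizer restarts, and does not materially affect the
correlation-based recovery and identifiability analyses, which are
invariant to location shifts.

## Recovery and identifiability

The validation loop draws latent parameter vectors from N(0, 1)^7,
simulates one 216-trial session each (alternating counterbalance arms),
refits the full model, and assembles (a) the confusion matrix
corr(simulated_i, recovered_j), (b) the identifiability matrix of
pairwise correlations among recovered parameters, and (c) batch
recovery rates: in each batch of 100 simulations a parameter counts as
recovered iff its simulated–recovered correlation is the largest entry
of its confusion-matrix row and significant at p < 0.05.  All
correlations are computed on the latent scale, where the sampler is
Gaussian.  The default is 300 simulations (the original analysis used
30,000; the desk-scale matrices are noisier but test the same bounds).
Under this criterion all seven parameters saturate at a 100% batch
rate; on the finer diagonal-correlation measure the dynamic modulators
are hardest to recover (the fatigue weight especially, since realized
cumulative fatigue spans only a fraction of its normalized range).

## Prediction pipeline

The metabolite→behavior pipeline mirrors standard small-N ML practice:
random train/test split (80/20, or 75/25 for parameter targets);
stage-1 screening dropping features with |Pearson r| < 0.1 against the
target on training rows (absolute value: negative predictors are
informative too); stage-2 selection ranking the survivors by AdaBoost
importance and keeping the importance-ranked nested subset (k = 1..K)
with minimal leave-one-out CV error; an XGBoost regressor whose six
hyperparameters (eta, max_depth, min_child_weight, gamma, lambda,
alpha) are tuned by Bayesian optimization — a Gaussian-process
expected-improvement loop over the unit-cube-scaled search space
(log-scaled eta and lambda), initialized with random draws — against
the leave-one-out RMSE; holdout evaluation (RMSE, one-tailed Pearson r,
r² as variance explained).

The permutation null retrains the model on label-shuffled training data
with hyperparameters frozen at the unpermuted optimum (re-tuning per
permutation would be intractable and changes the null hypothesis being
tested); the threshold is the k-th smallest permuted RMSE with
k = floor(0.05·n_perm) — the 250th order statistic at the reference
n_perm = 5000 — so a significant model beats 95% of null performance.
Shapley attributions are exact TreeSHAP values computed by the gradient
boosting library itself, satisfying local accuracy to float32
precision; rankings use mean absolute attribution.  The linear-vs-
inverted-U comparison fits y ~ x and y ~ (x − x̄)² by OLS and compares
AIC/BIC.

Everything upstream of evaluation (screening, subset search, tuning)
reads only training rows; this is enforced structurally and verified by
a test that perturbs test-row labels and asserts identical selection
and hyperparameters.

## Synthetic cohorts

The cohort generator emulates the study's statistical structure, not
its biophysics.  Eleven brain metabolites are sampled from a Gaussian
copula (common latent correlation 0.20) with log-normal margins at
plausible 7T-MRS concentration scales (e.g. Glu 10, NAA 12, Asp 2.5
a.u., CV 10–15%); Glx = Glu + Gln and six ratios to total creatine
complete the 18 features.  Plasma Glu/Gln/Asp/Lac are generated with
latent correlations to their brain counterparts of 0.54 (Gln), 0.27
(Lac) and near-zero (Glu, Asp).  Behavioral latents are Gaussian with
scales 0.40–0.55 — narrower than the recovery sampler, giving
realistically dispersed choice proportions — with three planted paths:
aspartate → mental-effort sensitivity (the r ≈ 0.42 link), a
centered-square glutamate term → mental-effort sensitivity (the
inverted-U, |r| ≈ 0.36), and aspartate → mental learning (closing the
gap to the aspartate–HME link of r ≈ −0.37).  One 216-trial session is
simulated per subject, and HME/HPE are realized choice proportions, so
the metabolite–behavior links pass through the full generative choice
model rather than being painted onto summary statistics.

Path coefficients were calibrated once by simulation
(`scripts/calibrate_cohort.py`) so the *raw-scale* sample correlations
hit the targets — the exponential parameter mapping and the realized
choice noise attenuate latent correlations, so latent weights are
larger than the target r values.  The raw-scale correlation against a
log-normal quantity has a heavier-tailed sampling distribution than the
normal-theory SE suggests; QC at N = 1000 uses 3·SE bands and passes
for typical seeds, with occasional borderline draws expected.

What the generator does not emulate: empirical metabolite covariance
(unknown; the copula is an assumption), measurement noise of spectral
quantification, effort-execution performance, and any region
specificity — an AI-like control region can be generated but carries no
planted behavioral links.  Passing tests therefore demonstrate that the
pipeline detects links of the reported strength under clean Gaussian-
copula features, not that the original biological claims replicate.

## Problem sizes

Default analysis scales are chosen for a laptop-class single core: 300
simulate-and-refit runs for recovery (vs 30,000 originally), 150–200
label permutations in tests (5000 is the reference default and the
order-statistic rule is tested at that size), GP tuning budgets of
12–40 evaluations, and N = 71/1000 synthetic cohorts.  All stochastic
stages take explicit seeds; one master seed fans out to independent
streams per stage.

## Limitations

* The subjective-value equation is the minimal additive form in which
  each named sensitivity plays its described role; richer forms
  (nonlinear incentive scaling, monetary amounts) are deliberately out
  of scope.
* Model evidence uses the Laplace approximation at the MAP rather than
  full variational iteration; nested-model likelihood monotonicity and
  complexity penalization are verified by tests, but evidence values
  are approximate.
* The recovery "success" criterion is an operationalization (the
  original rule is unpublished); rates are comparable in spirit, not
  numerically identical, to the original report.
* Small-sample ML results are sensitive to split and tuning seeds; the
  end-to-end power check therefore aggregates over 20 seeds rather than
  interpreting any single run.
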