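# Methods

## Model

`codaratio` learns an additive classifier in logit space,

    f(x) = Σ_k [ α_k + β_k · R(x; J+_k, J-_k) ],

where each `R` is either a balance (log-ratio of geometric means) or an
amalgamation (log-ratio of sums) over a sparse pair of disjoint feature
subsets, and the outcome is binary with `P(y=1|x) = sigmoid(f(x))`. Both
ratio families are scale-invariant: multiplying a sample's abundances by any
positive constant leaves every ratio, and hence every prediction, unchanged.
This is the property that makes the model meaningful for compositional data,
where totals are an artifact of the measurement process. Natural logarithms
are used throughout; any other base would be absorbed by β. The classical
normalization constant of balances is likewise omitted, since it too is
absorbed by β.

Finding the subsets directly is a combinatorial problem (more than 2^p
candidate pairs). Each stage instead optimizes a continuous relaxation:
soft assignments `w̃ = 2·sigmoid(w) − 1`, with positive parts weighting the
numerator and negative parts the denominator,

    B̃(x; w) = (w̃+ · log x)/‖w̃+‖₁ − (w̃− · log x)/‖w̃−‖₁        (balance)
    Ã(x; w) = log[(w̃+ · x + ε) / (w̃− · x + ε)]                 (amalgamation)

which coincide with the exact forms when `w̃ ∈ {−1, 0, +1}^p` and are
differentiable everywhere else (the ReLU kink at w̃_j = 0 uses subgradient
0). The surrogate cross-entropy objective is minimized jointly over
(w, α, β).

## Optimization

Full-batch gradient descent with momentum 0.9, closed-form gradients,
100 epochs by default. Full batch keeps runs bit-reproducible at the
problem sizes this package targets; per-epoch cost is O(n·p).

* `w` initialized i.i.d. uniform on [−0.01, 0.01]: soft assignments start
  near zero (no feature pre-committed to either side) while the half-norms
  ‖w̃±‖₁ stay safely away from zero.
* `α` initialized at the base-rate log-odds net of the mean offset, so class
  imbalance needs no reweighting.
* `β` initialized at 1. The gradient with respect to `w` is proportional to
  β, so a zero start would silence it; a unit slope on a near-zero ratio
  score is otherwise inert.
* Learning rate: chosen so the first step moves the most responsive soft
  assignment by `target_first_step` = 0.005 (small against the (−1,1)
  range), i.e. η = target / max_j |∂L/∂w_j|·(1−w̃_j²)/2, with a fallback of
  η = 1 if the initial gradient vanishes. No user tuning is required.
* Guard ε = 1e-8: the balance denominators ‖w̃±‖₁ are floored at ε (the
  expression is undefined at the all-zero assignment); the amalgamation adds
  ε inside the logs to guard an all-zero side. Gradients treat a floored
  denominator as constant, which keeps them consistent with finite
  differences away from the measure-zero switching point.
* If the final loss exceeds the initial one the best iterate seen is
  returned, so a fit can never end worse than it started.

Gradient correctness is contract-tested against central finite differences
(relative error < 1e-5; measured ~1e-9).

## Discretization and regularization

A trained soft assignment is converted to a hard sparse partition by
thresholding: `J+ = {j: w̃_j > t}`, `J- = {j: w̃_j < −t}`. Candidate
thresholds are the midpoints between consecutive distinct |w̃_j| values
(midpoints avoid knife-edge ties with the strict inequality), keeping only
thresholds whose partition has both sides nonempty, plus the sentinel t = 1
(always the empty partition, i.e. "no ratio").

The threshold acts as a sparsity knob, and it is cross-validated the way a
lasso penalty is: within each of 5 stratified folds, a fresh relaxation is
trained on the fold's training part, thresholded at every candidate t, refit
as a univariate logistic model (α, β only) on the training part and scored
on the held-out part. The sentinel is scored as the offset-only model. Each
fold trains its own relaxation because a soft assignment trained on all
samples has already seen every "held-out" fold: scored that way, spurious
ratios on pure-noise labels reach apparent CV AUC ≈ 0.74 and the sentinel
almost never wins. With fold-wise relaxations the scores are honest and null
data terminate cleanly.

The **λ-standard-error rule** then picks the sparsest candidate (fewest
active features, ties toward larger t) whose mean CV score is within λ
standard errors of the best candidate's score. λ = 1 by default; λ = 0 is
the plain argmax, and larger λ buys sparsity at some cost in accuracy.
Because the sentinel is in the candidate list with zero active features, a
ratio is kept only if "no ratio" falls outside the λ-SE band — the same rule
performs selection and termination.

The default CV score is held-out **negative cross-entropy** rather than
AUC. AUC is insensitive to the magnitude of an overfitted slope, so under
the winner's curse across ~p grid candidates a lucky spurious threshold
beats the sentinel on null data far too often (9/10 null replicates
measured); held-out cross-entropy charges overfitted slopes for their
miscalibration and restores clean termination (10/10). AUC remains
available via `score_metric="auc"`.

The selected partition is refit by maximum likelihood on the full training
set. The refit is a damped Newton solve (2 parameters, gradient-norm
tolerance 1e-8, deterministic); on (quasi-)separable data |β| is capped at
50 with a logged warning, which corresponds to odds ratios far beyond any
biologically meaningful scale.

## Stage-wise ensembling

Stages are fitted on the logit residual of the current model, implemented
exactly as a fixed offset in logit space (for logistic loss, residual
fitting *is* offset fitting). Stage k+1 therefore explains what stages
1..k did not, and the ratios come out ranked by explanatory power. Fitting
stops at the sentinel or at `max_ratios` (default 5; in practice the
sentinel fires first, and a handful of ratios suffices). Each stage derives
its relaxation seed and CV fold assignment from a stage-indexed seed,
recorded in the model's provenance, so full fits are bit-reproducible.

Models serialize to a versioned JSON document (feature names, not indices);
serialization round-trips reproduce predictions exactly. Prediction matches
features by name, so column order is free.

## Synthetic data

The generator emulates the structure the model assumes about HTS data:

1. latent log-abundances `z_i = base + dispersion · N(0, I_p)`;
2. outcome logit `α* + Σ_k β*_k · R(exp(z_i); J+_k, J-_k)` — the outcome
   depends on the latent composition *only through log-ratios*, so the
   generative law is scale-invariant by construction;
3. `y_i ~ Bernoulli(sigmoid(logit_i))`;
4. counts `~ Multinomial(depth_i, softmax(z_i))` with depths uniform in
   [5000, 50000] — totals are explicitly arbitrary;
5. optional independent zero-inflation.

Defaults: n = 1000, p = 100, one planted balance {1,2}/{3} with β* = 4,
α* = 0, unit dispersion, flat base log-abundance, no zero-inflation. Under
these conditions the true latent balance separates classes with AUC ≈ 0.9,
strong but not trivial signal. Counts are shifted by a pseudocount
(default 1.0) before log-ratios, the standard zero-handling for count CoDa.

What the generator does **not** emulate: correlation structure among taxa
(phylogenetic or ecological), overdispersion beyond multinomial sampling,
structured zeros, batch effects, or label noise. Passing the recovery tests
therefore shows the algorithm does what it claims under its own modeling
assumptions — not that it is robust to everything real microbiome data can
do.

## Validation against the exhaustive oracle

For p ≤ 12 the combinatorial problem is solved exactly by enumerating all
3^p − 2^(p+1) + 1 ordered pairs of disjoint nonempty subsets (ordered
enumeration accepts a 2× redundancy — swapping sides negates β — in exchange
for trivial auditability). On planted p = 8 instances, the stage-1 training
cross-entropy of the relaxation-plus-discretization pipeline lands within
5% of the exhaustive minimum in 20/20 seeded replicates — the desk-scale
evidence that the relaxation approximates the combinatorial optimum.

## Problem sizes and determinism

The bundled validation (tests and `scripts/acceptance.py`) uses n = 300–1000
samples and p = 8–2000 features with 20-replicate batteries; linear scaling
in p is checked as a per-epoch cost *ratio* between p = 2000 and p = 200,
never as absolute wall time. All randomness flows from explicit integer
seeds through `numpy.random.SeedSequence`; repeated runs of any fit, CLI
command or script are bit-identical.

## Known limitations

* Binary outcomes only; no continuous or multiclass response, no
  unsupervised mode.
* One λ per fit; a regularization path requires refitting.
* Feature sides contribute unweighted within a ratio (that is the point of
  the discretization, but it forgoes within-ratio weighting).
* The ε-guards make the relaxed amalgamation only approximately
  scale-invariant during *training* (exactly invariant at ε = 0 and in the
  discretized model actually used for prediction).
* Pseudocount handling is a modeling choice; results for features dominated
  by zeros depend on it.
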