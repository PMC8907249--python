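# Methods

## Data model

Follow-up time is grouped into `k` right-open intervals
`[0, a_1), [a_1, a_2), …, [a_{k−1}, ∞)` and recorded as the 1-based index
`t`, so `T = t` means the event fell in `[a_{t−1}, a_t)`.  Each record is
`(T̃, status, x)` with `T̃ = min(T, C)`, `status = ε·I(T ≤ C)` (0 censored,
1 event of interest, ≥ 2 competing) and a numeric covariate vector.
Censoring is assumed independent of the event time and non-informative.
Ties between event and censoring time in the same interval are resolved in
favour of the event (`Δ = I(T ≤ C)`), which fixes all risk-set conventions
below.  Left truncation, time-varying covariates and covariate-dependent
censoring are out of scope; categorical covariates must be numerically
encoded by the caller.

Continuous times are grouped at the `j/k` empirical quantiles
(`j = 1..k−1`) of the supplied times, so intervals receive roughly equal
occupancy; a value equal to a cut point belongs to the higher interval.
Whether to pool event and censoring times before taking quantiles is the
caller's choice; the simulator pools the uncensored continuous event times
of both event types, which share one grid.

## Censoring survival function

The subdistribution weights require `G(t) = P(C > t)`, estimated by the
discrete product-limit life table

    Ĝ(t) = ∏_{s=1..t} (1 − c_s / (n_s − d_s)),    Ĝ(0) = 1,

with `n_s = #{T̃ ≥ s}`, `d_s` the observed events (any type) and `c_s` the
censorings in interval `s`.  Subtracting `d_s` encodes that events precede
censoring within an interval: under the tie rule above a subject whose
event is recorded at `s` could never have been *observed* censored at `s`,
so keeping them in the censoring risk set would bias the censoring hazard
downward at every tied interval.  With events removed first the ratio
`c_s / (n_s − d_s)` is unbiased for the discrete censoring hazard
`P(C = s | C ≥ s)` under independence.  Empty risk sets carry the last
value forward with a warning.  `Ĝ(0) = 1` by construction of the 1-based
grid, so the weight ratio is defined for `T̃ = 1`.

## Subdistribution weights and imputation

For a subject observed with a competing event at `T̃`, the subdistribution
time of the event of interest is infinite and the single-event training
target `min(ϑ, C) = C` is missing.  The weight

    w_t = Ĝ(t−1) / Ĝ(T̃−1),   T̃ < t ≤ k−1,   w_t = 1 for t ≤ T̃,

estimates the probability that the subject is still in the type-1 risk set
at `t` given membership at `T̃`.  The imputed censoring time `Ĉ` is drawn
so that risk-set membership is reproduced in expectation *exactly*:

    P(Ĉ ≥ t) = w_t   ⟺   P(Ĉ = t) = w_t − w_{t+1}

on the support `{T̃, …, k−1}`, with the residual mass `w_{k−1}` (follow-up
ending administratively) placed on `k−1`.  `Ĉ = T̃` is a legitimate draw:
the unobserved censoring time may fall in the same interval as the
competing event, in which case the record reduces to censoring at `T̃`.
Competing-event subjects with `T̃ ≥ k−1` are imputed at `k−1`, the
degenerate endpoint of the support.  The pmf sums to 1 exactly, and
because `Ĝ` is marginal the pmf depends on the subject only through `T̃`,
which the implementation exploits by drawing all subjects with equal `T̃`
in one vectorized call.

This construction makes the procedure self-consistent in a strong sense:
replacing each sampled indicator by its expectation turns the Kaplan–Meier
complement of the imputed data into the subdistribution-hazard
product-limit estimator with weighted risk sets `n*_t = Σᵢ w_it`, and that
estimator coincides with the Aalen–Johansen cumulative incidence of the
original competing-risks data **to machine precision** (verified
numerically on arbitrary datasets).  The sampled version therefore matches
Aalen–Johansen up to imputation noise; at n = 30,000 the sup-norm gap is
≈ 0.001–0.002.  An alternative reading of the sampling rule — support
starting at `T̃+1` with pmf `w_{t−1} − w_t` — keeps imputed subjects at
risk one interval too long under the inclusive censoring convention and
produces a systematic downward bias of up to 0.04 in the reconstructed
CIF; it amounts to recording the same draw under a censoring-at-interval-
start convention and is not used.

Imputation is performed **once** per dataset with a single user seed;
repeating an experiment re-imputes with fresh derived seeds but never
averages datasets (multiple-imputation pooling is deliberately out of
scope — it multiplies training cost for learners that already smooth over
sampling noise).  The naive baseline `naive_censor` recodes `status ≥ 2`
as censoring at the unchanged `T̃`.

### Identifiability at the grid end

In a single-event dataset on `k` intervals nobody survives the terminal
interval `[a_{k−1}, ∞)` uneventfully — every subject still at risk there
has the event — so the subdistribution hazard at `t = k` is not
identifiable from imputed (or naive) data and any estimator saturates at 1
there, while the competing-risks Aalen–Johansen estimate stays below 1.
All calibration comparisons in this package are therefore evaluated on
`t = 1..k−1`.

## Simulator

Two event types.  Covariates `x₁, x₂ ~ N(0,1)`, `x₃, x₄ ~ Bernoulli(0.5)`,
independent.  With `η = exp(xᵀγ₁)`, the type-1 continuous-time CIF is

    F₁(t | x) = 1 − (1 − q + q·e^{−t})^η,

so `P(ε = 1 | x) = 1 − (1−q)^η`, and `q ∈ (0,1)` tunes the type-1 rate
(defaults: γ₁ = (0.4, −0.4, 0.2, −0.2), γ₂ = −γ₁).  The event type is
drawn first; type-1 times are sampled by inverting `F₁` at a uniform draw
on `(0, P(ε=1|x))`, type-2 times are exponential with rate `exp(xᵀγ₂)`.
Pooled continuous times are grouped into `k = 20` quantile intervals, and
a discrete censoring time is drawn from

    P(C = t) = b^{k+1−t} / Σ_{i=1..k} b^i,

uniform for `b = 1` (the medium-censoring default, giving ≈ 47–48%
censoring at these settings since `P(C < T) ≈ (k−1)/2k`).  Observed data
are `T̃ = min(T_disc, C)`, `status = ε·I(T_disc ≤ C)`.  At n = 30,000 the
default settings reproduce censoring ≈ 47.5%, type-1 rates ≈ 11.5 / 21.5 /
39.3% and type-2 rates ≈ 41.1 / 30.9 / 13.2% for q = 0.2 / 0.4 / 0.8.

What the generator does *not* emulate: covariate-dependent or informative
censoring, more than two event types, non-proportional covariate effects,
measurement error, and the high-dimensional mixed-type predictors of real
registries.  Tests passing on this generator demonstrate the estimators'
internal consistency under random censoring and a correctly recorded
discrete grid, not robustness to those violations.

## Reference learner

A logistic discrete hazard `h(t|x) = σ(β_t + f(x))` with per-interval
intercepts and either a linear effect `f(x) = xᵀw` (default) or a
one-hidden-layer tanh network.  The event-time distribution follows as
`P(T = t|x) = h(t|x)·∏_{s<t}(1 − h(s|x))` and the CIF as
`F̂(t|x) = 1 − ∏_{s≤t}(1 − h(s|x))`.  The training objective is

    (1 − α)·L_l + α·L_z,

where `L_l` is the grouped-time negative log-likelihood (an event at `t`
contributes `−log h(t|x) − Σ_{s<t} log(1 − h(s|x))`; a censoring at `t`
contributes `−Σ_{s≤t} log(1 − h(s|x))`, i.e. censored subjects survive
their censoring interval inclusive) and `L_z` is the same likelihood
restricted to uncensored subjects, each averaged over its own instance
count.  Optimization is full-batch Adam (lr 0.1, up to 500 epochs) keeping
the parameters with the best validation objective and stopping after 20
non-improving epochs.

**Default α = 0.** The uncensored-only term roughly doubles the effective
weight of event rows at the event rates studied here, inflating every
hazard and hence the predicted CIF (measured sup-norm miscalibration
≈ 0.14 at α = 0.1 versus ≈ 0.01 at α = 0, n = 30,000, q = 0.2).  Since
this learner's role is to verify that preprocessing — not loss shaping —
fixes calibration, the calibration-neutral α = 0 is the default and α is
left configurable for users who want to trade calibration for emphasis on
observed events.

The learner makes no claim of matching any particular deep survival
architecture; it is the simplest consumer that exposes the difference
between imputed and naive preprocessing.

## Evaluation

*Aalen–Johansen.*  `F̂_j(t) = Σ_{s≤t} Ŝ(s−1)·d_{js}/n_s` with `Ŝ` the
all-cause Kaplan–Meier; reduces to 1−KM when `J = 1`; validated against
`cmprsk::cuminc`.  *Calibration* compares the test-set average of the
model CIF with the Aalen–Johansen reference on the original
competing-risks test data (sup norm on `t ≤ k−1`).

*Concordance.*  For each `t`, `C₁(t)` is the probability that the risk
marker `M(t, x)` (by default the model CIF) ranks a subject with a type-1
event by `t` above a subject still event-free or removed by a competing
event.  An ordered pair `(i, j)` is comparable when `status_i = 1`,
`T̃_i ≤ t` and (`T̃_j > T̃_i` or `status_j = 2`); it receives the inverse
probability of censoring weight `1 / (Ĝ(T̃_i−1)·Ĝ(min(T̃_i, T̃_j)−1))`
from the test-set censoring life table, and marker ties count 1/2.
Without censoring all weights are 1 and the estimator equals exhaustive
comparable-pair concordance (tested exactly); times with no comparable
pair are reported as missing and excluded from the unweighted time
average.

## Experiment protocol

One simulation and one stratified split (train/validation/test =
1/2 : 1/6 : 1/3, equal status composition across splits) are held fixed;
each of `R = 10` repetitions re-imputes the training and validation sets
and refits the learner.  Child seeds derive from the base seed through a
`SeedSequence` spawn counter (child 0 simulation, child 1 split, children
`2+2r`/`3+2r` imputation/learner of repetition `r`), so runs are bit-
reproducible.  `compare_modes` runs the imputed and naive pipelines on the
identical simulation, split and learner seeds, making the per-repetition
calibration and concordance differences paired.  For speed the concordance
is computed on a fixed random subsample of 2,000 test subjects by default
(configurable; the pair enumeration is quadratic in the subsample size).

## Numerical choices and degenerate inputs

- Weight computation fails loudly (`DegenerateWeightError`) when
  `Ĝ(T̃−1) = 0` for a competing-event subject: no later censoring time is
  estimable from data with no censoring mass beyond `T̃`.
- `discretize` refuses fewer than `k` distinct times or tied quantiles.
- Hazards are clamped only through the numerically stable tanh-based
  sigmoid plus a 1e-12 floor inside logs; non-finite losses raise a
  training error rather than propagate.
- Stratified splitting rounds per-category allocations to the nearest
  integer, assigns remainders to the test split, and degrades to a warning
  when a category is smaller than the requested allocation.
- Problem sizes in the test suite follow the study conditions above
  (n = 30,000 for distributional checks) with smaller n only for
  exercising plumbing; the concordance brute-force oracle runs at n ≤ 50
  where exhaustive enumeration is exact.

## Known limitations

- The marginal (covariate-free) censoring estimate makes the weights valid
  under completely independent censoring only; covariate-dependent
  censoring would need a conditional estimator, which is out of scope.
- Single imputation adds Monte-Carlo noise of order `1/√n` to downstream
  estimates; for small n this can dominate (the package targets large-n
  learners).
- The last grid interval is uninformative for the subdistribution hazard
  (see above); users who need `F₁` at the grid end should extend the grid
  or report `t ≤ k−1`.
- The IPCW concordance uses the same dataset for the censoring estimate
  and the comparison, as is standard; no cross-fitting is performed.
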