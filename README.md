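# crimpute

**Subdistribution-weight censoring-time imputation for discrete-time
competing-risks survival analysis.**

## The problem

In time-to-event studies a subject can often experience one of several
mutually exclusive events: death from the disease of interest versus death
from other causes, hospital death versus discharge, and so on.  When the
aim is the cumulative incidence function (CIF) of the event of interest,

> F₁(t | x) = P(T ≤ t, ε = 1 | x),

the tempting shortcut of treating competing events as censoring is wrong:
the complement of the Kaplan–Meier estimator then systematically
*overestimates* F₁.  The classical remedy is the subdistribution hazard
(Fine–Gray) framework, but its weighted-likelihood machinery does not carry
over to modern machine-learning survival models, which consume plain
`(time, event, covariates)` records — and discrete-time augmentation
schemes blow the data up to n·k rows.

`crimpute` implements a preprocessing alternative: convert the
competing-risks dataset into an ordinary single-event dataset of the same
size by **imputing a censoring time for every subject who experienced a
competing event first**.  The subdistribution time of the event of interest
is ϑ = T if ε = 1 and ϑ = ∞ otherwise; for a competing-event subject the
learner's target `min(ϑ, C) = C` is unobserved, so it is sampled from the
discrete distribution implied by the subdistribution weights

> w_it = Ĝ(t−1) / Ĝ(T̃ᵢ−1),  T̃ᵢ < t ≤ k−1,  (w_it = 1 for t ≤ T̃ᵢ)

where Ĝ is a life-table estimate of the censoring survival function
G(t) = P(C > t).  The imputed dataset can then be fed to *any* single-event
discrete-time survival learner, and the learner's estimated CIF is an
unbiased estimate of the true type-1 CIF.

## What is in the package

| module | contents |
| --- | --- |
| `crimpute.data` | grouped-time data model, delimited-table I/O, quantile discretization, stratified splitting |
| `crimpute.censoring` | life-table estimate of the censoring survival function G |
| `crimpute.imputer` | subdistribution weights, censoring-time sampling, `impute_dataset`, naive competing-as-censored baseline |
| `crimpute.simulate` | discrete two-event competing-risks simulator (covariate-dependent event types, quantile grid, parametric censoring) |
| `crimpute.hazard` | reference logistic discrete-hazard learner (per-interval intercepts + linear or small-net covariate effect, two-term likelihood loss, early stopping) |
| `crimpute.metrics` | Aalen–Johansen CIF, Kaplan–Meier complement, calibration curves, IPCW concordance index for competing risks |
| `crimpute.experiments` | end-to-end simulate → split → preprocess → fit → evaluate protocol with paired imputed/naive comparison |
| `crimpute.cli` | `crimpute simulate / impute / fit / run-experiment` |

## Worked example

```python
import numpy as np
from crimpute import (SimConfig, simulate, stratified_split, impute_dataset,
                      naive_censor, fit, LearnerConfig, aalen_johansen,
                      km_complement, calibration_curves, cindex_ipcw, mean_cindex)

data = simulate(SimConfig(n=30_000, q=0.2, seed=1))      # 2 competing events
train, val, test = stratified_split(data, (1/2, 1/6, 1/3), seed=2)
reference = aalen_johansen(test, j=1)                    # nonparametric CIF

imputed_km = km_complement(impute_dataset(test, seed=3))
naive_km   = km_complement(naive_censor(test))

model = fit(impute_dataset(train, seed=3), impute_dataset(val, seed=4),
            LearnerConfig(seed=5))
cif = model.predict_cif(test.covariates)
```

Output (printing the corresponding summaries):

```
censoring / type-1 / type-2 rates: 47.7% / 11.3% / 41.1%
sup|1-KM - AJ| on t<=19, imputed: 0.0007
sup|1-KM - AJ| on t<=19, naive:   0.2602
learner calibration gap (t<=19):  0.0073
mean IPCW C-index:                0.6572
```

Reading: the simulator reproduces a medium-censoring scenario with a rare
event of interest and a frequent competing event.  The Kaplan–Meier
complement computed on the **imputed** single-event data agrees with the
Aalen–Johansen reference to 4 decimals, while the naive
competing-as-censored version overshoots it by 0.26 — the bias the method
removes.  A plain logistic discrete-hazard learner trained on the imputed
data is calibrated to within 0.008 of the reference curve, and its
predicted CIF discriminates event order with a time-averaged concordance
of 0.66.  (Comparisons stop at t = k−1: in single-event data everyone
still at risk in the terminal interval [a_{k−1}, ∞) experiences the
event, so the last interval carries no information about the
subdistribution.)

The same pipeline from the shell:

```bash
crimpute simulate --n 30000 --q 0.2 --seed 1 --output sim.csv
crimpute impute --input sim.csv --seed 3 --output imputed.csv
crimpute run-experiment --mode both --repetitions 10 --seed 1 --outdir results/
```

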