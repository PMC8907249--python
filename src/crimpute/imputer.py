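"""Subdistribution-weight imputation of censoring times.

The core preprocessing step: competing-risks records are converted into
single-event records so that any single-event discrete-time learner can
estimate the type-1 cumulative incidence function without bias.

For an individual whose first observed event is a competing one, the
subdistribution time of the event of interest is infinite, so the quantity
``min(theta_i, C_i) = C_i`` is unobserved (censoring would have happened
at some later, unseen time).  The estimated probability that individual
``i`` is still in the type-1 risk set at time ``t``, given membership at
the observed time ``T~_i``, is the subdistribution weight

    w_it = G^(t-1) / G^(T~_i - 1),     T~_i < t <= k-1,

with ``w_it = 1`` for ``t <= T~_i`` and ``G^`` the life-table censoring
survival estimate.  A censoring time ``C^_i`` is then sampled so that the
individual's probability of still being in the risk set at ``t`` (i.e.
``C^_i >= t``) equals ``w_it``:

    P(C^_i = t) = w_it - w_{i,t+1}    on the support {T~_i, ..., k-1},

where the leftover mass ``w_{i,k-1}`` (follow-up ending administratively)
sits on ``k-1``.  The probabilities are the one-step weight differences;
``C^_i = T~_i`` is possible because the true censoring time may fall in
the same interval as the competing event.  With this construction the
expected subdistribution-weighted risk set is reproduced exactly, and the
Kaplan-Meier complement of the imputed single-event data agrees with the
Aalen-Johansen cumulative incidence of the source data up to imputation
noise.

A single imputation with one user seed is performed; re-imputation across
experiment repetitions re-runs this step with derived seeds and never
averages datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .censoring import CensoringSurvival, estimate_censoring_survival
from .data import CompetingRisksDataset, SingleEventDataset
from .errors import ConfigurationError, DegenerateWeightError, GridMismatchError

__all__ = [
    "SubdistWeights",
    "ImputedCensoringDraw",
    "compute_weights",
    "sample_imputed_censoring",
    "impute_dataset",
    "naive_censor",
]


@dataclass(frozen=True)
class SubdistWeights:
    """Per-individual subdistribution weights on ``t = 1..k-1``.

    ``w[i, t-1]`` holds ``w_it``.  Rows of individuals with status 0 or 1
    are all-ones (the weights are unused for them).
    """

    w: np.ndarray
    obs_time: np.ndarray
    is_competing: np.ndarray
    k: int

    @property
    def n(self) -> int:
        return self.w.shape[0]

    def pmf(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Imputation pmf ``P(C^_i = t)`` for individual ``i``.

        Returns ``(support, probabilities)`` over ``{T~_i, ..., k-1}``
        where ``P(C^_i = t) = w_it - w_{i,t+1}`` and the residual mass
        ``w_{i,k-1}`` sits on ``k-1``, so that ``P(C^_i >= t) = w_it``;
        the probabilities sum to 1 exactly.  For ``T~_i >= k-1`` the pmf
        is a point mass at ``k-1``.
        """
        t_obs = int(self.obs_time[i])
        if t_obs >= self.k - 1:
            return np.array([self.k - 1]), np.array([1.0])
        support = np.arange(t_obs, self.k)  # t = T~ .. k-1
        # w_it on the support; w_{i,T~} = 1, then the Eq.-1 ratios
        w_here = np.concatenate([[1.0], self.w[i, t_obs : self.k - 1]])
        probs = np.empty(support.size)
        probs[:-1] = w_here[:-1] - w_here[1:]
        probs[-1] = w_here[-1]  # residual mass at k-1
        return support, probs


@dataclass(frozen=True)
class ImputedCensoringDraw:
    """One sampled censoring time ``C^_i >= T~_i`` for individual ``i``."""

    index: int
    time: int

    def __post_init__(self) -> None:
        if self.time < 1:
            raise ConfigurationError("imputed time must be a valid interval")


def compute_weights(
    dataset: CompetingRisksDataset, censoring: CensoringSurvival
) -> SubdistWeights:
    """Evaluate the subdistribution weights for every individual.

    Raises :class:`DegenerateWeightError` when a competing-event individual
    has ``G^(T~_i - 1) = 0``: no later censoring time is estimable because
    the data contain no censoring mass beyond their observed time.
    """
    k = dataset.grid.k
    if censoring.k_minus_1 != k - 1:
        raise GridMismatchError(
            f"censoring estimate on k={censoring.k_minus_1 + 1}, data on k={k}"
        )
    n = dataset.n
    is_comp = dataset.status >= 2
    w = np.ones((n, k - 1))
    if is_comp.any():
        g = censoring.values  # G^(0..k-1)
        denom = g[dataset.time[is_comp] - 1]
        if np.any(denom == 0):
            bad = np.flatnonzero(is_comp)[np.argmax(denom == 0)]
            raise DegenerateWeightError(
                f"individual {bad}: G^(T~-1) = 0 at T~ = {dataset.time[bad]}"
            )
        t_grid = np.arange(1, k)  # t = 1..k-1
        ratio = g[t_grid - 1][None, :] / denom[:, None]
        late = t_grid[None, :] > dataset.time[is_comp, None]
        w[is_comp] = np.where(late, ratio, 1.0)
    return SubdistWeights(w=w, obs_time=dataset.time.copy(), is_competing=is_comp, k=k)


def sample_imputed_censoring(
    weights: SubdistWeights, i: int, rng: np.random.Generator
) -> ImputedCensoringDraw:
    """Draw one censoring time for competing-event individual ``i``."""
    if not weights.is_competing[i]:
        raise ConfigurationError(
            f"individual {i} has status 0 or 1; nothing to impute"
        )
    support, probs = weights.pmf(i)
    time = int(rng.choice(support, p=probs))
    return ImputedCensoringDraw(index=i, time=time)


def impute_dataset(
    dataset: CompetingRisksDataset, seed: int | np.random.Generator
) -> SingleEventDataset:
    """Convert competing-risks records into single-event records.

    Individuals with status 0 or 1 pass through unchanged.  Individuals who
    experienced a competing event first get ``event = 0`` and a censoring
    time sampled from their subdistribution-weight pmf; ``n``, ordering and
    covariates are preserved.  Single imputation, deterministic given seed.
    """
    if dataset.grid.k < 3:
        raise ConfigurationError("imputation needs k >= 3 intervals")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    censoring = estimate_censoring_survival(dataset)
    weights = compute_weights(dataset, censoring)

    time = dataset.time.copy()
    event = (dataset.status == 1).astype(np.int64)
    comp_idx = np.flatnonzero(weights.is_competing)
    # The marginal G^ makes the pmf a function of T~ only, so individuals
    # sharing an observed time can be drawn in one vectorized call.
    for t_obs in np.unique(dataset.time[comp_idx]):
        group = comp_idx[dataset.time[comp_idx] == t_obs]
        support, probs = weights.pmf(int(group[0]))
        time[group] = rng.choice(support, p=probs, size=group.size)
    return SingleEventDataset(
        time=time,
        event=event,
        covariates=dataset.covariates,
        grid=dataset.grid,
        covariate_names=list(dataset.covariate_names),
    )


def naive_censor(dataset: CompetingRisksDataset) -> SingleEventDataset:
    """Baseline that treats competing events as censoring.

    Status >= 2 becomes ``event = 0`` at the original observed time; no
    times change.  Ignoring competing events this way biases the
    complement-of-Kaplan-Meier estimate of the type-1 cumulative incidence
    upward.
    """
    return SingleEventDataset(
        time=dataset.time.copy(),
        event=(dataset.status == 1).astype(np.int64),
        covariates=dataset.covariates,
        grid=dataset.grid,
        covariate_names=list(dataset.covariate_names),
    )
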