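"""Nonparametric life-table estimate of the censoring survival function.

The censoring distribution ``G(t) = P(C > t)`` is what the subdistribution
weights are built from.  On a grouped 1-based time grid the product-limit
(life-table) estimator is

    G^(t) = prod_{s=1..t} (1 - c_s / (n_s - d_s)),      G^(0) = 1,

where ``n_s = #{T~ >= s}``, ``d_s`` counts the observed events (any type)
at ``s`` and ``c_s`` the status-0 records at ``s``.  Within an interval
events precede censoring: under the observation rule ``Delta = I(T <= C)``
a tie is recorded as an event, so an individual with an event at ``s`` was
never at risk of being *observed* censored at ``s`` and must leave the
censoring risk set first.  With this convention the censoring-hazard
estimate ``c_s / (n_s - d_s)`` is unbiased for ``P(C = s | C >= s)`` under
independent censoring, and the downstream subdistribution-weighted
product-limit estimator reproduces the Aalen-Johansen cumulative incidence
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import CompetingRisksDataset
from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = ["CensoringSurvival", "estimate_censoring_survival"]


@dataclass(frozen=True)
class CensoringSurvival:
    """Estimated censoring survival ``G^(t)`` on ``t = 0..k-1``.

    ``values[t]`` is ``G^(t)`` with ``G^(0) = 1`` (the grid is 1-based, so
    ``P(C > 0) = 1`` by construction).  ``at_risk[s-1]`` and
    ``censored_count[s-1]`` hold the censoring-risk-set size ``n_s - d_s``
    and censoring count ``c_s`` for ``s = 1..k-1``.
    """

    values: np.ndarray
    at_risk: np.ndarray
    censored_count: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v[0] != 1.0:
            raise DataError("G^(0) must be 1")
        if np.any(np.diff(v) > 1e-12) or np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise DataError("G^ must be non-increasing in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def k_minus_1(self) -> int:
        return self.values.shape[0] - 1

    def __call__(self, t: np.ndarray | int) -> np.ndarray | float:
        """Evaluate ``G^(t)`` for integer ``t`` in ``0..k-1``."""
        return self.values[t]

    def to_table(self) -> np.ndarray:
        """Two-column array ``(t, G^(t))`` for export."""
        t = np.arange(self.values.shape[0])
        return np.column_stack([t, self.values])


def estimate_censoring_survival(
    dataset: CompetingRisksDataset,
) -> CensoringSurvival:
    """Life-table estimate of ``G(t) = P(C > t)`` for ``t = 0..k-1``.

    Empty risk sets before the last observed time carry the last value
    forward with a warning.
    """
    k = dataset.grid.k
    counts_all = np.bincount(dataset.time, minlength=k + 1)[1:]
    counts_cens = np.bincount(
        dataset.time[dataset.status == 0], minlength=k + 1
    )[1:]
    counts_event = np.bincount(
        dataset.time[dataset.status > 0], minlength=k + 1
    )[1:]

    # n_s = #{T~ >= s}: reverse cumulative sum of per-interval counts
    n_s_all = counts_all[::-1].cumsum()[::-1]
    risk = n_s_all - counts_event  # events leave before censoring acts

    values = np.ones(k)  # index t = 0..k-1
    g = 1.0
    for s in range(1, k):
        n_s = risk[s - 1]
        c_s = counts_cens[s - 1]
        if n_s == 0:
            if counts_all[s - 1 :].sum() > 0 and c_s == 0:
                logger.warning("empty censoring risk set at interval %d", s)
            values[s] = g
            continue
        g *= 1.0 - c_s / n_s
        values[s] = g
    return CensoringSurvival(
        values=values,
        at_risk=risk[: k - 1],
        censored_count=counts_cens[: k - 1],
    )
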