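"""Nonparametric reference estimators and evaluation metrics.

Aalen-Johansen cumulative incidence, the Kaplan-Meier complement for
single-event data, calibration-curve comparison against a covariate-free
reference, and the competing-risks concordance index with inverse
probability of censoring weighting (IPCW).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .censoring import CensoringSurvival, estimate_censoring_survival
from .data import CompetingRisksDataset, SingleEventDataset
from .errors import ConfigurationError, GridMismatchError

logger = logging.getLogger(__name__)

__all__ = [
    "StepCIF",
    "ConcordanceResult",
    "aalen_johansen",
    "km_complement",
    "calibration_curves",
    "plot_calibration",
    "cindex_ipcw",
    "mean_cindex",
]


@dataclass(frozen=True)
class StepCIF:
    """Covariate-free step cumulative incidence on ``t = 1..k``.

    ``values[t-1]`` is ``F^(t)``; ``at_risk`` and ``events`` are the
    life-table counts ``n_t`` and ``d_t`` behind it.
    """

    values: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    @property
    def k(self) -> int:
        return self.values.shape[0]

    def __call__(self, t: np.ndarray | int) -> np.ndarray | float:
        return self.values[np.asarray(t) - 1]


@dataclass(frozen=True)
class ConcordanceResult:
    """Per-time concordance ``C_1(t)`` with comparable-pair counts.

    ``values[t-1]`` is ``C_1(t)`` for ``t = 1..k-1`` (NaN when no pair is
    comparable); ``n_pairs`` counts the comparable ordered pairs.
    """

    values: np.ndarray
    n_pairs: np.ndarray

    @property
    def mean(self) -> float:
        return mean_cindex(self)


def aalen_johansen(dataset: CompetingRisksDataset, j: int = 1) -> StepCIF:
    """Aalen-Johansen estimate of the type-``j`` cumulative incidence.

        F^_j(t) = sum_{s<=t} S^(s-1) * d_js / n_s,

    with ``n_s`` the number at risk, ``d_js`` the type-``j`` events at
    ``s`` and ``S^`` the all-cause Kaplan-Meier survival (``S^(0) = 1``).
    Generalizes the Kaplan-Meier complement to competing risks; reduces to
    it when there is a single event type.
    """
    if not 1 <= j <= dataset.J:
        raise ConfigurationError(f"event type {j} not in 1..{dataset.J}")
    k = dataset.grid.k
    counts_all = np.bincount(dataset.time, minlength=k + 1)[1:]
    at_risk = counts_all[::-1].cumsum()[::-1]
    d_any = np.bincount(
        dataset.time[dataset.status > 0], minlength=k + 1
    )[1:]
    d_j = np.bincount(
        dataset.time[dataset.status == j], minlength=k + 1
    )[1:]

    values = np.empty(k)
    surv = 1.0  # S^(s-1)
    cif = 0.0
    for s in range(1, k + 1):
        n_s = at_risk[s - 1]
        if n_s == 0:
            if counts_all[s - 1 :].sum() > 0:
                logger.warning("empty risk set at interval %d; carrying forward", s)
            values[s - 1] = cif
            continue
        cif += surv * d_j[s - 1] / n_s
        surv *= 1.0 - d_any[s - 1] / n_s
        values[s - 1] = cif
    return StepCIF(values=values, at_risk=at_risk, events=d_j)


def km_complement(dataset: SingleEventDataset) -> StepCIF:
    """``1 - Kaplan-Meier`` of the event indicator on the discrete grid.

    The single-event analogue of :func:`aalen_johansen`; used as the
    estimator a single-event learner implicitly targets, e.g. to check that
    imputation preserves the type-1 cumulative incidence.
    """
    as_cr = CompetingRisksDataset(
        time=dataset.time,
        status=dataset.event,
        covariates=dataset.covariates,
        grid=dataset.grid,
        covariate_names=list(dataset.covariate_names),
    )
    return aalen_johansen(as_cr, j=1)


def calibration_curves(
    model_cifs: np.ndarray, reference: StepCIF
) -> tuple[pd.DataFrame, float]:
    """Compare a model's average CIF with a covariate-free reference.

    Parameters
    ----------
    model_cifs
        ``(n, k)`` matrix of per-individual model CIFs ``F^_1(t | x_i)``
        over the test set.
    reference
        Covariate-free reference curve (typically Aalen-Johansen on the
        original competing-risks test data) on the same grid.

    Returns the curve table ``(t, model_mean, reference)`` and the sup-norm
    gap between the two curves.
    """
    model_cifs = np.atleast_2d(np.asarray(model_cifs, dtype=float))
    if model_cifs.shape[1] != reference.k:
        raise GridMismatchError(
            f"model on k={model_cifs.shape[1]}, reference on k={reference.k}"
        )
    mean_curve = model_cifs.mean(axis=0)
    table = pd.DataFrame(
        {
            "t": np.arange(1, reference.k + 1),
            "model_mean": mean_curve,
            "reference": reference.values,
        }
    )
    gap = float(np.max(np.abs(mean_curve - reference.values)))
    return table, gap


def plot_calibration(
    table: pd.DataFrame, path: str, title: str | None = None
) -> None:
    """Render a calibration-curve table (from :func:`calibration_curves`)
    to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step(table["t"], table["reference"], where="post", color="crimson",
            label="Aalen-Johansen reference")
    ax.step(table["t"], table["model_mean"], where="post", color="teal",
            label="mean model CIF")
    ax.set_xlabel("time interval")
    ax.set_ylabel("type-1 cumulative incidence")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def cindex_ipcw(
    dataset: CompetingRisksDataset,
    marker: np.ndarray,
    t: int | None = None,
    censoring: CensoringSurvival | None = None,
    _chunk: int = 256,
) -> ConcordanceResult:
    """Competing-risks concordance index with IPCW pair weights.

    Estimates, for each evaluation time ``t``,

        C_1(t) = P( M(t, x_i) > M(t, x_j) |
                    eps_i = 1, T_i <= t, (T_i < T_j or eps_j = 2) ),

    the probability that the risk marker ranks an individual with an early
    type-1 event above one still event-free (or removed by a competing
    event).  An ordered pair ``(i, j)`` is comparable when ``i`` has an
    observed type-1 event at ``T~_i <= t`` and either ``T~_j > T~_i`` or
    ``j`` has a competing event; it is weighted by the inverse censoring
    survival ``1 / (G^(T~_i - 1) * G^(min(T~_i, T~_j) - 1))`` estimated
    from the same data, and ties in the marker count 1/2.  Without
    censoring all weights are 1 and the estimate equals the plain
    comparable-pair concordance fraction.

    Parameters
    ----------
    dataset
        Competing-risks test data.
    marker
        ``(n, k)`` matrix of marker values ``M(t, x_i)`` (by convention the
        model CIF) or an ``(n,)`` vector used for all times.
    t
        Single evaluation time; default all ``t = 1..k-1``.
    censoring
        Censoring survival estimate; computed from ``dataset`` if omitted.

    Times with no comparable pairs are reported as NaN.
    """
    k = dataset.grid.k
    marker = np.asarray(marker, dtype=float)
    if marker.ndim == 1:
        marker = np.tile(marker[:, None], (1, k))
    if marker.shape != (dataset.n, k):
        raise ConfigurationError(
            f"marker must be ({dataset.n}, {k}), got {marker.shape}"
        )
    if censoring is None:
        censoring = estimate_censoring_survival(dataset)
    g = censoring.values  # G^(0..k-1)

    times = np.arange(1, k) if t is None else np.array([t])
    if t is not None and not 1 <= t <= k - 1:
        raise ConfigurationError(f"evaluation time {t} not in 1..{k - 1}")

    time_v, status_v = dataset.time, dataset.status
    is_comp_j = status_v == 2 if dataset.J <= 2 else status_v >= 2
    values = np.full(k - 1, np.nan)
    n_pairs = np.zeros(k - 1, dtype=np.int64)
    inv_g_time = 1.0 / g[time_v - 1]  # 1 / G^(T~ - 1)

    for t_eval in times:
        cand = np.flatnonzero((status_v == 1) & (time_v <= t_eval))
        if cand.size == 0:
            continue
        num = 0.0
        den = 0.0
        npairs = 0
        m_t = marker[:, t_eval - 1]
        for lo in range(0, cand.size, _chunk):
            ii = cand[lo : lo + _chunk]
            t_i = time_v[ii][:, None]
            comparable = (time_v[None, :] > t_i) | is_comp_j[None, :]
            comparable[np.arange(ii.size), ii] = False
            # IPCW: 1 / (G^(T_i-1) * G^(min(T_i, T_j)-1))
            w = inv_g_time[ii][:, None] * np.minimum(
                inv_g_time[ii][:, None], inv_g_time[None, :]
            )
            w = np.where(comparable, w, 0.0)
            diff = m_t[ii][:, None] - m_t[None, :]
            conc = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
            num += float((w * conc).sum())
            den += float(w.sum())
            npairs += int(comparable.sum())
        if den > 0:
            values[t_eval - 1] = num / den
            n_pairs[t_eval - 1] = npairs
    return ConcordanceResult(values=values, n_pairs=n_pairs)


def mean_cindex(result: ConcordanceResult) -> float:
    """Unweighted mean of ``C_1(t)`` over times where it is defined."""
    defined = ~np.isnan(result.values)
    if not defined.any():
        return math.nan
    return float(result.values[defined].mean())
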