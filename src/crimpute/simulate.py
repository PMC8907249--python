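"""Simulator for grouped-time competing-risks data.

Generates two-event competing-risks datasets from a discretized
subdistribution hazard model.  The type-1 (event of interest) cumulative
incidence is, on the continuous time scale,

    F_1(t | x) = 1 - (1 - q + q * exp(-t)) ** eta,    eta = exp(x' gamma_1),

so the total type-1 mass is ``P(eps = 1 | x) = 1 - (1 - q) ** eta`` and the
mixture parameter ``q`` in (0, 1) tunes the type-1 event rate.  Conditional
on the competing event (``eps = 2``) the continuous time is exponential
with rate ``exp(x' gamma_2)``.  Continuous times of both event types are
pooled and grouped into ``k`` intervals at empirical quantiles, and a
discrete censoring time is drawn from

    P(C = t) = b ** (k + 1 - t) / sum_{i=1..k} b ** i,    t = 1..k,

uniform on the grid for ``b = 1``, front-loaded for ``b > 1``.  The
observed record is ``T~ = min(T, C)`` with status ``eps * I(T <= C)``
(a tie counts as an observed event).

Covariates: ``x1, x2 ~ N(0, 1)`` and ``x3, x4 ~ Bernoulli(0.5)``,
independent, with default coefficients ``gamma_1 = (0.4, -0.4, 0.2, -0.2)``
and ``gamma_2 = (-0.4, 0.4, -0.2, 0.2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CompetingRisksDataset, TimeGrid, discretize
from .errors import ConfigurationError

__all__ = [
    "SimConfig",
    "sample_covariates",
    "type1_probability",
    "sample_type1_time",
    "sample_type2_time",
    "sample_censoring_time",
    "simulate",
    "true_type1_cif",
]

GAMMA1_DEFAULT = (0.4, -0.4, 0.2, -0.2)
GAMMA2_DEFAULT = (-0.4, 0.4, -0.2, 0.2)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated dataset.

    ``q`` tunes the type-1 event rate, ``b`` the censoring rate (``b = 1``
    gives uniform censoring over the grid, the medium-censoring setting),
    ``k`` the number of time intervals.
    """

    n: int = 30_000
    q: float = 0.2
    b: float = 1.0
    k: int = 20
    gamma1: tuple[float, ...] = GAMMA1_DEFAULT
    gamma2: tuple[float, ...] = GAMMA2_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ConfigurationError(f"q must be in (0, 1), got {self.q}")
        if self.b <= 0:
            raise ConfigurationError(f"b must be positive, got {self.b}")
        if self.k < 2 or self.n < 1:
            raise ConfigurationError("need k >= 2 and n >= 1")
        if len(self.gamma1) != len(self.gamma2):
            raise ConfigurationError("gamma1 and gamma2 lengths differ")


def sample_covariates(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw the four standard covariates: two N(0,1), two Bernoulli(0.5)."""
    x12 = rng.standard_normal((n, 2))
    x34 = rng.binomial(1, 0.5, size=(n, 2)).astype(float)
    return np.column_stack([x12, x34])


def type1_probability(
    x: np.ndarray, q: float, gamma1: np.ndarray | tuple = GAMMA1_DEFAULT
) -> np.ndarray:
    """``P(eps = 1 | x) = 1 - (1 - q) ** exp(x' gamma_1)``."""
    eta = np.exp(np.atleast_2d(x) @ np.asarray(gamma1, dtype=float))
    return np.squeeze(1.0 - (1.0 - q) ** eta)


def sample_type1_time(
    x: np.ndarray,
    q: float,
    gamma1: np.ndarray | tuple,
    rng: np.random.Generator,
) -> np.ndarray:
    """Continuous type-1 event times by inverting the subdistribution CIF.

    With ``u ~ Uniform(0, p1)`` where ``p1 = P(eps = 1 | x)``, solving
    ``F_1(T | x) = u`` gives

        T = -log( ((1 - u) ** (1 / eta) - (1 - q)) / q ).

    ``u < p1`` guarantees a positive argument; a floor guards the
    probability-zero numerical boundary.
    """
    x = np.atleast_2d(x)
    eta = np.exp(x @ np.asarray(gamma1, dtype=float))
    p1 = 1.0 - (1.0 - q) ** eta
    u = rng.uniform(0.0, p1)
    inner = ((1.0 - u) ** (1.0 / eta) - (1.0 - q)) / q
    inner = np.clip(inner, 1e-300, None)  # guard exact-boundary round-off
    return -np.log(inner)


def sample_type2_time(
    x: np.ndarray, gamma2: np.ndarray | tuple, rng: np.random.Generator
) -> np.ndarray:
    """Competing-event times: exponential with rate ``exp(x' gamma_2)``."""
    rate = np.exp(np.atleast_2d(x) @ np.asarray(gamma2, dtype=float))
    return rng.exponential(1.0 / rate)


def censoring_pmf(b: float, k: int) -> np.ndarray:
    """``P(C = t) = b^(k+1-t) / sum_i b^i`` over ``t = 1..k``."""
    t = np.arange(1, k + 1)
    weights = float(b) ** (k + 1 - t)
    return weights / weights.sum()


def sample_censoring_time(
    b: float, k: int, rng: np.random.Generator, size: int | None = None
) -> np.ndarray | int:
    """Draw discrete censoring times from the geometric-weight pmf."""
    draw = rng.choice(np.arange(1, k + 1), p=censoring_pmf(b, k), size=size)
    return draw


def simulate(config: SimConfig) -> CompetingRisksDataset:
    """Generate one competing-risks dataset.

    Per individual: draw covariates, draw the event type from
    ``P(eps = 1 | x)``, draw the continuous time from the type-specific
    model, then pool all continuous times and group them into ``k``
    quantile intervals shared by both event types, and finally apply the
    discrete censoring time.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    x = sample_covariates(config.n, rng)
    p1 = np.atleast_1d(type1_probability(x, config.q, config.gamma1))
    eps = np.where(rng.uniform(size=config.n) < p1, 1, 2)

    t_cont = np.empty(config.n)
    idx1 = eps == 1
    if idx1.any():
        t_cont[idx1] = sample_type1_time(x[idx1], config.q, config.gamma1, rng)
    idx2 = ~idx1
    if idx2.any():
        t_cont[idx2] = sample_type2_time(x[idx2], config.gamma2, rng)

    t_disc, grid = discretize(t_cont, config.k)
    c = sample_censoring_time(config.b, config.k, rng, size=config.n)
    observed = t_disc <= c
    time = np.where(observed, t_disc, c)
    status = np.where(observed, eps, 0)
    return CompetingRisksDataset(
        time=time, status=status, covariates=x, grid=grid
    )


def true_type1_cif(
    grid: TimeGrid,
    x: np.ndarray,
    q: float,
    gamma1: np.ndarray | tuple = GAMMA1_DEFAULT,
) -> np.ndarray:
    """Model type-1 CIF evaluated at the grid's interval ends.

    Returns an ``(n, k)`` matrix with column ``t-1`` holding
    ``F_1(a_t | x)``; the last column is the total type-1 mass
    ``P(eps = 1 | x)`` since ``a_k = inf``.  Serves as the known-truth
    marker for calibration and discrimination checks on simulated data.
    """
    if grid.cut_points is None:
        raise ConfigurationError("grid has no continuous cut points")
    eta = np.exp(np.atleast_2d(x) @ np.asarray(gamma1, dtype=float))
    cif = np.empty((eta.shape[0], grid.k))
    for t, a_t in enumerate(grid.cut_points):
        cif[:, t] = 1.0 - (1.0 - q + q * np.exp(-a_t)) ** eta
    cif[:, grid.k - 1] = 1.0 - (1.0 - q) ** eta
    return cif
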