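"""Reference single-event discrete-time hazard learner.

A deliberately simple downstream consumer of (possibly imputed)
single-event data.  The model is a logistic discrete hazard

    h(t | x) = sigmoid(beta_t + f(x)),    t = 1..k,

with per-interval intercepts ``beta_t`` and either a linear covariate
effect ``f(x) = x' w`` (default) or a small one-hidden-layer network
``f(x) = u' tanh(W x + b)``.  The distribution of the event time follows as
``P(T = t | x) = h(t | x) * prod_{s<t} (1 - h(s | x))`` and the cumulative
incidence as ``F(t | x) = 1 - prod_{s<=t} (1 - h(s | x))``.

Training minimizes the two-term objective

    (1 - alpha) * L_l + alpha * L_z,

where ``L_l`` is the discrete-time negative log-likelihood — an event at
``t`` contributes ``-log h(t|x) - sum_{s<t} log(1 - h(s|x))``, a censoring
at ``t`` contributes ``-sum_{s<=t} log(1 - h(s|x))`` (censored individuals
count as surviving their censoring interval) — and ``L_z`` is the same
likelihood restricted to the uncensored instances.  ``alpha`` balances
overall fit against fit on the observed events.  Optimization is
full-batch Adam with early stopping on the validation objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SingleEventDataset
from .errors import ConfigurationError, GridMismatchError, TrainingError

__all__ = ["LearnerConfig", "HazardModel", "fit", "predict_cif"]


@dataclass(frozen=True)
class LearnerConfig:
    """Training configuration for the discrete-hazard learner.

    ``alpha`` weights the uncensored-only likelihood term; values above 0
    up-weight the observed events, sharpening discrimination at the cost
    of a systematic upward bias in the predicted cumulative incidence, so
    the calibration-first default is 0.  ``hidden = 0`` selects the linear
    model, ``hidden = m > 0`` a tanh layer of width m.
    """

    alpha: float = 0.0
    learning_rate: float = 0.1
    epochs: int = 500
    patience: int = 20
    hidden: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.epochs < 1 or self.patience < 1 or self.hidden < 0:
            raise ConfigurationError("epochs, patience >= 1 and hidden >= 0")


@dataclass
class HazardModel:
    """Fitted discrete-hazard model: intercepts plus covariate effect."""

    beta: np.ndarray  # per-interval intercepts, length k
    linear: np.ndarray | None  # covariate weights (linear variant)
    net: dict[str, np.ndarray] | None  # {'W', 'b', 'u'} (hidden variant)
    k: int
    config: LearnerConfig
    history: dict[str, list[float]] = field(default_factory=dict)

    def covariate_effect(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if self.linear is not None:
            return x @ self.linear
        assert self.net is not None
        z = np.tanh(x @ self.net["W"] + self.net["b"])
        return z @ self.net["u"]

    def predict_hazard(self, x: np.ndarray) -> np.ndarray:
        """``(n, k)`` matrix of hazards ``h(t | x)``; each in (0, 1)."""
        logits = self.beta[None, :] + self.covariate_effect(x)[:, None]
        return _sigmoid(logits)

    def predict_cif(self, x: np.ndarray, t: int | None = None) -> np.ndarray:
        """Model CIF ``F^(t | x) = 1 - prod_{s<=t}(1 - h(s | x))``.

        Returns the full ``(n, k)`` matrix, or the column at ``t`` when an
        evaluation time is given.
        """
        h = self.predict_hazard(x)
        cif = 1.0 - np.cumprod(1.0 - h, axis=1)
        if t is None:
            return cif
        if not 1 <= t <= self.k:
            raise ConfigurationError(f"t={t} outside the 1..{self.k} grid")
        return cif[:, t - 1]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _masks(data: SingleEventDataset) -> tuple[np.ndarray, np.ndarray]:
    """Person-period indicators: include[i, s] for s <= T_i, y[i, s] = event
    at exactly s.  Encodes the likelihood contributions above."""
    k = data.grid.k
    s_grid = np.arange(1, k + 1)[None, :]
    include = s_grid <= data.time[:, None]
    y = (s_grid == data.time[:, None]) & (data.event[:, None] == 1)
    return include.astype(float), y.astype(float)


def _objective_weights(event: np.ndarray, alpha: float) -> np.ndarray:
    """Per-individual weights realizing (1-alpha)*L_l + alpha*L_z with each
    term averaged over its own instance count."""
    n = event.shape[0]
    n_unc = max(int(event.sum()), 1)
    return (1.0 - alpha) / n + alpha * event / n_unc


def _loss_and_grad(
    params: dict[str, np.ndarray],
    x: np.ndarray,
    include: np.ndarray,
    y: np.ndarray,
    row_w: np.ndarray,
    hidden: int,
) -> tuple[float, dict[str, np.ndarray]]:
    if hidden:
        z = np.tanh(x @ params["W"] + params["b"])
        effect = z @ params["u"]
    else:
        effect = x @ params["w"]
    logits = params["beta"][None, :] + effect[:, None]
    h = _sigmoid(logits)
    eps = 1e-12
    cell_nll = -(y * np.log(h + eps) + (include - y) * np.log(1.0 - h + eps))
    loss = float((row_w[:, None] * cell_nll).sum())

    g_logit = row_w[:, None] * include * (h - y)  # d loss / d logits
    grads: dict[str, np.ndarray] = {"beta": g_logit.sum(axis=0)}
    g_effect = g_logit.sum(axis=1)
    if hidden:
        grads["u"] = z.T @ g_effect
        g_z = np.outer(g_effect, params["u"]) * (1.0 - z**2)
        grads["W"] = x.T @ g_z
        grads["b"] = g_z.sum(axis=0)
    else:
        grads["w"] = x.T @ g_effect
    return loss, grads


def _evaluate_loss(
    params: dict[str, np.ndarray],
    x: np.ndarray,
    include: np.ndarray,
    y: np.ndarray,
    row_w: np.ndarray,
    hidden: int,
) -> float:
    loss, _ = _loss_and_grad(params, x, include, y, row_w, hidden)
    return loss


def fit(
    train: SingleEventDataset,
    validation: SingleEventDataset,
    config: LearnerConfig = LearnerConfig(),
) -> HazardModel:
    """Fit the discrete-hazard model with early stopping.

    Full-batch Adam on the two-term objective; after each epoch the same
    objective is evaluated on the validation data and the parameters with
    the best validation loss are kept.  Training stops when the validation
    loss has not improved for ``config.patience`` epochs.
    """
    if train.grid.k != validation.grid.k:
        raise GridMismatchError("train and validation grids differ")
    k = train.grid.k
    p = train.p
    rng = np.random.default_rng(config.seed)

    # baseline intercepts: logit of the pooled marginal hazard
    marg = max(min(train.event.mean() / max(train.time.mean(), 1.0), 0.95), 1e-3)
    beta0 = np.log(marg / (1.0 - marg))
    params: dict[str, np.ndarray] = {"beta": np.full(k, beta0)}
    if config.hidden:
        m = config.hidden
        params["W"] = rng.normal(0.0, 1.0 / np.sqrt(p), size=(p, m))
        params["b"] = np.zeros(m)
        params["u"] = rng.normal(0.0, 1.0 / np.sqrt(m), size=m)
    else:
        params["w"] = np.zeros(p)

    inc_tr, y_tr = _masks(train)
    inc_va, y_va = _masks(validation)
    w_tr = _objective_weights(train.event, config.alpha)
    w_va = _objective_weights(validation.event, config.alpha)

    m1 = {key: np.zeros_like(v) for key, v in params.items()}
    m2 = {key: np.zeros_like(v) for key, v in params.items()}
    b1, b2, adam_eps = 0.9, 0.999, 1e-8
    best = {key: v.copy() for key, v in params.items()}
    best_val = np.inf
    stall = 0
    history: dict[str, list[float]] = {"train": [], "validation": []}

    for epoch in range(1, config.epochs + 1):
        loss, grads = _loss_and_grad(
            params, train.covariates, inc_tr, y_tr, w_tr, config.hidden
        )
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite training loss at epoch {epoch}")
        for key, g in grads.items():
            m1[key] = b1 * m1[key] + (1 - b1) * g
            m2[key] = b2 * m2[key] + (1 - b2) * g**2
            m1h = m1[key] / (1 - b1**epoch)
            m2h = m2[key] / (1 - b2**epoch)
            params[key] = params[key] - config.learning_rate * m1h / (
                np.sqrt(m2h) + adam_eps
            )
        val_loss = _evaluate_loss(
            params, validation.covariates, inc_va, y_va, w_va, config.hidden
        )
        history["train"].append(loss)
        history["validation"].append(val_loss)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best = {key: v.copy() for key, v in params.items()}
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break

    return HazardModel(
        beta=best["beta"],
        linear=best.get("w"),
        net=(
            {"W": best["W"], "b": best["b"], "u": best["u"]}
            if config.hidden
            else None
        ),
        k=k,
        config=config,
        history=history,
    )


def predict_cif(
    model: HazardModel, x: np.ndarray, t: int | None = None
) -> np.ndarray:
    """Functional alias for :meth:`HazardModel.predict_cif`."""
    return model.predict_cif(x, t)
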