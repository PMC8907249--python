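"""Data model and I/O for grouped-time (discrete) competing-risks survival data.

Observation scheme
------------------
Continuous follow-up is grouped into ``k`` intervals
``[0, a_1), [a_1, a_2), ..., [a_{k-1}, inf)`` and times are recorded as the
1-based interval index ``t`` meaning the event fell in ``[a_{t-1}, a_t)``.
Each individual carries an observed time ``T~ = min(T, C)`` in ``{1..k}``, a
status code (0 = right-censored, 1 = event of interest, j >= 2 = competing
event of type j) and a numeric covariate vector.  Event and censoring times
are assumed independent (random, non-informative censoring).

Tables are plain delimited text (comma by default, tab accepted) with a
header row; the ``time`` and ``status`` columns are required and every other
column is treated as a numeric covariate unless an explicit mapping is given.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DataError,
    DegenerateGridError,
    FormatError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TimeGrid",
    "CompetingRisksDataset",
    "SingleEventDataset",
    "read_survival_table",
    "write_survival_table",
    "discretize",
    "stratified_split",
]


@dataclass(frozen=True)
class TimeGrid:
    """A 1-based grid of ``k`` right-open time intervals.

    Parameters
    ----------
    k
        Number of intervals; at least 2.
    cut_points
        Optional ascending continuous boundaries ``a_1 < ... < a_{k-1}`` in
        the units of the raw times.  ``a_0 = 0`` and ``a_k = inf`` are
        implicit.  ``None`` when the data were recorded on the discrete grid
        directly.
    """

    k: int
    cut_points: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigurationError(f"need k >= 2 intervals, got k={self.k}")
        if self.cut_points is not None:
            cuts = np.asarray(self.cut_points, dtype=float)
            if cuts.shape != (self.k - 1,):
                raise ConfigurationError(
                    f"expected {self.k - 1} cut points for k={self.k}, "
                    f"got {cuts.shape}"
                )
            if not np.all(np.diff(cuts) > 0):
                raise ConfigurationError("cut points must be strictly increasing")
            object.__setattr__(self, "cut_points", cuts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeGrid):
            return NotImplemented
        if self.k != other.k:
            return False
        a, b = self.cut_points, other.cut_points
        if a is None or b is None:
            return a is None and b is None
        return np.array_equal(a, b)


def _validate_core(time: np.ndarray, status: np.ndarray, k: int) -> None:
    if time.size == 0:
        raise DataError("empty dataset")
    if np.any(time < 1) or np.any(time > k):
        bad = int(np.flatnonzero((time < 1) | (time > k))[0])
        raise FormatError(
            f"row {bad}: observed time {time[bad]} outside the 1..{k} grid"
        )
    if np.any(status < 0):
        bad = int(np.flatnonzero(status < 0)[0])
        raise FormatError(f"row {bad}: negative status {status[bad]}")


@dataclass
class CompetingRisksDataset:
    """Per-individual ``(T~_i, status_i, x_i)`` records on a discrete grid.

    ``status`` is the product Delta*epsilon: 0 for censored, the event type
    in ``{1..J}`` otherwise.  Covariates are a dense float matrix with one
    row per individual.
    """

    time: np.ndarray
    status: np.ndarray
    covariates: np.ndarray
    grid: TimeGrid
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.int64)
        self.status = np.asarray(self.status, dtype=np.int64)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.time.shape[0]:
            raise DataError(
                f"covariate rows ({self.covariates.shape[0]}) != "
                f"records ({self.time.shape[0]})"
            )
        _validate_core(self.time, self.status, self.grid.k)
        if not self.covariate_names:
            self.covariate_names = [f"x{j + 1}" for j in range(self.p)]

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def J(self) -> int:
        """Number of event types = largest observed status (at least 1)."""
        return max(int(self.status.max()), 1)

    def subset(self, idx: np.ndarray) -> "CompetingRisksDataset":
        return replace(
            self,
            time=self.time[idx],
            status=self.status[idx],
            covariates=self.covariates[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "status": self.status})
        for j, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, j]
        return df


@dataclass
class SingleEventDataset:
    """Single-event survival records ``(time_i, event_i, x_i)``.

    The output of the imputation step: ``time = min(theta_i, C_i)`` on the
    interval grid and ``event = I(theta_i <= C_i)`` in {0, 1}, where
    ``theta`` is the subdistribution time of the event of interest (equal to
    ``T`` when the type-1 event occurs, infinite otherwise).  Consumable by
    any single-event discrete-time learner.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: np.ndarray
    grid: TimeGrid
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.int64)
        self.event = np.asarray(self.event, dtype=np.int64)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        _validate_core(self.time, self.event, self.grid.k)
        if not np.isin(self.event, (0, 1)).all():
            raise FormatError("event indicator must be binary")
        if not self.covariate_names:
            self.covariate_names = [f"x{j + 1}" for j in range(self.p)]

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    def subset(self, idx: np.ndarray) -> "SingleEventDataset":
        return replace(
            self,
            time=self.time[idx],
            event=self.event[idx],
            covariates=self.covariates[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "status": self.event})
        for j, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, j]
        return df


def read_survival_table(
    path: str | Path,
    *,
    time_col: str = "time",
    status_col: str = "status",
    covariate_cols: Sequence[str] | None = None,
    k: int | None = None,
) -> CompetingRisksDataset:
    """Read a delimited survival table into a :class:`CompetingRisksDataset`.

    Parameters
    ----------
    path
        CSV or TSV file with a header row (delimiter sniffed).
    time_col, status_col
        Names of the observed-time and status columns.
    covariate_cols
        Explicit covariate column names; defaults to every remaining column.
    k
        Number of grid intervals; defaults to the maximum observed time.

    Raises
    ------
    ConfigurationError
        A mapped column is missing from the file.
    FormatError
        Non-integer or out-of-range time / status values.
    DataError
        A missing value, reported with its row number.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    delim = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=delim, float_precision="round_trip")
    for col in (time_col, status_col):
        if col not in df.columns:
            raise ConfigurationError(f"column {col!r} not found in {path.name}")
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns if c not in (time_col, status_col)]
    else:
        missing = [c for c in covariate_cols if c not in df.columns]
        if missing:
            raise ConfigurationError(f"covariate columns missing: {missing}")

    used = [time_col, status_col, *covariate_cols]
    na = df[used].isna()
    if na.to_numpy().any():
        row = int(na.any(axis=1).idxmax())
        raise DataError(f"missing value in row {row} of {path.name}")

    time_raw = df[time_col].to_numpy()
    if not np.array_equal(time_raw, np.asarray(time_raw, dtype=np.int64)):
        raise FormatError(f"{time_col!r} must be integer interval indices >= 1")
    time = np.asarray(time_raw, dtype=np.int64)
    if np.any(time < 1):
        raise FormatError(f"{time_col!r} contains values < 1 (grid is 1-based)")

    status_raw = df[status_col].to_numpy()
    if not np.array_equal(status_raw, np.asarray(status_raw, dtype=np.int64)):
        raise FormatError(f"{status_col!r} must be non-negative integers")
    status = np.asarray(status_raw, dtype=np.int64)

    try:
        cov = df[list(covariate_cols)].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(
            "covariate columns must be numeric (pre-encode categoricals)"
        ) from exc
    cov = cov.reshape(len(df), len(covariate_cols))

    if status.max(initial=0) == 0:
        logger.warning("%s: all records censored (J defaults to 1)", path.name)
    grid = TimeGrid(k=int(k if k is not None else max(time.max(), 2)))
    return CompetingRisksDataset(
        time=time,
        status=status,
        covariates=cov,
        grid=grid,
        covariate_names=list(covariate_cols),
    )


def write_survival_table(
    dataset: CompetingRisksDataset | SingleEventDataset, path: str | Path
) -> None:
    """Write a dataset as a comma-delimited table; round-trips exactly."""
    dataset.to_frame().to_csv(path, index=False)


def discretize(
    raw_times: np.ndarray, k: int
) -> tuple[np.ndarray, TimeGrid]:
    """Group continuous times into ``k`` intervals at empirical quantiles.

    Cut points are the ``j/k`` empirical quantiles (``j = 1..k-1``) of the
    supplied times, so each interval receives roughly equal occupancy.  A
    value exactly on a cut point belongs to the higher interval (right-open
    intervals).

    Returns the 1-based interval indices and the :class:`TimeGrid`.
    """
    raw = np.asarray(raw_times, dtype=float)
    if k < 2:
        raise ConfigurationError(f"need k >= 2, got {k}")
    if np.any(raw < 0):
        raise FormatError("raw times must be non-negative")
    if np.unique(raw).size < k:
        raise DegenerateGridError(
            f"only {np.unique(raw).size} distinct times for k={k} intervals"
        )
    cuts = np.quantile(raw, np.arange(1, k) / k)
    if np.unique(cuts).size < k - 1:
        raise DegenerateGridError("tied quantiles produce empty intervals")
    idx = np.searchsorted(cuts, raw, side="right") + 1
    return idx.astype(np.int64), TimeGrid(k=k, cut_points=cuts)


def stratified_split(
    dataset: CompetingRisksDataset,
    fractions: Sequence[float],
    seed: int,
) -> tuple[CompetingRisksDataset, CompetingRisksDataset, CompetingRisksDataset]:
    """Split into (train, validation, test) preserving status composition.

    Within each status category individuals are shuffled and allocated in
    the given proportions (rounded to the nearest integer, remainder to the
    test split), so event and censoring rates are equal across the three
    splits up to rounding.  Deterministic given ``seed``.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (3,) or np.any(fractions <= 0):
        raise ConfigurationError("need three positive split fractions")
    if not np.isclose(fractions.sum(), 1.0):
        raise ConfigurationError(f"fractions must sum to 1, got {fractions.sum()}")

    rng = np.random.default_rng(seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    for cat in np.unique(dataset.status):
        members = np.flatnonzero(dataset.status == cat)
        rng.shuffle(members)
        n_cat = members.size
        n_train = int(round(fractions[0] * n_cat))
        n_val = int(round(fractions[1] * n_cat))
        if n_train + n_val > n_cat:
            logger.warning(
                "status %d has only %d members; best-effort allocation", cat, n_cat
            )
            n_val = max(n_cat - n_train, 0)
        parts[0].append(members[:n_train])
        parts[1].append(members[n_train : n_train + n_val])
        parts[2].append(members[n_train + n_val :])
    splits = tuple(
        dataset.subset(np.sort(np.concatenate(p))) for p in parts
    )
    return splits  # type: ignore[return-value]
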