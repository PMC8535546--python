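"""Per-user one-step-ahead forecasters: supervised conversion, LSTM and SVR.

A user's 90-day training window is converted into sliding supervised
windows (seven consecutive days in, the eighth day out), a forecaster is
grid-searched on those windows, and the winner — the model with the lowest
training mean absolute error, in original seconds — becomes that user's
ensemble member.  Month-4 forecasts are produced recursively: each one-step
prediction is appended to the history and fed back for the next step.

Two model families are supported:

* ``lstm`` — the NumPy LSTM of :mod:`adherefit._lstm`, trained on min-max
  scaled series ([0, 1]) with the study grid: dropout {0.2, 0.4, 0.6} x
  batch size {1, 2, 4} x LSTM units {50, 75, 100, 125, 150}, 50 epochs,
  early stopping patience 15.
* ``svr`` — epsilon-tube support vector regression (scikit-learn) over
  polynomial / RBF / sigmoid kernels with penalty C searched in (0, 500]
  and epsilon fixed at 10.  Epsilon is specified in seconds, so the SVR is
  trained on the raw-seconds axis (identity transform).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVR

from ._lstm import LSTMNetwork

__all__ = [
    "LOOKBACK",
    "SupervisedWindows",
    "MinMaxTransform",
    "LSTMSpec",
    "SVRSpec",
    "TrainedRegressor",
    "to_supervised",
    "scale_series",
    "fit_lstm",
    "fit_svr",
    "grid_search_user",
    "forecast_recursive",
    "default_grid",
    "reduced_lstm_grid",
]

LOOKBACK = 7


@dataclass(frozen=True)
class SupervisedWindows:
    """Sliding-window supervised pairs: inputs (n, lookback), targets (n,)."""

    inputs: np.ndarray
    targets: np.ndarray
    lookback: int = LOOKBACK

    def __len__(self) -> int:
        return len(self.targets)


def to_supervised(series, lookback: int = LOOKBACK) -> SupervisedWindows:
    """Convert a series into (lookback-days in, next day out) pairs.

    A series of length L yields exactly L - lookback pairs, sliding by one
    day.
    """
    values = np.asarray(series, dtype=float).ravel()
    n = len(values) - lookback
    if n < 1:
        raise ValueError(
            f"series of length {len(values)} too short for lookback {lookback}"
        )
    inputs = np.lib.stride_tricks.sliding_window_view(values[:-1], lookback)[:n]
    return SupervisedWindows(
        inputs=inputs.copy(), targets=values[lookback:].copy(), lookback=lookback
    )


@dataclass(frozen=True)
class MinMaxTransform:
    """Per-user min-max scaling to [0, 1]; constant series map to zeros and
    invert exactly (offset-only inverse)."""

    lo: float
    hi: float

    @property
    def span(self) -> float:
        return self.hi - self.lo

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.span == 0:
            return np.zeros_like(x)
        return (x - self.lo) / self.span

    def inverse(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.span == 0:
            return np.full_like(z, self.lo)
        return z * self.span + self.lo

    @staticmethod
    def identity() -> "MinMaxTransform":
        return MinMaxTransform(lo=0.0, hi=1.0)


def scale_series(series) -> tuple[np.ndarray, MinMaxTransform]:
    """Min-max scale a series to [0, 1], returning the invertible transform."""
    values = np.asarray(series, dtype=float)
    t = MinMaxTransform(lo=float(values.min()), hi=float(values.max()))
    return t.transform(values), t


@dataclass(frozen=True)
class LSTMSpec:
    """One LSTM hyperparameter combination plus the fixed training recipe."""

    units: int = 100
    dropout: float = 0.2
    batch_size: int = 2
    lookback: int = LOOKBACK
    epochs: int = 50
    patience: int = 15
    cell_activation: str = "relu"

    @staticmethod
    def grid(
        units=(50, 75, 100, 125, 150),
        dropouts=(0.2, 0.4, 0.6),
        batch_sizes=(1, 2, 4),
        **fixed,
    ) -> list["LSTMSpec"]:
        """The study grid: dropout x batch size x units, 45 combinations by
        default, in documented (dropout, batch, units) order."""
        return [
            LSTMSpec(units=u, dropout=d, batch_size=b, **fixed)
            for d, b, u in itertools.product(dropouts, batch_sizes, units)
        ]


@dataclass(frozen=True)
class SVRSpec:
    """One SVR hyperparameter combination (epsilon-tube regression)."""

    kernel: str = "rbf"  # 'poly' | 'rbf' | 'sigmoid'
    C: float = 100.0
    epsilon: float = 10.0
    gamma: str | float = "scale"
    degree: int = 3  # polynomial kernel degree
    coef0: float = 0.0
    lookback: int = LOOKBACK
    # iteration cap: the degree-3 polynomial kernel on raw-second features
    # can cycle indefinitely in the solver; a capped fit just scores a worse
    # MAE and loses the grid search
    max_iter: int = 100_000

    def __post_init__(self):
        if self.kernel not in ("poly", "rbf", "sigmoid", "linear"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")

    @staticmethod
    def grid(
        kernels=("poly", "rbf", "sigmoid"),
        Cs=(1.0, 10.0, 50.0, 100.0, 200.0, 500.0),
        **fixed,
    ) -> list["SVRSpec"]:
        """Kernel x C grid within the (0, 500] penalty range."""
        return [SVRSpec(kernel=k, C=c, **fixed) for k, c in itertools.product(kernels, Cs)]


@dataclass
class TrainedRegressor:
    """One user's fitted forecaster: model, winning spec, training MAE and
    the scaling transform its inputs/outputs live on."""

    kind: str  # 'lstm' | 'svr'
    model: object
    spec: object
    transform: MinMaxTransform
    train_mae: float
    lookback: int

    def predict_next(self, window: np.ndarray) -> float:
        """One-step prediction from a lookback window in *original* seconds."""
        z = self.transform.transform(np.asarray(window, dtype=float)).reshape(1, -1)
        raw = float(np.asarray(self.model.predict(z)).ravel()[0])
        return float(self.transform.inverse(raw))


def _train_mae(model, windows: SupervisedWindows, transform: MinMaxTransform) -> float:
    pred_scaled = np.asarray(model.predict(windows.inputs)).ravel()
    pred = transform.inverse(pred_scaled)
    truth = transform.inverse(windows.targets)
    return float(np.abs(pred - truth).mean())


def fit_lstm(series, spec: LSTMSpec = LSTMSpec(), seed: int | None = 0) -> TrainedRegressor:
    """Train one LSTM on a user's series (min-max scaled), reporting the
    training-window MAE in original seconds."""
    values = np.asarray(series, dtype=float)
    scaled, transform = scale_series(values)
    windows = to_supervised(scaled, spec.lookback)
    net = LSTMNetwork(
        units=spec.units,
        lookback=spec.lookback,
        dropout=spec.dropout,
        cell_activation=spec.cell_activation,
        seed=seed,
    )
    net.fit(
        windows.inputs,
        windows.targets,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        patience=spec.patience,
    )
    return TrainedRegressor(
        kind="lstm",
        model=net,
        spec=spec,
        transform=transform,
        train_mae=_train_mae(net, windows, transform),
        lookback=spec.lookback,
    )


def fit_svr(series, spec: SVRSpec = SVRSpec(), seed: int | None = 0) -> TrainedRegressor:
    """Fit an epsilon-tube SVR on a user's raw-seconds supervised windows.

    The tube width epsilon (default 10) is in seconds, so no scaling is
    applied; the transform recorded on the result is the identity.  ``seed``
    is accepted for interface symmetry — the SVR solver is deterministic.
    """
    del seed
    values = np.asarray(series, dtype=float)
    windows = to_supervised(values, spec.lookback)
    model = SVR(
        kernel=spec.kernel,
        C=spec.C,
        epsilon=spec.epsilon,
        gamma=spec.gamma,
        degree=spec.degree,
        coef0=spec.coef0,
        max_iter=spec.max_iter,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(windows.inputs, windows.targets)
    transform = MinMaxTransform.identity()
    return TrainedRegressor(
        kind="svr",
        model=model,
        spec=spec,
        transform=transform,
        train_mae=_train_mae(model, windows, transform),
        lookback=spec.lookback,
    )


def default_grid(kind: str) -> list:
    if kind == "lstm":
        return LSTMSpec.grid()
    if kind == "svr":
        return SVRSpec.grid()
    raise ValueError(f"unknown regressor kind {kind!r}")


def reduced_lstm_grid(units: int = 16, epochs: int = 5) -> list[LSTMSpec]:
    """A single-combination LSTM grid for quick end-to-end runs."""
    return [LSTMSpec(units=units, dropout=0.2, batch_size=4, epochs=epochs)]


def grid_search_user(series, kind: str, grid=None, seed: int | None = 0) -> TrainedRegressor:
    """Train every grid combination on one user's series; return the model
    with the lowest training MAE (ties: first in grid order)."""
    if grid is None:
        grid = default_grid(kind)
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    fit = {"lstm": fit_lstm, "svr": fit_svr}[kind]
    best: TrainedRegressor | None = None
    for spec in grid:
        candidate = fit(series, spec, seed=seed)
        if best is None or candidate.train_mae < best.train_mae:
            best = candidate
    return best


#: A day has 86400 seconds; no daily accumulated workout can exceed it.
MAX_DAY_SECONDS = 86400.0


def forecast_recursive(model: TrainedRegressor, history, horizon: int = 30) -> np.ndarray:
    """Roll a one-step forecaster forward ``horizon`` days.

    Each prediction is appended to the history and becomes part of the next
    input window.  Predictions are clipped to the physically valid range
    [0, 86400] seconds/day — seconds cannot be negative, and unbounded
    feedback would otherwise let an ill-conditioned kernel model diverge
    over the 30-step roll-out.  A non-finite prediction is treated as 0.
    """
    hist = list(np.asarray(history, dtype=float).ravel())
    if len(hist) < model.lookback:
        raise ValueError(
            f"history of length {len(hist)} shorter than lookback {model.lookback}"
        )
    out = []
    for _ in range(horizon):
        window = np.array(hist[-model.lookback :])
        pred = model.predict_next(window)
        if not np.isfinite(pred):
            pred = 0.0
        pred = float(np.clip(pred, 0.0, MAX_DAY_SECONDS))
        out.append(pred)
        hist.append(pred)
    return np.array(out)
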