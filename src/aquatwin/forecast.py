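"""One-step-ahead forecasting of DO and NH3 from 5-min windows.

A forecast window is a fixed 24 x 8 matrix: 24 five-minute steps (2 h) by 8
features in the fixed order (DO, NH3, Temp, pH, Turb, Aaer, Afeed, dE),
min-max normalized.  The energy feature is per-interval Wh (the difference
of cumulative E): normalized cumulative energy is non-stationary and
saturates toward 1, carrying no signal.

Three interchangeable forecaster implementations are provided — persistence,
linear trend, and a trained recurrent (LSTM) reference model — behind one
``predict`` interface; the control loop runs with any of them and must not
depend on a trained artifact.  Forecast error is summarised by RMSE and MAE
in the physical units of each channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nnet import LSTMRegressor, TrainingHistory
from .series import NormalizationSpec, SensorSeries

WINDOW_STEPS = 24
FEATURES = ("DO", "NH3", "Temp", "pH", "Turb", "Aaer", "Afeed", "dE")
NORMALIZED_FEATURES = ("DO", "NH3", "Temp", "pH", "Turb", "dE")
TARGETS = ("DO", "NH3")


class InsufficientDataError(ValueError):
    """Fewer samples than one window plus target."""


@dataclass
class ForecastResult:
    """Denormalized one-step-ahead prediction at the step after the window."""

    DO: float
    NH3: float
    model: str
    window_end: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.DO) and np.isfinite(self.NH3)):
            raise ValueError("forecast must be finite")


@dataclass
class TrainingConfig:
    """Reference-model training configuration."""

    hidden: int = 64
    n_layers: int = 2
    dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 150
    patience: int = 10
    val_fraction: float = 0.15
    holdout_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        for name in ("hidden", "n_layers", "batch_size", "max_epochs", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class WindowSet:
    """Sliding windows X (N, 24, 8), normalized targets y (N, 2), and the spec."""

    X: np.ndarray
    y: np.ndarray
    spec: NormalizationSpec
    window_ends: pd.DatetimeIndex

    def __len__(self) -> int:
        return len(self.X)


def build_feature_frame(series: SensorSeries) -> pd.DataFrame:
    """Physical-unit feature matrix in the fixed feature order.

    Replaces cumulative E with the per-interval energy dE (first interval 0).
    """
    f = series.frame
    de = f["E"].diff().fillna(0.0)
    out = pd.DataFrame(
        {"DO": f["DO"], "NH3": f["NH3"], "Temp": f["Temp"], "pH": f["pH"],
         "Turb": f["Turb"], "Aaer": f["Aaer"], "Afeed": f["Afeed"], "dE": de},
        index=f.index,
    )
    return out


def make_windows(
    series: SensorSeries,
    spec: NormalizationSpec | None = None,
) -> WindowSet:
    """Cut a 5-min series into stride-1 windows of 24 steps plus targets.

    The target is the normalized (DO, NH3) pair at the step following each
    window; a series of length n yields n - 24 windows.  Continuous features
    are min-max normalized with ``spec`` (fitted on this series when absent);
    binary features pass through.  Missing values are not allowed here — run
    the preprocessing pipeline first.
    """
    feats = build_feature_frame(series)
    n = len(feats)
    if n < WINDOW_STEPS + 1:
        raise InsufficientDataError(
            f"need at least {WINDOW_STEPS + 1} samples, got {n}"
        )
    if feats.isna().any().any():
        raise ValueError("windows require a gap-free series")
    if spec is None:
        spec = NormalizationSpec.fit(feats, NORMALIZED_FEATURES)
    elif set(spec.features) != set(NORMALIZED_FEATURES):
        raise ValueError("spec features do not match the window feature set")
    norm = spec.apply(feats)[list(FEATURES)].to_numpy(dtype=float)

    n_windows = n - WINDOW_STEPS
    X = np.empty((n_windows, WINDOW_STEPS, len(FEATURES)))
    for k in range(n_windows):
        X[k] = norm[k:k + WINDOW_STEPS]
    y = norm[WINDOW_STEPS:, :2]
    ends = feats.index[WINDOW_STEPS - 1: n - 1]
    return WindowSet(X=X, y=y, spec=spec, window_ends=ends)


# ---------------------------------------------------------------------------
# Deterministic baselines


def _denorm_clamp(spec: NormalizationSpec | None, do: float, nh3: float):
    if spec is not None:
        do = spec.invert_value("DO", do)
        nh3 = spec.invert_value("NH3", nh3)
    return max(do, 0.0), max(nh3, 0.0)


def predict_baseline(
    window: np.ndarray,
    method: str = "persistence",
    spec: NormalizationSpec | None = None,
    window_end: pd.Timestamp | None = None,
) -> ForecastResult:
    """Deterministic one-step forecast from a single window.

    ``persistence`` returns the window's last DO/NH3 row; ``linear_trend``
    extrapolates one step ahead from an ordinary-least-squares line fitted
    over the window.  If ``spec`` is given the window is assumed normalized
    and the prediction is denormalized (and clamped at 0).
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.shape[1] < 2:
        raise ValueError("window must be 2-D with DO and NH3 in columns 0-1")
    if method == "persistence":
        do, nh3 = float(w[-1, 0]), float(w[-1, 1])
    elif method == "linear_trend":
        t = np.arange(len(w), dtype=float)
        preds = []
        for col in (0, 1):
            slope, intercept = np.polyfit(t, w[:, col], 1)
            preds.append(slope * len(w) + intercept)
        do, nh3 = preds
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    do, nh3 = _denorm_clamp(spec, do, nh3)
    return ForecastResult(DO=do, NH3=nh3, model=method, window_end=window_end)


class PersistenceForecaster:
    name = "persistence"

    def __init__(self, spec: NormalizationSpec | None = None) -> None:
        self.spec = spec

    def predict(self, window: np.ndarray, window_end=None) -> ForecastResult:
        return predict_baseline(window, "persistence", self.spec, window_end)


class LinearTrendForecaster:
    name = "linear_trend"

    def __init__(self, spec: NormalizationSpec | None = None) -> None:
        self.spec = spec

    def predict(self, window: np.ndarray, window_end=None) -> ForecastResult:
        return predict_baseline(window, "linear_trend", self.spec, window_end)


# ---------------------------------------------------------------------------
# Recurrent reference model


@dataclass
class TrainedModel:
    """Handle around a fitted recurrent model plus its data split."""

    model: LSTMRegressor
    spec: NormalizationSpec
    history: TrainingHistory
    holdout_idx: np.ndarray
    train_idx: np.ndarray
    val_idx: np.ndarray
    config: TrainingConfig
    name: str = "lstm"

    def predict(self, window: np.ndarray, window_end=None) -> ForecastResult:
        y = self.model.predict(np.asarray(window, dtype=float)[None, :, :])[0]
        do, nh3 = _denorm_clamp(self.spec, float(y[0]), float(y[1]))
        return ForecastResult(DO=do, NH3=nh3, model=self.name, window_end=window_end)


def split_indices(
    n: int, holdout_fraction: float, val_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded (train, val, holdout) index split; holdout reserved first."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_hold = int(round(n * holdout_fraction))
    holdout = np.sort(perm[:n_hold])
    rest = perm[n_hold:]
    n_val = max(1, int(round(len(rest) * val_fraction)))
    val = np.sort(rest[:n_val])
    train = np.sort(rest[n_val:])
    return train, val, holdout


def train_reference_model(
    windows: WindowSet, config: TrainingConfig | None = None
) -> TrainedModel:
    """Train the stacked-LSTM reference forecaster on a window set.

    A 20% holdout is reserved (seeded) before training; the remainder is
    split into training and validation sets.  Training stops when the
    validation loss has not improved for ``patience`` epochs, or at
    ``max_epochs``; the best validation weights are restored.
    """
    config = config if config is not None else TrainingConfig()
    if len(windows) < 100:
        raise InsufficientDataError(
            f"need >= 100 windows to train the reference model, got {len(windows)}"
        )
    train_idx, val_idx, hold_idx = split_indices(
        len(windows), config.holdout_fraction, config.val_fraction, config.seed
    )
    model = LSTMRegressor(
        n_features=windows.X.shape[2],
        hidden=config.hidden,
        n_layers=config.n_layers,
        n_outputs=2,
        dropout=config.dropout,
        seed=config.seed,
    )
    history = model.fit(
        windows.X[train_idx], windows.y[train_idx],
        windows.X[val_idx], windows.y[val_idx],
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        seed=config.seed,
    )
    return TrainedModel(
        model=model, spec=windows.spec, history=history,
        holdout_idx=hold_idx, train_idx=train_idx, val_idx=val_idx,
        config=config,
    )


# ---------------------------------------------------------------------------
# Metrics


def evaluate_forecast(y, yhat) -> tuple[float, float]:
    """(RMSE, MAE) in the units of the input channel."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch between y and yhat")
    if y.size == 0:
        raise ValueError("need at least one observation")
    err = y - yhat
    rmse = float(np.sqrt(np.mean(err * err)))
    mae = float(np.mean(np.abs(err)))
    return rmse, mae


def holdout_errors(
    trained: TrainedModel, windows: WindowSet
) -> dict[str, tuple[float, float]]:
    """Physical-unit (RMSE, MAE) per target channel on the reserved holdout."""
    idx = trained.holdout_idx
    pred = trained.model.predict(windows.X[idx])
    out = {}
    for j, ch in enumerate(TARGETS):
        y = np.array([windows.spec.invert_value(ch, v) for v in windows.y[idx, j]])
        p = np.array([max(trained.spec.invert_value(ch, v), 0.0) for v in pred[:, j]])
        out[ch] = evaluate_forecast(y, p)
    return out
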