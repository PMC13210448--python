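"""Sensor time-series containers, CSV I/O, preprocessing, and energy integration.

The pond's state at each sampling instant is a fixed vector of environmental
readings (dissolved oxygen, ammonia, temperature, pH, turbidity), binary
actuator states (aerator, feeder), instantaneous power draw and cumulative
energy.  Raw streams arrive at 1-min cadence; modelling uses 5-min aggregates.

The on-disk format is a plain CSV with a versioned header
(``timestamp,do_mg_l,nh3_mg_l,temp_c,ph,turbidity_ntu,aerator,feeder,power_w,
energy_wh``), ISO-8601 timestamps, empty field = missing, plus a JSON sidecar
(``<path>.meta.json``) carrying cadence and provenance.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Environmental channels that are smoothed / interpolated / normalized.
CONTINUOUS_CHANNELS = ("DO", "NH3", "Temp", "pH", "Turb")
#: Actuator channels: never averaged, carried forward on gaps.
BINARY_CHANNELS = ("Aaer", "Afeed")
#: All data channels, in canonical order.
CHANNELS = CONTINUOUS_CHANNELS + BINARY_CHANNELS + ("P", "E")

#: CSV header, versioned: position i maps to CHANNELS[i].
CSV_COLUMNS = (
    "do_mg_l", "nh3_mg_l", "temp_c", "ph", "turbidity_ntu",
    "aerator", "feeder", "power_w", "energy_wh",
)
_CSV_TO_CHANNEL = dict(zip(CSV_COLUMNS, CHANNELS))
_CHANNEL_TO_CSV = dict(zip(CHANNELS, CSV_COLUMNS))


class SchemaError(ValueError):
    """CSV header or cell contents do not match the documented schema."""


class OrderingError(ValueError):
    """Timestamps are not strictly increasing."""


class UnrecoverableGapError(ValueError):
    """Leading/trailing missing run exceeds the configured limit."""


class EmptySeriesError(ValueError):
    """Operation requires a non-empty series."""


@dataclass
class PondState:
    """One realization of the pond state vector.

    Concentrations in mg/L, temperature in deg C, turbidity in NTU, power in W,
    energy in Wh.  ``math.nan`` marks a missing reading.
    """

    timestamp: pd.Timestamp
    DO: float = math.nan
    NH3: float = math.nan
    Temp: float = math.nan
    pH: float = math.nan
    Turb: float = math.nan
    Aaer: float = 0.0
    Afeed: float = 0.0
    P: float = 0.0
    E: float = 0.0

    def validate(self) -> None:
        for name in ("DO", "NH3", "Turb", "P"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if not math.isnan(self.pH) and not 0.0 <= self.pH <= 14.0:
            raise ValueError(f"pH out of [0, 14]: {self.pH}")
        for name in BINARY_CHANNELS:
            v = getattr(self, name)
            if not math.isnan(v) and v not in (0, 1):
                raise ValueError(f"{name} must be binary, got {v}")


@dataclass
class SensorSeries:
    """A fixed-cadence, ordered sequence of pond states.

    ``frame`` is indexed by tz-aware UTC timestamps with columns CHANNELS.
    ``provenance`` is one of {"raw", "preprocessed", "aggregated",
    "simulated"}; gaps (missing rows relative to the cadence grid) are only
    tolerated while provenance == "raw".
    """

    frame: pd.DataFrame
    cadence: pd.Timedelta
    provenance: str = "raw"

    def __post_init__(self) -> None:
        if not isinstance(self.cadence, pd.Timedelta):
            self.cadence = pd.Timedelta(self.cadence)
        idx = self.frame.index
        if len(idx) and idx.tz is None:
            self.frame = self.frame.tz_localize("UTC")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def cadence_minutes(self) -> float:
        return self.cadence / pd.Timedelta(minutes=1)

    @classmethod
    def from_records(
        cls,
        records: Iterable[PondState],
        cadence: pd.Timedelta | str,
        provenance: str = "raw",
    ) -> "SensorSeries":
        rows = list(records)
        frame = pd.DataFrame(
            {ch: [getattr(r, ch) for r in rows] for ch in CHANNELS},
            index=pd.DatetimeIndex([r.timestamp for r in rows], tz="UTC"),
        )
        out = cls(frame, pd.Timedelta(cadence), provenance)
        out.validate()
        return out

    def records(self) -> Iterator[PondState]:
        for ts, row in self.frame.iterrows():
            yield PondState(timestamp=ts, **{ch: row[ch] for ch in CHANNELS})

    def validate(self) -> None:
        idx = self.frame.index
        if idx.has_duplicates:
            raise OrderingError("duplicate timestamps")
        if not idx.is_monotonic_increasing:
            raise OrderingError("timestamps not increasing")
        if self.provenance != "raw" and len(idx) > 1:
            deltas = np.diff(idx.asi8)
            if not np.all(deltas == self.cadence.value):
                raise OrderingError(
                    f"timestamps not equispaced at {self.cadence} "
                    f"(provenance={self.provenance})"
                )
        e = self.frame["E"].dropna().to_numpy()
        if len(e) > 1 and np.any(np.diff(e) < -1e-9):
            raise ValueError("cumulative energy E must be non-decreasing")

    def copy(self) -> "SensorSeries":
        return SensorSeries(self.frame.copy(), self.cadence, self.provenance)

    def missing_record_count(self) -> int:
        """Rows whose every data channel is missing (dropped records)."""
        return int(self.frame[list(CHANNELS)].isna().all(axis=1).sum())


# ---------------------------------------------------------------------------
# CSV I/O


def write_series(series: SensorSeries, path: str | Path) -> None:
    """Write the series to the documented CSV schema plus a JSON sidecar."""
    path = Path(path)
    df = series.frame.rename(columns=_CHANNEL_TO_CSV).copy()
    df.index.name = "timestamp"
    df.to_csv(path, date_format="%Y-%m-%dT%H:%M:%S%z", float_format="%.10g")
    meta = {
        "cadence_minutes": series.cadence_minutes,
        "provenance": series.provenance,
        "n_records": len(series),
        "schema": "aquatwin-sensor-csv-v1",
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_series(
    path: str | Path,
    cadence: pd.Timedelta | str | None = None,
) -> SensorSeries:
    """Read a sensor log CSV.

    The header must match the documented schema exactly.  Cells that fail to
    parse as numbers are flagged missing and reported (with 1-based file line
    numbers) through the module logger; unparseable timestamps raise
    :class:`SchemaError`; non-monotone timestamps raise :class:`OrderingError`.
    Cadence is taken from the argument, else the sidecar, else inferred from
    the median timestamp spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["timestamp", *CSV_COLUMNS]
    if list(df.columns) != expected:
        missing = set(expected) - set(df.columns)
        raise SchemaError(
            f"header mismatch; expected {expected}, missing {sorted(missing)}"
        )

    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    bad_ts = np.flatnonzero(ts.isna().to_numpy())
    if len(bad_ts):
        lines = [int(i) + 2 for i in bad_ts]  # +2: header + 1-based
        raise SchemaError(f"unparseable timestamps at lines {lines}")

    data = {}
    for col in CSV_COLUMNS:
        raw = df[col].str.strip()
        vals = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        malformed = np.flatnonzero(vals.isna().to_numpy() & (raw != "").to_numpy())
        if len(malformed):
            lines = [int(i) + 2 for i in malformed]
            logger.warning(
                "column %s: malformed values flagged missing at lines %s",
                col, lines,
            )
        data[_CSV_TO_CHANNEL[col]] = vals.to_numpy(dtype=float)

    frame = pd.DataFrame(data, index=pd.DatetimeIndex(ts))
    frame.index.name = None
    if not frame.index.is_monotonic_increasing or frame.index.has_duplicates:
        raise OrderingError("timestamps must be strictly increasing")

    meta_path = Path(str(path) + ".meta.json")
    provenance = "raw"
    if cadence is None and meta_path.exists():
        meta = json.loads(meta_path.read_text())
        cadence = pd.Timedelta(minutes=meta["cadence_minutes"])
        provenance = meta.get("provenance", "raw")
    elif meta_path.exists():
        provenance = json.loads(meta_path.read_text()).get("provenance", "raw")
    if cadence is None:
        if len(frame) < 2:
            raise SchemaError("cannot infer cadence from fewer than 2 records")
        cadence = pd.Timedelta(np.median(np.diff(frame.index.asi8)), unit="ns")
    out = SensorSeries(frame, pd.Timedelta(cadence), provenance)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Preprocessing


def moving_average(
    values: pd.Series, window: int, centered: bool = False
) -> pd.Series:
    """NaN-aware moving average; missing positions stay missing.

    Causal by default (window trailing the sample); ``centered=True`` uses a
    symmetric window (``window`` should then be odd).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    sm = values.rolling(window, min_periods=1, center=centered).mean()
    sm[values.isna()] = np.nan
    return sm


def interpolate_missing(values: pd.Series) -> pd.Series:
    """Linearly interpolate interior missing values between present neighbours.

    Leading/trailing runs are left missing (handled by the edge rule in
    :func:`preprocess`).
    """
    return values.interpolate(method="time", limit_area="inside")


def preprocess(
    series: SensorSeries,
    window: int = 5,
    *,
    centered: bool = False,
    max_edge_gap: int = 15,
) -> SensorSeries:
    """Run the preprocessing pipeline on a raw series.

    Stages, in order: moving-average filtering of the continuous
    environmental channels (NaN-aware, missing positions preserved), linear
    interpolation of interior missing values, timestamp synchronization
    (snap to the cadence grid, re-grid to an equispaced index, fill rows the
    re-gridding introduces).  Binary channels are never averaged: they are
    carried forward unmodified over gaps.  Power is interpolated but not
    smoothed (it is metered, not a noisy probe); cumulative energy is
    linearly interpolated.

    Leading/trailing missing runs longer than ``max_edge_gap`` samples raise
    :class:`UnrecoverableGapError`; shorter edge runs are filled by
    nearest-value extension.
    """
    if series.provenance != "raw":
        raise ValueError(f"preprocess expects provenance='raw', got {series.provenance!r}")
    if len(series) == 0:
        raise EmptySeriesError("empty series")

    df = series.frame.copy()

    # 1. filter
    for ch in CONTINUOUS_CHANNELS:
        df[ch] = moving_average(df[ch], window, centered=centered)
    # 2. interpolate (interior)
    for ch in CONTINUOUS_CHANNELS + ("P", "E"):
        df[ch] = interpolate_missing(df[ch])
    # 3. synchronize: snap to grid, deduplicate, re-grid
    snapped = df.index.round(series.cadence)
    df.index = snapped
    df = df[~df.index.duplicated(keep="first")]
    grid = pd.date_range(df.index[0], df.index[-1], freq=series.cadence)
    df = df.reindex(grid)

    for ch in CONTINUOUS_CHANNELS + ("P", "E"):
        col = df[ch]
        _check_edge_gaps(col, ch, max_edge_gap)
        col = interpolate_missing(col)
        df[ch] = col.ffill().bfill()
    for ch in BINARY_CHANNELS:
        df[ch] = df[ch].ffill().bfill().fillna(0.0)

    out = SensorSeries(df, series.cadence, provenance="preprocessed")
    out.validate()
    return out


def _check_edge_gaps(col: pd.Series, name: str, max_edge_gap: int) -> None:
    vals = col.to_numpy()
    present = ~np.isnan(vals)
    if not present.any():
        raise UnrecoverableGapError(f"channel {name} entirely missing")
    lead = int(np.argmax(present))
    trail = int(np.argmax(present[::-1]))
    if lead > max_edge_gap or trail > max_edge_gap:
        raise UnrecoverableGapError(
            f"channel {name}: edge missing run ({max(lead, trail)} samples) "
            f"exceeds limit {max_edge_gap}"
        )


def resample_to_5min(series: SensorSeries) -> SensorSeries:
    """Consolidate a preprocessed 1-min series into 5-min modelling bins.

    Continuous channels and power take the bin mean; binary channels take the
    bin maximum (any activity within the bin counts as on); cumulative energy
    takes the bin's last value.  Bins with every member missing stay missing
    and are logged.
    """
    if len(series) == 0:
        raise EmptySeriesError("empty series")
    if series.cadence != pd.Timedelta(minutes=1):
        raise ValueError("resample_to_5min expects 1-min cadence input")

    agg = {ch: "mean" for ch in CONTINUOUS_CHANNELS}
    agg.update({ch: "max" for ch in BINARY_CHANNELS})
    agg["P"] = "mean"
    agg["E"] = "last"
    df = series.frame.resample("5min").agg(agg)
    empty = df[list(CHANNELS)].isna().all(axis=1)
    if empty.any():
        logger.warning("%d five-minute bins have no members; flagged missing",
                       int(empty.sum()))
    out = SensorSeries(df, pd.Timedelta(minutes=5), provenance="aggregated")
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Normalization


@dataclass
class NormalizationSpec:
    """Per-feature min-max extrema fitted over a stated window.

    Degenerate features (min == max) map to 0 by convention; values outside
    the fitted range at apply time are clipped to [0, 1] and logged.
    """

    minima: dict[str, float] = field(default_factory=dict)
    maxima: dict[str, float] = field(default_factory=dict)

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.minima)

    @classmethod
    def fit(cls, frame: pd.DataFrame, features: Sequence[str]) -> "NormalizationSpec":
        spec = cls()
        for f in features:
            col = frame[f].dropna()
            lo = float(col.min()) if len(col) else 0.0
            hi = float(col.max()) if len(col) else 0.0
            if hi < lo:
                raise ValueError(f"feature {f}: max < min")
            spec.minima[f] = lo
            spec.maxima[f] = hi
        return spec

    def apply(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for f in self.features:
            lo, hi = self.minima[f], self.maxima[f]
            if hi == lo:
                out[f] = np.where(frame[f].isna(), np.nan, 0.0)
                continue
            z = (frame[f] - lo) / (hi - lo)
            n_out = int(((z < 0) | (z > 1)).sum())
            if n_out:
                logger.warning(
                    "feature %s: %d values outside fitted range; clipped", f, n_out
                )
            out[f] = z.clip(0.0, 1.0)
        return out

    def invert(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for f in self.features:
            lo, hi = self.minima[f], self.maxima[f]
            out[f] = frame[f] * (hi - lo) + lo
        return out

    def invert_value(self, feature: str, value: float) -> float:
        lo, hi = self.minima[feature], self.maxima[feature]
        return value * (hi - lo) + lo


def fit_apply_normalization(
    series: SensorSeries,
    spec: NormalizationSpec | None = None,
    features: Sequence[str] = CONTINUOUS_CHANNELS + ("P", "E"),
) -> tuple[SensorSeries, NormalizationSpec]:
    """Min-max normalize the continuous features of a series.

    If ``spec`` is given its feature set must match ``features`` and it is
    applied as-is (out-of-range values clipped); otherwise extrema are fitted
    on this series.  Returns the normalized series and the spec.
    """
    if spec is not None and set(spec.features) != set(features):
        raise ValueError("spec feature set does not match requested features")
    if spec is None:
        spec = NormalizationSpec.fit(series.frame, features)
    out = SensorSeries(spec.apply(series.frame), series.cadence, series.provenance)
    return out, spec


def invert_normalization(series: SensorSeries, spec: NormalizationSpec) -> SensorSeries:
    return SensorSeries(spec.invert(series.frame), series.cadence, series.provenance)


# ---------------------------------------------------------------------------
# Energy integration


def integrate_energy(segments: Iterable[tuple[float, float]]) -> float:
    """Integrate piecewise-constant power over time: E [Wh] = sum P [W] * t [h].

    Additive over concatenation of segments.  Negative power is a validation
    error; zero-duration segments contribute nothing.
    """
    total = 0.0
    for power, duration in segments:
        if power < 0:
            raise ValueError(f"negative power: {power}")
        if duration < 0:
            raise ValueError(f"negative duration: {duration}")
        total += power * duration
    return total
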