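"""Seeded synthetic pond deployments: ground truth, observation, schedules.

The generator emulates a 45-day pilot deployment of a ~200 L ornamental
(koi) pond: diurnal temperature, daylight photosynthesis that lifts
dissolved oxygen in the afternoon, feeding-driven ammonia pulses, low-power
actuators with fixed power ratings, ~0.7% record loss, sensor noise and
slow ammonia sensor drift, and an alternating manual/smart operating plan.

Ground truth is integrated at 1-min resolution.  In ``twin_consistent``
mode the truth follows the twin equations exactly (for parameter-recovery
tests); ``realistic`` mode adds a half-sinusoid photosynthetic DO source
over the daylight window and temperature-driven DO saturation, neither of
which the twin knows about, so model-plant mismatch is representable.

Everything is a pure function of (config, seed): one master seed spawns
independent per-subsystem streams, so changing e.g. the dropout rate never
reshuffles the sensor noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .series import CHANNELS, CONTINUOUS_CHANNELS, SensorSeries
from .twin import TwinParameters, do_saturation

MINUTES_PER_DAY = 1440
DT_MIN = 1.0 / 60.0  # one minute, in hours


def _default_truth() -> TwinParameters:
    # ground-truth rates for a lightly stocked ~200 L pond: night-time DO
    # sags below the 5 mg/L threshold without aeration, daytime
    # photosynthesis (realistic mode) covers respiration
    return TwinParameters(
        kLa=0.25, kLa_ambient=0.03, DOsat=None, Rresp=0.22,
        nit_mode="first_order", k_nit=0.06, gamma_O2=4.57,
        feed_rate=0.25, feed_background=0.004,
        dil_mode="first_order", k_dil=0.03,
        dt=DT_MIN,
    )


def _default_noise() -> dict[str, float]:
    return {"DO": 0.10, "NH3": 0.02, "Temp": 0.10, "pH": 0.05, "Turb": 1.0}


def _default_power() -> dict[str, float]:
    # actuator and infrastructure power ratings, W
    return {"aerator": 5.0, "pump": 8.0, "feeder": 15.0,
            "edge": 1.5, "sensors": 0.6, "compute": 1.0}


@dataclass
class ScenarioConfig:
    """Full description of one synthetic deployment."""

    duration_days: int = 45
    seed: int = 0
    volume_l: float = 200.0

    # diurnal temperature forcing (deg C)
    temp_mean: float = 28.0
    temp_amplitude: float = 1.5
    temp_peak_hour: float = 15.0

    # photosynthetic DO source (realistic mode only)
    photo_amplitude: float = 0.55       # peak source, mg/L/h
    daylight: tuple[float, float] = (6.0, 18.0)  # clock hours

    # feeding schedule
    feed_times: tuple[float, ...] = (8.0, 12.0, 17.0)  # clock hours
    feed_pulse_minutes: int = 30

    truth: TwinParameters = field(default_factory=_default_truth)

    # observation model
    noise_sd: dict[str, float] = field(default_factory=_default_noise)
    nh3_sensor_drift_per_day: float = 0.0
    dropout_prob: float = 0.007

    # fault injection: (hours from start, latency seconds)
    latency_faults: tuple[tuple[float, float], ...] = ()

    power_w: dict[str, float] = field(default_factory=_default_power)
    pump_always_on: bool = True
    compute_seconds_per_decision: float = 30.0  # smart-mode model+twin runtime

    # operating plan
    block_days: int = 1                 # alternating manual/smart block length
    manual_duty: float = 0.472          # manual aeration duty fraction
    manual_blocks: int = 4              # fixed daily on-blocks

    # exogenous channels (no dynamics of their own)
    ph_mean: float = 7.5
    turb_mean: float = 12.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be a probability")
        if not 0.0 <= self.manual_duty <= 1.0:
            raise ValueError("manual_duty must be in [0, 1]")
        if any(p < 0 for p in self.power_w.values()):
            raise ValueError("power ratings must be >= 0")
        if self.duration_days % self.block_days != 0:
            raise ValueError("mode blocks must tile the duration exactly")
        if not 0 <= self.daylight[0] < self.daylight[1] <= 24:
            raise ValueError("daylight window must be within one day")

    @property
    def n_minutes(self) -> int:
        return self.duration_days * MINUTES_PER_DAY

    # -- YAML round-trip --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["truth"] = self.truth.to_dict()
        d["feed_times"] = list(self.feed_times)
        d["daylight"] = list(self.daylight)
        d["latency_faults"] = [list(x) for x in self.latency_faults]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["truth"] = TwinParameters.from_dict(d["truth"])
        d["feed_times"] = tuple(d["feed_times"])
        d["daylight"] = tuple(d["daylight"])
        d["latency_faults"] = tuple(tuple(x) for x in d.get("latency_faults", ()))
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def streams(config: ScenarioConfig) -> dict[str, np.random.Generator]:
    """Named, independent random streams derived from the master seed."""
    root = np.random.SeedSequence(config.seed)
    names = ("sensor_noise", "dropout", "online_noise", "spare")
    return {n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))}


def mode_plan(config: ScenarioConfig) -> list[str]:
    """Alternating manual/smart labels, one per day, starting with manual."""
    labels = []
    for block in range(config.duration_days // config.block_days):
        labels += ["manual" if block % 2 == 0 else "smart"] * config.block_days
    return labels


# ---------------------------------------------------------------------------
# Schedules


def manual_mode_schedule(
    config: ScenarioConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed manual-mode actuation at 1-min cadence.

    The aerator runs ``manual_blocks`` evenly spaced daily blocks whose total
    length is the target duty fraction rounded to the nearest minute (the
    remainder minutes go to the earliest blocks).  Feeding happens at fixed
    clock times, each event holding the feeder on for the pulse duration.
    Returns (aerator, feeder) 0/1 arrays of length ``n_minutes``.
    """
    duty = config.manual_duty
    if not 0.0 <= duty <= 1.0:
        raise ValueError("target duty fraction must be in [0, 1]")
    on_total = round(duty * MINUTES_PER_DAY)
    blocks = config.manual_blocks
    spacing = MINUTES_PER_DAY // blocks
    base, rem = divmod(on_total, blocks)
    lengths = [base + (1 if i < rem else 0) for i in range(blocks)]
    if max(lengths) > spacing:
        raise ValueError(
            f"duty {duty} infeasible with {blocks} blocks of spacing {spacing} min"
        )
    day_aer = np.zeros(MINUTES_PER_DAY, dtype=np.int8)
    for i, length in enumerate(lengths):
        start = i * spacing
        day_aer[start:start + length] = 1

    day_feed = np.zeros(MINUTES_PER_DAY, dtype=np.int8)
    for clock_h in config.feed_times:
        start = int(round(clock_h * 60))
        day_feed[start:start + config.feed_pulse_minutes] = 1

    aer = np.tile(day_aer, config.duration_days)
    feed = np.tile(day_feed, config.duration_days)
    return aer, feed


def feeding_event_count(feed: np.ndarray) -> int:
    """Number of feeding events (rising edges) in a feeder trace."""
    f = np.asarray(feed, dtype=np.int8)
    return int(((np.diff(f, prepend=0)) == 1).sum())


# ---------------------------------------------------------------------------
# Ground truth


class TruthSimulator:
    """Step-wise ground-truth pond dynamics at 1-min resolution.

    Uses exactly the twin's forward-Euler recurrence; ``realistic`` mode
    adds the photosynthesis source to the DO balance and evaluates DO
    saturation from the diurnal temperature.  The controller drives this
    object step by step in closed loop.
    """

    def __init__(self, config: ScenarioConfig, mode: str = "realistic") -> None:
        if mode not in ("twin_consistent", "realistic"):
            raise ValueError(f"unknown mode {mode!r}")
        self.config = config
        self.mode = mode
        n = config.n_minutes
        minutes = np.arange(n)
        clock_h = (minutes % MINUTES_PER_DAY) / 60.0
        self.temp = config.temp_mean + config.temp_amplitude * np.cos(
            2 * np.pi * (clock_h - config.temp_peak_hour) / 24.0
        )
        p = config.truth
        if mode == "twin_consistent":
            const = p.DOsat if p.DOsat is not None else do_saturation(config.temp_mean)
            self.dosat = np.full(n, float(const))
            self.photo = np.zeros(n)
            self.temp = np.full(n, config.temp_mean)
        else:
            self.dosat = (
                np.full(n, p.DOsat) if p.DOsat is not None else do_saturation(self.temp)
            )
            dawn, dusk = config.daylight
            frac = (clock_h - dawn) / (dusk - dawn)
            self.photo = np.where(
                (frac > 0) & (frac < 1),
                config.photo_amplitude * np.sin(np.pi * np.clip(frac, 0, 1)),
                0.0,
            )

    def step(self, do: float, nh3: float, minute: int,
             aerator_on: int, feeding_on: int) -> tuple[float, float]:
        """One 1-min forward-Euler step of the true dynamics."""
        p = self.config.truth
        dt = DT_MIN
        kla = p.kLa if aerator_on else p.ambient_kla
        r_nit = p.k_nit * nh3 if p.nit_mode == "first_order" else p.Rnit
        r_dil = p.k_dil * nh3 if p.dil_mode == "first_order" else p.Rdil
        i_feed = p.feed_rate * (1.0 if feeding_on else 0.0) + p.feed_background
        do_next = do + dt * (
            kla * (self.dosat[minute] - do) - p.Rresp - p.gamma_O2 * r_nit
            + self.photo[minute]
        )
        nh3_next = nh3 + dt * (i_feed - r_nit - r_dil)
        return max(do_next, 0.0), max(nh3_next, 0.0)

    def initial_state(self) -> tuple[float, float]:
        return float(self.dosat[0] * 0.80), 0.15


@dataclass
class GroundTruthTrace:
    """Noise-free 1-min trace plus fault markers; deterministic per config."""

    series: SensorSeries
    latency_s: np.ndarray
    config: ScenarioConfig
    mode: str


def power_trace(
    config: ScenarioConfig,
    aer: np.ndarray,
    feed: np.ndarray,
    compute_active: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-minute instantaneous power (W) and its per-module decomposition."""
    n = len(aer)
    pw = config.power_w
    per_module = {
        "aerator": pw["aerator"] * aer.astype(float),
        "pump": np.full(n, pw["pump"] if config.pump_always_on else 0.0),
        "feeder": pw["feeder"] * feed.astype(float),
        "edge": np.full(n, pw["edge"]),
        "sensors": np.full(n, pw["sensors"]),
        "compute": pw["compute"] * (
            compute_active.astype(float) if compute_active is not None else np.zeros(n)
        ),
    }
    total = np.sum(list(per_module.values()), axis=0)
    return total, per_module


def latency_trace(config: ScenarioConfig) -> np.ndarray:
    """Per-minute communication latency (s); 0 except at injected faults."""
    lat = np.zeros(config.n_minutes)
    for hours, seconds in config.latency_faults:
        idx = int(round(hours * 60))
        if 0 <= idx < len(lat):
            lat[idx] = seconds
    return lat


def _build_series(
    config: ScenarioConfig,
    do: np.ndarray, nh3: np.ndarray, temp: np.ndarray,
    aer: np.ndarray, feed: np.ndarray,
    power: np.ndarray,
    start: str = "2026-01-01",
) -> SensorSeries:
    n = config.n_minutes
    clock_h = (np.arange(n) % MINUTES_PER_DAY) / 60.0
    ph = config.ph_mean + 0.05 * np.sin(2 * np.pi * (clock_h - 14.0) / 24.0)
    turb = config.turb_mean + 1.5 * np.sin(2 * np.pi * (clock_h - 12.0) / 24.0)
    # elementwise P*dt then cumulative sum: bit-identical to the sequential
    # running total in series.integrate_energy
    energy = np.cumsum(power * DT_MIN)
    idx = pd.date_range(start, periods=n, freq="1min", tz="UTC")
    frame = pd.DataFrame(
        {
            "DO": do, "NH3": nh3, "Temp": temp, "pH": ph, "Turb": turb,
            "Aaer": aer.astype(float), "Afeed": feed.astype(float),
            "P": power, "E": energy,
        },
        index=idx,
    )
    return SensorSeries(frame, pd.Timedelta(minutes=1), provenance="simulated")


def generate(
    config: ScenarioConfig,
    mode: str = "realistic",
    actuators: tuple[np.ndarray, np.ndarray] | None = None,
) -> GroundTruthTrace:
    """Integrate the ground-truth dynamics open-loop over the full duration.

    ``actuators`` defaults to the manual-mode schedule.  Same (config, seed)
    gives a bit-identical trace.
    """
    sim = TruthSimulator(config, mode)
    aer, feed = actuators if actuators is not None else manual_mode_schedule(config)
    n = config.n_minutes
    do = np.empty(n)
    nh3 = np.empty(n)
    d, a = sim.initial_state()
    for k in range(n):
        do[k], nh3[k] = d, a
        d, a = sim.step(d, a, k, int(aer[k]), int(feed[k]))
    power, _ = power_trace(config, aer, feed)
    series = _build_series(config, do, nh3, sim.temp, aer, feed, power)
    return GroundTruthTrace(series, latency_trace(config), config, mode)


def observe(trace: GroundTruthTrace, config: ScenarioConfig | None = None) -> SensorSeries:
    """Apply the observation model to a ground-truth trace.

    Adds per-channel Gaussian sensor noise, a linear NH3 sensor drift, and
    record-level dropout (the whole record goes missing) at the configured
    probability.  Deterministic per seed; with all noise/dropout parameters
    zero the observation equals the truth.
    """
    config = config if config is not None else trace.config
    rngs = streams(config)
    frame = trace.series.frame.copy()
    n = len(frame)

    noise_rng = rngs["sensor_noise"]
    for ch in CONTINUOUS_CHANNELS:
        sd = config.noise_sd.get(ch, 0.0)
        if sd > 0:
            frame[ch] = frame[ch].to_numpy() + noise_rng.normal(0.0, sd, n)
    if config.nh3_sensor_drift_per_day != 0.0:
        days = np.arange(n) / MINUTES_PER_DAY
        frame["NH3"] = frame["NH3"].to_numpy() + config.nh3_sensor_drift_per_day * days

    for ch in ("DO", "NH3", "Turb"):
        frame[ch] = np.clip(frame[ch].to_numpy(), 0.0, None)
    frame["pH"] = np.clip(frame["pH"].to_numpy(), 0.0, 14.0)

    if config.dropout_prob > 0:
        lost = rngs["dropout"].random(n) < config.dropout_prob
        frame.loc[lost, list(CHANNELS)] = np.nan

    return SensorSeries(frame, pd.Timedelta(minutes=1), provenance="raw")
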