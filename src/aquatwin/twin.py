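"""Physics-informed pond digital twin: DO/NH3 dynamics and calibration.

The twin tracks two states, dissolved oxygen and total ammonia (both mg/L),
under a pair of first-order mass balances:

    dDO/dt  = kLa_eff * (DOsat - DO) - R_resp - gamma_O2 * r_nit
    dNH3/dt = I_feed - r_nit - r_dil

discretized with an explicit forward-Euler step (default dt = 5 min).
``kLa_eff`` switches between the aerated transfer coefficient ``kLa`` and a
smaller ambient surface-exchange constant when the aerator is off; the
nitrification flux ``r_nit`` is first-order in NH3 by default (``k_nit *
NH3``), with a constant-rate mode; the oxygen cost of nitrifying one unit of
ammonia is ``gamma_O2`` (default 4.57 g O2 / g NH3-N, standard nitrification
stoichiometry).  Photosynthesis is deliberately absent from the twin — it
exists only in the scenario generator's ground truth, so model-plant mismatch
is representable.

Calibration fits selected rate constants to an observed baseline window by
least squares on the simulated-vs-observed DO and NH3 trajectories, each
channel scaled by its observed standard deviation (DO ~ 6 mg/L and NH3 ~ 0.2
mg/L differ by ~30x).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

_RATE_FIELDS = (
    "kLa", "kLa_ambient", "Rresp", "k_nit", "Rnit", "feed_rate",
    "feed_background", "k_dil", "Rdil",
)

_UNITS = {
    "kLa": "1/h", "kLa_ambient": "1/h", "DOsat": "mg/L",
    "Rresp": "mg/L/h", "k_nit": "1/h", "Rnit": "mg/L/h",
    "gamma_O2": "g O2 per g NH3", "feed_rate": "mg/L/h",
    "feed_background": "mg/L/h", "k_dil": "1/h", "Rdil": "mg/L/h",
    "dt": "h",
}


class NumericError(ArithmeticError):
    """Non-finite state encountered while stepping the twin."""


class InsufficientDataError(ValueError):
    """Calibration window shorter than the configured minimum."""


def do_saturation(temp_c: float | np.ndarray) -> float | np.ndarray:
    """Freshwater DO saturation (mg/L) vs temperature (deg C).

    Standard empirical cubic fit for air-saturated fresh water at sea level;
    about 9.1 mg/L at 20 C, 7.7 mg/L at 28 C.
    """
    t = np.asarray(temp_c, dtype=float)
    sat = 14.652 - 0.41022 * t + 7.9910e-3 * t**2 - 7.7774e-5 * t**3
    return float(sat) if np.isscalar(temp_c) else sat


@dataclass
class TwinParameters:
    """Rate constants and step size of the pond twin.

    ``DOsat`` may be a constant (mg/L) or ``None``, in which case the
    saturation concentration is evaluated from water temperature via
    :func:`do_saturation` at every step.  ``nit_mode``/``dil_mode`` select
    first-order (``k_nit * NH3`` / ``k_dil * NH3``) or constant-rate sink
    forms.  Setting ``nit_mode="constant"`` with ``gamma_O2=1`` reproduces
    the literal two-independent-constants reading of the balance equations.
    """

    kLa: float = 0.15                  # aerated O2 transfer, 1/h
    kLa_ambient: float | None = None   # off-state surface exchange; default kLa/10
    DOsat: float | None = 8.0          # mg/L, or None -> temperature curve
    Rresp: float = 0.20                # respiration demand, mg/L/h
    nit_mode: str = "first_order"      # {"first_order", "constant"}
    k_nit: float = 0.05                # 1/h
    Rnit: float = 0.01                 # mg/L/h (constant mode)
    gamma_O2: float = 4.57             # O2 demand per unit NH3 nitrified
    feed_rate: float = 0.20            # ammonia input while feeding, mg/L/h
    feed_background: float = 0.0       # continuous excretion, mg/L/h
    dil_mode: str = "first_order"      # {"first_order", "constant"}
    k_dil: float = 0.02                # 1/h
    Rdil: float = 0.004                # mg/L/h (constant mode)
    dt: float = 1.0 / 12.0             # step size, h (5 min)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.DOsat is not None and self.DOsat <= 0:
            raise ValueError("DOsat must be > 0")
        if self.nit_mode not in ("first_order", "constant"):
            raise ValueError(f"unknown nit_mode {self.nit_mode!r}")
        if self.dil_mode not in ("first_order", "constant"):
            raise ValueError(f"unknown dil_mode {self.dil_mode!r}")

    @property
    def ambient_kla(self) -> float:
        return self.kLa / 10.0 if self.kLa_ambient is None else self.kLa_ambient

    def dosat_at(self, temp_c: float | None) -> float:
        if self.DOsat is not None:
            return self.DOsat
        if temp_c is None:
            raise ValueError("DOsat is temperature-dependent; temp_c required")
        return do_saturation(temp_c)

    # -- config file round-trip ------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for name in (*_RATE_FIELDS, "DOsat", "gamma_O2", "dt"):
            v = getattr(self, name)
            if v is not None:
                out[name] = {"value": float(v), "units": _UNITS[name]}
            else:
                out[name] = {"value": None, "units": _UNITS[name]}
        out["nit_mode"] = self.nit_mode
        out["dil_mode"] = self.dil_mode
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "TwinParameters":
        kwargs = {}
        for k, v in d.items():
            kwargs[k] = v["value"] if isinstance(v, dict) else v
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TwinParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class TwinState:
    """Twin state: DO and NH3 (mg/L) at ``time`` hours since simulation start."""

    DO: float
    NH3: float
    time: float = 0.0


def step(
    state: TwinState,
    params: TwinParameters,
    aerator_on: int | bool,
    feeding_on: int | bool,
    temp_c: float | None = None,
) -> TwinState:
    """One forward-Euler step of the twin dynamics.

    Euler undershoot below zero is clamped to 0 (concentrations are
    physical) and logged at debug level.
    """
    if not (math.isfinite(state.DO) and math.isfinite(state.NH3)):
        raise NumericError(f"non-finite state at t={state.time} h")
    dosat = params.dosat_at(temp_c)
    kla = params.kLa if aerator_on else params.ambient_kla
    r_nit = params.k_nit * state.NH3 if params.nit_mode == "first_order" else params.Rnit
    r_dil = params.k_dil * state.NH3 if params.dil_mode == "first_order" else params.Rdil
    i_feed = params.feed_rate * (1.0 if feeding_on else 0.0) + params.feed_background

    do_next = state.DO + params.dt * (
        kla * (dosat - state.DO) - params.Rresp - params.gamma_O2 * r_nit
    )
    nh3_next = state.NH3 + params.dt * (i_feed - r_nit - r_dil)
    if do_next < 0.0:
        logger.debug("DO undershoot clamped at t=%.4f h", state.time)
        do_next = 0.0
    if nh3_next < 0.0:
        logger.debug("NH3 undershoot clamped at t=%.4f h", state.time)
        nh3_next = 0.0
    if not (math.isfinite(do_next) and math.isfinite(nh3_next)):
        raise NumericError(f"non-finite update at t={state.time} h")
    return TwinState(DO=do_next, NH3=nh3_next, time=state.time + params.dt)


def simulate(
    initial: TwinState,
    params: TwinParameters,
    actuator_trace: Sequence[tuple[int, int]],
    n_steps: int,
    temps: Sequence[float] | None = None,
) -> list[TwinState]:
    """Iterate :func:`step` ``n_steps`` times; returns n_steps + 1 states."""
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    if len(actuator_trace) < n_steps:
        raise ValueError("actuator trace shorter than n_steps")
    if temps is not None and len(temps) < n_steps:
        raise ValueError("temperature trace shorter than n_steps")
    states = [initial]
    s = initial
    for k in range(n_steps):
        aer, feed = actuator_trace[k]
        t = temps[k] if temps is not None else None
        try:
            s = step(s, params, aer, feed, temp_c=t)
        except NumericError as err:
            raise NumericError(f"{err} (step index {k})") from None
        states.append(s)
    return states


def simulate_arrays(
    do0: float,
    nh30: float,
    params: TwinParameters,
    aer: np.ndarray,
    feed: np.ndarray,
    dosat: np.ndarray | float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vector-output fast path: same recurrence as :func:`step`, tight loop.

    ``dosat`` may be a scalar or a per-step array (precomputed from
    temperature); defaults to the constant in ``params``.  Returns arrays of
    length ``len(aer) + 1`` including the initial state.
    """
    n = len(aer)
    if dosat is None:
        dosat = params.dosat_at(None)
    dosat_arr = np.broadcast_to(np.asarray(dosat, dtype=float), (n,))
    kla_on, kla_off = params.kLa, params.ambient_kla
    first_nit = params.nit_mode == "first_order"
    first_dil = params.dil_mode == "first_order"
    k_nit, rnit_c = params.k_nit, params.Rnit
    k_dil, rdil_c = params.k_dil, params.Rdil
    gamma, rresp = params.gamma_O2, params.Rresp
    frate, fbg, dt = params.feed_rate, params.feed_background, params.dt

    do = np.empty(n + 1)
    nh3 = np.empty(n + 1)
    do[0], nh3[0] = do0, nh30
    d, a = float(do0), float(nh30)
    for k in range(n):
        kla = kla_on if aer[k] else kla_off
        r_nit = k_nit * a if first_nit else rnit_c
        r_dil = k_dil * a if first_dil else rdil_c
        i_feed = frate * feed[k] + fbg
        d = d + dt * (kla * (dosat_arr[k] - d) - rresp - gamma * r_nit)
        a = a + dt * (i_feed - r_nit - r_dil)
        if d < 0.0:
            d = 0.0
        if a < 0.0:
            a = 0.0
        do[k + 1], nh3[k + 1] = d, a
    return do, nh3


def one_step_predictions(
    obs_do: np.ndarray,
    obs_nh3: np.ndarray,
    params: TwinParameters,
    aer: np.ndarray,
    feed: np.ndarray,
    dosat: np.ndarray | float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synchronized (teacher-forced) one-step predictions.

    From every observed state, one Euler step forward; this is how a twin
    that is continuously re-synchronized with the sensor stream tracks the
    pond.  Returns predictions aligned with observations[1:].
    """
    obs_do = np.asarray(obs_do, dtype=float)
    obs_nh3 = np.asarray(obs_nh3, dtype=float)
    n = len(obs_do) - 1
    aer = np.asarray(aer, dtype=float)[:n]
    feed = np.asarray(feed, dtype=float)[:n]
    if dosat is None:
        dosat = params.dosat_at(None)
    dosat = np.broadcast_to(np.asarray(dosat, dtype=float), (n,))
    d, a = obs_do[:-1], obs_nh3[:-1]
    kla = np.where(aer > 0, params.kLa, params.ambient_kla)
    r_nit = params.k_nit * a if params.nit_mode == "first_order" else params.Rnit
    r_dil = params.k_dil * a if params.dil_mode == "first_order" else params.Rdil
    i_feed = params.feed_rate * feed + params.feed_background
    do_pred = d + params.dt * (kla * (dosat - d) - params.Rresp
                               - params.gamma_O2 * r_nit)
    nh3_pred = a + params.dt * (i_feed - r_nit - r_dil)
    return np.maximum(do_pred, 0.0), np.maximum(nh3_pred, 0.0)


def goodness_of_fit(simulated: Sequence[float], observed: Sequence[float]) -> float:
    """Coefficient of determination R^2 = 1 - SS_res / SS_tot."""
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape or sim.ndim != 1:
        raise ValueError("sequences must be 1-D and equal length")
    if len(obs) < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if np.ptp(obs) == 0.0 or ss_tot == 0.0:
        raise ValueError("R^2 undefined for constant observed sequence")
    ss_res = float(np.sum((obs - sim) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# Calibration


@dataclass
class CalibrationResult:
    """Fitted parameters plus optimizer and identifiability diagnostics."""

    params: TwinParameters
    free_params: tuple[str, ...]
    cost: float
    success: bool
    identifiable: bool
    message: str
    residuals_do: np.ndarray
    residuals_nh3: np.ndarray
    r2_do: float | None = None
    r2_nh3: float | None = None

    def residual_report(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"residual_do": self.residuals_do, "residual_nh3": self.residuals_nh3}
        ).to_csv(path, index_label="step")


def calibrate(
    observed,
    actuator_trace: np.ndarray | Sequence[tuple[int, int]],
    free_params: Sequence[str],
    bounds: dict[str, tuple[float, float]] | None = None,
    base: TwinParameters | None = None,
    *,
    scale_residuals: bool = True,
    min_window_steps: int = 24,
    dosat: np.ndarray | float | None = None,
    residual_mode: str = "trajectory",
) -> CalibrationResult:
    """Least-squares fit of selected twin rate constants to an observed window.

    ``observed`` is a 5-min :class:`~aquatwin.series.SensorSeries` (or a
    DataFrame with DO/NH3 columns).  Residuals are the per-step differences
    between the simulated and observed DO and NH3 trajectories, each channel
    divided by its observed standard deviation when ``scale_residuals`` (an
    unscaled mode is available).  The simulation starts from the first
    observed state and uses the recorded actuator trace.

    ``residual_mode`` selects how the simulation tracks the window:
    ``"trajectory"`` (default) simulates the whole window open-loop from the
    first observed state; ``"one_step"`` re-synchronizes with the
    observations at every step (the regime of a twin that runs alongside a
    live sensor stream), which is robust to unmodelled slow forcings.

    Non-identifiability (e.g. kLa and Rresp both free against a constant
    equilibrium trace) is detected from the rank of the residual Jacobian at
    the solution and flagged rather than raised.
    """
    if residual_mode not in ("trajectory", "one_step"):
        raise ValueError(f"unknown residual_mode {residual_mode!r}")
    frame = observed.frame if hasattr(observed, "frame") else observed
    obs_do = frame["DO"].to_numpy(dtype=float)
    obs_nh3 = frame["NH3"].to_numpy(dtype=float)
    n_steps = len(obs_do) - 1
    if n_steps < min_window_steps:
        raise InsufficientDataError(
            f"calibration window has {n_steps} steps; minimum {min_window_steps}"
        )
    trace = np.asarray(actuator_trace, dtype=float)
    if trace.shape[0] < n_steps:
        raise ValueError("actuator trace shorter than observation window")
    aer, feed = trace[:n_steps, 0], trace[:n_steps, 1]

    base = base if base is not None else TwinParameters()
    free_params = tuple(free_params)
    for name in free_params:
        if name not in _RATE_FIELDS:
            raise ValueError(f"{name} is not a calibratable rate parameter")
    bounds = bounds or {}
    lo = np.array([bounds.get(p, (0.0, np.inf))[0] for p in free_params])
    hi = np.array([bounds.get(p, (0.0, np.inf))[1] for p in free_params])
    x0 = np.array(
        [np.clip(getattr(base, p) or 0.0, lo[i], hi[i]) for i, p in enumerate(free_params)]
    )

    def _channel_sd(obs: np.ndarray) -> float:
        sd = float(np.std(obs))
        # an (all but) constant channel carries no scale information
        floor = 1e-9 * max(1.0, float(np.abs(obs).max()))
        return sd if (scale_residuals and sd > floor) else 1.0

    sd_do = _channel_sd(obs_do)
    sd_nh3 = _channel_sd(obs_nh3)

    def predict(p: TwinParameters) -> tuple[np.ndarray, np.ndarray]:
        if residual_mode == "trajectory":
            sim_do, sim_nh3 = simulate_arrays(
                obs_do[0], obs_nh3[0], p, aer, feed, dosat=dosat
            )
            return sim_do[1:], sim_nh3[1:]
        return one_step_predictions(obs_do, obs_nh3, p, aer, feed, dosat=dosat)

    def residuals(x: np.ndarray) -> np.ndarray:
        p = replace(base, **dict(zip(free_params, x)))
        sim_do, sim_nh3 = predict(p)
        return np.concatenate(
            [(sim_do - obs_do[1:]) / sd_do, (sim_nh3 - obs_nh3[1:]) / sd_nh3]
        )

    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-12,
                        ftol=1e-12, gtol=1e-12)
    fitted = replace(base, **dict(zip(free_params, sol.x)))
    sim_do, sim_nh3 = predict(fitted)

    # identifiability: condition of the parameter-scaled Jacobian (columns
    # times |x|, i.e. sensitivities to relative parameter changes).  A tiny
    # smallest/largest singular-value ratio means some free-parameter
    # combination leaves the fit unchanged (e.g. kLa and Rresp against a
    # constant equilibrium trace, which only pins kLa*(DOsat-DO) - Rresp).
    jac_scaled = sol.jac * np.maximum(np.abs(sol.x), 1e-12)
    sv = np.linalg.svd(jac_scaled, compute_uv=False)
    identifiable = bool(sv[0] > 0 and (sv[-1] / sv[0]) > 1e-3)
    if not identifiable:
        logger.warning(
            "calibration non-identifiable: free params %s are structurally "
            "confounded on this window", free_params,
        )
    if not sol.success:
        logger.warning("calibration did not converge: %s", sol.message)

    def _safe_r2(sim: np.ndarray, obs: np.ndarray) -> float | None:
        try:
            return goodness_of_fit(sim, obs)
        except ValueError:
            return None

    return CalibrationResult(
        params=fitted,
        free_params=free_params,
        cost=float(sol.cost),
        success=bool(sol.success),
        identifiable=identifiable,
        message=str(sol.message),
        residuals_do=sim_do - obs_do[1:],
        residuals_nh3=sim_nh3 - obs_nh3[1:],
        r2_do=_safe_r2(sim_do, obs_do[1:]),
        r2_nh3=_safe_r2(sim_nh3, obs_nh3[1:]),
    )


# ---------------------------------------------------------------------------
# Sensitivity analysis


@dataclass
class SensitivityResult:
    """One closed-loop run under a single +/-10% parameter perturbation."""

    parameter: str                 # "reference" for the unperturbed run
    fraction: float                # signed perturbation, e.g. +0.10
    duty_cycle_pct: float          # aerator duty over the run, %
    total_energy_wh: float
    delta_duty_pct: float = 0.0
    delta_energy_wh: float = 0.0


def sensitivity_analysis(
    scenario_config,
    params: TwinParameters,
    controller_config,
    perturb: Sequence[tuple[str, float]] | None = None,
    forecaster: str = "persistence",
) -> list[SensitivityResult]:
    """One-at-a-time +/-10% perturbation of DO_th, NH3_th and kLa.

    Each perturbation triggers one full smart-mode closed-loop run on an
    identical seeded scenario; the unperturbed reference run is reported
    first.  Returns one entry per run (reference + 6 by default).
    """
    from . import control  # deferred: control imports this module's types

    if perturb is None:
        perturb = [(p, f) for p in ("DO_th", "NH3_th", "kLa") for f in (-0.10, +0.10)]

    def run(p: TwinParameters, cfg) -> tuple[float, float]:
        res = control.run_closed_loop(
            scenario_config, mode="smart", forecaster=forecaster,
            twin_params=p, controller_config=cfg,
        )
        aer = res.series.frame["Aaer"].to_numpy()
        duty = 100.0 * float(aer.mean())
        energy = float(res.series.frame["E"].iloc[-1])
        return duty, energy

    ref_duty, ref_energy = run(params, controller_config)
    results = [SensitivityResult("reference", 0.0, ref_duty, ref_energy)]
    for name, frac in perturb:
        p, cfg = params, controller_config
        if name == "kLa":
            p = replace(params, kLa=params.kLa * (1 + frac))
        elif name == "DO_th":
            cfg = replace(
                controller_config,
                do_threshold=controller_config.do_threshold * (1 + frac),
            )
        elif name == "NH3_th":
            cfg = replace(
                controller_config,
                nh3_threshold=controller_config.nh3_threshold * (1 + frac),
            )
        else:
            raise ValueError(f"unknown perturbation target {name!r}")
        duty, energy = run(p, cfg)
        results.append(
            SensitivityResult(
                name, frac, duty, energy,
                delta_duty_pct=duty - ref_duty,
                delta_energy_wh=energy - ref_energy,
            )
        )
    return results
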