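# Methods

## Scope and architecture

`aquatwin` is a desk-scale implementation of a closed-loop, energy-aware
pond-management architecture: sensing → preprocessing → forecasting →
digital-twin validation → actuation → feedback. All hardware, networking and
dashboard concerns are out of scope; latency is an injected scenario
variable, not a measurement. The package is organised so that the control
loop is testable without any trained artifact or external data: the
deterministic baseline forecasters and the synthetic scenario generator are
first-class components, not fixtures.

## The pond twin

Two states, DO and NH₃ (mg/L), evolve under first-order mass balances
discretized with explicit forward Euler (default Δt = 1/12 h = 5 min):

    dDO/dt  = k_La,eff (DO_sat − DO) − R_resp − γ_O2 · r_nit
    dNH3/dt = I_feed − r_nit − r_dil

Assumptions: a well-mixed single compartment (no stratification), exogenous
temperature/pH/turbidity, no nitrite/nitrate pools, and no photosynthesis
term — the last deliberately, so that model–plant mismatch is representable
against a ground truth that does have photosynthetic forcing.

Parameter conventions and defaults:

| parameter | units | default | rationale |
|---|---|---|---|
| `kLa` (aerated) | 1/h | 0.15 (twin) / 0.25 (scenario truth) | plausible for a 5 W air pump in ~200 L |
| `kLa_ambient` | 1/h | `kLa`/10 | still surface exchange; aeration must matter or gatekeeping is vacuous |
| `DOsat` | mg/L | 8.0 constant, or `None` → empirical freshwater cubic in temperature | unit tests want a constant; realistic runs want the curve (~9.1 mg/L at 20 °C) |
| `Rresp` | mg/L/h | 0.20 | light stocking density |
| `k_nit` | 1/h | 0.05 | first-order nitrification in NH₃ |
| `gamma_O2` | g O₂/g NH₃ | 4.57 | standard nitrification stoichiometry |
| `feed_rate` | mg/L/h | 0.20 | ammonia input while feeding is active |
| `k_dil` | 1/h | 0.02 | water exchange/filtration |
| `dt` | h | 1/12 | modelling cadence |

The balance equations as printed in engineering practice sometimes carry a
single symbol for the nitrification term in both equations. We resolve this
as one nitrification *flux* `r_nit` (mg NH₃/L/h) whose oxygen demand is
`γ_O2 · r_nit`; setting `nit_mode="constant"` with `gamma_O2=1` reproduces
the literal two-independent-constants reading exactly. Both nitrification
and dilution have first-order (default) and constant-rate modes. A small
constant background excretion term (`feed_background`) is available and off
by default.

Numerical choices: Euler undershoot below zero is clamped to 0 and logged
(concentrations are physical); the update never overshoots `DOsat` from
below while Δt·kLa < 1; non-finite states raise with the step index. With
sinks off the discrete DO trajectory equals the closed form
`DOsat − (DOsat − DO₀)(1 − Δt·kLa)ⁿ` to machine precision, which the tests
assert.

## Calibration

`twin.calibrate` fits selected rate constants by bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective). Residuals are
simulated-minus-observed DO and NH₃, each channel divided by its observed
standard deviation (DO ≈ 6 and NH₃ ≈ 0.2 differ by ~30×; an unscaled mode
exists). A near-constant channel (sd below 1e-9 of its scale) contributes
unscaled residuals rather than exploding.

Two residual regimes:

* `trajectory` (default) — simulate the whole window open-loop from the
  first observed state. This is the right oracle for parameter recovery on
  twin-consistent data (noiseless recovery is exact to ≪0.1% relative; with
  σ = 0.1 mg/L Gaussian noise on a 3-day window, kLa is recovered within 5%
  in ≈99/100 seeded replicates).
* `one_step` — re-synchronize with the observations at every step, the
  regime of a twin running alongside a live sensor stream. On realistic
  scenarios (where ground truth contains photosynthesis the twin does not
  model) free-running 3-day simulation cannot track the diurnal DO swing,
  while the synchronized twin tracks both channels with R² well above 0.9;
  the acceptance report therefore quotes synchronized R².

Identifiability: the condition number of the parameter-scaled Jacobian at
the solution (columns × |x|) flags structurally confounded fits — e.g. kLa
and Rresp both free against a constant equilibrium trace, which only pins
the combination `kLa(DOsat − DO) − Rresp`. Ratio < 1e-3 of largest to
smallest singular value ⇒ flagged, not raised (measured separation in our
cases: ~3e-4 confounded vs ~6e-2 well-posed).

## Preprocessing pipeline

Raw 1-min streams pass through: moving-average filter (causal, default 5
samples; NaN-aware, missing positions preserved) → linear interpolation of
interior gaps → timestamp synchronization (snap to grid, re-grid, fill
re-gridding gaps). Filtering before interpolation (rather than the
reverse) is a deliberate, documented choice of this package — the two
orders give slightly different values around gaps, and nothing forces one
over the other. Binary actuator channels
are never averaged (carried forward); power is interpolated but not
smoothed (it is metered, not a noisy probe); energy is cumulative and
interpolates linearly. Leading/trailing gaps longer than a configurable
limit (default 15 samples) are unrecoverable and raise.

5-min consolidation: mean for continuous channels and power, any-on
(maximum) for binaries, last value for cumulative energy, all-missing bins
stay missing and are logged. Min–max normalization maps continuous features
to [0,1]; degenerate features (min = max) map to 0; out-of-range values at
apply time are clipped and logged rather than raised, because live streams
drift beyond training ranges.

## Synthetic deployments

The generator emulates a 45-day pilot deployment of a ~200 L koi pond at
1-min resolution: diurnal temperature (mean 28 °C, amplitude 1.5 °C, peak
15:00 — tropical ornamental-pond conditions), temperature-dependent DO
saturation, a half-sinusoid photosynthetic DO source over a 06:00–18:00
daylight window (peak 0.55 mg/L/h; some daylight forcing must exist for
afternoon aeration savings to be possible), three daily feeding events
(08:00/12:00/17:00) modelled as 30-min rectangular ammonia pulses with the
feeder drawing power for the pulse, record-level dropout at probability
0.007, per-channel Gaussian sensor noise (DO 0.10, NH₃ 0.02, Temp 0.10
mg/L or °C), optional linear NH₃ sensor drift, and actuator/infrastructure
power ratings of 5 W (aerator), 8 W (pump, always-on by default), 15 W
(feeder), 1.5 W (edge computer), 0.6 W (sensor network) and 1 W
(model+twin compute, active ~30 s per smart decision).

`twin_consistent` mode integrates exactly the twin equations (constant
DOsat, no photosynthesis) so that re-stepping the trace through the twin
reproduces it to < 1e-12 — the substrate for parameter-recovery and
closed-loop safety tests. `realistic` mode adds the forcings above.

Seeding: one master seed spawns independent named streams (sensor noise,
dropout, online controller noise), so changing the dropout rate never
reshuffles the weather. Every trace is a pure function of (config, seed).

What the generator does **not** emulate: weather fronts, sensor drift
nonlinearity, biofilter maturation, fish behaviour, or the real
deployment's unpublished raw data. Passing tests demonstrate correctness of
the machinery and the qualitative energy story, not field performance.

The manual operating mode aerates in 4 evenly spaced daily blocks totalling
the target duty fraction (default 0.472) rounded to the nearest minute
(0.472 × 1440 → 680 on-minutes/day), with remainder minutes assigned to the
earliest blocks.

## Forecasting

Windows are 24 five-minute steps × 8 features in fixed order (DO, NH₃,
Temp, pH, Turb, Aaer, Afeed, dE). The energy feature is per-interval Wh
(difference of cumulative E): normalized cumulative energy saturates toward
1 and carries no signal. Predictions are denormalized and clamped at 0.

Three interchangeable forecasters: persistence (last row), linear trend
(OLS line over the window, extrapolated one step), and a stacked-LSTM
reference model (2 × 64 units, dropout 0.2 on the final hidden state, dense
head; Adam at 1e-3, batch 32, up to 150 epochs, early stopping with
patience 10 — patience is a package default, exposed in config). The LSTM
is implemented in numpy with hand-written backpropagation through time,
verified against central finite differences in the test suite; a 20%
holdout is reserved (seeded) before any training. The control loop runs
with any forecaster and defaults to persistence — its correctness must not
depend on a trained artifact. Forecast errors are reported in physical
units (RMSE and MAE per channel); whether normalized or physical units are
the convention elsewhere is ambiguous, so the unit is always stated.

## Controller

Thresholds DO_th = 5 mg/L and NH3_th = 0.5 mg/L (standard aquaculture
water-quality limits). Candidate proposal: aerate iff predicted DO < DO_th;
delay feeding iff predicted NH₃ > NH3_th; both breaches yield the combined
action; otherwise no-op. Published pseudocode for this class of controller
is sometimes printed with the feeding inequality inverted (delay feeding
when predicted NH₃ is *below* the threshold), which contradicts the
behaviour such systems actually describe; this package implements the
exceed-threshold reading and records the alternative here rather than
hiding it.

Twin validation simulates each candidate over a 12-step (1 h) horizon —
long enough for aeration to act, short enough to stay relevant at 5-min
cadence — against a safety floor/ceiling that default to the thresholds
themselves (no separate safety band is defined anywhere authoritative). A
trajectory that starts in violation must recover within the horizon and
stay recovered. Among accepted candidates the one with the lowest projected
actuator energy executes (ties: fewest actuator switches); commands hold
for 5 min (zero-order hold). Feeding delay is delay-to-next-window only
(the event retries every 5 min); ration reduction is out of scope. If no
candidate is accepted, or measured latency exceeds 2 s (the upper edge of
the acceptable 1–2 s control-latency band), the rule-based fallback acts on
measured values. During the first 2 h, while the forecast window fills, the
fallback layer controls the actuators and is logged as such — every
executed command therefore has accepted-verdict or fallback provenance, and
the decision log is a pure function of (config, seed).

The pump is always-on by default (its duty in a real deployment is clearly
scheduled, but the schedule is not published; it is exposed as config).

## Energy analytics and statistics

Per-module energy is E = P_active · t_active with duty relative to the full
experiment span (1080 h for 45 days). Event deltas difference cumulative
energy at window edges. Time slices default to the four 6-h clock windows
(Morning 06–12, Afternoon 12–18, Evening 18–24, Night 00–06). Mode saving
is η = (E_base − E_smart)/E_base × 100, negative values allowed and
flagged. The mode comparison is an independent-samples t-test on daily
aggregates (daily totals, not raw 1-min samples, to dodge temporal
autocorrelation); the unequal-variance (Welch) form is the default because
per-mode variances genuinely differ, with the pooled form available.
Reports round percentages to 2 d.p. and Wh to 1 d.p.; machine-readable
output keeps full precision.

For mode comparisons the package runs manual and smart over the *same*
scenario horizon in parallel (identical weather), rather than alternating
blocks; the alternating day-block plan (default 1-day blocks, supporting
daily aggregation) is available via `scenario.mode_plan` for workflows that
want interleaved accounting. How a real alternating deployment split its
days between modes is not published, so the equal-split default is an
assumption and is flagged as such.

## Problem sizes

Unit and property tests run on 1–3-day scenarios; the closed-loop safety
and dominance checks use 2-day runs over 5 seeds; calibration recovery uses
3-day windows with 100 Monte-Carlo replicates; the acceptance script uses a
6-day scenario for the closed-loop study. These sizes were chosen so the
full suite runs in well under a minute on one core while every statistic
retains its qualitative behaviour; all of them scale up by changing
`duration_days`.

## Known limitations

* The twin is two-state and well-mixed; it cannot represent stratification,
  sediment oxygen demand, or nitrite accumulation.
* The sensitivity analysis perturbs the controller's model and thresholds
  one-at-a-time (±10%) on a fixed seeded scenario; it is a robustness probe,
  not a global sensitivity study.
* Energy dominance of smart mode is a property of scenarios with daylight
  photosynthesis and a generously scheduled manual mode; in a pond whose
  manual schedule is already near-optimal the saving shrinks accordingly.
* The numpy LSTM is sized for desk-scale experiments; it makes no claim to
  production training performance.
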