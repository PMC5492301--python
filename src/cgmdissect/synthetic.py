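"""Synthetic meal-test session generator.

Emulates the structure of an in-clinic CGM validation session: an 8-hour
mixed-meal blood-glucose excursion, sparse reference draws every 15 +/- 5
minutes, and n >= 2 parallel CGM traces built through the full error chain

    CGM_i(t) = a_i(t) * (h * BG)(t) + b_i(t) + cc(t) + ssc_i(t)

where h is the first-order blood-to-interstitium kernel with time constant
tau, a_i/b_i are polynomial gain and offset of the sensor calibration, and
cc/ssc_i are stationary AR noise processes on the CGM grid.  Ground truth
is attached to every generated session so each pipeline stage can be
validated by parameter recovery.

The default configuration is calibrated so that an ensemble of generated
profiles reproduces the glycemic-range occupancy (~97.8% of samples at or
above 70 mg/dL, about a third above 180 mg/dL) and rate-of-change profile
(~77% of 1-min rates within +/-1 mg/dL/min) reported for the study the
generator emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .noise import POPULATION_CC_AR, POPULATION_SSC_AR, ARModel, simulate_ar
from .series import GlucoseSeries, ReferenceSamples, SeriesError


class GenerationError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SensorTruth:
    """Generative calibration and noise parameters of one sensor."""

    gain_coeffs: np.ndarray = field(repr=False)
    offset_coeffs: np.ndarray = field(repr=False)
    ssc_ar: ARModel = POPULATION_SSC_AR

    def __post_init__(self) -> None:
        object.__setattr__(self, "gain_coeffs", np.atleast_1d(np.asarray(self.gain_coeffs, float)))
        object.__setattr__(self, "offset_coeffs", np.atleast_1d(np.asarray(self.offset_coeffs, float)))
        if self.gain_coeffs.size == 0 or self.offset_coeffs.size == 0:
            raise GenerationError("gain and offset polynomials must be nonempty")
        self.ssc_ar.require_stationary()


@dataclass(frozen=True)
class SessionTruth:
    """Full generative truth of a session: kinetics, sensors, common noise."""

    tau: float
    sensors: list[SensorTruth]
    cc_ar: ARModel = POPULATION_CC_AR

    def __post_init__(self) -> None:
        if not np.isfinite(self.tau) or self.tau < 0:
            raise GenerationError("tau must be non-negative")
        if len(self.sensors) < 1:
            raise GenerationError("need at least one sensor truth")
        self.cc_ar.require_stationary()


@dataclass(frozen=True)
class SessionData:
    """One meal-test session: parallel CGM traces plus reference samples."""

    cgm: list[GlucoseSeries]
    reference: ReferenceSamples
    session_id: str = ""
    subject_id: str = ""
    truth: SessionTruth | None = None

    def __post_init__(self) -> None:
        if not self.cgm:
            raise SeriesError("session needs at least one CGM trace")
        t0, dt = self.cgm[0].t0, self.cgm[0].dt
        for s in self.cgm[1:]:
            if s.t0 != t0 or s.dt != dt or s.values.size != self.cgm[0].values.size:
                raise SeriesError("all CGM traces must share one grid")
        lo, hi = self.reference.span
        if t0 > lo + 1e-9 or self.cgm[0].t_end < hi - 1e-9:
            raise SeriesError("CGM span must cover the reference span")

    @property
    def n_sensors(self) -> int:
        return len(self.cgm)


# ---------------------------------------------------------------------------
# blood-glucose profile


@dataclass(frozen=True)
class MealTestConfig:
    """Shape parameters of the synthetic meal-test BG excursion.

    The profile is basal level + a log-normal-shaped meal excursion + a
    late counter-regulatory dip + smooth low-frequency variability.  Means
    and SDs describe the across-session population; one session draws one
    value of each.  Units: minutes and mg/dL.
    """

    duration: float = 480.0
    dt: float = 1.0
    basal_mean: float = 132.0
    basal_sd: float = 12.0
    meal_amp_mean: float = 140.0
    meal_amp_sd: float = 30.0
    meal_peak_lo: float = 50.0
    meal_peak_hi: float = 90.0
    meal_width: float = 0.75
    dip_amp_mean: float = 36.0
    dip_amp_sd: float = 28.0
    dip_center: float = 340.0
    dip_center_sd: float = 40.0
    dip_width: float = 0.35
    slow_var_amp: float = 8.0
    fast_var_amp: float = 3.8
    floor: float = 40.0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise GenerationError("duration and dt must be positive")
        if self.basal_mean <= self.floor:
            raise GenerationError("basal level must sit above the hypoglycemia floor")


def _lognormal_bump(t: np.ndarray, peak: float, width: float) -> np.ndarray:
    tt = np.maximum(t, 1e-9)
    return np.exp(-np.log(tt / peak) ** 2 / (2.0 * width**2))


def generate_bg_profile(config: MealTestConfig, seed: int | np.random.Generator) -> GlucoseSeries:
    """Draw one 1-min BG profile for a meal-test session.

    Draws whose nadir would cross ``config.floor`` (default 40 mg/dL, a
    clinically implausible depth for a supervised session) are redrawn;
    a configuration that cannot produce a valid profile is rejected.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = config
    t = np.arange(0.0, c.duration + c.dt / 2, c.dt)
    for _ in range(200):
        basal = rng.normal(c.basal_mean, c.basal_sd)
        amp = max(rng.normal(c.meal_amp_mean, c.meal_amp_sd), 0.0)
        peak = rng.uniform(c.meal_peak_lo, c.meal_peak_hi)
        dip_amp = max(rng.normal(c.dip_amp_mean, c.dip_amp_sd), 0.0)
        dip_center = rng.normal(c.dip_center, c.dip_center_sd)
        bg = basal + amp * _lognormal_bump(t, peak, c.meal_width)
        if dip_center > 0:
            bg = bg - dip_amp * _lognormal_bump(t, dip_center, c.dip_width)
        for _i in range(3):  # slow physiological variability
            period = rng.uniform(90.0, 240.0)
            phase = rng.uniform(0.0, 2 * np.pi)
            bg = bg + (c.slow_var_amp / np.sqrt(3)) * rng.normal() * np.sin(
                2 * np.pi * t / period + phase
            )
        for _i in range(2):  # faster oscillatory component
            period = rng.uniform(35.0, 70.0)
            phase = rng.uniform(0.0, 2 * np.pi)
            bg = bg + (c.fast_var_amp / np.sqrt(2)) * abs(rng.normal()) * np.sin(
                2 * np.pi * t / period + phase
            )
        if bg.min() >= c.floor:
            return GlucoseSeries(0.0, c.dt, bg)
    raise GenerationError("configuration cannot produce a profile above the glucose floor")


# ---------------------------------------------------------------------------
# error-chain building blocks


def bg_to_ig(bg: GlucoseSeries, tau: float) -> GlucoseSeries:
    """Blood-to-interstitium first-order kinetics.

    Discrete zero-order-hold realization of convolution with the unit-area
    kernel h(t) = (1/tau) exp(-t/tau):

        IG[k] = e^(-dt/tau) IG[k-1] + (1 - e^(-dt/tau)) BG[k],  IG[0] = BG[0]

    Steady-state gain is exactly 1; tau = 0 degenerates to the identity.
    """
    if not np.isfinite(tau) or tau < 0:
        raise GenerationError("tau must be non-negative")
    if tau == 0:
        return bg.with_values(bg.values.copy())
    a = np.exp(-bg.dt / tau)
    # IG[k] - a IG[k-1] = (1-a) BG[k], initialized at steady state
    zi = np.array([a * bg.values[0]])
    ig, _ = lfilter([1.0 - a], [1.0, -a], bg.values, zi=zi)
    return bg.with_values(ig)


def apply_calibration(
    ig: GlucoseSeries, gain_coeffs: np.ndarray, offset_coeffs: np.ndarray
) -> GlucoseSeries:
    """Sensor calibration distortion IGS(t) = a(t) IG(t) + b(t).

    a and b are polynomials in t (minutes from the session origin) with
    coefficients in increasing order.  The gain must stay positive over the
    series span.
    """
    gain = np.atleast_1d(np.asarray(gain_coeffs, float))
    off = np.atleast_1d(np.asarray(offset_coeffs, float))
    if gain.size == 0 or off.size == 0:
        raise GenerationError("gain and offset coefficient lists must be nonempty")
    t = ig.times
    a_t = np.polynomial.polynomial.polyval(t, gain)
    b_t = np.polynomial.polynomial.polyval(t, off)
    if np.any(a_t <= 0):
        raise GenerationError("gain polynomial is non-positive somewhere on the span")
    return ig.with_values(a_t * ig.values + b_t)


# ---------------------------------------------------------------------------
# session assembly


@dataclass(frozen=True)
class SessionConfig:
    """Sampling layout of a generated session."""

    meal: MealTestConfig = MealTestConfig()
    cgm_dt: float = 5.0
    ref_gap_lo: float = 10.0
    ref_gap_hi: float = 20.0
    ref_noise_sd_frac: float = 0.0  # proportional reference error; 0 = gold standard
    ar_burn_in: int = 500

    def __post_init__(self) -> None:
        if self.cgm_dt <= 0:
            raise GenerationError("cgm_dt must be positive")
        if not (0 < self.ref_gap_lo <= self.ref_gap_hi):
            raise GenerationError("reference gap window must satisfy 0 < lo <= hi")


def _reference_times(duration: float, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """Draw instants 0 = t_1 < ... <= duration with gaps ~ U[lo, hi].

    Times are rounded to whole minutes (laboratory timestamp resolution);
    the final sample is clamped to the session end so the reference span
    covers the CGM span used for smoothing.
    """
    times = [0.0]
    t = 0.0
    while t < duration:
        t += rng.uniform(lo, hi)
        times.append(min(round(t), duration))
    return np.unique(np.asarray(times, dtype=float))


def generate_session(
    truth: SessionTruth,
    config: SessionConfig,
    seed: int | np.random.Generator,
    session_id: str = "",
    subject_id: str = "",
) -> SessionData:
    """Assemble one full synthetic session from a given ground truth."""
    if len(truth.sensors) < 2:
        raise GenerationError("decomposition-capable sessions need n >= 2 sensors")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bg = generate_bg_profile(config.meal, rng)

    ig = bg_to_ig(bg, truth.tau)
    stride = config.cgm_dt / bg.dt
    if abs(stride - round(stride)) > 1e-9:
        raise GenerationError("cgm_dt must be a multiple of the BG grid dt")
    stride = int(round(stride))
    idx = np.arange(0, bg.values.size, stride)
    n_cgm = idx.size

    cc = simulate_ar(truth.cc_ar, n_cgm, rng, config.ar_burn_in)
    traces = []
    t_grid = ig.times
    for sensor in truth.sensors:
        # the calibrated signal is computed on raw arrays: dispersed
        # gain/offset draws can push it negative at glucose lows, and the
        # sensor clips only its final output at zero
        a_t = np.polynomial.polynomial.polyval(t_grid, sensor.gain_coeffs)
        if np.any(a_t <= 0):
            raise GenerationError("gain polynomial is non-positive on the session span")
        igs_vals = a_t * ig.values + np.polynomial.polynomial.polyval(
            t_grid, sensor.offset_coeffs
        )
        ssc = simulate_ar(sensor.ssc_ar, n_cgm, rng, config.ar_burn_in)
        vals = igs_vals[idx] + cc + ssc
        traces.append(GlucoseSeries(0.0, config.cgm_dt, np.maximum(vals, 0.0)))

    ref_t = _reference_times(config.meal.duration, config.ref_gap_lo, config.ref_gap_hi, rng)
    ref_v = bg.value_at(ref_t)
    if config.ref_noise_sd_frac > 0:
        ref_v = ref_v * (1.0 + config.ref_noise_sd_frac * rng.normal(size=ref_v.size))
    return SessionData(traces, ReferenceSamples(ref_t, ref_v), session_id, subject_id, truth)


# ---------------------------------------------------------------------------
# population sampling


@dataclass(frozen=True)
class PopulationConfig:
    """Across-session distributions of the generative truth parameters.

    Defaults are the published linear-calibration population values for the
    Enlite sensor: tau 9.4 +/- 6.5 min, gain 1.1 +/- 0.4 and
    -0.0009 +/- 0.0016 /min, offset -11.2 +/- 38.8 mg/dL and
    0.09 +/- 0.19 mg/dL/min.  Setting every SD to 0 pins all sessions at
    the population mean.
    """

    tau_mean: float = 9.4
    tau_sd: float = 6.5
    a0_mean: float = 1.1
    a0_sd: float = 0.4
    a1_mean: float = -0.0009
    a1_sd: float = 0.0016
    b0_mean: float = -11.2
    b0_sd: float = 38.8
    b1_mean: float = 0.09
    b1_sd: float = 0.19
    cc_ar: ARModel = POPULATION_CC_AR
    ssc_ar: ARModel = POPULATION_SSC_AR
    n_sensors: int = 2
    n_subjects: int = 10

    def __post_init__(self) -> None:
        for name in ("tau_sd", "a0_sd", "a1_sd", "b0_sd", "b1_sd"):
            if getattr(self, name) < 0:
                raise GenerationError(f"{name} must be non-negative")
        if self.tau_mean <= 0:
            raise GenerationError("tau_mean must be positive")
        if self.n_sensors < 2:
            raise GenerationError("need at least 2 parallel sensors")


def _draw_sensor_truth(
    pop: PopulationConfig, horizon: float, rng: np.random.Generator
) -> SensorTruth:
    for _ in range(200):
        gain = np.array([rng.normal(pop.a0_mean, pop.a0_sd), rng.normal(pop.a1_mean, pop.a1_sd)])
        if np.all(np.polynomial.polynomial.polyval(np.linspace(0, horizon, 50), gain) > 0.05):
            break
    else:
        raise GenerationError("could not draw a positive gain polynomial")
    offset = np.array([rng.normal(pop.b0_mean, pop.b0_sd), rng.normal(pop.b1_mean, pop.b1_sd)])
    return SensorTruth(gain, offset, pop.ssc_ar)


def draw_session_truth(
    pop: PopulationConfig, rng: np.random.Generator, horizon: float = 480.0
) -> SessionTruth:
    tau = rng.normal(pop.tau_mean, pop.tau_sd)
    while tau <= 0:
        tau = rng.normal(pop.tau_mean, pop.tau_sd)
    sensors = [_draw_sensor_truth(pop, horizon, rng) for _ in range(pop.n_sensors)]
    return SessionTruth(float(tau), sensors, pop.cc_ar)


def generate_dataset(
    population_config: PopulationConfig,
    n_sessions: int,
    seed: int,
    session_config: SessionConfig | None = None,
) -> list[SessionData]:
    """Draw independent per-session truths and build the sessions.

    Sessions are assigned to ``n_subjects`` subjects round-robin, mirroring
    a repeated-measures inpatient layout.
    """
    if n_sessions < 0:
        raise GenerationError("n_sessions must be >= 0")
    cfg = session_config or SessionConfig()
    rng = np.random.default_rng(seed)
    sessions = []
    for i in range(n_sessions):
        truth = draw_session_truth(population_config, rng, horizon=cfg.meal.duration)
        sid = f"s{i + 1:03d}"
        subj = f"p{(i % population_config.n_subjects) + 1:02d}"
        sessions.append(generate_session(truth, cfg, rng, session_id=sid, subject_id=subj))
    return sessions


def inject_signal_loss(
    session: SessionData, start: float, duration: float, sensor: int = 0
) -> SessionData:
    """Blank a contiguous CGM window (sensor malfunction) for QC testing."""
    traces = []
    for i, s in enumerate(session.cgm):
        vals = s.values.copy()
        if i == sensor:
            t = s.times
            vals[(t >= start) & (t < start + duration)] = np.nan
        traces.append(GlucoseSeries(s.t0, s.dt, vals))
    return replace(session, cgm=traces)


def make_study_fixture(
    seed: int,
    n_sessions: int = 40,
    n_faulty: int = 3,
    population_config: PopulationConfig | None = None,
    session_config: SessionConfig | None = None,
    loss_duration: float = 60.0,
) -> list[SessionData]:
    """The study-layout fixture: 40 sessions of which 3 carry signal loss.

    The faulty sessions (chosen deterministically from the seed) have one
    sensor blanked for ``loss_duration`` minutes mid-session, long enough
    to trip the default QC gap rule.
    """
    pop = population_config or PopulationConfig()
    sessions = generate_dataset(pop, n_sessions, seed, session_config)
    rng = np.random.default_rng(seed + 1)
    faulty = rng.choice(n_sessions, size=n_faulty, replace=False)
    for j in faulty:
        sessions[j] = inject_signal_loss(sessions[j], start=150.0, duration=loss_duration)
    return sessions
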