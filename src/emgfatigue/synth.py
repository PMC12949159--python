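"""Synthetic baseline sessions and constant-power trials with known truth.

Every downstream stage is testable without any data download: the
generator emits raw-format EMG traces, crank records, breath tables and
IC manoeuvres for control, expiratory-resistance and isotime-control
trials, together with a :class:`SyntheticTruth` holding the ground-truth
activation- and muscle-fatigue trajectories.

Model choices (see docstrings for details):

* linear EMG-power coupling with multiplicative Gaussian noise on the
  per-revolution EMG amplitude (SD calibrated so the downstream fitted
  r^2 is ~0.96 with the default effort ladder);
* linear decline of the maximal evocable EMG fraction (activation
  fatigue) and linear growth of the power deficit at a given EMG
  (muscle fatigue) from exercise onset;
* tolerance times drawn per participant, with the expiratory-resistance
  trial a fixed fraction of the control draw and the isotime-control
  trial truncated at the resistance duration;
* expiratory resistance affects only the time factor, the IRV decline
  rate and the Borg growth rates -- no airway mechanics are simulated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .lungmech import ICManoeuvre, tidal_volume_20s
from .sigproc import (
    HYPERBOLIC,
    ISOKINETIC,
    MUSCLES,
    CrankSignal,
    EMGTrace,
    rms_envelope,
)

logger = logging.getLogger(__name__)

CONTROL = "control"
RESISTANCE = "resistance"
ISOTIME_CONTROL = "isotime_control"
CONDITIONS = (CONTROL, RESISTANCE, ISOTIME_CONTROL)

#: stable sub-stream identifiers for the seed sequence
_STREAM_TRAITS = 0
_STREAM_TOLERANCE = 1
_STREAM_BOUT_NOISE = 2
_STREAM_CARRIER = 3
_STREAM_IC = 4

#: visit index per generated session (baseline-only session is visit 0)
_VISIT = {None: 0, CONTROL: 1, RESISTANCE: 2, ISOTIME_CONTROL: 3}

#: per-muscle full-effort RMS amplitude, mV (arbitrary realistic scales;
#: they cancel in the fractional-EMG normalization)
MUSCLE_GAIN_MV = {
    "vastus_lateralis": 0.90,
    "rectus_femoris": 0.50,
    "vastus_medialis": 0.80,
    "lateral_gastrocnemius": 0.40,
}

#: carrier band for the synthetic EMG noise (the sensors' own bandwidth)
CARRIER_BAND = (20.0, 450.0)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    A fixed ``seed`` makes every generated artefact bit-identical. The
    ``af_rate`` / ``mf_rate`` declines are specified in W/s for a
    participant whose true maximum equals ``max_power_mean`` and scale
    proportionally with the drawn maximum, which keeps end-exercise
    power positive across the whole draw distribution.
    """

    n_participants: int = 14
    seed: int = 0
    cadence_target: float = 70.0  # rpm
    emg_rate: float = 2000.0  # Hz
    # efforts of the eight ~5 s baseline bouts (25/50/75/100%, each twice)
    baseline_efforts: tuple = (0.25, 0.50, 0.75, 1.00, 0.25, 0.50, 0.75, 1.00)
    # SD of the multiplicative per-revolution EMG amplitude noise,
    # calibrated so the fitted baseline r^2 averages ~0.96
    baseline_r2_noise: float = 0.17
    tolerance_mean_control: float = 575.0  # s
    tolerance_sd_control: float = 137.0  # s
    resistance_time_factor: float = 487.0 / 575.0
    expiratory_resistance: float = 7.0  # cmH2O/L/s, applied in the resistance arm
    af_rate: float = 0.26  # W/s at the reference maximum
    mf_rate: float = 0.04  # W/s at the reference maximum
    af_rate_resistance: Optional[float] = None  # override for the resistance arm
    max_power_mean: float = 342.0  # W single-leg
    max_power_sd: float = 108.0
    task_power_mean: float = 193.0  # W chainring
    task_power_sd: float = 47.0
    vo2peak_mean: float = 3.5  # L/min
    vo2peak_sd: float = 0.8
    irv_baseline: float = 2.5  # L
    irv_decline_rate_control: float = 0.00357  # L/s
    irv_decline_rate_resistance: float = 0.00474  # L/s
    vt_rest: float = 1.0  # L
    vt_amplitude: float = 1.8  # L, rise to the exercise plateau
    vt_tau: float = 60.0  # s
    ic_noise_sd: float = 0.05  # L, replicate-to-replicate manoeuvre noise
    borg_dyspnoea_rate_control: float = 8.5 / 575.0  # Borg units per s
    borg_dyspnoea_rate_resistance: float = 8.5 / 487.0
    borg_leg_rate_control: float = 8.0 / 487.0
    borg_leg_rate_resistance: float = 8.5 / 487.0
    bout_duration_s: float = 6.0
    bout_gap_s: float = 35.0  # 0 W cycling between baseline bouts (>= 30 s)
    intolerance_dwell_s: float = 6.0  # sub-60 rpm dwell appended at the limit
    tolerance_floor_s: float = 60.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if not (self.cadence_target > 0 and self.emg_rate > 0):
            raise ValueError("cadence and EMG rate must be positive")
        if len(self.baseline_efforts) < 4:
            raise ValueError("need at least 4 baseline efforts")
        if any(not (0.0 < f <= 1.0) for f in self.baseline_efforts):
            raise ValueError("effort fractions must lie in (0, 1]")
        for name in (
            "baseline_r2_noise",
            "af_rate",
            "mf_rate",
            "irv_decline_rate_control",
            "irv_decline_rate_resistance",
            "ic_noise_sd",
            "borg_dyspnoea_rate_control",
            "borg_dyspnoea_rate_resistance",
            "borg_leg_rate_control",
            "borg_leg_rate_resistance",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.af_rate_resistance is not None and self.af_rate_resistance < 0:
            raise ValueError("af_rate_resistance must be >= 0")
        if not (0 < self.resistance_time_factor <= 1):
            raise ValueError("resistance_time_factor must lie in (0, 1]")
        if self.max_power_mean <= 0:
            raise ValueError("true maximal power must be positive (non-positive slope)")
        if self.tolerance_sd_control < 0 or self.tolerance_mean_control <= 0:
            raise ValueError("tolerance-time parameters out of range")


def noise_free(config: SimConfig) -> SimConfig:
    """Copy of the config with every measurement-noise source switched off."""
    return replace(config, baseline_r2_noise=0.0, ic_noise_sd=0.0)


@dataclass
class ParticipantTraits:
    """Fixed per-participant quantities shared across conditions."""

    max_power_w: float  # true single-leg maximum (also the EMG-power slope)
    task_power_w: float  # chainring constant power
    vo2peak_l_min: float


@dataclass
class SyntheticTruth:
    """Ground truth for one generated session or trial."""

    true_slope: float  # W per unit fractional EMG
    true_intercept: float  # W
    af_rate: float  # W/s, this participant/condition
    mf_rate: float  # W/s
    true_tolerance_time: float  # s (NaN for a baseline-only session)
    irv_baseline: float  # L
    irv_decline_rate: float  # L/s
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        if self.true_slope <= 0:
            raise ValueError("true slope must be positive")
        if self.af_rate < 0 or self.mf_rate < 0:
            raise ValueError("fatigue rates must be >= 0")

    # -- trajectories ------------------------------------------------------
    def true_max_emg_fraction(self, t) -> np.ndarray:
        """Maximal evocable EMG fraction at time ``t`` (1 at onset, non-increasing)."""
        t = np.maximum(np.asarray(t, dtype=float), 0.0)
        return 1.0 - self.af_rate * t / self.true_slope

    def true_muscle_deficit(self, t) -> np.ndarray:
        """Power deficit (W) at a given EMG (0 at onset, non-decreasing)."""
        t = np.maximum(np.asarray(t, dtype=float), 0.0)
        return self.mf_rate * t

    def true_activation_fatigue(self, t) -> np.ndarray:
        """Activation fatigue (W) at time ``t``."""
        t = np.maximum(np.asarray(t, dtype=float), 0.0)
        return self.af_rate * t

    def true_isokinetic_power(self, t) -> np.ndarray:
        """Maximal evocable single-leg isokinetic power (W) at time ``t``."""
        return (
            self.true_slope * self.true_max_emg_fraction(t)
            + self.true_intercept
            - self.true_muscle_deficit(t)
        )

    def true_irv(self, t) -> np.ndarray:
        """Inspiratory reserve volume trajectory (L); flat before onset."""
        t = np.maximum(np.asarray(t, dtype=float), 0.0)
        return self.irv_baseline - self.irv_decline_rate * t


@dataclass
class TrialDataset:
    """Everything one constant-power visit produces, raw formats included."""

    participant_id: str
    condition: str
    task_power_w: float  # chainring
    tolerance_time_s: float  # protocol end (truncation time for isotime-control)
    at_intolerance: bool
    baseline_emg: list  # per bout: list of 4 EMGTrace
    baseline_crank: list  # per bout: CrankSignal
    trial_crank: CrankSignal  # constant-power phase + final isokinetic phase
    end_emg: list  # 4 EMGTrace covering the final isokinetic phase
    breaths: pd.DataFrame  # time_s, vt_l, ve_l_min, vo2_l_min, vco2_l_min
    ic_manoeuvres: list  # ICManoeuvre, duplicates per stage
    borg: dict  # stage -> {"dyspnoea": x, "leg": y}
    vo2peak_l_min: float


# ---------------------------------------------------------------------------
# profiles and random streams
# ---------------------------------------------------------------------------


class PiecewiseConstant:
    """Right-open piecewise-constant profile on [0, duration)."""

    def __init__(self, breakpoints: Sequence[float], values: Sequence):
        if len(values) != len(breakpoints):
            raise ValueError("one value per breakpoint required")
        if list(breakpoints) != sorted(breakpoints) or breakpoints[0] != 0:
            raise ValueError("breakpoints must start at 0 and be sorted")
        self.breakpoints = list(breakpoints)
        self.values = list(values)

    def __call__(self, t):
        idx = np.clip(
            np.searchsorted(self.breakpoints, np.asarray(t, dtype=float), side="right") - 1,
            0,
            len(self.values) - 1,
        )
        return np.asarray(self.values, dtype=object)[idx]

    def segments(self, duration: float):
        """Yield (start, end, value) covering [0, duration)."""
        for i, (start, value) in enumerate(zip(self.breakpoints, self.values)):
            end = self.breakpoints[i + 1] if i + 1 < len(self.breakpoints) else duration
            end = min(end, duration)
            if end > start:
                yield start, end, value


def _rng(config: SimConfig, participant_seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, int(participant_seed), *stream])


def participant_traits(config: SimConfig, participant_seed: int) -> ParticipantTraits:
    """Draw the fixed traits for one participant (deterministic in the seeds)."""
    rng = _rng(config, participant_seed, _STREAM_TRAITS)
    max_power = rng.normal(config.max_power_mean, config.max_power_sd)
    while max_power < 100.0:  # keep the EMG-power slope physiological
        max_power = rng.normal(config.max_power_mean, config.max_power_sd)
    # task power tracks the participant's capacity (it was prescribed
    # relative to individual ramp-test landmarks), so stronger
    # participants ride at proportionally higher constant power
    task_power = max(
        50.0,
        rng.normal(config.task_power_mean, config.task_power_sd)
        * max_power
        / config.max_power_mean,
    )
    vo2peak = max(1.5, rng.normal(config.vo2peak_mean, config.vo2peak_sd))
    return ParticipantTraits(
        max_power_w=float(max_power),
        task_power_w=float(task_power),
        vo2peak_l_min=float(vo2peak),
    )


def draw_tolerance_time(
    config: SimConfig, participant_seed: int, condition: str = CONTROL
) -> float:
    """Tolerance time (s) for one participant and condition.

    The control time is Normal(mean, SD); the resistance time is the
    *same participant's* control draw times ``resistance_time_factor``;
    the isotime-control truncation equals the resistance time. Draws
    that would put any condition at or below the 60 s floor are redrawn
    from an incremented stream (logged).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    floor = config.tolerance_floor_s
    for attempt in range(1000):
        rng = _rng(config, participant_seed, _STREAM_TOLERANCE, attempt)
        control_time = rng.normal(
            config.tolerance_mean_control, config.tolerance_sd_control
        )
        if control_time * min(1.0, config.resistance_time_factor) > floor:
            break
        logger.info(
            "participant %s: drawn tolerance %.0f s <= %.0f s floor; redrawing "
            "(attempt %d)",
            participant_seed,
            control_time,
            floor,
            attempt + 1,
        )
    else:
        raise ValueError(
            "tolerance-time distribution is almost entirely below the "
            f"{floor:.0f} s floor; reconsider the configuration"
        )
    if condition == CONTROL:
        return float(control_time)
    return float(control_time * config.resistance_time_factor)


# ---------------------------------------------------------------------------
# raw-signal generators
# ---------------------------------------------------------------------------


def generate_emg_trace(
    amplitude_per_revolution: Sequence[float],
    config: SimConfig,
    seed,
    muscle: str = "vastus_lateralis",
    t0: float = 0.0,
) -> EMGTrace:
    """Band-limited noise carrier amplitude-modulated per crank revolution.

    The carrier is zero-mean Gaussian noise band-passed to 20-450 Hz
    (the sensor bandwidth), shaped by a Hann burst over the revolution
    and normalized so that the peak of the trailing 200-sample RMS
    envelope of the *unfiltered* trace equals the requested amplitude
    exactly (proportionality constant 1.0). The same carrier realization
    is reused for every revolution, so recovered peak ratios are exact;
    fresh randomness enters through the per-revolution amplitudes.
    """
    amplitudes = np.asarray(amplitude_per_revolution, dtype=float)
    if amplitudes.ndim != 1 or amplitudes.size == 0:
        raise ValueError("need a one-dimensional, non-empty amplitude list")
    if np.any(amplitudes < 0):
        raise ValueError("per-revolution amplitudes must be >= 0")
    n_rev = int(round(config.emg_rate * 60.0 / config.cadence_target))
    rng = np.random.default_rng(seed)
    carrier = rng.standard_normal(n_rev)
    sos = sps.butter(
        4, [CARRIER_BAND[0], CARRIER_BAND[1]], btype="bandpass", fs=config.emg_rate,
        output="sos",
    )
    carrier = sps.sosfiltfilt(sos, carrier)
    template = carrier * np.hanning(n_rev)
    peak = float(np.max(rms_envelope(template, min(200, n_rev))))
    template = template / peak
    samples = np.concatenate([a * template for a in amplitudes])
    return EMGTrace(samples=samples, rate=config.emg_rate, muscle=muscle, t0=t0)


def _torque_shape(angle_deg: np.ndarray) -> np.ndarray:
    # raised sinusoid, two peaks per revolution; exact mean of 1 over the
    # 180 equally spaced 2-degree samples of a revolution
    return 1.0 - np.cos(2.0 * np.deg2rad(angle_deg))


def generate_crank_signal(
    power_profile,
    cadence_profile,
    config: SimConfig,
    duration: float,
    mode_profile=ISOKINETIC,
    t0: float = 0.0,
) -> CrankSignal:
    """Crank record sampled every 2 degrees of crank angle.

    ``power_profile`` (single-leg W) and ``mode_profile`` may be
    scalars, callables of time, or :class:`PiecewiseConstant`;
    ``cadence_profile`` (rpm) must be a scalar or piecewise-constant so
    the 2-degree sample times can be laid out in closed form. Per-sample
    torque is the instantaneous single-leg power over angular velocity,
    shaped within the revolution by a two-peak raised sinusoid whose
    revolution mean is exactly 1; left and right cranks are identical.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if isinstance(cadence_profile, (int, float, np.integer, np.floating)):
        cadence_profile = PiecewiseConstant([0.0], [float(cadence_profile)])
    if not isinstance(cadence_profile, PiecewiseConstant):
        raise TypeError("cadence_profile must be a scalar or PiecewiseConstant")

    def _eval(profile, t: np.ndarray, dtype=float) -> np.ndarray:
        if isinstance(profile, PiecewiseConstant):
            return profile(t).astype(dtype) if dtype is not object else profile(t)
        if callable(profile):
            return np.asarray([profile(ti) for ti in np.atleast_1d(t)])
        return np.full(t.shape, profile)

    times = []
    t = 0.0
    for start, end, cadence in cadence_profile.segments(duration):
        if cadence <= 0:
            power_here = _eval(power_profile, np.array([start]))[0]
            if power_here > 0:
                raise ValueError("cadence is 0 where power > 0")
            raise ValueError("cannot sample a stationary crank (cadence <= 0)")
        dt = 1.0 / (3.0 * cadence)  # time per 2 degrees
        n = int(math.floor((end - t) / dt + 1e-9))
        times.append(t + dt * np.arange(n))
        t += n * dt
    if t <= duration + 1e-9:
        times.append(np.array([t]))  # closing boundary sample
    rel_t = np.concatenate(times)
    n_samples = rel_t.size
    angle = 2.0 * np.arange(n_samples)
    cadence = cadence_profile(rel_t).astype(float)
    omega = cadence * 2.0 * np.pi / 60.0
    power = _eval(power_profile, rel_t).astype(float)
    if np.any(power < 0):
        raise ValueError("power profile must be non-negative")
    torque = np.where(power > 0, power / omega, 0.0) * _torque_shape(angle)
    mode = _eval(mode_profile, rel_t, dtype=object)
    return CrankSignal(
        time=t0 + rel_t,
        angle=angle,
        torque_left=torque,
        torque_right=torque.copy(),
        angular_velocity=omega,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# sessions and trials
# ---------------------------------------------------------------------------


def _carrier_seed(config: SimConfig, participant_seed: int, visit: int, muscle_idx: int):
    # one carrier per (participant, visit, muscle): shared across bouts of a
    # visit so the normalization constant cancels exactly in fractional EMG
    return [config.seed, int(participant_seed), _STREAM_CARRIER, visit, muscle_idx]


def _bout_revolution_count(config: SimConfig) -> int:
    return int(math.ceil(config.bout_duration_s * config.cadence_target / 60.0 - 1e-9))


def _emg_bout(
    config: SimConfig,
    participant_seed: int,
    visit: int,
    fraction_per_revolution: np.ndarray,
    t0: float,
) -> list:
    traces = []
    for mi, muscle in enumerate(MUSCLES):
        amps = fraction_per_revolution * MUSCLE_GAIN_MV[muscle]
        traces.append(
            generate_emg_trace(
                amps,
                config,
                seed=_carrier_seed(config, participant_seed, visit, mi),
                muscle=muscle,
                t0=t0,
            )
        )
    return traces


def generate_baseline_session(
    config: SimConfig, participant_seed: int, visit: Optional[str] = None
):
    """Eight variable-effort isokinetic bouts with known truth.

    Returns ``(emg_bouts, crank_bouts, truth)`` where ``emg_bouts[k]``
    is the list of four muscle traces of bout ``k`` and
    ``crank_bouts[k]`` the matching crank record. Bouts last
    ``bout_duration_s`` at the target cadence, separated by >= 30 s of
    0 W cycling (represented by the gap between bout time offsets). The
    per-bout true single-leg power is ``effort x true maximum`` and the
    per-revolution EMG amplitude is ``(power - intercept)/slope`` times
    ``1 + eps`` with ``eps ~ Normal(0, baseline_r2_noise)``.
    """
    traits = participant_traits(config, participant_seed)
    visit_idx = _VISIT[visit] if visit in _VISIT else _VISIT[None]
    truth = SyntheticTruth(
        true_slope=traits.max_power_w,
        true_intercept=0.0,
        af_rate=0.0,
        mf_rate=0.0,
        true_tolerance_time=float("nan"),
        irv_baseline=config.irv_baseline,
        irv_decline_rate=0.0,
        condition=visit,
    )
    noise_rng = _rng(config, participant_seed, _STREAM_BOUT_NOISE, visit_idx)
    n_rev = _bout_revolution_count(config)
    emg_bouts, crank_bouts = [], []
    for k, effort in enumerate(config.baseline_efforts):
        start = k * (config.bout_duration_s + config.bout_gap_s)
        crank_bouts.append(
            generate_crank_signal(
                power_profile=effort * traits.max_power_w,
                cadence_profile=config.cadence_target,
                config=config,
                duration=config.bout_duration_s,
                mode_profile=ISOKINETIC,
                t0=start,
            )
        )
        eps = noise_rng.normal(0.0, config.baseline_r2_noise, n_rev)
        fractions = np.clip(effort * (1.0 + eps), 0.0, None)
        emg_bouts.append(
            _emg_bout(config, participant_seed, visit_idx, fractions, t0=start)
        )
    return emg_bouts, crank_bouts, truth


def _breath_table(
    config: SimConfig, traits: ParticipantTraits, end_time: float
) -> pd.DataFrame:
    """Breath-by-breath table from 30 s before exercise onset to ``end_time``."""
    rr_rest, rr_max, rr_tau = 12.0, 35.0, 90.0
    vo2_rest, vo2_tau = 0.4, 45.0
    rows = []
    t = -30.0
    while t <= end_time:
        if t < 0:
            rr, vt, vo2 = rr_rest, config.vt_rest, vo2_rest
        else:
            rise = 1.0 - math.exp(-t / rr_tau)
            rr = rr_rest + (rr_max - rr_rest) * rise
            vt = config.vt_rest + config.vt_amplitude * (1.0 - math.exp(-t / config.vt_tau))
            vo2 = vo2_rest + (traits.vo2peak_l_min - vo2_rest) * (
                1.0 - math.exp(-t / vo2_tau)
            )
        rows.append(
            {
                "time_s": t,
                "vt_l": vt,
                "ve_l_min": vt * rr,
                "vo2_l_min": vo2,
                "vco2_l_min": 0.95 * vo2,
            }
        )
        t += 60.0 / rr
    return pd.DataFrame(rows)


def generate_constant_power_trial(
    config: SimConfig, condition: str, participant_seed: int
):
    """One constant-power visit: baseline bouts, trial signals and truth.

    The control tolerance time is drawn per participant; the resistance
    time is that draw times ``resistance_time_factor``, and the
    isotime-control trial is truncated at the resistance duration (all
    three derive from the same participant seed, so the pairing is
    consistent across separately generated conditions). Control and
    resistance trials end with a sub-60 rpm dwell followed by a ~5 s
    maximal isokinetic phase; the isotime-control trial switches
    directly to the isokinetic phase at truncation. The final-phase EMG
    and power embed the truth trajectories evaluated at termination.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    traits = participant_traits(config, participant_seed)
    visit_idx = _VISIT[condition]
    scale = traits.max_power_w / config.max_power_mean
    af_cfg = (
        config.af_rate_resistance
        if (condition == RESISTANCE and config.af_rate_resistance is not None)
        else config.af_rate
    )
    af_rate = af_cfg * scale
    mf_rate = config.mf_rate * scale
    irv_rate = (
        config.irv_decline_rate_resistance
        if condition == RESISTANCE
        else config.irv_decline_rate_control
    )
    tolerance = draw_tolerance_time(config, participant_seed, condition)
    at_intolerance = condition in (CONTROL, RESISTANCE)
    truth = SyntheticTruth(
        true_slope=traits.max_power_w,
        true_intercept=0.0,
        af_rate=af_rate,
        mf_rate=mf_rate,
        true_tolerance_time=tolerance,
        irv_baseline=config.irv_baseline,
        irv_decline_rate=irv_rate,
        condition=condition,
    )

    baseline_emg, baseline_crank, _ = generate_baseline_session(
        config, participant_seed, visit=condition
    )

    # --- trial crank: task phase (+ dwell at intolerance) + isokinetic phase
    single_leg_task = traits.task_power_w / 2.0
    end_power = float(truth.true_isokinetic_power(tolerance))
    if end_power <= 0:
        raise ValueError("degenerate trial: no evocable power left at termination")
    dwell = config.intolerance_dwell_s if at_intolerance else 0.0
    iso_start = tolerance + dwell
    iso_end = iso_start + config.bout_duration_s
    breaks = [0.0, tolerance, iso_start] if dwell else [0.0, iso_start]
    cadence_vals = (
        [config.cadence_target, 55.0, config.cadence_target]
        if dwell
        else [config.cadence_target, config.cadence_target]
    )
    power_vals = (
        [single_leg_task, single_leg_task, end_power]
        if dwell
        else [single_leg_task, end_power]
    )
    mode_vals = (
        [HYPERBOLIC, HYPERBOLIC, ISOKINETIC] if dwell else [HYPERBOLIC, ISOKINETIC]
    )
    trial_crank = generate_crank_signal(
        power_profile=PiecewiseConstant(breaks, power_vals),
        cadence_profile=PiecewiseConstant(breaks, cadence_vals),
        config=config,
        duration=iso_end,
        mode_profile=PiecewiseConstant(breaks, mode_vals),
    )

    # --- final-phase EMG, truth evaluated at termination
    noise_rng = _rng(config, participant_seed, _STREAM_BOUT_NOISE, visit_idx, 1)
    n_rev = _bout_revolution_count(config)
    eps = noise_rng.normal(0.0, config.baseline_r2_noise, n_rev)
    end_fraction = float(truth.true_max_emg_fraction(tolerance))
    fractions = np.clip(end_fraction * (1.0 + eps), 0.0, None)
    end_emg = _emg_bout(
        config, participant_seed, visit_idx, fractions, t0=float(trial_crank.time[0])
    )
    # align the final-phase EMG with the isokinetic samples
    iso_t0 = float(trial_crank.time[np.argmax(trial_crank.mode == ISOKINETIC)])
    end_emg = [replace(tr, t0=iso_t0) for tr in end_emg]

    # --- breaths, IC manoeuvres, Borg
    breaths = _breath_table(config, traits, end_time=iso_end)
    isotime = tolerance if condition != CONTROL else draw_tolerance_time(
        config, participant_seed, RESISTANCE
    )
    stage_times = {"baseline": 0.0, "isotime": isotime, "limit_of_tolerance": tolerance}
    ic_rng = _rng(config, participant_seed, _STREAM_IC, visit_idx)
    manoeuvres = []
    for stage, t_stage in stage_times.items():
        vt20 = tidal_volume_20s(breaths, t_stage)
        ic_true = float(truth.true_irv(t_stage)) + vt20
        for replicate in (1, 2):
            manoeuvres.append(
                ICManoeuvre(
                    time=t_stage,
                    inspired_volume=ic_true + ic_rng.normal(0.0, config.ic_noise_sd),
                    replicate=replicate,
                    stage=stage,
                )
            )
    d_rate = (
        config.borg_dyspnoea_rate_resistance
        if condition == RESISTANCE
        else config.borg_dyspnoea_rate_control
    )
    l_rate = (
        config.borg_leg_rate_resistance
        if condition == RESISTANCE
        else config.borg_leg_rate_control
    )
    borg = {
        stage: {
            "dyspnoea": min(10.0, d_rate * t_stage),
            "leg": min(10.0, l_rate * t_stage),
        }
        for stage, t_stage in stage_times.items()
    }

    dataset = TrialDataset(
        participant_id=f"p{int(participant_seed):03d}",
        condition=condition,
        task_power_w=traits.task_power_w,
        tolerance_time_s=tolerance,
        at_intolerance=at_intolerance,
        baseline_emg=baseline_emg,
        baseline_crank=baseline_crank,
        trial_crank=trial_crank,
        end_emg=end_emg,
        breaths=breaths,
        ic_manoeuvres=manoeuvres,
        borg=borg,
        vo2peak_l_min=traits.vo2peak_l_min,
    )
    return dataset, truth


def truth_table(truth: SyntheticTruth, times: Sequence[float]) -> pd.DataFrame:
    """Truth sidecar table on a time grid (written next to the raw data)."""
    t = np.asarray(times, dtype=float)
    return pd.DataFrame(
        {
            "time_s": t,
            "true_max_emg_fraction": truth.true_max_emg_fraction(t),
            "true_muscle_deficit_w": truth.true_muscle_deficit(t),
            "true_irv_l": truth.true_irv(t),
        }
    )
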