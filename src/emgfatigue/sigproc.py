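"""Crank-synchronous EMG and isokinetic-power signal processing.

Transforms raw surface-EMG traces and crank records into per-revolution
peak RMS EMG and three-revolution isokinetic power:

* zero-phase 4th-order Butterworth band-pass (10-500 Hz by default),
* trailing 200-sample RMS envelope,
* crank-angle revolution segmentation (cumulative angle, 2 deg samples),
* selection of three consecutive, cadence-constrained isokinetic
  revolutions and pairing of left-crank power with the four-muscle
  composite fractional EMG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: Muscles instrumented on the left leg, in canonical order.
MUSCLES = (
    "vastus_lateralis",
    "rectus_femoris",
    "vastus_medialis",
    "lateral_gastrocnemius",
)

#: Short column labels used in delimited EMG tables (same order as MUSCLES).
MUSCLE_COLUMNS = {
    "vastus_lateralis": "vl_mv",
    "rectus_femoris": "rf_mv",
    "vastus_medialis": "vm_mv",
    "lateral_gastrocnemius": "lg_mv",
}

HYPERBOLIC = "hyperbolic"
ISOKINETIC = "isokinetic"

DEFAULT_BAND = (10.0, 500.0)
DEFAULT_RMS_WINDOW = 200
DEFAULT_TARGET_RPM = 70.0
DEFAULT_CADENCE_TOLERANCE = 0.05


@dataclass
class EMGTrace:
    """A single-muscle EMG voltage series.

    Parameters
    ----------
    samples : array of mV values.
    rate : sampling rate in Hz.
    muscle : one of :data:`MUSCLES`.
    t0 : time of the first sample, seconds.
    filtered : whether the band-pass has already been applied.
    """

    samples: np.ndarray
    rate: float
    muscle: str
    t0: float = 0.0
    filtered: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("EMG samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EMG samples must be finite")
        if self.muscle not in MUSCLES:
            raise ValueError(f"unknown muscle {self.muscle!r}; expected one of {MUSCLES}")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class CrankSignal:
    """Angle-indexed crank record sampled every 2 degrees.

    ``angle`` is cumulative (unwrapped) crank angle in degrees, ``mode``
    is the per-sample ergometer mode (``"hyperbolic"`` or
    ``"isokinetic"``).
    """

    time: np.ndarray
    angle: np.ndarray
    torque_left: np.ndarray
    torque_right: np.ndarray
    angular_velocity: np.ndarray
    mode: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        self.torque_left = np.asarray(self.torque_left, dtype=float)
        self.torque_right = np.asarray(self.torque_right, dtype=float)
        self.angular_velocity = np.asarray(self.angular_velocity, dtype=float)
        self.mode = np.asarray(self.mode, dtype=object)
        n = self.time.size
        for name in ("angle", "torque_left", "torque_right", "angular_velocity", "mode"):
            if getattr(self, name).size != n:
                raise ValueError("all crank series must have equal length")
        if np.any(np.diff(self.angle) < 0):
            raise ValueError("crank angle must be non-decreasing")
        if np.any(self.angular_velocity < 0):
            raise ValueError("angular velocity must be non-negative")

    def __len__(self) -> int:
        return self.time.size

    @property
    def cadence_rpm(self) -> np.ndarray:
        """Per-sample cadence in rpm (from angular velocity)."""
        return self.angular_velocity * 60.0 / (2.0 * np.pi)

    def subset(self, mask: np.ndarray) -> "CrankSignal":
        """Return a new signal restricted to ``mask`` (boolean, contiguous use intended)."""
        return CrankSignal(
            time=self.time[mask],
            angle=self.angle[mask],
            torque_left=self.torque_left[mask],
            torque_right=self.torque_right[mask],
            angular_velocity=self.angular_velocity[mask],
            mode=self.mode[mask],
        )


@dataclass
class Revolution:
    """One contiguous 360-degree crank revolution and its features."""

    index: int
    start_time: float
    end_time: float
    mean_cadence: float  # rpm
    left_power: float  # W, revolution mean of torque_left * omega
    isokinetic: bool
    emg_peaks: dict = field(default_factory=dict)  # muscle -> peak RMS (mV)

    def __post_init__(self) -> None:
        if not self.end_time > self.start_time:
            raise ValueError("revolution must have positive duration")
        if not np.isfinite(self.left_power):
            raise ValueError("revolution power must be finite")


@dataclass
class IsokineticResult:
    """Three-revolution isokinetic power paired with composite fractional EMG."""

    p_iso_single_leg: float
    p_iso_chainring: float
    fr_emg: float
    revolutions_used: tuple

    def __post_init__(self) -> None:
        if not np.isclose(self.p_iso_chainring, 2.0 * self.p_iso_single_leg):
            raise ValueError("chainring power must be twice single-leg power")
        if not self.fr_emg > 0:
            raise ValueError("composite fractional EMG must be positive")


# ---------------------------------------------------------------------------
# filtering and envelopes
# ---------------------------------------------------------------------------


def bandpass_filter(
    trace: EMGTrace,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 4,
) -> EMGTrace:
    """Zero-phase Butterworth band-pass of an unfiltered EMG trace.

    The filter is applied forward-backward (``sosfiltfilt``) so that
    envelope peaks stay aligned with crank angle. If ``high`` is at or
    above the Nyquist frequency it is clipped to 0.99 x Nyquist with a
    logged warning; with the sensors' own 20-450 Hz bandwidth the exact
    numerical upper edge is immaterial.
    """
    if trace.filtered:
        raise ValueError("trace is already filtered")
    if not low < high:
        raise ValueError("low cut-off must be below high cut-off")
    nyquist = trace.rate / 2.0
    if high >= nyquist:
        clipped = 0.99 * nyquist
        logger.warning(
            "band-pass upper edge %.1f Hz >= Nyquist (%.1f Hz); clipping to %.1f Hz",
            high,
            nyquist,
            clipped,
        )
        high = clipped
    sos = sps.butter(order, [low, high], btype="bandpass", fs=trace.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, trace.samples)
    return replace(trace, samples=filtered, filtered=True)


def rms_envelope(trace, window_samples: int = DEFAULT_RMS_WINDOW):
    """Trailing-window RMS envelope.

    Element ``i`` is the RMS of the samples in the window *ending* at
    ``i`` (inclusive). The first ``window_samples - 1`` elements are
    computed on the partial window, so the output has the same length
    as the input. Accepts an :class:`EMGTrace` (returns a trace whose
    samples are the envelope) or a bare array (returns an array).
    """
    is_trace = isinstance(trace, EMGTrace)
    x = trace.samples if is_trace else np.asarray(trace, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute the RMS envelope of an empty trace")
    if window_samples < 1:
        raise ValueError("window must contain at least one sample")
    if window_samples > x.size:
        raise ValueError("window longer than the trace")
    csum = np.concatenate(([0.0], np.cumsum(x * x)))
    idx = np.arange(1, x.size + 1)
    lo = np.maximum(idx - window_samples, 0)
    counts = idx - lo
    env = np.sqrt((csum[idx] - csum[lo]) / counts)
    if is_trace:
        return replace(trace, samples=env)
    return env


# ---------------------------------------------------------------------------
# crank segmentation and power
# ---------------------------------------------------------------------------


def instantaneous_power(torque: np.ndarray, angular_velocity: np.ndarray) -> np.ndarray:
    """Element-wise power (W) from torque (N m) and angular velocity (rad/s)."""
    torque = np.asarray(torque, dtype=float)
    angular_velocity = np.asarray(angular_velocity, dtype=float)
    if torque.shape != angular_velocity.shape:
        raise ValueError("torque and angular velocity must have equal length")
    if not (np.all(np.isfinite(torque)) and np.all(np.isfinite(angular_velocity))):
        raise ValueError("inputs must be finite")
    return torque * angular_velocity


def segment_revolutions(crank: CrankSignal) -> list:
    """Split a crank record into complete 360-degree revolutions.

    Revolutions start at the first sample; the trailing partial
    revolution is dropped. ``mean_cadence`` is 360 deg / duration
    expressed in rpm; ``left_power`` is the revolution mean of
    ``torque_left * angular_velocity`` over the samples in the
    revolution. A revolution is flagged isokinetic when the majority of
    its samples are in isokinetic mode.
    """
    if len(crank) == 0:
        return []
    rel = crank.angle - crank.angle[0]
    # tiny tolerance so an exact 360 k endpoint counts as complete
    n_rev = int(np.floor(rel[-1] / 360.0 + 1e-9))
    if n_rev < 1:
        return []
    bounds = np.searchsorted(rel, 360.0 * np.arange(n_rev + 1) - 1e-9, side="left")
    revolutions = []
    power = crank.torque_left * crank.angular_velocity
    for k in range(n_rev):
        i0, i1 = bounds[k], bounds[k + 1]
        start = crank.time[i0]
        end = crank.time[i1] if i1 < len(crank) else crank.time[-1]
        duration = end - start
        iso = np.count_nonzero(crank.mode[i0:i1] == ISOKINETIC) * 2 >= (i1 - i0)
        revolutions.append(
            Revolution(
                index=k,
                start_time=start,
                end_time=end,
                mean_cadence=60.0 / duration,
                left_power=float(np.mean(power[i0:i1])),
                isokinetic=bool(iso),
            )
        )
    return revolutions


def revolution_peak_emg(envelope: EMGTrace, revolution: Revolution) -> float:
    """Maximum envelope value within ``[start_time, end_time)`` of a revolution."""
    t = envelope.times
    mask = (t >= revolution.start_time) & (t < revolution.end_time)
    if not np.any(mask):
        raise ValueError(
            f"envelope has no samples inside revolution {revolution.index} "
            f"[{revolution.start_time:.3f}, {revolution.end_time:.3f}) s"
        )
    return float(np.max(envelope.samples[mask]))


def select_isokinetic_revolutions(
    revolutions: Sequence[Revolution],
    target_rpm: float = DEFAULT_TARGET_RPM,
    tolerance_fraction: float = DEFAULT_CADENCE_TOLERANCE,
) -> tuple:
    """Pick three consecutive cadence-constrained isokinetic revolutions.

    All length-3 runs of consecutive revolutions that are isokinetic and
    within ``tolerance_fraction`` of the target cadence qualify; the run
    with the highest mean left power wins (maximal-effort intent), ties
    going to the earliest run. Returns the three list indices.
    """
    n_iso = sum(1 for r in revolutions if r.isokinetic)
    if n_iso < 3:
        raise ValueError(f"need at least 3 isokinetic revolutions, have {n_iso}")
    ok = [
        r.isokinetic and abs(r.mean_cadence - target_rpm) / target_rpm <= tolerance_fraction
        for r in revolutions
    ]
    best: tuple | None = None
    best_power = -np.inf
    for i in range(len(revolutions) - 2):
        if ok[i] and ok[i + 1] and ok[i + 2]:
            mean_power = np.mean([revolutions[j].left_power for j in (i, i + 1, i + 2)])
            if mean_power > best_power:  # strict: ties keep the earliest run
                best_power = mean_power
                best = (i, i + 1, i + 2)
    if best is None:
        near = min(
            (r for r in revolutions if r.isokinetic),
            key=lambda r: abs(r.mean_cadence - target_rpm),
        )
        raise ValueError(
            "no run of 3 consecutive revolutions within "
            f"{100 * tolerance_fraction:.0f}% of {target_rpm:.0f} rpm; best near-miss: "
            f"revolution {near.index} at {near.mean_cadence:.1f} rpm"
        )
    return best


# ---------------------------------------------------------------------------
# composite EMG and the paired EMG / P_iso datum
# ---------------------------------------------------------------------------


def composite_fr_emg(per_muscle_peaks: Mapping, visit_max_per_muscle: Mapping) -> float:
    """Four-muscle composite fractional EMG.

    Each muscle's peak is normalized to its own visit maximum and the
    four fractions are averaged without weighting.
    """
    fractions = []
    for muscle in MUSCLES:
        peak = per_muscle_peaks[muscle]
        vmax = visit_max_per_muscle[muscle]
        if not vmax > 0:
            raise ValueError(f"visit maximum for {muscle} must be positive")
        fractions.append(peak / vmax)
    return float(np.mean(fractions))


def revolution_features(
    crank: CrankSignal,
    traces: Sequence[EMGTrace],
    band=DEFAULT_BAND,
    window_samples: int = DEFAULT_RMS_WINDOW,
) -> list:
    """Segment a crank record and attach per-muscle RMS peaks to each revolution.

    ``traces`` must contain one trace per muscle in :data:`MUSCLES`
    (any order). Unfiltered traces are band-passed first.
    """
    by_muscle = {tr.muscle: tr for tr in traces}
    missing = [m for m in MUSCLES if m not in by_muscle]
    if missing:
        raise ValueError(f"missing EMG traces for muscles: {missing}")
    envelopes = {}
    for muscle in MUSCLES:
        tr = by_muscle[muscle]
        if not tr.filtered:
            tr = bandpass_filter(tr, band[0], band[1])
        envelopes[muscle] = rms_envelope(tr, window_samples)
    revolutions = segment_revolutions(crank)
    for rev in revolutions:
        rev.emg_peaks = {
            muscle: revolution_peak_emg(envelopes[muscle], rev) for muscle in MUSCLES
        }
    return revolutions


def visit_maxima(revolution_groups: Sequence[Sequence[Revolution]]) -> dict:
    """Per-muscle maximum per-revolution RMS peak over every bout in a visit.

    The denominator for fractional EMG. Pass the revolution lists of all
    isokinetic bouts in the visit (baseline efforts plus the
    end-exercise bout).
    """
    maxima = {muscle: 0.0 for muscle in MUSCLES}
    for revs in revolution_groups:
        for rev in revs:
            for muscle in MUSCLES:
                peak = rev.emg_peaks.get(muscle)
                if peak is not None and peak > maxima[muscle]:
                    maxima[muscle] = peak
    return maxima


def isokinetic_result(
    crank: CrankSignal,
    traces: Sequence[EMGTrace],
    visit_max_per_muscle: Mapping,
    target_rpm: float = DEFAULT_TARGET_RPM,
    tolerance_fraction: float = DEFAULT_CADENCE_TOLERANCE,
    band=DEFAULT_BAND,
    window_samples: int = DEFAULT_RMS_WINDOW,
) -> IsokineticResult:
    """Three-revolution isokinetic power paired with composite fractional EMG.

    Left-crank power is averaged over the three selected revolutions;
    the EMG datum is the mean of the three per-revolution four-muscle
    composites (normalized to the visit maxima). Chainring power is
    reported as twice one leg.
    """
    revolutions = revolution_features(crank, traces, band=band, window_samples=window_samples)
    return isokinetic_result_from_revolutions(
        revolutions, visit_max_per_muscle, target_rpm, tolerance_fraction
    )


def isokinetic_result_from_revolutions(
    revolutions: Sequence[Revolution],
    visit_max_per_muscle: Mapping,
    target_rpm: float = DEFAULT_TARGET_RPM,
    tolerance_fraction: float = DEFAULT_CADENCE_TOLERANCE,
) -> IsokineticResult:
    """As :func:`isokinetic_result`, starting from featured revolutions."""
    selected = select_isokinetic_revolutions(revolutions, target_rpm, tolerance_fraction)
    p_iso = float(np.mean([revolutions[i].left_power for i in selected]))
    fr = float(
        np.mean(
            [
                composite_fr_emg(revolutions[i].emg_peaks, visit_max_per_muscle)
                for i in selected
            ]
        )
    )
    return IsokineticResult(
        p_iso_single_leg=p_iso,
        p_iso_chainring=2.0 * p_iso,
        fr_emg=fr,
        revolutions_used=selected,
    )
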