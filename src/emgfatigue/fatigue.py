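"""Baseline EMG-power regression and fatigue decomposition.

The baseline relationship between composite fractional EMG and
single-leg isokinetic power is fit by ordinary least squares. The drop
in maximal isokinetic power at end-exercise (performance fatigue, PF)
is apportioned into the power equivalent of the reduction in maximal
evocable EMG (activation fatigue, AF) and the residual deficit at the
measured EMG (muscle fatigue, MF = max(0, PF - AF)).

All PF/AF/MF values are single-leg watts; the power reserve uses
chainring (twice one-leg) watts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_INTOLERANCE_RPM = 60.0
DEFAULT_INTOLERANCE_DWELL_S = 5.0


@dataclass
class BaselineRelationship:
    """Least-squares fit of single-leg isokinetic power on fractional EMG."""

    slope: float  # W per unit fractional EMG
    intercept: float  # W
    r_squared: float
    n_points: int
    max_point: tuple  # (fr_emg, p_iso) of the point with the largest fr_emg

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("baseline slope must be positive")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared out of range")
        if self.n_points < 4:
            raise ValueError("baseline requires at least 4 points")

    def predict(self, fr_emg: float) -> float:
        """Expected single-leg power at a given fractional EMG."""
        return self.slope * fr_emg + self.intercept


@dataclass
class FatigueIndices:
    """PF / AF / MF bundle for one trial endpoint (single-leg W)."""

    pf: float
    af: float
    mf: float
    p_iso_baseline_max: float
    p_iso_end: float
    fr_emg_baseline_max: float
    fr_emg_end: float
    clamp_active: bool
    power_reserve_chainring: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mf < 0:
            raise ValueError("muscle fatigue is clamped at 0 W and cannot be negative")


def fit_baseline(points: Sequence) -> BaselineRelationship:
    """Fit the baseline fractional-EMG vs isokinetic-power relationship.

    Parameters
    ----------
    points : sequence of (fr_emg, p_iso_single_leg) pairs, at least 4.

    Ordinary least squares with a free intercept; ``r_squared`` is the
    squared Pearson correlation. The max point is the observation with
    the largest fractional EMG (it anchors the decomposition).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (fr_emg, p_iso) pairs")
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 baseline points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) <= 0:
        raise ValueError("fractional EMG values are degenerate (no spread)")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    syy = float(np.sum((y - ym) ** 2))
    slope = sxy / sxx
    intercept = ym - slope * xm
    if slope <= 0:
        raise ValueError(
            f"non-physiological baseline session: fitted slope {slope:.2f} W <= 0"
        )
    r_squared = 1.0 if syy == 0 else min(1.0, sxy * sxy / (sxx * syy))
    imax = int(np.argmax(x))
    return BaselineRelationship(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        n_points=pts.shape[0],
        max_point=(float(x[imax]), float(y[imax])),
    )


def decompose(
    baseline: BaselineRelationship,
    end_p_iso: float,
    end_fr_emg: float,
    task_power: Optional[float] = None,
) -> FatigueIndices:
    """Apportion end-exercise performance fatigue into AF and MF.

    PF is the drop in single-leg isokinetic power from the baseline
    maximum point; AF is the baseline slope times the drop in fractional
    EMG from that same point (it may be negative when end-exercise EMG
    exceeds the baseline maximum -- reported, not clamped); MF is the
    balance clamped at 0 W. If ``task_power`` (chainring W) is given the
    chainring power reserve is attached.
    """
    if not (end_p_iso > 0 and end_fr_emg > 0):
        raise ValueError("end-exercise power and fractional EMG must be positive")
    fr_base, p_base = baseline.max_point
    pf = p_base - end_p_iso
    af = baseline.slope * (fr_base - end_fr_emg)
    mf = max(0.0, pf - af)
    clamp = pf - af < 0
    if clamp:
        logger.info("MF clamp active: PF - AF = %.2f W < 0", pf - af)
    reserve = None
    if task_power is not None:
        reserve = power_reserve(2.0 * end_p_iso, task_power)
    return FatigueIndices(
        pf=pf,
        af=af,
        mf=mf,
        p_iso_baseline_max=p_base,
        p_iso_end=end_p_iso,
        fr_emg_baseline_max=fr_base,
        fr_emg_end=end_fr_emg,
        clamp_active=bool(clamp),
        power_reserve_chainring=reserve,
    )


def detect_intolerance(
    time: np.ndarray,
    cadence_rpm: np.ndarray,
    threshold_rpm: float = DEFAULT_INTOLERANCE_RPM,
    dwell_s: float = DEFAULT_INTOLERANCE_DWELL_S,
) -> Optional[float]:
    """First time the cadence stays below threshold for the dwell duration.

    Returns the start of the first contiguous sub-threshold run lasting
    at least ``dwell_s`` seconds (the moment the task can no longer be
    sustained), or ``None`` if cadence never fails. The series should be
    sampled at >= 1 Hz for a meaningful result.
    """
    time = np.asarray(time, dtype=float)
    cadence_rpm = np.asarray(cadence_rpm, dtype=float)
    if time.shape != cadence_rpm.shape:
        raise ValueError("time and cadence must have equal length")
    below = cadence_rpm < threshold_rpm
    if not np.any(below):
        return None
    # run boundaries on the boolean series
    edges = np.flatnonzero(np.diff(below.astype(int)))
    starts = [0] if below[0] else []
    starts += [int(i) + 1 for i in edges if below[i + 1]]
    ends = [int(i) + 1 for i in edges if below[i]]  # first index after the run
    if below[-1]:
        ends.append(time.size)
    for s, e in zip(starts, ends):
        run_end = time[e] if e < time.size else time[-1]
        if run_end - time[s] >= dwell_s:
            return float(time[s])
    return None


def power_reserve(p_iso_chainring_end: float, task_power: float) -> float:
    """Chainring isokinetic power at intolerance minus the task power (W)."""
    if p_iso_chainring_end < 0 or task_power < 0:
        raise ValueError("powers must be non-negative")
    reserve = p_iso_chainring_end - task_power
    if reserve < 0:
        logger.warning(
            "negative power reserve (%.1f W): end isokinetic power below task power",
            reserve,
        )
    return reserve
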