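"""Operating lung volumes during exercise.

Inspiratory capacity (IC) manoeuvres performed in duplicate at baseline,
isotime and the limit of tolerance are combined with a 20 s mean tidal
volume preceding each manoeuvre to give the inspiratory reserve volume,
IRV = IC - VT. Condition deltas (resistance at its limit minus the
isotime control) quantify dynamic hyperinflation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("baseline", "isotime", "limit_of_tolerance")

#: Replicate IC manoeuvres differing by more than this fraction are flagged.
IC_DISCORDANCE_FRACTION = 0.10

TIDAL_WINDOW_S = 20.0


@dataclass
class BreathRecord:
    """One breath-by-breath row: tidal volume, ventilation and gas exchange."""

    time: float  # s
    vt: float  # L
    ve: float  # L/min
    vo2: float  # L/min
    vco2: float  # L/min

    def __post_init__(self) -> None:
        if not self.vt > 0:
            raise ValueError("tidal volume must be positive")


@dataclass
class ICManoeuvre:
    """A single inspiratory-capacity manoeuvre (EELV to TLC)."""

    time: float  # s
    inspired_volume: float  # L
    replicate: int
    stage: str = "baseline"

    def __post_init__(self) -> None:
        if not self.inspired_volume > 0:
            raise ValueError("inspired volume must be positive")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")


@dataclass
class ICEstimate:
    """Reconciled duplicate IC manoeuvres."""

    value: float  # L, mean of replicates
    n_replicates: int
    discordant: bool  # replicates differ by > 10%
    single: bool  # only one replicate available


@dataclass
class LungVolumes:
    """IC, matched 20 s tidal volume and IRV at one stage."""

    stage: str
    ic: float  # L
    vt20: float  # L
    irv: float  # L (= ic - vt20; may be <= 0, flagged)
    flags: tuple = ()

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")


def _breath_frame(breaths) -> pd.DataFrame:
    if isinstance(breaths, pd.DataFrame):
        df = breaths
    else:
        df = pd.DataFrame(
            {
                "time_s": [b.time for b in breaths],
                "vt_l": [b.vt for b in breaths],
            }
        )
    if not df["time_s"].is_monotonic_increasing:
        raise ValueError("breath times must be increasing")
    return df


def tidal_volume_20s(breaths, manoeuvre_time: float) -> float:
    """Mean tidal volume over the 20 s preceding an IC manoeuvre.

    Breaths whose time falls in the half-open window
    ``(manoeuvre_time - 20, manoeuvre_time]`` contribute, unweighted.
    """
    df = _breath_frame(breaths)
    window = df[
        (df["time_s"] > manoeuvre_time - TIDAL_WINDOW_S)
        & (df["time_s"] <= manoeuvre_time)
    ]
    if window.empty:
        raise ValueError(
            f"no breaths in the 20 s window ending at {manoeuvre_time:.1f} s"
        )
    return float(window["vt_l"].mean())


def inspiratory_capacity(manoeuvres: Sequence[ICManoeuvre]) -> ICEstimate:
    """Reconcile duplicate IC manoeuvres by their mean.

    Replicates differing by more than 10% (relative to their mean) are
    flagged discordant but still averaged; a lone replicate is flagged
    single.
    """
    if len(manoeuvres) == 0:
        raise ValueError("at least one IC manoeuvre is required")
    volumes = np.array([m.inspired_volume for m in manoeuvres], dtype=float)
    value = float(volumes.mean())
    discordant = False
    if volumes.size >= 2:
        discordant = bool(np.ptp(volumes) / value > IC_DISCORDANCE_FRACTION)
        if discordant:
            logger.warning(
                "discordant IC replicates %s L (spread > %.0f%%)",
                np.round(volumes, 2).tolist(),
                100 * IC_DISCORDANCE_FRACTION,
            )
    single = volumes.size == 1
    if single:
        logger.info("single IC replicate %.2f L", value)
    return ICEstimate(
        value=value, n_replicates=int(volumes.size), discordant=discordant, single=single
    )


def stage_volumes(breaths, manoeuvres: Sequence[ICManoeuvre], stage: str) -> LungVolumes:
    """IC, 20 s tidal volume and IRV for one stage.

    The tidal volume is matched per replicate (20 s window before each
    manoeuvre) and averaged alongside the IC replicates. A negative IRV
    is flagged, never clamped: values near zero are physiologically
    meaningful at the limit of tolerance and clamping would bias deltas.
    """
    stage_man = [m for m in manoeuvres if m.stage == stage]
    if not stage_man:
        raise ValueError(f"no IC manoeuvres for stage {stage!r}")
    ic = inspiratory_capacity(stage_man)
    vt20 = float(np.mean([tidal_volume_20s(breaths, m.time) for m in stage_man]))
    irv = ic.value - vt20
    flags = []
    if ic.discordant:
        flags.append("ic_discordant")
    if ic.single:
        flags.append("ic_single_replicate")
    if irv <= 0:
        flags.append("irv_nonpositive")
        logger.warning("IRV %.2f L <= 0 at stage %s (flagged, not clamped)", irv, stage)
    return LungVolumes(stage=stage, ic=ic.value, vt20=vt20, irv=irv, flags=tuple(flags))


def hyperinflation_delta(
    resistance_lot: LungVolumes, isotime_control: LungVolumes
) -> tuple:
    """(delta IC, delta IRV) as resistance-at-limit minus isotime-control.

    More negative delta IRV means more dynamic hyperinflation.
    """
    return (
        resistance_lot.ic - isotime_control.ic,
        resistance_lot.irv - isotime_control.irv,
    )
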