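"""Delimited-table readers/writers, run configuration and the data layout.

All artefacts are plain UTF-8 delimited text with a header row. Readers
auto-detect comma vs tab delimiters; writers default to comma. Schemas:

* EMG table: ``time_s, vl_mv, rf_mv, vm_mv, lg_mv``
* crank table: ``time_s, angle_deg, torque_left_nm, torque_right_nm,
  omega_rad_s, mode``
* breath table: ``time_s, vt_l, ve_l_min, vo2_l_min, vco2_l_min``
* IC manoeuvre table: ``time_s, stage, replicate, inspired_volume_l``
* truth sidecar: ``time_s, true_max_emg_fraction, true_muscle_deficit_w,
  true_irv_l``

Raw signal tables are written at %.10g (lossless round-trip to the
declared precision); report tables are written at fixed precision
(0.01 W, 0.01 L, 0.1 s) for reproducible diffs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .lungmech import ICManoeuvre, STAGES
from .sigproc import (
    MUSCLE_COLUMNS,
    MUSCLES,
    CrankSignal,
    EMGTrace,
    HYPERBOLIC,
    ISOKINETIC,
)
from .synth import SyntheticTruth, TrialDataset

logger = logging.getLogger(__name__)

EMG_COLUMNS = ["time_s"] + [MUSCLE_COLUMNS[m] for m in MUSCLES]
CRANK_COLUMNS = [
    "time_s",
    "angle_deg",
    "torque_left_nm",
    "torque_right_nm",
    "omega_rad_s",
    "mode",
]
BREATH_COLUMNS = ["time_s", "vt_l", "ve_l_min", "vo2_l_min", "vco2_l_min"]
IC_COLUMNS = ["time_s", "stage", "replicate", "inspired_volume_l"]
TRUTH_COLUMNS = [
    "time_s",
    "true_max_emg_fraction",
    "true_muscle_deficit_w",
    "true_irv_l",
]

SIGNAL_FLOAT_FORMAT = "%.10g"

#: interval (s) kept between hyperbolic-mode crank samples on disk; the
#: isokinetic phase is always written at full 2-degree resolution
HYPERBOLIC_WRITE_INTERVAL_S = 0.2


class SchemaError(ValueError):
    """A delimited table does not match its declared schema."""


def _read_table(path, required_columns: Sequence[str]) -> pd.DataFrame:
    # sep=None lets pandas sniff comma vs tab consistently
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def _write_table(df: pd.DataFrame, path, delimiter: str = ",", float_format=SIGNAL_FLOAT_FORMAT):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=delimiter, index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------


def write_emg_table(traces: Sequence[EMGTrace], path, delimiter: str = ",") -> None:
    """Write the four muscle traces of one bout as a single table."""
    by_muscle = {tr.muscle: tr for tr in traces}
    missing = [m for m in MUSCLES if m not in by_muscle]
    if missing:
        raise ValueError(f"missing traces for muscles {missing}")
    ref = by_muscle[MUSCLES[0]]
    data = {"time_s": ref.times}
    for m in MUSCLES:
        tr = by_muscle[m]
        if len(tr) != len(ref) or tr.rate != ref.rate or tr.t0 != ref.t0:
            raise ValueError("EMG traces of a bout must share the same time base")
        data[MUSCLE_COLUMNS[m]] = tr.samples
    _write_table(pd.DataFrame(data), path, delimiter)


def read_emg_table(path) -> list:
    """Read one bout's EMG table into four :class:`EMGTrace` objects."""
    df = _read_table(path, EMG_COLUMNS)
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise SchemaError(f"{path}: EMG table needs at least two samples")
    rate = 1.0 / float(np.median(np.diff(t)))
    return [
        EMGTrace(
            samples=df[MUSCLE_COLUMNS[m]].to_numpy(),
            rate=rate,
            muscle=m,
            t0=float(t[0]),
        )
        for m in MUSCLES
    ]


# ---------------------------------------------------------------------------
# crank
# ---------------------------------------------------------------------------


def crank_to_frame(crank: CrankSignal) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": crank.time,
            "angle_deg": crank.angle,
            "torque_left_nm": crank.torque_left,
            "torque_right_nm": crank.torque_right,
            "omega_rad_s": crank.angular_velocity,
            "mode": crank.mode,
        }
    )


def write_crank_table(
    crank: CrankSignal,
    path,
    delimiter: str = ",",
    decimate_hyperbolic: bool = False,
) -> None:
    """Write a crank record; optionally thin the hyperbolic-mode samples.

    Long constant-power phases carry no per-revolution information the
    pipeline needs beyond the cadence trace, so on request hyperbolic
    samples are kept only every ~0.2 s (cumulative angle stays intact,
    well above the 1 Hz floor needed for intolerance detection) while
    isokinetic samples are written at full resolution.
    """
    df = crank_to_frame(crank)
    if decimate_hyperbolic and len(df):
        hyper = df["mode"] == HYPERBOLIC
        bins = np.floor(df["time_s"].to_numpy() / HYPERBOLIC_WRITE_INTERVAL_S)
        first_in_bin = np.ones(len(df), dtype=bool)
        first_in_bin[1:] = bins[1:] != bins[:-1]
        df = df[~hyper | first_in_bin]
    _write_table(df, path, delimiter)


def read_crank_table(path) -> CrankSignal:
    df = _read_table(path, CRANK_COLUMNS)
    return CrankSignal(
        time=df["time_s"].to_numpy(),
        angle=df["angle_deg"].to_numpy(),
        torque_left=df["torque_left_nm"].to_numpy(),
        torque_right=df["torque_right_nm"].to_numpy(),
        angular_velocity=df["omega_rad_s"].to_numpy(),
        mode=df["mode"].to_numpy(dtype=object),
    )


# ---------------------------------------------------------------------------
# breaths, IC manoeuvres, truth sidecar
# ---------------------------------------------------------------------------


def write_breath_table(breaths: pd.DataFrame, path, delimiter: str = ",") -> None:
    _write_table(breaths[BREATH_COLUMNS], path, delimiter)


def read_breath_table(path) -> pd.DataFrame:
    df = _read_table(path, BREATH_COLUMNS)
    vt = df["vt_l"]
    if ((vt < 0.2) | (vt > 6.0)).any():
        logger.warning("%s: tidal volumes outside the plausible 0.2-6 L range", path)
    if not df["time_s"].is_monotonic_increasing:
        raise SchemaError(f"{path}: breath times must be strictly increasing")
    return df.astype({c: float for c in BREATH_COLUMNS})


def write_ic_table(manoeuvres: Sequence[ICManoeuvre], path, delimiter: str = ",") -> None:
    df = pd.DataFrame(
        {
            "time_s": [m.time for m in manoeuvres],
            "stage": [m.stage for m in manoeuvres],
            "replicate": [m.replicate for m in manoeuvres],
            "inspired_volume_l": [m.inspired_volume for m in manoeuvres],
        }
    )
    _write_table(df, path, delimiter)


def read_ic_table(path) -> list:
    df = _read_table(path, IC_COLUMNS)
    bad = set(df["stage"]) - set(STAGES)
    if bad:
        raise SchemaError(f"{path}: unknown stages {sorted(bad)}")
    return [
        ICManoeuvre(
            time=float(r.time_s),
            inspired_volume=float(r.inspired_volume_l),
            replicate=int(r.replicate),
            stage=str(r.stage),
        )
        for r in df.itertuples()
    ]


def write_truth_table(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    _write_table(df[TRUTH_COLUMNS], path, delimiter)


def read_truth_table(path) -> pd.DataFrame:
    return _read_table(path, TRUTH_COLUMNS).astype({c: float for c in TRUTH_COLUMNS})


# ---------------------------------------------------------------------------
# trial directory layout
# ---------------------------------------------------------------------------


def write_trial_dataset(dataset: TrialDataset, truth: SyntheticTruth, trial_dir) -> None:
    """Write one visit (baseline bouts + trial + sidecars) under ``trial_dir``."""
    trial_dir = Path(trial_dir)
    trial_dir.mkdir(parents=True, exist_ok=True)
    for k, (traces, crank) in enumerate(
        zip(dataset.baseline_emg, dataset.baseline_crank), start=1
    ):
        write_emg_table(traces, trial_dir / f"bout{k}_emg.csv")
        write_crank_table(crank, trial_dir / f"bout{k}_crank.csv")
    write_crank_table(
        dataset.trial_crank, trial_dir / "trial_crank.csv", decimate_hyperbolic=True
    )
    write_emg_table(dataset.end_emg, trial_dir / "end_emg.csv")
    write_breath_table(dataset.breaths, trial_dir / "breath.csv")
    write_ic_table(dataset.ic_manoeuvres, trial_dir / "ic.csv")
    from .synth import truth_table  # local import to avoid cycle at module load

    grid = np.arange(0.0, dataset.tolerance_time_s + 1.0, 1.0)
    write_truth_table(truth_table(truth, grid), trial_dir / "truth.csv")
    meta = {
        "participant_id": dataset.participant_id,
        "condition": dataset.condition,
        "task_power_w": dataset.task_power_w,
        "tolerance_time_s": dataset.tolerance_time_s,
        "at_intolerance": dataset.at_intolerance,
        "borg": dataset.borg,
        "vo2peak_l_min": dataset.vo2peak_l_min,
        "n_baseline_bouts": len(dataset.baseline_crank),
    }
    (trial_dir / "meta.json").write_text(json.dumps(meta, indent=2))


def read_trial_dataset(trial_dir) -> TrialDataset:
    """Reconstruct a :class:`TrialDataset` from a trial directory."""
    trial_dir = Path(trial_dir)
    meta = json.loads((trial_dir / "meta.json").read_text())
    n_bouts = int(meta["n_baseline_bouts"])
    baseline_emg, baseline_crank = [], []
    for k in range(1, n_bouts + 1):
        baseline_emg.append(read_emg_table(trial_dir / f"bout{k}_emg.csv"))
        baseline_crank.append(read_crank_table(trial_dir / f"bout{k}_crank.csv"))
    return TrialDataset(
        participant_id=meta["participant_id"],
        condition=meta["condition"],
        task_power_w=float(meta["task_power_w"]),
        tolerance_time_s=float(meta["tolerance_time_s"]),
        at_intolerance=bool(meta["at_intolerance"]),
        baseline_emg=baseline_emg,
        baseline_crank=baseline_crank,
        trial_crank=read_crank_table(trial_dir / "trial_crank.csv"),
        end_emg=read_emg_table(trial_dir / "end_emg.csv"),
        breaths=read_breath_table(trial_dir / "breath.csv"),
        ic_manoeuvres=read_ic_table(trial_dir / "ic.csv"),
        borg=meta["borg"],
        vo2peak_l_min=float(meta["vo2peak_l_min"]),
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Pipeline run configuration; any CLI flag overrides a config-file value."""

    out_dir: str = "emgfatigue_out"
    n_participants: int = 14
    seed: int = 1
    conditions: tuple = ("control", "resistance", "isotime_control")
    noise_free: bool = False
    cadence_target: float = 70.0
    filter_low_hz: float = 10.0
    filter_high_hz: float = 500.0
    rms_window_samples: int = 200
    isokinetic_tolerance: float = 0.05
    intolerance_threshold_rpm: float = 60.0
    intolerance_dwell_s: float = 5.0
    delimiter: str = ","

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if not 0 < self.isokinetic_tolerance < 1:
            raise ConfigError("isokinetic_tolerance must lie in (0, 1)")
        if not 0 < self.filter_low_hz < self.filter_high_hz:
            raise ConfigError("filter band must satisfy 0 < low < high")
        if self.rms_window_samples < 1:
            raise ConfigError("rms_window_samples must be >= 1")
        unknown = set(self.conditions) - {"control", "resistance", "isotime_control"}
        if unknown:
            raise ConfigError(f"unknown conditions {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"{path}: unknown config keys {sorted(bad)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "conditions" in raw and raw["conditions"] is not None:
            raw["conditions"] = tuple(raw["conditions"])
        return cls(**raw)

    def defaulted_parameters(self) -> dict:
        """Every tunable with its effective value (for the run log)."""
        return dataclasses.asdict(self)
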