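"""End-to-end orchestration: simulate -> sigproc -> fatigue -> lungmech -> stats.

:func:`analyze_trial` turns one visit's raw signals into a
:class:`~emgfatigue.stats.TrialSummary`; :func:`run_pipeline` simulates a
cohort, writes the raw data tree, re-reads it through the table readers
(so the full I/O path is exercised), analyses every trial and writes the
report tables plus a run log.
"""

from __future__ import annotations

import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import fatigue as fat
from . import lungmech, sigproc, stats, synth
from .io import RunConfig, read_trial_dataset, write_trial_dataset
from .sigproc import HYPERBOLIC, ISOKINETIC
from .stats import TrialSummary
from .synth import SimConfig, TrialDataset

logger = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """Knobs of the measurement pipeline (defaults match the protocol)."""

    band: tuple = (10.0, 500.0)
    rms_window_samples: int = 200
    target_rpm: float = 70.0
    cadence_tolerance: float = 0.05
    intolerance_threshold_rpm: float = 60.0
    intolerance_dwell_s: float = 5.0

    @classmethod
    def from_run_config(cls, cfg: RunConfig) -> "AnalysisParams":
        return cls(
            band=(cfg.filter_low_hz, cfg.filter_high_hz),
            rms_window_samples=cfg.rms_window_samples,
            target_rpm=cfg.cadence_target,
            cadence_tolerance=cfg.isokinetic_tolerance,
            intolerance_threshold_rpm=cfg.intolerance_threshold_rpm,
            intolerance_dwell_s=cfg.intolerance_dwell_s,
        )


@dataclass
class TrialAnalysis:
    """Full analysis bundle for one visit."""

    summary: TrialSummary
    baseline: fat.BaselineRelationship
    indices: fat.FatigueIndices
    baseline_points: list  # (fr_emg, p_iso_single_leg) per bout
    volumes: dict  # stage -> LungVolumes
    detected_intolerance_s: Optional[float]
    end_result: sigproc.IsokineticResult


def baseline_relationship_from_session(
    emg_bouts: Sequence,
    crank_bouts: Sequence,
    params: AnalysisParams = AnalysisParams(),
) -> fat.BaselineRelationship:
    """Fit the EMG-power baseline from a baseline-only session.

    Visit maxima are taken over all bouts of the session; each bout
    contributes one (fr_emg, P_iso) point.
    """
    revs = [
        sigproc.revolution_features(
            crank, traces, band=params.band, window_samples=params.rms_window_samples
        )
        for traces, crank in zip(emg_bouts, crank_bouts)
    ]
    maxima = sigproc.visit_maxima(revs)
    points = []
    for bout_revs in revs:
        res = sigproc.isokinetic_result_from_revolutions(
            bout_revs, maxima, params.target_rpm, params.cadence_tolerance
        )
        points.append((res.fr_emg, res.p_iso_single_leg))
    return fat.fit_baseline(points)


def analyze_trial(
    dataset: TrialDataset, params: AnalysisParams = AnalysisParams()
) -> TrialAnalysis:
    """Process one visit end to end (no ground truth involved).

    The visit maximum for EMG normalization is the per-muscle maximum
    over every isokinetic bout of the visit: the eight baseline efforts
    plus the end-exercise bout. When the end-exercise bout sets the
    visit maximum for a muscle (possible only through noise), a warning
    is logged because the two normalization conventions then diverge.
    """
    bout_revs = [
        sigproc.revolution_features(
            crank, traces, band=params.band, window_samples=params.rms_window_samples
        )
        for traces, crank in zip(dataset.baseline_emg, dataset.baseline_crank)
    ]
    iso_mask = dataset.trial_crank.mode == ISOKINETIC
    end_crank = dataset.trial_crank.subset(iso_mask)
    end_revs = sigproc.revolution_features(
        end_crank,
        dataset.end_emg,
        band=params.band,
        window_samples=params.rms_window_samples,
    )
    baseline_maxima = sigproc.visit_maxima(bout_revs)
    maxima = sigproc.visit_maxima(bout_revs + [end_revs])
    divergent = [m for m in sigproc.MUSCLES if maxima[m] > baseline_maxima[m]]
    if divergent:
        logger.warning(
            "%s/%s: end-exercise EMG exceeds the baseline maximum for %s; "
            "visit-maximum normalization used",
            dataset.participant_id,
            dataset.condition,
            divergent,
        )

    points = []
    for revs in bout_revs:
        res = sigproc.isokinetic_result_from_revolutions(
            revs, maxima, params.target_rpm, params.cadence_tolerance
        )
        points.append((res.fr_emg, res.p_iso_single_leg))
    baseline = fat.fit_baseline(points)
    end_result = sigproc.isokinetic_result_from_revolutions(
        end_revs, maxima, params.target_rpm, params.cadence_tolerance
    )
    indices = fat.decompose(
        baseline,
        end_result.p_iso_single_leg,
        end_result.fr_emg,
        task_power=dataset.task_power_w,
    )

    hyper = dataset.trial_crank.mode == HYPERBOLIC
    detected = fat.detect_intolerance(
        dataset.trial_crank.time[hyper],
        dataset.trial_crank.cadence_rpm[hyper],
        threshold_rpm=params.intolerance_threshold_rpm,
        dwell_s=params.intolerance_dwell_s,
    )
    tolerance = detected if detected is not None else dataset.tolerance_time_s
    if dataset.at_intolerance and detected is None:
        logger.warning(
            "%s/%s: no intolerance detected in a trial flagged as run to the limit",
            dataset.participant_id,
            dataset.condition,
        )

    stages = sorted({m.stage for m in dataset.ic_manoeuvres})
    volumes = {
        stage: lungmech.stage_volumes(dataset.breaths, dataset.ic_manoeuvres, stage)
        for stage in stages
    }
    lot = volumes.get("limit_of_tolerance")
    end_borg = dataset.borg.get("limit_of_tolerance", {})

    summary = TrialSummary(
        participant_id=dataset.participant_id,
        condition=dataset.condition,
        tolerance_time_s=float(tolerance),
        pf_w=indices.pf,
        af_w=indices.af,
        mf_w=indices.mf,
        clamp_active=indices.clamp_active,
        power_reserve_w=indices.power_reserve_chainring,
        r_squared_baseline=baseline.r_squared,
        ic_l=lot.ic if lot else np.nan,
        irv_l=lot.irv if lot else np.nan,
        borg_dyspnoea=end_borg.get("dyspnoea", np.nan),
        borg_leg=end_borg.get("leg", np.nan),
        vo2peak_l_min=float(dataset.breaths["vo2_l_min"].max()),
    )
    return TrialAnalysis(
        summary=summary,
        baseline=baseline,
        indices=indices,
        baseline_points=points,
        volumes=volumes,
        detected_intolerance_s=detected,
        end_result=end_result,
    )


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------

REPORT_PRECISION = {
    "w": 2,  # 0.01 W
    "l": 2,  # 0.01 L
    "s": 1,  # 0.1 s
}


def _sim_config(cfg: RunConfig) -> SimConfig:
    sim = SimConfig(
        n_participants=cfg.n_participants,
        seed=cfg.seed,
        cadence_target=cfg.cadence_target,
    )
    return synth.noise_free(sim) if cfg.noise_free else sim


def simulate_cohort(cfg: RunConfig) -> Path:
    """Generate and write the raw data tree; returns the data directory."""
    sim = _sim_config(cfg)
    data_dir = Path(cfg.out_dir) / "data"
    for pid in range(1, cfg.n_participants + 1):
        for condition in cfg.conditions:
            dataset, truth = synth.generate_constant_power_trial(sim, condition, pid)
            write_trial_dataset(
                dataset, truth, data_dir / dataset.participant_id / condition
            )
    logger.info("simulated %d participants under %s", cfg.n_participants, data_dir)
    return data_dir


def analyze_cohort(cfg: RunConfig, data_dir=None) -> stats.StudyReport:
    """Read every trial directory, analyse it, and write the report tables."""
    out = Path(cfg.out_dir)
    data_dir = Path(data_dir) if data_dir is not None else out / "data"
    params = AnalysisParams.from_run_config(cfg)
    trial_dirs = sorted(p for p in data_dir.glob("*/*") if (p / "meta.json").exists())
    if not trial_dirs:
        raise ValueError(f"no trial directories found under {data_dir}")
    summaries = []
    fatigue_rows = []
    lung_rows = []
    for trial_dir in trial_dirs:
        dataset = read_trial_dataset(trial_dir)
        analysis = analyze_trial(dataset, params)
        s = analysis.summary
        summaries.append(s)
        fatigue_rows.append(
            {
                "participant_id": s.participant_id,
                "condition": s.condition,
                "pf_w": round(s.pf_w, 2),
                "af_w": round(s.af_w, 2),
                "mf_w": round(s.mf_w, 2),
                "clamp_active": s.clamp_active,
                "power_reserve_w": round(s.power_reserve_w, 2),
                "r_squared_baseline": round(s.r_squared_baseline, 4),
                "tolerance_time_s": round(s.tolerance_time_s, 1),
            }
        )
        for stage, vol in analysis.volumes.items():
            lung_rows.append(
                {
                    "participant_id": s.participant_id,
                    "condition": s.condition,
                    "stage": stage,
                    "ic_l": round(vol.ic, 2),
                    "vt20_l": round(vol.vt20, 2),
                    "irv_l": round(vol.irv, 2),
                    "flags": ";".join(vol.flags),
                }
            )
    results = out / "results"
    results.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(fatigue_rows).to_csv(results / "fatigue_report.csv", index=False)
    pd.DataFrame(lung_rows).to_csv(results / "lung_volumes.csv", index=False)
    stats.summaries_frame(summaries).to_csv(results / "summaries.csv", index=False)
    report = stats.study_report(summaries)
    report.comparisons.to_csv(
        results / "stats_comparisons.csv", index=False, float_format="%.4g"
    )
    report.correlations.to_csv(
        results / "stats_correlations.csv", index=False, float_format="%.4g"
    )
    _write_summary_text(report, results / "summary.txt")
    return report


def _write_summary_text(report: stats.StudyReport, path: Path) -> None:
    lines = ["Paired comparisons", "==================", ""]
    for row in report.comparisons.itertuples():
        if row.note:
            lines.append(
                f"{row.endpoint}: {row.condition_a} vs {row.condition_b}, n={row.n} "
                f"-- {row.note}"
            )
        else:
            lines.append(
                f"{row.endpoint}: {row.mean_a:.2f} vs {row.mean_b:.2f} "
                f"(diff {row.mean_diff:.2f}, 95% CI {row.ci_low:.2f} to "
                f"{row.ci_high:.2f}, t({row.df:.0f}) = {row.t:.2f}, "
                f"P = {row.p:.4f}, n = {row.n})"
            )
    lines += ["", "Correlations vs delta IRV", "=========================", ""]
    for row in report.correlations.itertuples():
        if row.note:
            lines.append(f"{row.delta_endpoint}: n={row.n} -- {row.note}")
        else:
            lines.append(
                f"{row.delta_endpoint}: r = {row.r:.3f} (r^2 = {row.r_squared:.2f}, "
                f"P = {row.p:.4f}, n = {row.n})"
            )
    lines += ["", report.footer, ""]
    path.write_text("\n".join(lines))


def _write_run_log(cfg: RunConfig, path: Path) -> None:
    from importlib.metadata import version as _pkg_version

    import scipy

    sim = _sim_config(cfg)
    lines = [
        f"emgfatigue {__version__}",
        f"python {platform.python_version()}",
        f"numpy {np.__version__} scipy {scipy.__version__} pandas {pd.__version__} "
        f"click {_pkg_version('click')} pyyaml {_pkg_version('PyYAML')}",
        f"seed {cfg.seed}",
        "",
        "run configuration (every tunable, defaulted or not):",
    ]
    for key, value in cfg.defaulted_parameters().items():
        lines.append(f"  {key} = {value!r}")
    lines.append("")
    lines.append("generator configuration:")
    import dataclasses as _dc

    for f in _dc.fields(sim):
        lines.append(f"  {f.name} = {getattr(sim, f.name)!r}")
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(cfg: RunConfig) -> stats.StudyReport:
    """Simulate (if no data exist), analyse, and write every report artefact."""
    out = Path(cfg.out_dir)
    data_dir = out / "data"
    if not data_dir.exists():
        simulate_cohort(cfg)
    report = analyze_cohort(cfg, data_dir)
    _write_run_log(cfg, out / "results" / "run_log.txt")
    return report
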