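"""Paired comparisons, correlations and the study-level report.

Two-sided dependent t-tests with the 95% confidence interval of the
difference, Pearson correlations between fatigue deltas and
hyperinflation deltas, percent-change summaries and isotime alignment.
No multiple-testing correction is applied (noted in the report footer);
missing pairs are dropped per endpoint (listwise) and the per-endpoint
n is always reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

logger = logging.getLogger(__name__)


@dataclass
class PairedResult:
    """Dependent-samples t-test with the 95% CI of the mean difference."""

    mean_a: float
    mean_b: float
    mean_diff: float
    t_stat: float
    df: int
    p_value: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if self.df != self.n - 1:
            raise ValueError("df must equal n - 1")
        if not (self.ci_low <= self.mean_diff <= self.ci_high):
            raise ValueError("CI must bracket the mean difference")


@dataclass
class CorrResult:
    """Pearson product-moment correlation."""

    r: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| cannot exceed 1")
        if not math.isclose(self.r_squared, self.r * self.r, abs_tol=1e-12):
            raise ValueError("r_squared must equal r**2")


@dataclass
class TrialSummary:
    """Per-participant, per-condition endpoint bundle consumed by the report."""

    participant_id: str
    condition: str  # control | resistance | isotime_control
    tolerance_time_s: float = np.nan
    pf_w: float = np.nan
    af_w: float = np.nan
    mf_w: float = np.nan
    clamp_active: bool = False
    power_reserve_w: float = np.nan  # chainring W
    r_squared_baseline: float = np.nan
    ic_l: float = np.nan
    irv_l: float = np.nan
    borg_dyspnoea: float = np.nan
    borg_leg: float = np.nan
    vo2peak_l_min: float = np.nan


def paired_t(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> PairedResult:
    """Two-sided dependent Student's t-test on per-pair differences a - b.

    The confidence interval is ``mean_diff +/- t_{1-alpha/2, n-1} * SE``.
    Pairs with equal length >= 3 are required and the differences must
    have positive variance (a constant shift makes t undefined here).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: paired t is undefined")
    n = d.size
    se = sd / math.sqrt(n)
    mean_diff = float(d.mean())
    t_stat = mean_diff / se
    dof = n - 1
    p = 2.0 * sstats.t.sf(abs(t_stat), dof)
    tcrit = sstats.t.ppf(1 - alpha / 2, dof)
    return PairedResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        mean_diff=mean_diff,
        t_stat=float(t_stat),
        df=dof,
        p_value=float(p),
        ci_low=mean_diff - tcrit * se,
        ci_high=mean_diff + tcrit * se,
        n=n,
    )


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> CorrResult:
    """Pearson correlation with the p-value from the t transform (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sstats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrResult(r=r, r_squared=r * r, p_value=float(res.pvalue), n=x.size)


def percent_reduction(control: float, resistance: float) -> float:
    """Percent reduction relative to control: 100 (control - resistance) / control."""
    if not control > 0:
        raise ValueError("control value must be positive")
    return 100.0 * (control - resistance) / control


def isotime_align(resistance_tolerance_s: float, control_tolerance_s: float) -> float:
    """Isotime for the paired control comparison = the resistance tolerance time.

    Control-trial measurements at this time are the isotime-control
    values. A control trial shorter than the resistance trial is a
    protocol violation and is flagged.
    """
    if control_tolerance_s < resistance_tolerance_s:
        logger.warning(
            "protocol violation: control trial (%.0f s) shorter than the paired "
            "resistance trial (%.0f s)",
            control_tolerance_s,
            resistance_tolerance_s,
        )
    return float(resistance_tolerance_s)


# ---------------------------------------------------------------------------
# study-level report
# ---------------------------------------------------------------------------

#: endpoint column -> (condition providing sample a, condition providing sample b)
_PAIRED_ENDPOINTS = [
    ("tolerance_time_s", "resistance", "control"),
    ("pf_w", "resistance", "isotime_control"),
    ("af_w", "resistance", "isotime_control"),
    ("mf_w", "resistance", "isotime_control"),
    ("power_reserve_w", "resistance", "isotime_control"),
    ("ic_l", "resistance", "isotime_control"),
    ("irv_l", "resistance", "isotime_control"),
    ("borg_dyspnoea", "resistance", "isotime_control"),
    ("borg_leg", "resistance", "isotime_control"),
    ("vo2peak_l_min", "resistance", "isotime_control"),
]

#: fatigue / perception deltas correlated against the IRV delta
_DELTA_ENDPOINTS = ["pf_w", "af_w", "mf_w", "borg_leg"]

REPORT_FOOTER = (
    "Two-sided dependent t-tests; no multiple-testing correction applied. "
    "Listwise deletion per endpoint; n is reported per row."
)


@dataclass
class StudyReport:
    """Paired-comparison and correlation tables for a cohort."""

    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    footer: str = REPORT_FOOTER


def summaries_frame(summaries: Sequence[TrialSummary]) -> pd.DataFrame:
    """Long-format DataFrame of trial summaries (one row per trial)."""
    return pd.DataFrame([vars(s) for s in summaries])


def study_report(summaries: Sequence[TrialSummary]) -> StudyReport:
    """Assemble the paired comparisons and delta correlations for a cohort.

    For each endpoint, the resistance trial is compared against its
    reference condition with a dependent t-test after dropping
    participants with a missing value in either arm. Degenerate
    endpoints (zero-variance differences, n < 3) produce a row with the
    means and a note instead of a test. Correlations relate the
    resistance-minus-isotime-control deltas of PF/AF/MF and leg effort
    to the IRV delta.
    """
    long = summaries_frame(summaries)
    if long.empty or long["participant_id"].nunique() < 3:
        raise ValueError("need complete paired data for at least 3 participants")
    wide = long.pivot_table(
        index="participant_id",
        columns="condition",
        aggfunc="first",
    )

    def _column(endpoint: str, condition: str) -> pd.Series:
        try:
            return wide[(endpoint, condition)]
        except KeyError:
            return pd.Series(np.nan, index=wide.index)

    rows = []
    for endpoint, cond_a, cond_b in _PAIRED_ENDPOINTS:
        a = _column(endpoint, cond_a)
        b = _column(endpoint, cond_b)
        ok = a.notna() & b.notna()
        av, bv = a[ok].to_numpy(), b[ok].to_numpy()
        row = {
            "endpoint": endpoint,
            "condition_a": cond_a,
            "condition_b": cond_b,
            "n": int(ok.sum()),
            "mean_a": float(np.mean(av)) if av.size else np.nan,
            "mean_b": float(np.mean(bv)) if bv.size else np.nan,
            "mean_diff": float(np.mean(av - bv)) if av.size else np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "t": np.nan,
            "df": np.nan,
            "p": np.nan,
            "note": "",
        }
        try:
            res = paired_t(av, bv)
            row.update(
                ci_low=res.ci_low,
                ci_high=res.ci_high,
                t=res.t_stat,
                df=res.df,
                p=res.p_value,
            )
        except ValueError as exc:
            row["note"] = str(exc)
        rows.append(row)
    comparisons = pd.DataFrame(rows)

    corr_rows = []
    d_irv = _column("irv_l", "resistance") - _column("irv_l", "isotime_control")
    for endpoint in _DELTA_ENDPOINTS:
        delta = _column(endpoint, "resistance") - _column(endpoint, "isotime_control")
        ok = delta.notna() & d_irv.notna()
        row = {
            "delta_endpoint": f"delta_{endpoint}",
            "vs": "delta_irv_l",
            "n": int(ok.sum()),
            "r": np.nan,
            "r_squared": np.nan,
            "p": np.nan,
            "note": "",
        }
        try:
            res = pearson_corr(delta[ok].to_numpy(), d_irv[ok].to_numpy())
            row.update(r=res.r, r_squared=res.r_squared, p=res.p_value)
        except ValueError as exc:
            row["note"] = str(exc)
        corr_rows.append(row)
    correlations = pd.DataFrame(corr_rows)
    return StudyReport(comparisons=comparisons, correlations=correlations)
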