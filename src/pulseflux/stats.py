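"""Regression and summary statistics for the per-pulse feature tables.

Within each subject's qualifying window, each LDF feature (``PA_LDF``,
``LDF_TOT``, ``PF``) is regressed on ``PA_PPG`` by ordinary least squares;
R is the Pearson correlation, the two-sided p-value comes from
``t = R * sqrt((n-2) / (1-R^2))`` with ``n-2`` degrees of freedom, and 95%
confidence bounds on slope and intercept use the same t reference
distribution. The pooled regression concatenates all subjects' window rows
into one fit.

The LDF pulsatility index (PLI) is the per-pulse LDF amplitude divided by the
time-average of the raw LDF signal over the analysis interval — dimensionless
and invariant to rescaling of the LDF channel. A variant using the pulsatile
flux area ``PF`` as numerator is available through ``numerator="PF"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DataError, DegenerateRegressorError, ParameterError
from .features import PulseFeatureRow, features_to_frame
from .recording import Recording
from .selection import QualifyingWindow

__all__ = [
    "RegressionResult",
    "PLIResult",
    "SubjectSummary",
    "regress",
    "pooled_regress",
    "pulsatility_index",
    "subject_summary",
    "cohort_regressions",
]

LDF_FEATURES = ("PA_LDF", "LDF_TOT", "PF")


@dataclass(frozen=True)
class RegressionResult:
    x_name: str
    y_name: str
    n: int
    slope: float
    intercept: float
    r: float
    p: float
    slope_ci_low: float
    slope_ci_high: float
    intercept_ci_low: float
    intercept_ci_high: float

    def equation(self) -> str:
        return (
            f"{self.y_name} = {self.intercept:.4g} + {self.slope:.4g}*{self.x_name}"
            f"  (R = {self.r:.3f}, p = {self.p:.3g}, n = {self.n})"
        )


def _ols(x, y, x_name: str, y_name: str, conf: float = 0.95) -> RegressionResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ParameterError(f"x and y lengths differ: {n} vs {len(y)}")
    if n < 3:
        raise ParameterError(f"need at least 3 points for a regression, got {n}")
    if float(np.var(x)) == 0.0:
        raise DegenerateRegressorError(f"{x_name} has zero variance")
    fit = scipy.stats.linregress(x, y)
    tcrit = float(scipy.stats.t.ppf(0.5 + conf / 2.0, n - 2))
    return RegressionResult(
        x_name=x_name,
        y_name=y_name,
        n=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        slope_ci_low=float(fit.slope - tcrit * fit.stderr),
        slope_ci_high=float(fit.slope + tcrit * fit.stderr),
        intercept_ci_low=float(fit.intercept - tcrit * fit.intercept_stderr),
        intercept_ci_high=float(fit.intercept + tcrit * fit.intercept_stderr),
    )


def regress(rows, y_feature: str) -> RegressionResult:
    """OLS of one LDF feature on PA_PPG over a set of feature rows."""
    if y_feature not in LDF_FEATURES:
        raise ParameterError(
            f"y_feature must be one of {LDF_FEATURES}, got {y_feature!r}"
        )
    df = features_to_frame(rows)
    if len(df) < 3:
        raise ParameterError(f"need at least 3 pulses, got {len(df)}")
    return _ols(df["PA_PPG"], df[y_feature], "PA_PPG", y_feature)


def pooled_regress(rows_by_subject, y_feature: str) -> RegressionResult:
    """Single OLS over all subjects' rows concatenated.

    ``rows_by_subject`` is a sequence of per-subject row collections (lists of
    rows or DataFrames); n in the result is the total pulse count.
    """
    frames = [features_to_frame(rows) for rows in rows_by_subject]
    if len(frames) < 2:
        raise ParameterError(f"need at least 2 subjects, got {len(frames)}")
    return regress(pd.concat(frames, ignore_index=True), y_feature)


@dataclass(frozen=True)
class PLIResult:
    per_pulse: np.ndarray
    mean: float
    mean_ldf: float
    numerator: str


def pulsatility_index(
    rows, ldf_signal_in_window, numerator: str = "PA_LDF"
) -> PLIResult:
    """LDF pulsatility index over one analysis window.

    ``MEAN_LDF`` is the time-average of the raw LDF samples over the window
    interval; each pulse contributes ``PA_LDF / MEAN_LDF`` (or
    ``PF / MEAN_LDF`` with ``numerator="PF"``); the summary value is the mean
    over the window's pulses.
    """
    if numerator not in ("PA_LDF", "PF"):
        raise ParameterError(f"numerator must be 'PA_LDF' or 'PF', got {numerator!r}")
    df = features_to_frame(rows)
    if df.empty:
        raise ParameterError("need at least one feature row")
    mean_ldf = float(np.mean(np.asarray(ldf_signal_in_window, dtype=float)))
    if mean_ldf <= 0:
        raise DataError(f"window mean LDF must be positive, got {mean_ldf:.6g}")
    per_pulse = df[numerator].to_numpy(dtype=float) / mean_ldf
    return PLIResult(
        per_pulse=per_pulse,
        mean=float(per_pulse.mean()),
        mean_ldf=mean_ldf,
        numerator=numerator,
    )


@dataclass
class SubjectSummary:
    subject_id: str
    mean_PA_PPG: float
    mean_PLI: float
    LDF_30_PULSE: float
    LDF_30_MINUTE: float
    regressions: dict[str, RegressionResult] = field(default_factory=dict)


def subject_summary(
    recording: Recording,
    window: QualifyingWindow,
    pli_numerator: str = "PA_LDF",
) -> SubjectSummary:
    """Per-subject summary over the qualifying window and the full recording.

    ``LDF_30_PULSE`` is the mean LDF between the window's first pulse onset
    and last pulse end; ``LDF_30_MINUTE`` is the mean over the whole
    recording (the names reflect the 30-pulse / 30-minute study design, but
    any window/recording lengths are accepted).
    """
    fs = recording.fs
    first = window.rows[0]
    last = window.rows[-1]
    i0 = int(round((first.onset_s - recording.t0) * fs))
    i1 = int(round((last.onset_s + last.T_LDF - recording.t0) * fs))
    i0 = max(0, i0)
    i1 = min(recording.n_samples - 1, i1)
    if i1 <= i0:
        raise DataError("window interval is empty in this recording")
    window_ldf = recording.ldf[i0 : i1 + 1]
    pli = pulsatility_index(window.rows, window_ldf, numerator=pli_numerator)
    return SubjectSummary(
        subject_id=recording.subject_id,
        mean_PA_PPG=float(np.mean([r.PA_PPG for r in window.rows])),
        mean_PLI=pli.mean,
        LDF_30_PULSE=float(np.mean(window_ldf)),
        LDF_30_MINUTE=float(np.mean(recording.ldf)),
        regressions={f: regress(window.rows, f) for f in LDF_FEATURES},
    )


def cohort_regressions(summaries: list[SubjectSummary]) -> dict[str, RegressionResult]:
    """Cohort-level regressions over per-subject summary values.

    Returns the regression of the window-interval mean perfusion on the
    whole-recording mean perfusion (one point per subject) and of the mean
    pulsatility index on the mean PPG amplitude.
    """
    if len(summaries) < 3:
        raise ParameterError(f"need at least 3 subjects, got {len(summaries)}")
    ldf_window = [s.LDF_30_PULSE for s in summaries]
    ldf_overall = [s.LDF_30_MINUTE for s in summaries]
    pli = [s.mean_PLI for s in summaries]
    pa = [s.mean_PA_PPG for s in summaries]
    return {
        "ldf_window_vs_overall": _ols(
            ldf_overall, ldf_window, "LDF_30_MINUTE", "LDF_30_PULSE"
        ),
        "pli_vs_pa_ppg": _ols(pa, pli, "mean_PA_PPG", "mean_PLI"),
    }
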