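"""End-to-end pipeline: preprocess → detect → pair → extract → select → analyze.

One :class:`PipelineConfig` drives the whole run, either over recording files
on disk or over a freshly simulated cohort. Outputs are delimited text (per
subject: feature table, window rows, boundary audit; cohort: regression report
and subject summaries) plus a JSON run manifest, and a fixed seed makes the
whole run byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, PulsefluxError
from .features import extract_features, features_to_frame
from .io import read_recording, write_boundaries, write_features, write_recording
from .recording import Recording
from .segment import detect_pulses, pair_pulses, preprocess
from .selection import NoQualifyingWindow, QualifyingWindow, find_qualifying_window
from .simulate import SimConfig, simulate_cohort
from .stats import (
    LDF_FEATURES,
    cohort_regressions,
    pooled_regress,
    subject_summary,
)

logger = logging.getLogger("pulseflux")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    recordings: list[str] = field(default_factory=list)
    sim: SimConfig | None = None
    n_subjects: int = 10
    band_low_hz: float | None = 0.05
    band_high_hz: float | None = 10.0
    rate_hint_hz: float | None = None
    window_len: int = 30
    min_count: int = 6
    threshold_frac: float = 0.60
    outdir: str = "pulseflux_out"
    seed: int = 0
    write_signals: bool = False

    def validate(self) -> "PipelineConfig":
        if not self.recordings and self.sim is None:
            raise ConfigurationError(
                "recordings: no recording paths given and no sim block configured"
            )
        if self.recordings:
            for p in self.recordings:
                if not Path(p).exists():
                    raise ConfigurationError(f"recordings: path does not exist: {p}")
        if self.sim is not None:
            self.sim.validate()
            if self.n_subjects < 1:
                raise ConfigurationError(
                    f"n_subjects: must be >= 1, got {self.n_subjects}"
                )
        if self.window_len < 2:
            raise ConfigurationError(f"window_len: must be >= 2, got {self.window_len}")
        if not (0.0 < self.threshold_frac < 1.0):
            raise ConfigurationError(
                f"threshold_frac: must lie in (0, 1), got {self.threshold_frac}"
            )
        if not (1 <= self.min_count <= self.window_len):
            raise ConfigurationError(
                f"min_count: must lie in [1, window_len], got {self.min_count}"
            )
        return self

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = data.pop("sim", None)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg.validate()


@dataclass
class SubjectResult:
    subject_id: str
    features: list
    selection: QualifyingWindow | NoQualifyingWindow
    summary: object | None
    diagnostics: dict


def analyze_recording(
    recording: Recording, config: PipelineConfig
) -> SubjectResult:
    """Run the per-subject stages on one recording."""
    rec = preprocess(recording, config.band_low_hz, config.band_high_hz)
    ppg_bounds = detect_pulses(
        rec.ppg, rec.fs, expected_rate_hint=config.rate_hint_hz, channel="PPG"
    )
    ldf_bounds = detect_pulses(
        rec.ldf, rec.fs, expected_rate_hint=config.rate_hint_hz, channel="LDF"
    )
    pairing = pair_pulses(ppg_bounds, ldf_bounds, rec.fs)
    extraction = extract_features(pairing, rec)
    diagnostics = {
        "n_ppg_pulses": len(ppg_bounds),
        "n_ldf_pulses": len(ldf_bounds),
        "n_pairs": len(pairing),
        "n_ppg_unmatched": pairing.n_ppg_unmatched,
        "n_ldf_unmatched": pairing.n_ldf_unmatched,
        "n_rows": len(extraction.rows),
        "n_skipped": extraction.n_skipped,
        "n_clipped": extraction.n_clipped,
    }
    selection = find_qualifying_window(
        extraction.rows,
        window_len=config.window_len,
        min_count=config.min_count,
        threshold_frac=config.threshold_frac,
    )
    summary = None
    if selection.qualified:
        summary = subject_summary(rec, selection)
    else:
        logger.warning(
            "subject %s: no qualifying window (best n_small=%d at pulse %d)",
            recording.subject_id,
            selection.best_n_small,
            selection.best_start_index,
        )
    return SubjectResult(
        subject_id=recording.subject_id,
        features=extraction.rows,
        selection=selection,
        summary=summary,
        diagnostics=diagnostics,
    )


@dataclass
class CohortResult:
    subjects: list[SubjectResult]
    pooled: dict
    cohort: dict


def _regression_frame(entries) -> pd.DataFrame:
    recs = []
    for label, reg in entries:
        d = dataclasses.asdict(reg)
        d["scope"] = label
        recs.append(d)
    cols = ["scope", "x_name", "y_name", "n", "slope", "intercept", "r", "p",
            "slope_ci_low", "slope_ci_high", "intercept_ci_low", "intercept_ci_high"]
    return pd.DataFrame(recs, columns=cols)


def run_pipeline(config: PipelineConfig) -> CohortResult:
    """Execute every stage per subject, then the cohort-level analysis.

    Writes per-subject feature tables and window rows, a combined regression
    report, a subject-summary table, and a JSON manifest into
    ``config.outdir``. Subjects without a qualifying window are excluded from
    the pooled and cohort analyses (and logged).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    recordings: list[Recording] = []
    if config.recordings:
        for p in config.recordings:
            recordings.append(read_recording(p))
    else:
        for cfg, rec, _truth in simulate_cohort(
            config.sim, n_subjects=config.n_subjects, seed=config.seed
        ):
            recordings.append(rec)
            if config.write_signals:
                write_recording(rec, outdir / f"{rec.subject_id}_recording.csv")

    results: list[SubjectResult] = []
    for rec in recordings:
        try:
            res = analyze_recording(rec, config)
        except PulsefluxError as exc:
            logger.error("subject %s failed: %s", rec.subject_id, exc)
            raise
        write_features(res.features, outdir / f"{rec.subject_id}_features.csv")
        if res.selection.qualified:
            write_features(
                res.selection.rows, outdir / f"{rec.subject_id}_window.csv"
            )
        results.append(res)

    qualified = [r for r in results if r.selection.qualified]
    pooled = {}
    cohort = {}
    if len(qualified) >= 2:
        rows_by_subject = [r.selection.rows for r in qualified]
        pooled = {
            feat: pooled_regress(rows_by_subject, feat) for feat in LDF_FEATURES
        }
    if len(qualified) >= 3:
        cohort = cohort_regressions([r.summary for r in qualified])

    entries = []
    for res in qualified:
        for feat, reg in res.summary.regressions.items():
            entries.append((res.subject_id, reg))
    for feat, reg in pooled.items():
        entries.append(("pooled", reg))
    for name, reg in cohort.items():
        entries.append((name, reg))
    _regression_frame(entries).to_csv(
        outdir / "regressions.csv", index=False, float_format=_FLOAT_FMT
    )

    summary_recs = []
    for res in qualified:
        s = res.summary
        summary_recs.append(
            {
                "subject_id": s.subject_id,
                "mean_PA_PPG": s.mean_PA_PPG,
                "mean_PLI": s.mean_PLI,
                "LDF_30_PULSE": s.LDF_30_PULSE,
                "LDF_30_MINUTE": s.LDF_30_MINUTE,
                "window_start_index": res.selection.start_pulse_index,
                "window_start_s": res.selection.start_time_s,
                "window_n_small": res.selection.n_small,
            }
        )
    pd.DataFrame(summary_recs).to_csv(
        outdir / "subject_summaries.csv", index=False, float_format=_FLOAT_FMT
    )

    manifest = {
        "pulseflux_version": __version__,
        "seed": config.seed,
        "config": _jsonable(asdict(config)),
        "subjects": {r.subject_id: r.diagnostics for r in results},
        "n_qualified": len(qualified),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return CohortResult(subjects=results, pooled=pooled, cohort=cohort)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
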