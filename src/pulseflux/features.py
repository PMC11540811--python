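"""Per-pulse features of paired PPG/LDF cardiac cycles.

For each cardiac cycle the package computes:

* ``PA_PPG`` — peak-to-peak amplitude of the PPG pulse (volts, arbitrary gain);
* ``PA_LDF`` — peak-to-peak amplitude of the LDF pulse (relative units);
* ``LDF_TOT`` — total LDF per pulse: area under the LDF curve over the whole
  pulse duration (relative units · s), trapezoidal rule, integrated above zero;
* ``PF`` — pulsatile flux: area of the LDF pulse above its intra-pulse minimum,
  so that ``PF + min * T_LDF == LDF_TOT`` holds identically;
* ``T_LDF`` — LDF pulse duration, trough to trough (s).

Amplitudes are taken over the half-open pulse window ``[onset, end)``;
areas are integrated over the closed span ``[onset, end]`` so the integration
interval length equals ``T_LDF`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, DegeneratePulseError, ParameterError
from .recording import Recording
from .segment import PairingResult, PulsePair

__all__ = [
    "PulseFeatureRow",
    "FeatureExtraction",
    "pulse_amplitude",
    "ldf_total",
    "pulsatile_flux",
    "extract_features",
    "features_to_frame",
    "frame_to_features",
]

FEATURE_COLUMNS = [
    "onset_s",
    "PA_PPG",
    "PA_LDF",
    "LDF_TOT",
    "PF",
    "T_LDF",
    "ldf_mean_in_pulse",
]


@dataclass(frozen=True)
class PulseFeatureRow:
    onset_s: float
    PA_PPG: float
    PA_LDF: float
    LDF_TOT: float
    PF: float
    T_LDF: float
    ldf_mean_in_pulse: float


@dataclass
class FeatureExtraction:
    """Feature rows plus diagnostics about skipped or clipped pulses."""

    rows: list[PulseFeatureRow]
    n_skipped: int = 0
    n_clipped: int = 0

    def __len__(self):
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def __getitem__(self, i):
        return self.rows[i]

    def to_frame(self) -> pd.DataFrame:
        return features_to_frame(self.rows)


def pulse_amplitude(samples_in_pulse: np.ndarray) -> float:
    """Peak-to-peak amplitude, max minus min, over one pulse window."""
    x = np.asarray(samples_in_pulse, dtype=float)
    if x.size < 3:
        raise DegeneratePulseError(
            f"pulse window has {x.size} samples; need at least 3"
        )
    return float(x.max() - x.min())


def _clip_negative(x: np.ndarray) -> tuple[np.ndarray, bool]:
    if np.all(x < 0):
        raise DataError("all LDF samples in pulse are negative")
    if np.any(x < 0):
        return np.clip(x, 0.0, None), True
    return x, False


def ldf_total(samples_in_pulse: np.ndarray, fs: float) -> float:
    """Total LDF per pulse: trapezoidal area under the curve, above zero.

    ``samples_in_pulse`` covers the closed pulse span (end sample included),
    so the integration interval is ``(len - 1) / fs`` seconds. Negative
    samples (measurement noise) are clipped to zero.
    """
    x = np.asarray(samples_in_pulse, dtype=float)
    if x.size < 3:
        raise DegeneratePulseError(
            f"pulse window has {x.size} samples; need at least 3"
        )
    if fs <= 0:
        raise ParameterError(f"fs must be positive, got {fs}")
    x, _ = _clip_negative(x)
    return float(np.trapezoid(x, dx=1.0 / fs))


def pulsatile_flux(samples_in_pulse: np.ndarray, fs: float) -> float:
    """Pulsatile flux: trapezoidal area above the intra-pulse minimum.

    Equals ``ldf_total - min * duration`` identically, because the baseline is
    the horizontal line through the pulse's lowest LDF value.
    """
    x = np.asarray(samples_in_pulse, dtype=float)
    if x.size < 3:
        raise DegeneratePulseError(
            f"pulse window has {x.size} samples; need at least 3"
        )
    if fs <= 0:
        raise ParameterError(f"fs must be positive, got {fs}")
    x, _ = _clip_negative(x)
    return float(np.trapezoid(x - x.min(), dx=1.0 / fs))


def extract_features(
    pairs: PairingResult | list[PulsePair], recording: Recording
) -> FeatureExtraction:
    """One feature row per pulse pair, ordered by onset time.

    Degenerate pulses (too few samples, all-negative LDF) are skipped, never
    imputed; the skip count is reported in the result. Pulses whose LDF window
    contained negative samples (clipped to zero before integration) are
    counted in ``n_clipped``.
    """
    pair_list = list(pairs)
    if not pair_list:
        raise ParameterError("pair list must be nonempty")
    fs = recording.fs
    rows: list[PulseFeatureRow] = []
    n_skipped = 0
    n_clipped = 0
    for pair in sorted(pair_list, key=lambda p: p.ppg.onset_idx):
        try:
            ppg_win = recording.ppg[pair.ppg.onset_idx : pair.ppg.end_idx]
            ldf_win = recording.ldf[pair.ldf.onset_idx : pair.ldf.end_idx + 1]
            pa_ppg = pulse_amplitude(ppg_win)
            pa_ldf = pulse_amplitude(ldf_win[:-1])
            if ldf_win.size < 3:
                raise DegeneratePulseError("LDF window too short")
            clipped_win, was_clipped = _clip_negative(ldf_win)
            t_ldf = (pair.ldf.end_idx - pair.ldf.onset_idx) / fs
            tot = float(np.trapezoid(clipped_win, dx=1.0 / fs))
            pf = float(np.trapezoid(clipped_win - clipped_win.min(), dx=1.0 / fs))
        except (DegeneratePulseError, DataError):
            n_skipped += 1
            continue
        if was_clipped:
            n_clipped += 1
        rows.append(
            PulseFeatureRow(
                onset_s=recording.t0 + pair.ppg.onset_idx / fs,
                PA_PPG=pa_ppg,
                PA_LDF=pa_ldf,
                LDF_TOT=tot,
                PF=pf,
                T_LDF=t_ldf,
                ldf_mean_in_pulse=tot / t_ldf,
            )
        )
    return FeatureExtraction(rows=rows, n_skipped=n_skipped, n_clipped=n_clipped)


def features_to_frame(rows) -> pd.DataFrame:
    """Feature rows as a DataFrame with the canonical column order."""
    if isinstance(rows, pd.DataFrame):
        return rows[FEATURE_COLUMNS].copy()
    data = [
        {col: getattr(r, col) for col in FEATURE_COLUMNS} for r in rows
    ]
    return pd.DataFrame(data, columns=FEATURE_COLUMNS)


def frame_to_features(df: pd.DataFrame) -> list[PulseFeatureRow]:
    return [
        PulseFeatureRow(**{col: float(rec[col]) for col in FEATURE_COLUMNS})
        for rec in df.to_dict("records")
    ]
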