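"""Qualifying-window search.

The analysis interval is the *first* run of ``window_len`` consecutive pulses
in which at least ``min_count`` pulses have a PPG amplitude less than or equal
to ``threshold_frac`` of the maximum PPG amplitude *within that window*. The
default rule (30 pulses, >= 6 pulses at <= 60% of the window maximum)
guarantees enough amplitude spread for a meaningful within-subject regression
while keeping the interval short enough to avoid slow confounders.

Candidate windows advance one pulse at a time (the strictest reading of
"first"); the step is exposed as a parameter. When no window qualifies the
search returns a :class:`NoQualifyingWindow` carrying the best near-miss seen
— a legitimate outcome, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputTooShortError, ParameterError
from .features import PulseFeatureRow, frame_to_features

__all__ = ["QualifyingWindow", "NoQualifyingWindow", "find_qualifying_window"]


@dataclass
class QualifyingWindow:
    """A qualifying run of pulses with its qualification evidence."""

    start_pulse_index: int
    rows: list[PulseFeatureRow]
    window_max_PA_PPG: float
    n_small: int
    start_time_s: float
    qualified: bool = True

    def __len__(self):
        return len(self.rows)


@dataclass
class NoQualifyingWindow:
    """No window qualified; records the closest miss for diagnostics."""

    best_n_small: int
    best_start_index: int
    n_windows_scanned: int
    qualified: bool = False


def find_qualifying_window(
    rows,
    window_len: int = 30,
    min_count: int = 6,
    threshold_frac: float = 0.60,
    step: int = 1,
) -> QualifyingWindow | NoQualifyingWindow:
    """Scan for the first qualifying window of ``window_len`` pulses.

    ``rows`` is a sequence of :class:`PulseFeatureRow` (or a feature
    DataFrame) ordered by onset time. The amplitude comparison is inclusive
    (``<=``) and the reference maximum is taken within each candidate window,
    not globally. Raises :class:`InputTooShortError` with fewer than
    ``window_len`` rows.
    """
    if isinstance(rows, pd.DataFrame):
        rows = frame_to_features(rows)
    rows = list(rows)
    if window_len < 2:
        raise ParameterError(f"window_len must be >= 2, got {window_len}")
    if not (0.0 < threshold_frac < 1.0):
        raise ParameterError(
            f"threshold_frac must lie in (0, 1), got {threshold_frac}"
        )
    if not (1 <= min_count <= window_len):
        raise ParameterError(
            f"min_count must lie in [1, window_len], got {min_count}"
        )
    if step < 1:
        raise ParameterError(f"step must be >= 1, got {step}")
    if len(rows) < window_len:
        raise InputTooShortError(
            f"need at least {window_len} pulses, got {len(rows)}"
        )

    amps = np.array([r.PA_PPG for r in rows], dtype=float)
    best_n_small = -1
    best_start = 0
    n_scanned = 0
    for start in range(0, len(rows) - window_len + 1, step):
        window = amps[start : start + window_len]
        wmax = float(window.max())
        n_small = int(np.sum(window <= threshold_frac * wmax))
        n_scanned += 1
        if n_small >= min_count:
            return QualifyingWindow(
                start_pulse_index=start,
                rows=rows[start : start + window_len],
                window_max_PA_PPG=wmax,
                n_small=n_small,
                start_time_s=rows[start].onset_s,
            )
        if n_small > best_n_small:
            best_n_small = n_small
            best_start = start
    return NoQualifyingWindow(
        best_n_small=best_n_small,
        best_start_index=best_start,
        n_windows_scanned=n_scanned,
    )
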