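"""Cardiac-cycle delineation and two-channel pulse pairing.

Pulses are delineated trough-to-trough: a pulse runs from one diastolic
minimum to the next, so consecutive pulses tile the covered span with no gap
and no overlap, and each pulse window is an unambiguous integration interval
for per-pulse areas. Each channel is delineated independently, then PPG and
LDF pulses are paired by nearest onset; independent delineation tolerates the
small transit lag between the two measurement sites.

Indexing convention: 0-based, half-open ``[onset_idx, end_idx)`` per pulse;
``end_idx`` of one pulse is the ``onset_idx`` of the next.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .errors import DataError, ParameterError, PulseDetectionError
from .recording import Recording

__all__ = [
    "PulseBoundary",
    "PulsePair",
    "PairingResult",
    "preprocess",
    "detect_pulses",
    "pair_pulses",
]

#: physiological search band for the cardiac period, seconds (30–200 bpm)
_PERIOD_MIN_S = 60.0 / 200.0
_PERIOD_MAX_S = 60.0 / 30.0
_FILTER_ORDER = 3


@dataclass(frozen=True)
class PulseBoundary:
    channel: str  # "PPG" or "LDF"
    onset_idx: int
    peak_idx: int
    end_idx: int

    def __post_init__(self):
        if not (self.onset_idx < self.peak_idx < self.end_idx):
            raise DataError(
                f"pulse indices must satisfy onset < peak < end, got "
                f"({self.onset_idx}, {self.peak_idx}, {self.end_idx})"
            )

    def duration_s(self, fs: float) -> float:
        return (self.end_idx - self.onset_idx) / fs


@dataclass(frozen=True)
class PulsePair:
    ppg: PulseBoundary
    ldf: PulseBoundary
    lag_s: float  # LDF onset time minus PPG onset time


@dataclass
class PairingResult:
    """Matched pulse pairs plus a diagnostic of what could not be matched."""

    pairs: list[PulsePair]
    n_ppg_unmatched: int
    n_ldf_unmatched: int

    def __len__(self):
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, i):
        return self.pairs[i]


def preprocess(
    recording: Recording,
    band_low_hz: float | None = 0.05,
    band_high_hz: float | None = 10.0,
) -> Recording:
    """Band-limit the PPG channel and low-pass smooth the LDF channel.

    The PPG channel is band-passed (``band_low_hz``–``band_high_hz``,
    Butterworth order 3, zero-phase, so pulse timing and amplitude are not
    phase-distorted). The LDF channel is only low-passed: its mean level
    carries the perfusion baseline and must not be removed. With both band
    edges ``None`` the recording is returned unchanged (a copy).
    """
    if band_low_hz is None and band_high_hz is None:
        return recording.copy()
    nyq = recording.fs / 2.0
    low = 0.0 if band_low_hz is None else float(band_low_hz)
    if band_high_hz is None:
        raise ParameterError("band_high_hz is required when band_low_hz is set")
    high = float(band_high_hz)
    if not (0.0 <= low < high < nyq):
        raise ParameterError(
            f"band ({low}, {high}) Hz must satisfy 0 <= low < high < Nyquist ({nyq} Hz)"
        )
    recording.validate()
    if low > 0:
        sos_ppg = scipy.signal.butter(
            _FILTER_ORDER, [low, high], btype="bandpass", fs=recording.fs, output="sos"
        )
    else:
        sos_ppg = scipy.signal.butter(
            _FILTER_ORDER, high, btype="lowpass", fs=recording.fs, output="sos"
        )
    sos_ldf = scipy.signal.butter(
        _FILTER_ORDER, high, btype="lowpass", fs=recording.fs, output="sos"
    )
    return recording.copy(
        ppg=scipy.signal.sosfiltfilt(sos_ppg, recording.ppg),
        ldf=scipy.signal.sosfiltfilt(sos_ldf, recording.ldf),
    )


def _estimate_period_s(x: np.ndarray, fs: float) -> float:
    """Cardiac period from the autocorrelation of the detrended signal."""
    # cap the autocorrelation cost on very long recordings
    n_max = int(120 * fs)
    xs = x[:n_max] if len(x) > n_max else x
    xs = xs - xs.mean()
    ac = scipy.signal.correlate(xs, xs, mode="full", method="fft")[len(xs) - 1:]
    if ac[0] <= 0:
        raise PulseDetectionError("signal has no variance; no pulses detectable")
    ac = ac / ac[0]
    lo = int(np.ceil(_PERIOD_MIN_S * fs))
    hi = min(int(np.floor(_PERIOD_MAX_S * fs)), len(ac) - 1)
    if hi <= lo:
        raise PulseDetectionError("signal too short to estimate a cardiac period")
    k = lo + int(np.argmax(ac[lo : hi + 1]))
    if ac[k] < 0.15:
        raise PulseDetectionError(
            "no cardiac periodicity found (autocorrelation peak "
            f"{ac[k]:.3f} below 0.15)"
        )
    # guard against locking onto a multiple of the fundamental period
    half = k // 2
    if half >= lo and ac[half] >= 0.7 * ac[k]:
        k = half
    return k / fs


def _refine_feet(
    smoothed: np.ndarray, troughs: np.ndarray, period_s: float, fs: float
) -> np.ndarray:
    """Move each trough to the pulse foot by the intersecting-tangent rule.

    The foot is where the tangent at the maximum systolic upstroke slope
    crosses the diastolic baseline level; this pins the onset to the steep
    rising edge instead of the noise-dominated flat diastolic tail.
    """
    deriv = np.gradient(smoothed)
    search = max(2, int(round(0.35 * period_s * fs)))
    out = []
    for t in troughs:
        hi = min(int(t) + search, len(smoothed) - 1)
        if hi <= t + 1:
            out.append(int(t))
            continue
        d = int(t) + int(np.argmax(deriv[int(t) : hi]))
        slope = deriv[d]
        if slope <= 0:
            out.append(int(t))
            continue
        foot = d - (smoothed[d] - smoothed[int(t)]) / slope
        foot_idx = int(round(foot))
        out.append(int(np.clip(foot_idx, int(t), hi - 1)))
    refined = np.asarray(out, dtype=int)
    keep = np.concatenate([[True], np.diff(refined) > 0])
    return refined[keep]


def detect_pulses(
    signal: np.ndarray,
    fs: float,
    expected_rate_hint: float | None = None,
    channel: str = "PPG",
) -> list[PulseBoundary]:
    """Trough-to-trough delineation of one channel.

    Onsets are local minima separated by a refractory interval of half the
    estimated cardiac period; the peak is the maximum strictly between
    consecutive onsets. The period comes from ``expected_rate_hint`` (Hz) when
    given, otherwise from the autocorrelation of the detrended signal. Leading
    and trailing partial cycles are discarded. Raises
    :class:`PulseDetectionError` when no periodicity is detectable.
    """
    signal = np.asarray(signal, dtype=float)
    if fs <= 0:
        raise ParameterError(f"fs must be positive, got {fs}")
    if len(signal) < 3 * fs:
        raise ParameterError(
            f"signal must cover at least 3 s, got {len(signal) / fs:.2f} s"
        )
    x = scipy.signal.detrend(signal)
    scale = max(1.0, float(np.abs(signal).max()))
    if float(x.std()) <= 1e-12 * scale:
        raise PulseDetectionError("signal is flat; no pulses detectable")

    if expected_rate_hint is not None:
        if expected_rate_hint <= 0:
            raise ParameterError(
                f"expected_rate_hint must be positive, got {expected_rate_hint}"
            )
        period_s = 1.0 / expected_rate_hint
    else:
        period_s = _estimate_period_s(x, fs)

    refractory = max(1, int(round(0.5 * period_s * fs)))
    # short moving-average smoothing for trough finding; measurement noise on
    # the flat diastolic tail would otherwise jitter the raw argmin widely
    w = max(1, int(round(0.04 * period_s * fs)))
    if w > 1:
        kernel = np.ones(w) / w
        smoothed = np.convolve(x, kernel, mode="same")
    else:
        smoothed = x
    spread = float(np.percentile(smoothed, 97.5) - np.percentile(smoothed, 2.5))
    troughs, _ = scipy.signal.find_peaks(
        -smoothed, distance=refractory, prominence=0.05 * spread
    )
    if len(troughs) < 2:
        raise PulseDetectionError(
            f"found {len(troughs)} trough(s); need at least 2 for one pulse"
        )
    troughs = _refine_feet(smoothed, troughs, period_s, fs)
    bounds = []
    for a, b in zip(troughs[:-1], troughs[1:]):
        if b - a < 3:
            continue
        peak = int(a + 1 + np.argmax(signal[a + 1 : b]))
        bounds.append(
            PulseBoundary(channel=channel, onset_idx=int(a), peak_idx=peak,
                          end_idx=int(b))
        )
    if not bounds:
        raise PulseDetectionError("no complete pulses after discarding partial cycles")
    return bounds


def pair_pulses(
    ppg_bounds: list[PulseBoundary],
    ldf_bounds: list[PulseBoundary],
    fs: float,
) -> PairingResult:
    """Greedy nearest-onset matching of PPG pulses to LDF pulses.

    A candidate pair is admissible when the onset lag is below half the local
    cardiac period (the shorter of the two pulse durations). Candidates are
    consumed in order of increasing absolute lag, so the result does not
    depend on which channel is passed first. Unmatched pulses are dropped and
    counted in the returned diagnostic.
    """
    if not ppg_bounds or not ldf_bounds:
        raise ParameterError("both boundary lists must be nonempty")
    ppg_on = np.array([b.onset_idx for b in ppg_bounds])
    ldf_on = np.array([b.onset_idx for b in ldf_bounds])

    candidates = []
    for i, on in enumerate(ppg_on):
        j = int(np.searchsorted(ldf_on, on))
        for jj in (j - 1, j, j + 1):
            if 0 <= jj < len(ldf_on):
                lag = int(ldf_on[jj]) - int(on)
                half_period = 0.5 * min(
                    ppg_bounds[i].end_idx - ppg_bounds[i].onset_idx,
                    ldf_bounds[jj].end_idx - ldf_bounds[jj].onset_idx,
                )
                if abs(lag) < half_period:
                    candidates.append((abs(lag), int(on), int(ldf_on[jj]), i, jj))
    candidates.sort()

    used_ppg: set[int] = set()
    used_ldf: set[int] = set()
    chosen = []
    for _, _, _, i, j in candidates:
        if i in used_ppg or j in used_ldf:
            continue
        used_ppg.add(i)
        used_ldf.add(j)
        chosen.append(
            PulsePair(
                ppg=ppg_bounds[i],
                ldf=ldf_bounds[j],
                lag_s=(ldf_bounds[j].onset_idx - ppg_bounds[i].onset_idx) / fs,
            )
        )
    chosen.sort(key=lambda p: p.ppg.onset_idx)
    return PairingResult(
        pairs=chosen,
        n_ppg_unmatched=len(ppg_bounds) - len(chosen),
        n_ldf_unmatched=len(ldf_bounds) - len(chosen),
    )
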