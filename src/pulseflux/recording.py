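"""Two-channel recording container.

A :class:`Recording` holds one synchronized pair of uniformly sampled signals:
the finger photoplethysmogram (PPG, volts at arbitrary gain) and the laser
Doppler flux (LDF, relative perfusion units). Both channels share the sampling
rate ``fs`` and the start time ``t0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataError


@dataclass
class Recording:
    fs: float
    ppg: np.ndarray
    ldf: np.ndarray
    subject_id: str = "anonymous"
    t0: float = 0.0

    def __post_init__(self):
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.ldf = np.asarray(self.ldf, dtype=float)
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if self.ppg.ndim != 1 or self.ldf.ndim != 1:
            raise DataError("channels must be one-dimensional sample arrays")
        if len(self.ppg) != len(self.ldf):
            raise DataError(
                f"channel lengths differ: ppg has {len(self.ppg)} samples, "
                f"ldf has {len(self.ldf)}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.ppg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def validate(self) -> "Recording":
        """Raise :class:`DataError` on non-finite samples; return self."""
        for name, ch in (("ppg", self.ppg), ("ldf", self.ldf)):
            if not np.all(np.isfinite(ch)):
                bad = int(np.flatnonzero(~np.isfinite(ch))[0])
                raise DataError(f"non-finite sample in {name} channel at index {bad}")
        return self

    def copy(self, **changes) -> "Recording":
        out = replace(self, **changes)
        if "ppg" not in changes:
            out.ppg = self.ppg.copy()
        if "ldf" not in changes:
            out.ldf = self.ldf.copy()
        return out
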