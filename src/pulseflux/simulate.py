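"""Synthetic two-channel PPG/LDF recordings with exact per-pulse ground truth.

The generator emulates the measurement situation of a supine resting subject:
a finger photoplethysmogram whose beat-to-beat amplitude waxes and wanes slowly
(vasomotion), and a laser Doppler flux signal whose per-pulse amplitude is
linearly coupled to the PPG amplitude with additive noise, riding on a
non-pulsatile perfusion baseline.

Each cardiac cycle is a unimodal template stretched over one beat period, laid
down trough-to-trough so consecutive pulses tile the recording. The constructed
per-pulse values (onset time, amplitudes, areas, duration) are returned as
:class:`GroundTruth`, giving every downstream stage an exact oracle.

Model, per pulse k starting at time ``t_k`` with period ``T_k``:

* ``PA_PPG_k = ppg_amplitude * (1 - depth/2 * (1 + sin(2*pi*f_env*t_k + phi)))``
  — amplitude spans ``[ppg_amplitude*(1-depth), ppg_amplitude]``.
* ``PA_LDF_k = max(0, a + b * PA_PPG_k + eps_k)``, ``eps_k ~ N(0, feature_noise_sd)``.
* PPG channel: ``PA_PPG_k * template(u)``, ``u`` the within-beat phase in [0, 1).
* LDF channel: ``baseline(t) + PA_LDF_k * template(u)``.

The template peaks at 1 and is 0 at both ends, so the peak-to-peak amplitude of
a constructed pulse equals the coefficient in front of it exactly.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError
from .recording import Recording

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_recording",
    "simulate_cohort",
    "TEMPLATES",
]


def _template_halfsine(u: np.ndarray, peak_frac: float) -> np.ndarray:
    return np.sin(np.pi * u)


def _template_triangle(u: np.ndarray, peak_frac: float) -> np.ndarray:
    p = peak_frac
    return np.where(u < p, u / p, (1.0 - u) / (1.0 - p))


def _template_asym(u: np.ndarray, peak_frac: float) -> np.ndarray:
    """Fast systolic upstroke (quarter sine) then a smooth squared-cosine decay."""
    p = peak_frac
    up = np.sin(0.5 * np.pi * np.clip(u, 0.0, p) / p)
    down = np.cos(0.5 * np.pi * (np.clip(u, p, 1.0) - p) / (1.0 - p)) ** 2
    return np.where(u < p, up, down)


def _area_halfsine(peak_frac: float) -> float:
    return 2.0 / math.pi


def _area_triangle(peak_frac: float) -> float:
    return 0.5


def _area_asym(peak_frac: float) -> float:
    # quarter-sine over [0, p] integrates to 2p/pi; cos^2 over [p, 1] to (1-p)/2
    return 2.0 * peak_frac / math.pi + 0.5 * (1.0 - peak_frac)


#: name -> (template function on phase u in [0,1], analytic mean of the template)
TEMPLATES: dict[str, tuple[Callable, Callable]] = {
    "halfsine": (_template_halfsine, _area_halfsine),
    "triangle": (_template_triangle, _area_triangle),
    "asym": (_template_asym, _area_asym),
}


@dataclass
class SimConfig:
    """Parameters of one synthetic recording.

    Defaults describe the resting study conditions the package targets:
    30-minute recordings sampled at 1000 Hz, heart rate in the mid-60s bpm,
    a vasomotion-range amplitude envelope (0.07 Hz, 50% depth), and an LDF
    amplitude linearly coupled to the PPG amplitude.
    """

    duration_s: float = 1800.0
    fs: float = 1000.0
    heart_rate_bpm: float = 65.0
    #: per-beat period jitter (SD as a fraction of the mean period)
    hr_jitter_frac: float = 0.02
    ppg_amplitude: float = 1.0
    envelope_freq_hz: float = 0.07
    envelope_depth: float = 0.5
    #: envelope phase in radians; None draws one uniformly from the seed
    envelope_phase: float | None = None
    coupling_intercept: float = 0.17
    coupling_slope: float = 0.095
    feature_noise_sd: float = 0.017
    ldf_baseline: float = 1.0
    ldf_drift_amp: float = 0.0
    ldf_drift_freq_hz: float = 0.003
    measurement_noise_sd: float = 0.01
    template: str = "asym"
    template_peak_frac: float = 0.3
    seed: int = 0
    subject_id: str = "sim"

    def validate(self) -> "SimConfig":
        def bad(fieldname, msg):
            raise ConfigurationError(f"{fieldname}: {msg}")

        if not self.duration_s > 0:
            bad("duration_s", f"must be > 0, got {self.duration_s}")
        if not self.fs > 0:
            bad("fs", f"must be > 0, got {self.fs}")
        if not (30.0 < self.heart_rate_bpm < 200.0):
            bad("heart_rate_bpm", f"must lie in (30, 200), got {self.heart_rate_bpm}")
        if not (0.0 <= self.envelope_depth < 1.0):
            bad("envelope_depth", f"must lie in [0, 1), got {self.envelope_depth}")
        if self.envelope_freq_hz < 0:
            bad("envelope_freq_hz", f"must be >= 0, got {self.envelope_freq_hz}")
        if self.feature_noise_sd < 0:
            bad("feature_noise_sd", f"must be >= 0, got {self.feature_noise_sd}")
        if self.measurement_noise_sd < 0:
            bad("measurement_noise_sd", f"must be >= 0, got {self.measurement_noise_sd}")
        if self.ldf_baseline < 0:
            bad("ldf_baseline", f"must be >= 0, got {self.ldf_baseline}")
        if self.ppg_amplitude <= 0:
            bad("ppg_amplitude", f"must be > 0, got {self.ppg_amplitude}")
        if not (0.0 <= self.hr_jitter_frac < 0.3):
            bad("hr_jitter_frac", f"must lie in [0, 0.3), got {self.hr_jitter_frac}")
        if self.template not in TEMPLATES:
            bad("template", f"unknown template {self.template!r}; "
                            f"choose from {sorted(TEMPLATES)}")
        if not (0.0 < self.template_peak_frac < 1.0):
            bad("template_peak_frac",
                f"must lie in (0, 1), got {self.template_peak_frac}")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()


@dataclass
class GroundTruth:
    """Exact constructed per-pulse values for one synthetic recording.

    All arrays are aligned; amplitudes are template coefficients (peak-to-peak
    values of the noiseless pulse), areas are analytic integrals over the beat.
    """

    onset_s: np.ndarray
    pa_ppg: np.ndarray
    pa_ldf: np.ndarray
    ldf_tot: np.ndarray
    pf: np.ndarray
    t_ldf: np.ndarray

    def __len__(self) -> int:
        return len(self.onset_s)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "onset_s": self.onset_s,
                "PA_PPG": self.pa_ppg,
                "PA_LDF": self.pa_ldf,
                "LDF_TOT": self.ldf_tot,
                "PF": self.pf,
                "T_LDF": self.t_ldf,
            }
        )


def _baseline_integral(cfg: SimConfig, t_a: float, t_b: float) -> float:
    """Exact integral of the non-pulsatile LDF baseline over [t_a, t_b]."""
    total = cfg.ldf_baseline * (t_b - t_a)
    if cfg.ldf_drift_amp and cfg.ldf_drift_freq_hz > 0:
        w = 2.0 * math.pi * cfg.ldf_drift_freq_hz
        total += cfg.ldf_drift_amp / w * (math.cos(w * t_a) - math.cos(w * t_b))
    return total


def generate_recording(config: SimConfig) -> tuple[Recording, GroundTruth]:
    """Synthesize one recording and its exact per-pulse ground truth.

    Only complete cardiac cycles are laid down; a trailing partial beat is left
    at baseline and is not part of the ground truth. Identical configs
    (including seed) produce bitwise-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    phase = (
        rng.uniform(0.0, 2.0 * math.pi)
        if config.envelope_phase is None
        else float(config.envelope_phase)
    )

    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    ppg = np.zeros(n)
    ldf = np.full(n, config.ldf_baseline)
    if config.ldf_drift_amp:
        ldf += config.ldf_drift_amp * np.sin(
            2.0 * math.pi * config.ldf_drift_freq_hz * t
        )

    template_fn, area_fn = TEMPLATES[config.template]
    tpl_mean = area_fn(config.template_peak_frac)
    period0 = 60.0 / config.heart_rate_bpm

    onsets, pa_ppg, pa_ldf, ldf_tot, pf, t_dur = [], [], [], [], [], []
    t_k = 0.0
    while True:
        if config.hr_jitter_frac > 0:
            period = period0 * (1.0 + config.hr_jitter_frac * rng.standard_normal())
            period = float(np.clip(period, 0.5 * period0, 1.5 * period0))
        else:
            period = period0
        if t_k + period > config.duration_s + 1e-12:
            break

        amp_ppg = config.ppg_amplitude * (
            1.0
            - config.envelope_depth
            * 0.5
            * (1.0 + math.sin(2.0 * math.pi * config.envelope_freq_hz * t_k + phase))
        )
        eps = (
            config.feature_noise_sd * rng.standard_normal()
            if config.feature_noise_sd > 0
            else 0.0
        )
        amp_ldf = max(
            0.0, config.coupling_intercept + config.coupling_slope * amp_ppg + eps
        )

        i0 = int(round(t_k * config.fs))
        i1 = min(int(round((t_k + period) * config.fs)), n)
        if i1 > i0:
            u = (np.arange(i0, i1) / config.fs - t_k) / period
            shape = template_fn(np.clip(u, 0.0, 1.0), config.template_peak_frac)
            ppg[i0:i1] += amp_ppg * shape
            ldf[i0:i1] += amp_ldf * shape

        pulsatile_area = amp_ldf * tpl_mean * period
        onsets.append(t_k)
        pa_ppg.append(amp_ppg)
        pa_ldf.append(amp_ldf)
        pf.append(pulsatile_area)
        ldf_tot.append(pulsatile_area + _baseline_integral(config, t_k, t_k + period))
        t_dur.append(period)
        t_k += period

    if config.measurement_noise_sd > 0:
        ppg += config.measurement_noise_sd * rng.standard_normal(n)
        ldf += config.measurement_noise_sd * rng.standard_normal(n)

    rec = Recording(
        fs=config.fs, ppg=ppg, ldf=ldf, subject_id=config.subject_id, t0=0.0
    )
    truth = GroundTruth(
        onset_s=np.asarray(onsets),
        pa_ppg=np.asarray(pa_ppg),
        pa_ldf=np.asarray(pa_ldf),
        ldf_tot=np.asarray(ldf_tot),
        pf=np.asarray(pf),
        t_ldf=np.asarray(t_dur),
    )
    return rec, truth


def simulate_cohort(
    base: SimConfig,
    n_subjects: int = 10,
    seed: int = 0,
    heart_rates_bpm: Sequence[float] | None = None,
    hr_range_bpm: tuple[float, float] = (51.0, 79.0),
    baseline_log_sd: float = 0.3,
    intercept_sd: float = 0.05,
    ppg_amp_log_sd: float = 0.25,
) -> list[tuple[SimConfig, Recording, GroundTruth]]:
    """Simulate a cohort of subjects with between-subject heterogeneity.

    Each subject gets an independent child seed derived from ``seed``, a heart
    rate drawn uniformly from ``hr_range_bpm`` (or taken from
    ``heart_rates_bpm`` when given, e.g. a demographics table), a log-normally
    scattered non-pulsatile LDF baseline, a normally scattered coupling
    intercept (floored at 0), a log-normally scattered PPG amplitude (finger
    optics and vascular tone differ between subjects), and a random envelope
    phase. The within-subject coupling slope and noise are shared across the
    cohort.
    """
    base.validate()
    if n_subjects < 1:
        raise ConfigurationError(f"n_subjects: must be >= 1, got {n_subjects}")
    if heart_rates_bpm is not None and len(heart_rates_bpm) != n_subjects:
        raise ConfigurationError(
            f"heart_rates_bpm: expected {n_subjects} values, got {len(heart_rates_bpm)}"
        )
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        hr = (
            float(heart_rates_bpm[i])
            if heart_rates_bpm is not None
            else float(rng.uniform(*hr_range_bpm))
        )
        baseline = base.ldf_baseline * float(rng.lognormal(0.0, baseline_log_sd))
        intercept = max(
            0.0, base.coupling_intercept + intercept_sd * float(rng.standard_normal())
        )
        ppg_amp = base.ppg_amplitude * float(rng.lognormal(0.0, ppg_amp_log_sd))
        cfg = replace(
            base,
            heart_rate_bpm=hr,
            ldf_baseline=baseline,
            coupling_intercept=intercept,
            ppg_amplitude=ppg_amp,
            envelope_phase=float(rng.uniform(0.0, 2.0 * math.pi)),
            seed=int(child.generate_state(1)[0] % (2**31 - 1)),
            subject_id=f"sim{i + 1:02d}",
        )
        rec, truth = generate_recording(cfg)
        out.append((cfg, rec, truth))
    return out
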