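"""Delimited-text input/output.

Recordings travel as plain CSV with comment-line metadata::

    # pulseflux recording
    # subject_id: s01
    # fs: 1000.0
    time_s,ppg,ldf
    0.000000,0.0123,1.2045
    ...

Feature tables and pulse-boundary audits are ordinary headed CSV. All writers
use fixed formats so a rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .errors import RecordingParseError
from .recording import Recording

_FLOAT_FMT = "%.10g"


def write_recording(recording: Recording, path) -> None:
    """Write a recording as headed CSV with metadata comment lines."""
    t = recording.time
    with open(path, "w") as fh:
        fh.write("# pulseflux recording\n")
        fh.write(f"# subject_id: {recording.subject_id}\n")
        fh.write(f"# fs: {_FLOAT_FMT % recording.fs}\n")
        fh.write("time_s,ppg,ldf\n")
        for ti, pi, li in zip(t, recording.ppg, recording.ldf):
            fh.write(f"{ti:.6f},{_FLOAT_FMT % pi},{_FLOAT_FMT % li}\n")


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`, validating as it goes.

    Raises :class:`RecordingParseError` (with a 1-based line number where it
    applies) on a missing column, a non-numeric entry, a non-monotone time
    column, or a time step inconsistent with the declared sampling rate.
    """
    meta: dict[str, str] = {}
    header_line = None
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        header_line = lineno
        break
    if header_line is None:
        raise RecordingParseError("file contains no header row")

    columns = [c.strip() for c in lines[header_line - 1].split(",")]
    for required in ("time_s", "ppg", "ldf"):
        if required not in columns:
            raise RecordingParseError(
                f"missing column {required!r} in header {columns}", line=header_line
            )
    if "fs" not in meta:
        raise RecordingParseError("missing '# fs:' metadata line")
    try:
        fs = float(meta["fs"])
    except ValueError:
        raise RecordingParseError(f"non-numeric fs metadata {meta['fs']!r}") from None
    if fs <= 0:
        raise RecordingParseError(f"declared fs must be positive, got {fs}")

    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    numeric = {}
    for col in ("time_s", "ppg", "ldf"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())
        allbad = np.flatnonzero(vals.isna().to_numpy())
        first_bad = bad[0] if len(bad) else (allbad[0] if len(allbad) else None)
        if first_bad is not None:
            raise RecordingParseError(
                f"non-numeric {col} value {df[col].iloc[int(first_bad)]!r}",
                line=header_line + 1 + int(first_bad),
            )
        numeric[col] = vals.to_numpy(dtype=float)

    t = numeric["time_s"]
    if len(t) < 2:
        raise RecordingParseError("recording needs at least 2 samples")
    dt = np.diff(t)
    nonmono = np.flatnonzero(dt <= 0)
    if len(nonmono):
        raise RecordingParseError(
            "time column is not strictly increasing",
            line=header_line + 2 + int(nonmono[0]),
        )
    if abs(float(np.median(dt)) * fs - 1.0) > 0.01:
        raise RecordingParseError(
            f"median time step {float(np.median(dt)):.6g} s disagrees with "
            f"declared fs {fs:g} Hz by more than 1%"
        )
    rec = Recording(
        fs=fs,
        ppg=numeric["ppg"],
        ldf=numeric["ldf"],
        subject_id=meta.get("subject_id", "anonymous"),
        t0=float(t[0]),
    )
    return rec.validate()


def write_features(rows, path) -> None:
    """Write a per-pulse feature table (CSV, fixed column order)."""
    from .features import features_to_frame

    df = features_to_frame(rows)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"onset_s", "PA_PPG", "PA_LDF", "LDF_TOT", "PF", "T_LDF",
                "ldf_mean_in_pulse"}
    missing = expected - set(df.columns)
    if missing:
        raise RecordingParseError(f"feature table missing columns {sorted(missing)}")
    return df


def write_boundaries(bounds: Iterable, fs: float, path) -> None:
    """Export pulse boundaries for audit as (channel, onset_s, peak_s, end_s)."""
    rows = [
        {
            "channel": b.channel,
            "onset_s": b.onset_idx / fs,
            "peak_s": b.peak_idx / fs,
            "end_s": b.end_idx / fs,
        }
        for b in bounds
    ]
    pd.DataFrame(rows, columns=["channel", "onset_s", "peak_s", "end_s"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
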