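"""Subject demographics table and its summary.

The packaged fixture (``data/table1_demographics.csv``) is the ten-subject
cohort table of the resting study this package reanalyses: five male and five
female healthy young adults with height (m), weight (kg), BMI (kg/m²), supine
blood pressure (mmHg), and heart rate (bpm).

The summary reports per-column mean and sample SD (n−1 denominator), the
number of subjects with BMI above 25.0 kg/m², and the number with supine
systolic pressure of at least 120 mmHg (the elevated-blood-pressure rule
applied to this cohort).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "DemographicsRow",
    "DemographicsSummary",
    "load_demographics",
    "summarize_demographics",
]

NUMERIC_COLUMNS = (
    "age",
    "height",
    "weight",
    "bmi",
    "systolic_bp",
    "diastolic_bp",
    "heart_rate",
)


@dataclass(frozen=True)
class DemographicsRow:
    subject_id: str
    sex: str
    age: float
    height: float
    weight: float
    bmi: float
    systolic_bp: float
    diastolic_bp: float
    heart_rate: float


@dataclass
class DemographicsSummary:
    n: int
    mean: dict[str, float]
    sd: dict[str, float | None]  # None when n == 1 (sample SD undefined)
    n_bmi_over_25: int
    n_systolic_ge_120: int

    def table(self) -> pd.DataFrame:
        """Mean ± SD per column, rounded to one decimal as conventionally reported."""
        return pd.DataFrame(
            {
                "mean": {k: round(v, 1) for k, v in self.mean.items()},
                "sd": {
                    k: (None if v is None else round(v, 1)) for k, v in self.sd.items()
                },
            }
        )


def load_demographics(path=None, bmi_tol: float = 1.0) -> list[DemographicsRow]:
    """Load a demographics table; ``path=None`` loads the packaged cohort fixture.

    Validates that every field is present and positive and that the tabulated
    BMI agrees with weight/height² within ``bmi_tol`` kg/m². Published tables
    carry rounded height and weight, so the recomputed BMI can differ from the
    printed one by several tenths; the default tolerance allows for that.
    """
    if path is None:
        ref = resources.files("pulseflux.data") / "table1_demographics.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"subject_id", "sex"} | set(NUMERIC_COLUMNS)
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"demographics table missing columns {sorted(missing)}")
    rows = []
    for rec in df.to_dict("records"):
        sid = str(rec["subject_id"])
        for col in NUMERIC_COLUMNS:
            val = rec[col]
            if pd.isna(val):
                raise ValidationError(f"subject {sid}: missing field {col!r}")
            if not float(val) > 0:
                raise ValidationError(
                    f"subject {sid}: field {col!r} must be positive, got {val}"
                )
        sex = str(rec["sex"]).upper()
        if sex not in ("M", "F"):
            raise ValidationError(f"subject {sid}: sex must be M or F, got {rec['sex']!r}")
        implied = float(rec["weight"]) / float(rec["height"]) ** 2
        if abs(implied - float(rec["bmi"])) > bmi_tol:
            raise ValidationError(
                f"subject {sid}: bmi {rec['bmi']} inconsistent with "
                f"weight/height^2 = {implied:.1f} (tolerance {bmi_tol})"
            )
        rows.append(
            DemographicsRow(
                subject_id=sid,
                sex=sex,
                **{col: float(rec[col]) for col in NUMERIC_COLUMNS},
            )
        )
    return rows


def summarize_demographics(table: list[DemographicsRow]) -> DemographicsSummary:
    """Per-column mean and sample SD plus the two categorical counts."""
    if not table:
        raise ValidationError("demographics table is empty")
    n = len(table)
    mean: dict[str, float] = {}
    sd: dict[str, float | None] = {}
    for col in NUMERIC_COLUMNS:
        vals = np.array([getattr(r, col) for r in table], dtype=float)
        mean[col] = float(vals.mean())
        sd[col] = float(vals.std(ddof=1)) if n > 1 else None
    return DemographicsSummary(
        n=n,
        mean=mean,
        sd=sd,
        n_bmi_over_25=sum(1 for r in table if r.bmi > 25.0),
        n_systolic_ge_120=sum(1 for r in table if r.systolic_bp >= 120.0),
    )
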