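"""Summarize the packaged ten-subject cohort demographics table."""

from pulseflux import load_demographics, summarize_demographics

rows = load_demographics()
summary = summarize_demographics(rows)

print(summary.table().to_string())
print(f"subjects with BMI > 25.0 kg/m2: {summary.n_bmi_over_25}")
print(f"subjects with supine systolic BP >= 120 mmHg: {summary.n_systolic_ge_120}")
print("Means and SDs (n-1) describe the young healthy cohort; the two counts")
print("flag slightly-overweight subjects and elevated supine systolic pressure.")
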