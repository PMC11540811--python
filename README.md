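# pulseflux

Per-pulse analysis of synchronized finger photoplethysmography (PPG) and
laser Doppler flux (LDF) recordings — for physiologists and biomedical
engineers asking whether the PPG pulse amplitude, the workhorse behind the
clinical peripheral perfusion index, actually tracks skin blood perfusion.

Given a two-channel recording (PPG voltage + LDF perfusion in relative
units, uniformly sampled), the package:

1. band-limits the channels and delineates each into cardiac pulses
   (trough-to-trough, with tangent-foot onset refinement), then pairs PPG and
   LDF pulses by nearest onset;
2. extracts per-pulse features: peak-to-peak amplitudes PA_PPG and PA_LDF,
   total LDF area per beat LDF_TOT, pulsatile flux area PF (area above the
   intra-beat minimum), and beat duration T_LDF;
3. finds the **qualifying window** — the first 30 consecutive pulses in
   which ≥ 6 pulses have PA_PPG ≤ 60% of the window's maximum PA_PPG, i.e.
   enough spontaneous amplitude spread for a meaningful regression;
4. fits, per subject, ordinary least squares of each LDF feature on PA_PPG
   (R, two-sided p from *t* = R·√((n−2)/(1−R²)), 95% t-based CIs), the
   pooled regression over all subjects' windows, the LDF pulsatility index
   PLI = PA_LDF / MEAN_LDF, and the window-vs-whole-recording perfusion
   comparison; plus a cohort demographics summary.

A seedable synthetic-data generator produces realistic two-channel
recordings — vasomotion-modulated PPG amplitude, linearly coupled LDF
amplitude on a perfusion baseline — with exact per-pulse ground truth, so the
entire pipeline is testable end to end without any data download.

## Worked example

```python
from pulseflux import SimConfig, generate_recording, analyze_recording, PipelineConfig

config = SimConfig(duration_s=300.0, fs=250.0, seed=6)
recording, truth = generate_recording(config)
result = analyze_recording(recording, PipelineConfig(sim=config))
for reg in result.summary.regressions.values():
    print(reg.equation())
print(f"mean PLI = {result.summary.mean_PLI:.3f}")
```

prints

```
PA_LDF = 0.1694 + 0.09834*PA_PPG  (R = 0.830, p = 1.42e-08, n = 30)
LDF_TOT = 0.9889 + 0.07926*PA_PPG  (R = 0.602, p = 0.000437, n = 30)
PF = 0.08319 + 0.05146*PA_PPG  (R = 0.830, p = 1.44e-08, n = 30)
mean PLI = 0.216
```

Each line is the within-subject regression over the 30-pulse qualifying
window: beat-to-beat changes in the PPG amplitude track the LDF perfusion
features with moderate-to-strong correlation, and the fitted PA_LDF slope
recovers the generator's true coupling (0.095) within its confidence bounds.
The PLI is the LDF pulse amplitude as a fraction of the window's mean
perfusion level — dimensionless and scale-free.

The `examples/` directory holds one short script per capability (simulation,
segmentation + extraction, window selection, subject regressions, cohort
analysis, demographics); each prints its numbers with a line on what they
mean. A thin CLI mirrors the same stages:

```sh
pulseflux simulate --duration-s 120 --fs 250 --out rec.csv
pulseflux analyze rec.csv --outdir out
pulseflux demographics
```

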