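# Methods

## The measurement problem

Finger photoplethysmography (PPG) is ubiquitous in pulse oximetry, and the
peak-to-peak amplitude of its cardiac pulse (PA_PPG) drives the clinically
reported peripheral perfusion index. Whether beat-to-beat changes in PA_PPG
actually track skin blood perfusion is best probed against laser Doppler flux
(LDF), which measures microvascular perfusion (red-cell concentration ×
velocity, relative units, ~1–2 mm depth) at an adjacent finger site. This
package implements the per-pulse analysis for such synchronized two-channel
recordings: delineation into cardiac cycles, per-pulse features, selection of
an analysis window with enough amplitude spread, and the within-subject,
pooled and cohort-level regressions.

## Per-pulse quantities

Pulses are delineated trough-to-trough (diastolic minimum to diastolic
minimum), so each beat owns an unambiguous half-open index window
`[onset, end)` and consecutive beats tile the signal. Per beat:

| quantity | definition | units |
|---|---|---|
| `PA_PPG` | max − min of the PPG samples in the beat | V (arbitrary gain) |
| `PA_LDF` | max − min of the LDF samples in the beat | relative units |
| `LDF_TOT` | trapezoidal area under the LDF curve over the beat, above zero | units·s |
| `PF` | trapezoidal area above the intra-beat LDF minimum | units·s |
| `T_LDF` | beat duration, trough to trough | s |

The `PF` baseline is the horizontal line through the beat's lowest LDF value,
which makes `PF + min · T_LDF = LDF_TOT` an exact identity (it is asserted in
the tests to 1e-9 relative). `LDF_TOT` is integrated above zero, not above an
instrument dark level; negative samples (possible under measurement noise)
are clipped to zero and counted in a diagnostic. Areas are integrated over
the closed sample span `[onset, end]` so the interval length equals `T_LDF`;
at cardiac sampling rates the trapezoidal discretization error is far below
measurement noise (checked against a 10×-oversampled Riemann sum).

## Delineation and pairing

The PPG channel is band-passed 0.05–10 Hz and the LDF channel low-passed at
10 Hz (Butterworth order 3, zero-phase `sosfiltfilt`, so amplitudes and
timing are not phase-distorted; the LDF mean level is preserved because it
carries the perfusion baseline). The cardiac period is estimated from the
autocorrelation of the detrended signal over the 30–200 bpm band, with a
subharmonic guard (if the autocorrelation at half the chosen lag is at least
70% of the peak, the half lag wins). Troughs are local minima of a lightly
smoothed copy (moving average, 4% of the period) separated by a refractory
interval of half the period; each trough is then refined to the pulse foot by
the intersecting-tangent rule (tangent at the maximum systolic upstroke slope
intersected with the diastolic level). Without the refinement, per-sample
noise on the flat diastolic tail jitters the raw argmin by tens of
milliseconds; with it, onsets recover simulator ground truth to well under
30 ms at 2% noise. A flat or aperiodic signal raises a detection error rather
than returning an empty list.

The two channels are delineated independently and then paired greedily by
nearest onset, admitting a pair only when the lag is below half the local
period; consuming candidates in order of increasing |lag| makes the matching
symmetric in its arguments. Unmatched pulses are dropped and counted.

## Window selection

The analysis sample is the first window of 30 consecutive pulses in which at
least 6 pulses have `PA_PPG` at or below 60% of the maximum `PA_PPG` in that
same window (the comparison is inclusive; the maximum is local to the window,
never global). The scan starts at pulse 0 and advances one pulse at a time —
the strictest reading of "first" — with the step exposed as a parameter.
"No window qualifies" is a legitimate result carrying the best near-miss, not
an exception. The implementation is tested for exact agreement with a literal
brute-force enumeration on 1000+ random and adversarial sequences, including
ties exactly at the 60% boundary.

## Inference

Each LDF feature is regressed on `PA_PPG` by ordinary least squares. R is the
Pearson coefficient; the two-sided p-value uses
`t = R·sqrt((n−2)/(1−R²))` with `n−2` degrees of freedom, and 95% confidence
bounds on slope and intercept use the same t reference — the standard normal-
errors OLS inference. The pooled regression concatenates all subjects'
window rows (10 × 30 = 300 pulses in the target design) into a single fit.
Cohort-level regressions run over per-subject summaries: window-interval mean
LDF against whole-recording mean LDF, and mean pulsatility index against mean
`PA_PPG`.

The LDF pulsatility index is `PLI = PA_LDF / MEAN_LDF` with `MEAN_LDF` the
time-average of the raw LDF signal over the window interval — not the mean of
per-pulse amplitudes. This denominator makes PLI dimensionless and invariant
to rescaling the LDF channel. A variant with the pulsatile area `PF` as
numerator exists (`numerator="PF"`) because the two definitions circulate for
pulsatility-type indices; the amplitude-based form is the default and the one
all summaries report.

"Elevated blood pressure" in the demographics summary is operationalized as
supine systolic ≥ 120 mmHg; diastolic is not used. Sample SDs use the n−1
denominator and are undefined (reported as absent, not zero) for a single
subject. The packaged cohort table's printed BMI values differ from
`weight/height²` by up to ~0.6 kg/m² (rounded heights and weights), so the
loader's BMI consistency check defaults to a 1.0 kg/m² tolerance.

## The synthetic-data generator

`generate_recording` emulates a supine resting recording: constant mean heart
rate with 2% per-beat period jitter, a sinusoidal vasomotion envelope
(default 0.07 Hz — within the 0.01–0.1 Hz vasomotion band — at 50% depth)
modulating the PPG amplitude, and an LDF pulse amplitude coupled as
`PA_LDF = a + b·PA_PPG + ε`, `ε ~ N(0, σ)`, floored at zero, riding on a
constant non-pulsatile baseline (optional slow drift). Coupling defaults
`a = 0.17`, `b = 0.095` put the LDF amplitudes in a realistic relative-unit
range; `σ = 0.017` is calibrated in closed form so that a qualifying window
yields a within-subject R near 0.7 (the moderate-to-strong band typical of
such data): with the envelope spanning amplitudes `[0.5, 1.0]` V,
`sd(PA_PPG) = 0.25/√2` and `R = b·sd_x/√(b²·var_x + σ²) ≈ 0.70`. The beat
template peaks at 1 and vanishes at both ends, so every constructed
coefficient is exactly the beat's peak-to-peak amplitude and the analytic
per-beat areas are exact ground truth. Three templates are available:
an asymmetric fast-upstroke/slow-decay shape (default, the realistic
morphology), a half-sine and a triangle (analytically integrable, used by
tests). The envelope period and depth are a judgment call — the waxing and
waning of real recordings is visible but not parameterized anywhere — and
are deliberately deep enough that qualifying windows exist early, as they did
for all subjects in the target design.

`simulate_cohort` adds between-subject heterogeneity: heart rate uniform in
51–79 bpm (or taken from a demographics table), log-normal spread of the
non-pulsatile LDF baseline (σ = 0.3) and of the PPG amplitude (σ = 0.25,
emulating between-subject differences in finger optics and vascular tone),
normal spread of the coupling intercept (SD 0.05), and a random envelope
phase, all derived from one root seed through independent child seeds.

What the generator does **not** emulate — and hence what passing tests do not
establish about real data: respiratory modulation of heart rate and
amplitude, arrhythmia and ectopic beats, motion artifacts, site-to-site
transit-time dynamics, and any physiological covariance between a subject's
beat duration and perfusion. Two visible consequences: the within-subject
correlation of `LDF_TOT` is diluted relative to `PA_LDF` because the 2%
period jitter adds `baseline·T` variance uncorrelated with `PA_PPG`; and the
cohort-level PLI regression is weak because the generator draws baseline
perfusion independently of PPG amplitude. Real cohorts need not behave this
way, which is exactly why the package's validation targets are the
recoverable properties (slope recovery, CI calibration, pooling attenuation)
rather than any particular observed correlation.

## Numerical and design choices

- Zero-phase filtering replicates no particular hardware filter; it was
  chosen so areas and amplitudes are unbiased by phase distortion.
- 0-based, half-open pulse indexing; `end` of one pulse is `onset` of the next.
- Degenerate pulses (fewer than 3 samples, all-negative LDF) are skipped with
  a diagnostic count, never imputed.
- All randomness flows from a single seed (`numpy` `SeedSequence` children per
  subject); the same configuration reruns byte-identically, including every
  CSV the pipeline writes (fixed float formats).
- Tests and the acceptance study run on scaled-down problem sizes chosen for
  statistical sufficiency: 45–300 s recordings at 125–250 Hz rather than
  30 min at 1000 Hz. All rates and durations are parameters; nothing in the
  implementation depends on the scale.

## Known limitations

- Pulse delineation assumes a dominant cardiac periodicity; heavily corrupted
  or highly arrhythmic signals raise detection errors instead of degrading
  silently.
- The pairing is onset-based and greedy; it does not model a physiological
  transit-time prior beyond the half-period admissibility bound.
- OLS inference assumes independent within-window residuals; beat-to-beat
  autocorrelation in real data would make the reported CIs slightly
  optimistic. Mixed-effects extensions are out of scope.
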