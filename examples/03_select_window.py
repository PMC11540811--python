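"""Locate the qualifying 30-pulse analysis window.

The analysis interval is the first 30 consecutive pulses in which at least
six have a PPG amplitude at or below 60% of the window's own maximum — enough
amplitude spread for a meaningful within-subject regression.
"""

from pulseflux import (
    SimConfig, detect_pulses, extract_features, find_qualifying_window,
    generate_recording, pair_pulses,
)

config = SimConfig(duration_s=300.0, fs=250.0, seed=6)
recording, _ = generate_recording(config)
ppg = detect_pulses(recording.ppg, recording.fs, channel="PPG")
ldf = detect_pulses(recording.ldf, recording.fs, channel="LDF")
rows = extract_features(pair_pulses(ppg, ldf, recording.fs), recording).rows

window = find_qualifying_window(rows, window_len=30, min_count=6,
                                threshold_frac=0.60)
if window.qualified:
    print(f"qualifying window starts at pulse {window.start_pulse_index} "
          f"(t = {window.start_time_s:.1f} s)")
    print(f"window max PA_PPG = {window.window_max_PA_PPG:.3f} V; "
          f"{window.n_small} of 30 pulses at or below 60% of it")
    print("These 30 pulses form the subject's analysis sample; the spread in")
    print("their amplitudes is what makes the regression informative.")
else:
    print(f"no qualifying window; best near-miss had {window.best_n_small} "
          f"small pulses at pulse {window.best_start_index}")
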