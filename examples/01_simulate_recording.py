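"""Generate a synthetic two-channel PPG/LDF recording with ground truth.

The simulator lays down one asymmetric pulse per cardiac cycle on both
channels; the PPG amplitude waxes and wanes with a slow vasomotion envelope
and the LDF amplitude follows it linearly with noise, on top of a
non-pulsatile perfusion baseline.
"""

from pulseflux import SimConfig, generate_recording, write_recording

config = SimConfig(duration_s=120.0, fs=250.0, seed=1)
recording, truth = generate_recording(config)
write_recording(recording, "example_recording.csv")

print(f"recording: {recording.n_samples} samples at {recording.fs:g} Hz "
      f"({recording.duration_s:.0f} s), {len(truth)} complete pulses")
print(truth.to_frame().head().round(4).to_string(index=False))
print("Each row is one constructed pulse: onset time, PPG and LDF peak-to-peak")
print("amplitudes, total and pulsatile LDF areas, and beat duration — the exact")
print("values any downstream stage should recover.")
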