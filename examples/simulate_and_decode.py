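"""Simulate one block-design session and compare the four feature spaces.

Generates a synthetic finger-tapping-style recording (6 channels, 8 trials
of 10 s task / 20 s rest at 10 Hz), then decodes the behavioral state per
timepoint with increasingly rich feature spaces.  The onset delay is the
time from a true task onset to the first sample the classifier marks
active — the figure of merit for real-time neurofeedback.
"""

import warnings

from nirspeed import PipelineConfig, SimulationSpec, generate_recording, run_full_pipeline

warnings.filterwarnings("ignore")

spec = SimulationSpec(n_channels=6, n_trials=8, seed=42)
rec, events, amps = generate_recording(spec)
print(f"simulated {rec.n_samples} samples x {rec.n_channels} channels "
      f"at {rec.sampling_rate_hz:g} Hz, {events.n_blocks} task blocks")

cfg = PipelineConfig(max_channels=4)
report = run_full_pipeline(rec, events, cfg)

print(f"\n{'condition':<14}{'accuracy':>10}{'onset (s)':>11}{'offset (s)':>12}")
for name, row in report["conditions"].items():
    print(f"{name:<14}{row['accuracy']:>10.3f}"
          f"{row['mean_onset_delay_s']:>11.2f}{row['mean_offset_delay_s']:>12.2f}")
print(f"\nchannels kept in the multichannel condition: "
      f"{report['n_channels_selected']} (ranked by training-half CNR)")
print("Each row adds one feature-space ingredient; accuracy should rise and"
      "\nthe onset delay fall as history, deoxy-Hb and more channels enter.")
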