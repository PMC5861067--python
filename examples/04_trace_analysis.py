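"""Extract pumping kinematics from a (synthetic) ROI-intensity recording.

Generates a 30-fps two-channel intensity trace — 20 continuous cycles with
two embedded burst events, plus noise — exactly as the x-ray video analysis
would see it, then runs the full pipeline: smoothing, normalization, stroke
detection, burst classification, and the cycle-timing table.
"""

import mozpump as mp

config = mp.default_config()
recipe = mp.default_recipe(seed=42)
trace, truth = mp.generate_trace(recipe, config)

out = mp.analyze_trace(trace)

print(f"recording: {trace.time_s[-1]:.1f} s at {trace.fps:.0f} fps")
for pump in ("cp", "pp"):
    n = len(out["events"][pump])
    n_true = len(truth.channel_events(pump))
    print(f"  {pump} channel: {n} strokes detected ({n_true} generated), "
          f"{out['n_bursts'][pump]} classified as burst "
          f"({truth.n_bursts(pump)} generated)")

summary = out["summary"]
print("\ncontinuous-cycle timing (mean over cycles):")
for var, label in (
    ("total_cycle_ms", "total cycle"),
    ("cp_cycle_ms", "cibarial stroke"),
    ("pp_cycle_ms", "pharyngeal stroke"),
    ("between_starts_ms", "pump start offset"),
):
    print(f"  {label:18s} {summary.loc[var, 'mean']:6.0f} "
          f"+/- {summary.loc[var, 'sd']:4.0f} ms")
print(f"  cycle frequency    {summary.loc['cycle_frequency_hz', 'mean']:6.1f} Hz")
print("\nThe recovered rhythm matches the generated 233.5 ms cycle; the "
      "pharyngeal bursts stand out by their ~17x amplitude.")
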