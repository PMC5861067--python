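"""Simulate one period of each drinking mode and compare their performance.

Builds the published mosquito parameterization, runs the quasi-steady
two-pump network model for the continuous (~4 Hz reciprocating) and burst
(single large-stroke) modes, and prints the time-averaged intake, peak
proboscis suction, expended power, and backflow statistics.
"""

import mozpump as mp

config = mp.default_config()
timing = mp.default_timing()

summaries = {}
for mode in ("continuous", "burst"):
    result = mp.simulate_mode(mode, config, timing)
    summaries[mode] = mp.summarize(result)

for mode, s in summaries.items():
    print(f"{mode} mode (one {result.timing.period(mode) * 1e3:.1f} ms period):"
          if mode == "burst" else f"{mode} mode:")
    print(f"  average intake          Q  = {s.q_avg_nl_s:6.2f} nL/s")
    print(f"  peak proboscis suction  dp = {s.dp_max_kpa:6.2f} kPa")
    print(f"  expended power          P  = {s.power_avg_nw:6.2f} nW")
    if mode == "continuous":
        print(f"  peak backflow rate      {100 * s.max_backflow_fraction:.0f}% "
              "of peak inflow")
        print(f"  backflow volume         {100 * s.backflow_volume_fraction:.0f}% "
              "of net intake")

ratios = mp.mode_comparison(summaries["continuous"], summaries["burst"])
print("\nburst / continuous:")
print(f"  flow   x{ratios['flow_ratio']:.0f}   pressure x{ratios['dp_ratio']:.0f}"
      f"   power x{ratios['power_ratio']:.0f}")
print(f"  continuous delivers {ratios['effectiveness_ratio']:.0f}x more flow "
      "per unit power: bursts are fast but costly.")
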