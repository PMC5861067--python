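"""Pump stroke volumes, the pulsed-pipe illustration, and the capillary
priming threshold.

The volume table gives each pump's spheroid volume at rest and fully
expanded.  The pulsed-pipe example shows why burst pumping moves so much
more fluid despite the linear pressure-flow law.  The meniscus threshold
shows that only the burst generates enough suction to pull an air-liquid
interface up the food canal (e.g. to re-prime after swallowing a bubble).
"""

import mozpump as mp

UM = 1e-6
config = mp.default_config()

print("Pump volumes (nL):")
print(mp.volume_table(config).round(2).to_string())

flows, steady = mp.pulsed_pipe_example(25 * UM, 6.4e-3, 3.0e-3, [(1e3, 1.0)])
_, pulsed = mp.pulsed_pipe_example(25 * UM, 6.4e-3, 3.0e-3, [(40e3, 0.8), (0.0, 0.2)])
print(f"\nStraight pipe, 25 um x 6.4 mm: 1 kPa steady -> {steady * 1e12:.1f} nL/s;")
print(f"40 kPa at 80% duty -> {pulsed * 1e12:.0f} nL/s average.")

results = {
    mode: mp.simulate_mode(mode, config) for mode in ("continuous", "burst")
}
dp_m, feasible = mp.meniscus_threshold(
    config.fluid.surface_tension_n_m, 25 * UM, results
)
print(f"\nMeniscus jump at the canal tip: {dp_m / 1e3:.1f} kPa.")
for mode, ok in feasible.items():
    verdict = "can" if ok else "cannot"
    print(f"  {mode} mode {verdict} draw the meniscus up the canal")
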