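"""Replicate the benchtop validation protocols and process them.

The step test removes 12 weighed pellets, one every 30 minutes; the drift
test logs a static load; the combined test scripts a 30/60/30/60/30 s
light pattern with pellet removals and switch flips.  Each fixture carries
its expected outcome, so the filters can be checked against a known truth.
"""

import numpy as np

from cagescale import (FilterConfig, classify_light, cumulative_intake,
                       ldr_smooth, mass_filter, plateau_filter,
                       simulate_benchtop)

fc = FilterConfig()


def process(log):
    pl = plateau_filter(log.t, mass_filter(log.t, log.mass, fc.buffer,
                                           fc.plateau_min_duration), fc,
                        raw=log.mass)
    return cumulative_intake(pl, log.calibration_mass), pl


# --- step test: pellet-mass recovery ---------------------------------------
fx = simulate_benchtop("step", seed=0)
intake, _ = process(fx.log)
steps = np.array([
    intake.cumulative[np.searchsorted(fx.log.t, tr + 60)]
    - intake.cumulative[np.searchsorted(fx.log.t, tr - 60)]
    for tr in fx.expected["removal_times"]
])
err = np.abs(steps - fx.expected["pellet_masses"])
print("step test: 12 pellets removed every 30 min")
print(f"  recovered masses (g): {np.round(steps, 3)}")
print(f"  worst error: {err.max() * 1000:.1f} mg "
      "(each pellet weighed to 10 mg)")

# --- drift test: static load ------------------------------------------------
fx = simulate_benchtop("drift", seed=0)
_, pl = process(fx.log)
print("\ndrift test: 55 g static load, 2 h")
print(f"  reported drift: {abs(pl.mass[-1] - pl.mass[0]) * 1000:.1f} mg "
      "(anything under the 100 mg buffer is noise)")
print(f"  raw fluctuation (3 sd): ±{3 * np.std(fx.log.mass):.3f} g "
      "— twice this sets the band-pass buffer")

# --- combined test: lights, switches, pellets -------------------------------
fx = simulate_benchtop("combined", seed=0)
segs = classify_light(fx.log.t, ldr_smooth(fx.log.ldr, 5))
print("\ncombined test: scripted lights with pellet removal")
for (s, e, lab) in segs.segments:
    print(f"  {lab:>4} for {e - s:.0f} s")
intake, _ = process(fx.log)
print(f"  total removed: {intake.total:.2f} g "
      f"(scripted {fx.expected['pellet_masses'].sum():.2f} g)")
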