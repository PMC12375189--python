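"""Validation statistics: origin-constrained regression and correlations.

Device-reported masses are compared with manual weighings by least squares
through the origin (slope = sum(xy)/sum(x^2)); agreement with a 1:1
relationship is tested with a two-tailed F test against slope 1.  Pearson
matrices compare the device's feeding and interaction timelines.
"""

import numpy as np

from cagescale import (FilterConfig, RunConfig, compress, cumulative_intake,
                       mass_filter, pearson_matrix, plateau_filter, preset,
                       run_pipeline, simulate_benchtop, simulate_recording,
                       slope_unity_test)

# --- calibration check: device vs manual pellet masses ----------------------
fc = FilterConfig()
device, manual = [], []
for cal in (28.0, 55.0, 82.0):
    fx = simulate_benchtop("calibration", seed=1, calibration_mass=cal)
    log = fx.log
    pl = plateau_filter(log.t, mass_filter(log.t, log.mass, fc.buffer,
                                           fc.plateau_min_duration), fc,
                        raw=log.mass)
    intake = cumulative_intake(pl, log.calibration_mass)
    for tr, m in zip(fx.expected["removal_times"],
                     fx.expected["pellet_masses"]):
        i0 = np.searchsorted(log.t, tr - 30)
        i1 = np.searchsorted(log.t, tr + 30)
        device.append(intake.cumulative[i1] - intake.cumulative[i0])
        manual.append(m)

r = slope_unity_test(device, manual)
print("calibration test (device vs manually weighed pellets):")
print(f"  slope {r.slope:.4f}, r2 {r.r2:.4f}, "
      f"F({r.dfn},{r.dfd}) = {r.F:.3f}, p = {r.p:.3f}")
print("  p > 0.05: the device does not differ from a 1:1 readout\n")

# --- correlation of feeding and activity timelines --------------------------
log, _ = simulate_recording(preset("wt_ld"), seed=4)
res = run_pipeline(RunConfig(input=log, fit_rhythm=False))
_, feed = compress(res.trace.times, res.trace.feeding_rate, 1800.0, "mean")
_, inter = compress(res.trace.times, res.trace.interaction_rate, 1800.0,
                    "mean")
m = pearson_matrix([feed, inter], labels=["feeding", "interactions"])
print("Pearson r, 30-min binned timelines:")
print(m.to_frame().round(3))
print("\nfeeding tracks food-seeking activity when both follow the same "
      "nocturnal rhythm")
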