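"""Simulate one head-tracking recording and run the full metric suite.

A subject walks laps around a 12 x 8 m circuit wearing a visual-inertial
tracker; an optical tracking system provides the gold-standard pose.
The injected tracker errors (2% scale under-estimation, 15 deg/h yaw
drift, smooth positional noise, unknown clock offset and frames) are
what the evaluation pipeline must see through.
"""

import headtrack as ht
from headtrack.synthetic import ErrorModel, SimulationConfig, simulate_pair

errors = ErrorModel(
    scale_factor=0.98,          # tracker under-estimates scene scale by 2%
    yaw_drift_rate=15.0,        # deg/h of heading drift
    position_noise_sd=0.005,    # 5 mm smooth positional noise
    orientation_noise_sd=0.2,   # deg
    time_offset=0.8,            # s of clock offset, unknown to the pipeline
    world_yaw=120.0,            # unknown world-frame rotation
    world_translation=(4.0, -2.0, 0.1),
    mount_rotvec=(5.0, 12.0, -4.0),   # head-mount placement, deg
)
pair = simulate_pair(SimulationConfig(error_model=errors, seed=42))
result = ht.evaluate_pair(pair)

print(f"recovered clock offset: {result.sync.delta_t:.3f} s (injected 0.800)")
print(f"{'metric':>10s} {'value':>10s}  units")
for e in result.report.entries:
    print(f"{e.name:>10s} {e.value:10.4f}  {e.units}")
print()
print("TLE/SpE near -2% reflect the injected scale factor; ATE collects the")
print("residual positional error after world registration. Note that on a")
print("~1 min recording YDr is dominated by orientation noise, not by the")
print("injected 15 deg/h drift: a final yaw error of a few degrees divided by")
print("a hundredth of an hour is hundreds of deg/h. Drift rates only become")
print("interpretable on long recordings (see docs/methods.md).")
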