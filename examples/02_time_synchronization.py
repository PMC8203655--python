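"""Recover a clock offset from the nod/shake synchronization segment.

Both devices record the same five slow nods and five slow shakes of the
head; cross-correlating the angular-velocity norms pins down the
constant offset between their clocks to one sample of the common grid.
"""

import numpy as np

from headtrack import alignment
from headtrack.kinematics import derive_kinematics
from headtrack.synthetic import SimulationConfig, simulate_truth

truth, sync_end = simulate_truth(SimulationConfig(seed=3))
kin = derive_kinematics(truth.slice_time(0.0, sync_end))
norm = np.linalg.norm(kin.omega, axis=1)
t_gold, x_gold = kin.t[::4], norm[::4]        # optical tracker at 50 Hz

for injected in (-1.3, 0.37, 2.0):
    res = alignment.estimate_time_offset((kin.t + injected, norm), (t_gold, x_gold))
    print(f"injected {injected:+.2f} s -> recovered {res.delta_t:+.4f} s "
          f"(profile peak {res.lag_index} of {len(res.correlation_profile)})")

print()
print("Each offset is recovered within one 20 ms sample of the 50 Hz grid;")
print("shifting the device timestamps by -delta_t aligns the two streams.")
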