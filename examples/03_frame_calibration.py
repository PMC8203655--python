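"""Register the device world frame and calibrate away the head mount.

The tracker reports poses in its own world frame and its body frame is
rotated by the (unknown) head-mount placement. Rigid point-set
registration over the first 30 s of walking recovers the world
transform; the rotation-only attitude calibration (mean heading to +x,
gravity to -z) recovers a mount-independent head frame.
"""

import numpy as np
from scipy.spatial.transform import Rotation

import headtrack as ht
from headtrack.synthetic import ErrorModel, SimulationConfig, simulate_pair

mount = (6.0, 15.0, -8.0)   # deg rotation vector of the mount placement
errors = ErrorModel(world_rotvec=(12.0, -8.0, 25.0),
                    world_translation=(3.0, 1.0, -0.4),
                    mount_rotvec=mount)
pair = simulate_pair(SimulationConfig(error_model=errors, seed=11))
result = ht.evaluate_pair(pair)

world = result.frame_tree.transforms[("W_hat", "W")]
print("estimated world rotation (deg rotvec):",
      np.round(np.degrees(Rotation.from_matrix(world.matrix).as_rotvec()), 3))
print("injected                             :", errors.world_rotvec)

r_dev = result.frame_tree.transforms[("B_hat", "C_hat")].matrix
r_gold = result.frame_tree.transforms[("B", "C")].matrix
m_est = Rotation.from_matrix(r_gold.T @ r_dev)
print("estimated mount rotation (deg rotvec):",
      np.round(np.degrees(m_est.as_rotvec()), 3))
print("injected mount rotation              :", mount)
print(f"post-calibration ATE: {result.report['ATE']:.2e} m")
print()
print("Noiseless, both frames are recovered exactly, so the absolute")
print("trajectory error collapses to numerical precision.")
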