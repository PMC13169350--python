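"""Conformational-state metrics on an extended-to-compact transition.

Builds a two-arm bead trajectory whose arms converge midway (emulating two
flexible tails folding against each other), then computes the arm-to-arm
centre-of-mass distance, inter-arm contacts and H-bond count, smooths them
with a running average, and summarises both phases with pooled statistics.
"""

import numpy as np

from nptraj.hbond import hbond_count_series
from nptraj.md_io import Selection
from nptraj.synthetic import gen_two_state_trajectory
from nptraj.traj_metrics import (com_distance_series, contact_count_series,
                                 moving_average, phase_statistics)

N_FRAMES, TRANSITION = 200, 100
traj, truth = gen_two_state_trajectory(N_FRAMES, TRANSITION, ramp_frames=20,
                                       n_hbond_pairs=3, seed=0)

arm_a = Selection(chains=frozenset({"A"}), atom_names=frozenset({"CA"}))
arm_b = Selection(chains=frozenset({"B"}), atom_names=frozenset({"CA"}))

com = com_distance_series(traj, arm_a, arm_b, label="com_distance")
contacts = contact_count_series(traj, Selection(chains=frozenset({"A"})),
                                Selection(chains=frozenset({"B"})),
                                cutoff_nm=0.45, label="arm_contacts")
hbonds = hbond_count_series(traj, Selection(chains=frozenset({"A"})),
                            Selection(chains=frozenset({"B"})),
                            label="hbonds")
com_smooth = moving_average(com, window_ns=10.0)

phases = phase_statistics(
    {"com_distance": [com], "arm_contacts": [contacts], "hbonds": [hbonds]},
    boundaries_ns=[(0, TRANSITION), (TRANSITION, N_FRAMES - 1)])

print(f"{N_FRAMES} frames; programmed transition at frame {TRANSITION}")
print(f"{'metric':<14}{'extended mean±SD':>20}{'compact mean±SD':>20}")
for label, ((m1, s1), (m2, s2)) in phases.stats.items():
    print(f"{label:<14}{m1:>13.2f}±{s1:<6.2f}{m2:>13.2f}±{s2:<6.2f}")

assert np.allclose(com.values, truth["separation_nm"])
print("\nThe arm separation drops from the extended to the compact phase "
      "while inter-arm contacts and H-bonds appear only after the "
      "transition — the signature used to split a trajectory into "
      "conformational states before computing per-state statistics.")
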