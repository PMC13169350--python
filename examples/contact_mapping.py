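"""Map a nanoparticle-binding motif from per-residue contact ratios.

Builds three synthetic replicates in which residues 112-116 are programmed
to touch a gold surface in ~90% of adsorbed frames (background residues
~5%), runs the conditional contact-ratio pipeline and ranks contiguous
high-contact runs. The top-ranked motif should be the programmed block.
"""

import numpy as np

from nptraj.contacts import (ContactConfig, average_contact_ratios,
                             rank_binding_motifs, replicate_contacts)
from nptraj.synthetic import ContactSchedule, gen_interface_trajectory

MOTIF = [112, 113, 114, 115, 116]

replicates = []
for seed in (1, 2, 3):
    schedule = ContactSchedule.random(
        n_residues=120, n_frames=200, seed=seed,
        motif=(MOTIF, 0.9), background_rate=0.05)
    traj, truth = gen_interface_trajectory(schedule, seed=seed,
                                           cap_angle_deg=60.0)
    replicates.append(replicate_contacts(traj, ContactConfig()))

table = average_contact_ratios(replicates)
motifs, sites = rank_binding_motifs(table, min_len=3, threshold=0.5)

print(f"replicates used: {table.n_replicates_used}")
print("top contiguous binding motifs (mean conditional contact ratio):")
for m in motifs[:3]:
    ids = f"{m.residue_ids[0]}-{m.residue_ids[-1]}"
    print(f"  chain {m.chain} residues {ids}: ratio {m.mean_ratio:.3f}")
print(f"single-residue sites above threshold: {len(sites)}")

top = motifs[0]
assert top.residue_ids == MOTIF
print(f"\nThe top motif is the programmed block {MOTIF}: a contact ratio "
      "near 0.9 means the motif touches the gold surface in ~90% of the "
      "frames where the protein is adsorbed at all.")
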