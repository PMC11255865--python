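"""Build a (backbone RMSD, inter-domain orientation angle) conformational
landscape from a two-domain toy trajectory, assign major/minor states, and
compare residue-COM distances between the two conformations.

The generator scripts a hinge motion between a 20-degree (major) and an
8-degree (minor) orientation with 80/20 occupancy and 0.2 A atomic jitter.
"""

import numpy as np

from crystbio import (
    assign_states,
    compare_conformations,
    featurize,
    kde_landscape,
    pick_representative_frames,
)
from crystbio.synth import gen_two_domain_trajectory

gen = gen_two_domain_trajectory(
    angle_major=20.0, angle_minor=8.0, occupancy_minor=0.2,
    jitter_sigma=0.2, n_frames=2000, seed=7,
)
feats = featurize(gen.trajectory, gen.reference, gen.angle_definition)

grid = kde_landscape(feats)
print("KDE modes (rmsd A, angle deg, density):")
for m in grid.modes()[:2]:
    print(f"  rmsd {m[0]:.2f}  angle {m[1]:.2f}  density {m[2]:.3f}")
# Two modes: the major state near 20 degrees at low RMSD and the minor
# state near 8 degrees at higher RMSD from the reference.

labels, occupancy = assign_states(feats, gen.bounds)
accuracy = float(np.mean(labels == gen.labels))
print(f"occupancy: {occupancy}")
print(f"state-assignment accuracy vs scripted labels: {accuracy:.3f}")

reps = pick_representative_frames(feats, gen.bounds)
table = compare_conformations(
    gen.trajectory[reps["major"]],
    gen.trajectory[reps["minor"]],
    sites=[r for r in gen.reference.residues if gen.reference.residue_name(int(r)) == "ASP"],
)
print("\nlargest residue-COM distance changes (minor - major):")
print(table.head(5).to_string(index=False))
# Inter-domain pairs move by several Angstrom when the hinge closes;
# intra-domain distances are unchanged because the domains are rigid.
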