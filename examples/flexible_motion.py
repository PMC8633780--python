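"""Geometric simulation of flexible motion along a low-frequency mode.

The all-atom dimer is biased in 0.1 A steps along normal mode 07 while
bonding geometry (bond lengths, angles as 1-3 distances, locked torsions
as 1-4 distances), the retained non-covalent network (cut-off -4 kcal/mol)
and steric exclusion are restored after every step.  No force field: the
run measures how far the structure can travel before geometry can no
longer be restored to within 0.1 A."""

import numpy as np

from flexor.enm import build_enm, lowest_modes
from flexor.fixtures import two_helix_dimer
from flexor.geosim import GeoSimConfig, run_geosim
from flexor.structure_io import add_polar_hydrogens

s = add_polar_hydrogens(two_helix_dimer(seed=0))
enm_net = build_enm(s)
mode = lowest_modes(enm_net, 1)[0]

for direction in ("parallel", "antiparallel"):
    cfg = GeoSimConfig(direction=direction)
    ens = run_geosim(s, mode, cfg, enm_net=enm_net)
    per_atom = np.linalg.norm(ens.frames[-1] - ens.frames[0], axis=1)
    print(f"mode {mode.index:02d} {direction}: {ens.steps_completed} steps "
          f"({ens.halt_reason}), {len(ens.frames)} frames, "
          f"max atom displacement {per_atom.max():.2f} A, "
          f"final frame violation {ens.frame_violations[-1]:.3f} A")

# A run that reaches max_steps explored the full biased path; a run halting
# with geometry_unrestorable hit the amplitude limit the constraint network
# allows in that direction.  The per-atom displacement shows which parts of
# the structure carry the motion.
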