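"""Detect the cavity of a hemispherical bead cup with the dual-probe method.

The cup's mouth admits a water-sized probe (1.4 Å) but bridges the large
probe (3 Å), so the cavity lies inside the large-probe SES and outside the
small-probe one — exactly the definition of a pocket.  The brute-force
rolling-probe oracle gives an independent reference volume.
"""

import numpy as np

from nanopockets import PocketParams, detect_pockets
from nanopockets.fixtures import make_cup_fixture, oracle_pocket_volume

cup = make_cup_fixture(seed=1)          # 140 beads, inner radius 4.5 Å
params = PocketParams(spacing=0.5)      # probes 1.4 / 3.0 Å, cutoff 100 Å³

pockets = detect_pockets(cup, params)
print(f"pockets found: {len(pockets)}")
for p in pockets:
    cx, cy, cz = p.center
    print(f"  volume {p.volume:.1f} A^3, center ({cx:.2f}, {cy:.2f}, {cz:.2f}) A, "
          f"{len(p.wall_atom_ids)} wall atoms")

oracle = oracle_pocket_volume(cup, params, resolution=0.5)
print(f"oracle volume {oracle[0]:.1f} A^3 "
      f"(engine within {100 * abs(pockets[0].volume - oracle[0]) / oracle[0]:.1f}%)")
print("-> one pocket the size of the constructed cavity; its center sits at "
      "the cup's center, and every shell bead lines its wall.")
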