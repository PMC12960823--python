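"""Preserving domain integrity with rigid blocks.

Large rigid-body rotations strain plain elastic networks: the network has
no notion that a domain should move as one body, so its geometry can
distort along the way. Declaring the moving arm a rigid block connects all
its internal pairs cutoff-free with uniform unit springs. Here we compare
the same hinge transition with and without the block and measure how much
the arm's internal distances distort along the path.
"""

import numpy as np
from scipy.spatial.distance import pdist

from bdpath import BDParams, FixtureSpec, make_two_state, run_transition

pair = make_two_state(FixtureSpec(n_residues=60, motion="hinge", amplitude=70.0))
arm = list(range(30, 60))  # the rotating distal arm
d0 = pdist(pair.start.positions[arm])


def max_distortion(path):
    return max(np.sqrt(np.mean((pdist(f.positions[arm]) - d0) ** 2))
               for f in path.frames)


bd = BDParams(seed=3, max_checkpoints=4000)
free = run_transition(pair.start, pair.target, bd_params=bd)
blocked = run_transition(pair.start, pair.target, bd_params=bd,
                         rigid_blocks=[arm])

print(f"without rigid block: max RMS intra-arm distance distortion "
      f"{max_distortion(free):.2f} Å")
print(f"with rigid block:    max RMS intra-arm distance distortion "
      f"{max_distortion(blocked):.2f} Å")
print("the block keeps the arm's internal geometry while it rotates")
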