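"""Render one synthetic PNN stack and recover its mesh nodes.

A perineuronal net imaged with structured-illumination microscopy shows
its mesh junctions ("nodes") as diffraction-limited bright spots.  Here
we render a known 80-node net, detect the spots, and compare against the
generator's ground truth.
"""

import numpy as np
from scipy.spatial import cKDTree

from pnnkit import DetectParams, detect_nodes
from pnnkit.synthetic import PnnStackParams, generate_pnn_stack

params = PnnStackParams(n_nodes=80, shell_radius=5.0, snr=10.0)
stack, truth = generate_pnn_stack(params, seed=7)
print(f"stack shape (z, y, x): {stack.shape}, "
      f"voxel {stack.geometry.lateral_spacing} µm lateral / "
      f"{stack.geometry.axial_spacing} µm axial")

nodes = detect_nodes(stack, DetectParams(min_separation_um=0.4))
dist, _ = cKDTree(nodes.coords).query(truth.node_coords)

print(f"true nodes:      {truth.n_nodes}")
print(f"detected nodes:  {len(nodes)}")
print(f"median localization error: {np.median(dist) * 1000:.0f} nm")
# The detected count should sit within a few percent of 80 and the
# median error well below the 150 nm lateral resolution limit —
# sub-voxel refinement puts it near 20 nm.
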