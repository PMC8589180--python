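"""The two threshold operators behind the segmentation stages.

Phansalkar local thresholding binarizes low-contrast vessels against an
adaptive local mean/SD; Kapur max-entropy picks the global histogram split
maximizing the summed entropies of foreground and background — used here
to isolate the bright large SCP vessels.
"""

import numpy as np

from izmap import SceneParams, generate_scene, max_entropy_threshold, phansalkar_threshold

scene = generate_scene(SceneParams(stage_group="moderate", seed=7))

vessel_mask = phansalkar_threshold(scene.dcp)
frac = 100 * np.count_nonzero(vessel_mask) / vessel_mask.size
print(f"Phansalkar on DCP: {frac:.1f}% of pixels are vessel foreground")

level, scp_fg = max_entropy_threshold(scene.scp)
frac = 100 * np.count_nonzero(scp_fg) / scp_fg.size
print(f"max-entropy level on SCP: {level:.3f} -> {frac:.1f}% foreground")
# The entropy split separates vasculature from background; the artifact
# stage (scp_artifact_mask) then keeps only components of large-vessel
# calibre, discarding the capillary mesh.
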