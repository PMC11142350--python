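"""Per-label volumes, gray fractions, and the per-type volume breakdown.

Plants a toy labeled volume with two corresponding leaf regions plus a
"general" gray label (a coarse territory with no correspondence row of its
own) and walks through the volumetric accounting.
"""

import numpy as np

from atlasconcord import (
    AtlasHierarchy,
    CorrespondenceEdge,
    LabeledVolume,
    Region,
    classify_relations,
    cortical_fractions,
    gray_fraction,
    label_volumes,
    volume_by_relation_type,
)

arr = np.zeros((10, 10, 10), dtype=np.int32)
arr[0, 0, :3] = 1   # leaf region L1: 3 voxels
arr[1, 0, :3] = 2   # leaf region L2: 3 voxels
arr[2, 0, :4] = 9   # general gray label: 4 voxels
arr[3, 0, :2] = 7   # white-matter tract: 2 voxels
volume = LabeledVolume(arr, voxel_size=(1, 1, 1),
                       label_map={1: "L1", 2: "L2", 9: "GEN", 7: "WM"})

h = AtlasHierarchy("demo", [
    Region(100, "ROOT", "Whole brain", "gray", None),
    Region(1, "L1", "Leaf one", "gray", 100),
    Region(2, "L2", "Leaf two", "gray", 100),
    Region(9, "GEN", "General territory", "gray", 100),
    Region(7, "WM", "White tract", "white", 100),
])

print("label volumes (mm^3):", label_volumes(volume))
print(f"gray fraction of labeled volume: {gray_fraction(volume, h):.4f}")
# 10 of 12 labeled voxels are gray -> 0.8333

components = classify_relations(
    [CorrespondenceEdge("L1", "M1"), CorrespondenceEdge("L2", "M2")],
    ["L1", "L2"], ["M1", "M2"],
)
bd = volume_by_relation_type(volume, components, ["L1", "L2"], h)
print(bd.to_frame().to_string(index=False))
# Type I holds 6 of the 10 mm^3 of labeled gray (the 4 mm^3 general label
# counts toward the denominator but has no row of its own) -> 60.00%.

print("cortical composition:", cortical_fractions(volume, [1, 2], {1: "motor", 2: "visual"}))
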