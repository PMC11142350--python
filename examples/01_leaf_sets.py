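"""Extract a leaf-level region set from a hierarchical atlas ontology.

Builds a tiny cortical hierarchy, collapses its layer subdivisions into
their parent areas, and promotes an over-fine pair of subdivisions one
level up — the two standard curation moves that turn a raw ontology into a
flat leaf-level partition usable for cross-species comparison.
"""

from atlasconcord import (
    AtlasHierarchy,
    Region,
    collapse_layers,
    native_leaves,
    promote_to_parent,
    to_dot,
)

h = AtlasHierarchy(
    "demo-cortex",
    [
        Region(1, "ROOT", "Whole brain", "gray", None),
        Region(2, "MO", "Primary motor area", "gray", 1),
        Region(3, "MO1", "Primary motor area, layer 1", "gray", 2),
        Region(4, "MO5", "Primary motor area, layer 5", "gray", 2),
        Region(5, "RSP", "Retrosplenial area", "gray", 1),
        Region(6, "RSPv", "Retrosplenial area, ventral part", "gray", 5),
        Region(7, "RSPd", "Retrosplenial area, dorsal part", "gray", 5),
    ],
)

collapsed = collapse_layers(h)  # default layer name patterns
leaves = native_leaves(collapsed)
print("leaves after layer collapse:", sorted(collapsed[r].acronym for r in leaves.region_ids))
# -> MO (its layers folded in), RSPv, RSPd

promoted = promote_to_parent(leaves, collapsed, {6, 7})
print("after promoting RSPv+RSPd:", sorted(collapsed[r].acronym for r in promoted.region_ids))
print("provenance:", {collapsed[r].acronym: p for r, p in promoted.provenance.items()})
# MO is tagged layer_collapsed, RSP promoted_parent: the leaf set records
# how each member entered the partition.

print()
print(to_dot(collapsed))  # paste into GraphViz to see the pruned tree
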