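# atlasconcord

Cross-species brain-atlas reconciliation for comparative neuroanatomy.

Expert neuroanatomists group brain compartments into very different
hierarchies — across atlases of one species, and even more so between
species such as mouse and marmoset.  `atlasconcord` implements the
leaf-level reconciliation strategy: instead of comparing hierarchies, it
anchors all comparison on a flat set of *leaf-level structures* (the most
granular named compartments, after collapsing cortical layers and
occasional promotion one level up) and treats cross-species homology
candidates as a bipartite graph over the two species' leaf sets.

The toolkit is aimed at comparative neuroanatomists and atlas builders who
work with hierarchical ontologies (Allen-style nested JSON or flat
parent-child CSV) and co-registered labeled NIfTI volumes.

## What it computes

**Correspondence typing.** Connected components of the bipartite
correspondence graph are classified by their side cardinalities:

| code | meaning |
|------|---------|
| O    | no counterpart in the other species |
| I    | one-to-one |
| II   | 1 mouse region : n marmoset regions |
| III  | n mouse regions : 1 marmoset region |
| IV   | many-to-many |

with a star (`I*`, `IV*`) marking components containing any uncertain
edge.  `summarize` tabulates per-type counts and percentages per side;
`count_with_correspondence` counts regions belonging to any non-O
component.

**Hierarchy transplantation.** `transplant_hierarchy` prunes any atlas
tree to a chosen leaf set plus its ancestors, so either species' grouping
can be superimposed on the common leaf basis (idempotent; preserves the
leaf set exactly).

**Volumetric accounting.** Per-label physical volumes, gray-matter
fractions, per-relation-type volume breakdowns (with "general" gray labels
counted in the denominator but given no row of their own), and fractional
cortical composition.

**Segmentation merging.** For a primary parcellation refined by specialist
atlases: voxel-overlap matrices, row-normalized conditional probabilities
P(primary | secondary), maximum-concordance assignment restricted to a
declared scope, and scoped relabeling (`apply_refinement`, `merge_multi`)
that never changes the labeled voxel set and is order-invariant for
disjoint scopes.

**Synthetic fixtures.** `generate_pair` fabricates a full two-species
fixture — divergent hierarchies, blob label volumes, a refinement volume,
and correspondence edges with known types — so everything above is testable
without downloading any real atlas.

## Worked example

```python
from atlasconcord import CorrespondenceEdge, classify_relations, summarize

leaves_mouse = ["MEA", "FRP", "PVHf", "PVHlp", "PVHmpv", "AMBd", "AMBv", "LSS"]
leaves_marm  = ["ME", "A10", "A8C", "A8aD", "A8aV", "A8b", "PaPo", "AmbC", "AmbL", "VLLa"]
edges = (
    [CorrespondenceEdge("MEA", "ME")]
    + [CorrespondenceEdge("FRP", b) for b in ["A10", "A8C", "A8aD", "A8aV", "A8b"]]
    + [CorrespondenceEdge(a, "PaPo") for a in ["PVHf", "PVHlp", "PVHmpv"]]
    + [CorrespondenceEdge(a, b) for a in ["AMBd", "AMBv"] for b in ["AmbC", "AmbL"]]
)
components = classify_relations(edges, leaves_mouse, leaves_marm)
print(summarize(components, leaves_mouse, leaves_marm).to_text())
```

prints

```
 type  count_a  percent_a  count_b  percent_b
Total        8      100.0       10      100.0
    O        1       12.5        1       10.0
    I        1       12.5        1       10.0
   II        1       12.5        5       50.0
  III        3       37.5        1       10.0
   IV        2       25.0        2       20.0
```

— the medial amygdalar nucleus pairs one-to-one (I), the frontal pole fans
out to five marmoset areas (II), three paraventricular hypothalamic parts
converge on one marmoset nucleus (III), the ambiguus divisions are
many-to-many (IV), and one region per side has no counterpart (O).
Percentages are of each side's leaf total, rounded half-up.

More narrative walkthroughs live in `examples/` (leaf-set curation,
correspondence typing, volumetrics, refinement merging, querying), each
printing the numbers it computes.  A thin CLI (`atlasconcord summarize /
query / merge / fixtures`) wraps the same functions for shell use.

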