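"""Classify cross-species correspondence edges into relation types.

Uses a hand-curated excerpt of mouse/marmoset leaf-region links (medial
amygdalar nucleus, frontal pole, paraventricular hypothalamic parts,
ambiguus nucleus divisions...) and shows the computed O/I/II/III/IV codes
and the per-type breakdown table.
"""

from atlasconcord import (
    CorrespondenceEdge,
    classify_relations,
    count_with_correspondence,
    name_match_candidates,
    summarize,
)

leaves_mouse = ["MEA", "FRP", "PVHf", "PVHlp", "PVHmpv", "AMBd", "AMBv", "LSS"]
leaves_marm = ["ME", "A10", "A8C", "A8aD", "A8aV", "A8b", "PaPo", "AmbC", "AmbL", "VLLa"]

edges = (
    [CorrespondenceEdge("MEA", "ME", note="one-to-one")]
    + [CorrespondenceEdge("FRP", b) for b in ["A10", "A8C", "A8aD", "A8aV", "A8b"]]
    + [CorrespondenceEdge(a, "PaPo") for a in ["PVHf", "PVHlp", "PVHmpv"]]
    + [CorrespondenceEdge(a, b) for a in ["AMBd", "AMBv"] for b in ["AmbC", "AmbL"]]
)

components = classify_relations(edges, leaves_mouse, leaves_marm)
for c in sorted(components, key=lambda c: c.type_label):
    print(f"{c.type_label:>3}: {sorted(c.side_a)} <-> {sorted(c.side_b)}")
# MEA-ME is Type I; FRP fans out to five marmoset areas (II); three PVH
# parts converge on PaPo (III); the ambiguus divisions are many-to-many
# (IV); LSS and VLLa have no counterpart (O).

print()
print(summarize(components, leaves_mouse, leaves_marm).to_text())
na, nb = count_with_correspondence(components)
print(f"\nregions with a counterpart: mouse {na}/{len(leaves_mouse)}, "
      f"marmoset {nb}/{len(leaves_marm)}")

# The nomenclature "initial guess": word-order-insensitive name similarity.
cands = name_match_candidates(
    ["triangular septal nucleus"], ["triangular nucleus of septum"], threshold=0.8
)
print("\nname-match candidate:", cands[0])
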