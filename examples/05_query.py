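"""Query a region's cross-species correspondence and export views.

Generates a synthetic atlas pair, resolves a region from free text, reports
its counterparts, both ancestor chains and volumes, then writes coronal
slice images and DOT trees (matched colors across species).
"""

from pathlib import Path

from atlasconcord import (
    FixtureConfig,
    classify_relations,
    export_views,
    generate_pair,
    query,
    resolve_region,
)

pair = generate_pair(FixtureConfig(seed=21))
leaves_a = sorted(a for a in pair.truth_types if a.startswith("A"))
leaves_b = sorted(b for b in pair.truth_types if b.startswith("B"))
components = classify_relations(pair.truth_edges, leaves_a, leaves_b)

region = resolve_region("A0001", pair.hierarchy_a)
print(f"resolved: {region.acronym} ({region.name})")

result = query(region, "a", components, pair.hierarchy_a, pair.hierarchy_b,
               volume_home=pair.volume_a, volume_other=pair.volume_b)
print("relation type:", result.relation_type)
print("counterparts:", [r.acronym for r in result.counterpart_regions])
print("home path:", " < ".join(r.acronym for r in result.path_home))
for acr, mm3 in result.volumes_mm3.items():
    print(f"volume of {acr}: {mm3:.3f} mm^3")

out = Path("scratch/query_views")
files = export_views(result, out, pair.volume_a, pair.volume_b,
                     pair.hierarchy_a, pair.hierarchy_b)
print("wrote:", *[f.name for f in files])
# A Type O query would emit home-species files only: with no counterpart
# there is no counterpart tree or slice to show.
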