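"""Hierarchy loading, leaf extraction, promotion, interpolation, transplant."""

import json

import numpy as np
import pytest

from atlasconcord.ontology import (
    AtlasHierarchy,
    HierarchyError,
    LeafSet,
    Region,
    collapse_layers,
    interpolate_leaf_sets,
    load_hierarchy,
    native_leaves,
    path_to_root,
    promote_to_parent,
    save_hierarchy_csv,
    to_dot,
    transplant_hierarchy,
)
from conftest import make_random_hierarchy


# ---------------------------------------------------------------- loading
def test_load_parent_child_csv(tmp_path):
    p = tmp_path / "h.csv"
    p.write_text(
        "id,acronym,name,parent_id,tissue_class\n"
        "1,ROOT,Whole brain,,gray\n"
        "2,A,Area A,1,gray\n"
        "3,B,Area B,1,white\n"
    )
    h = load_hierarchy(p)
    assert h.root_id == 1
    assert h.leaf_ids() == {2, 3}
    assert h[3].tissue_class == "white"


def test_load_nested_json(tmp_path):
    p = tmp_path / "h.json"
    p.write_text(
        json.dumps(
            {
                "id": 1,
                "acronym": "ROOT",
                "name": "Whole brain",
                "children": [
                    {
                        "id": 2,
                        "acronym": "A",
                        "name": "Area A",
                        "children": [
                            {"id": 3, "acronym": "A1", "name": "Sub A1", "children": []}
                        ],
                    }
                ],
            }
        )
    )
    h = load_hierarchy(p)
    assert h.leaf_ids() == {3}
    assert h.ancestors(3) == (2, 1)


def test_orphan_parent_is_structural_error(tmp_path):
    p = tmp_path / "h.csv"
    p.write_text("id,acronym,name,parent_id\n1,R,Root,\n5,X,Area X,99\n")
    with pytest.raises(HierarchyError, match="99"):
        load_hierarchy(p)


def test_duplicate_id_rejected():
    regions = [
        Region(1, "R", "Root", "gray", None),
        Region(2, "A", "A", "gray", 1),
        Region(2, "B", "B", "gray", 1),
    ]
    with pytest.raises(HierarchyError, match="duplicate"):
        AtlasHierarchy("dup", regions)


def test_cycle_rejected():
    regions = [
        Region(1, "R", "Root", "gray", None),
        Region(2, "A", "A", "gray", 3),
        Region(3, "B", "B", "gray", 2),
    ]
    with pytest.raises(HierarchyError):
        AtlasHierarchy("cyc", regions)


def test_csv_round_trip(tmp_path, rng):
    h = make_random_hierarchy(40, rng)
    save_hierarchy_csv(h, tmp_path / "h.csv")
    h2 = load_hierarchy(tmp_path / "h.csv")
    assert set(h2.regions) == set(h.regions)
    assert all(h2[i].parent_id == h[i].parent_id for i in h.regions)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_tree_validity_edge_count(seed):
    h = make_random_hierarchy(30, np.random.default_rng(seed))
    n_edges = sum(1 for r in h.regions.values() if r.parent_id is not None)
    assert n_edges == len(h) - 1
    assert all(h.ancestors(rid)[-1] == h.root_id for rid in h.regions if rid != h.root_id)


# ---------------------------------------------------------------- leaves
def test_native_leaves_depth1(tiny_hierarchy):
    ls = native_leaves(tiny_hierarchy)
    assert ls.region_ids == {2, 3}
    assert set(ls.provenance.values()) == {"native_leaf"}


def test_single_node_root_is_leaf():
    h = AtlasHierarchy("one", [Region(1, "R", "Root", "gray", None)])
    assert native_leaves(h).region_ids == {1}


def test_native_leaves_matches_childless_scan(rng):
    h = make_random_hierarchy(50, rng)
    expected = {
        rid
        for rid in h.regions
        if not any(r.parent_id == rid for r in h.regions.values())
    }
    assert native_leaves(h).region_ids == expected


# ---------------------------------------------------------------- layer collapse
def test_collapse_layers_removes_layer_leaves(layered_hierarchy):
    h = collapse_layers(layered_hierarchy, [", layer"])
    assert 3 not in h and 4 not in h
    assert h.is_leaf(2)
    assert h.aliases == {3: 2, 4: 2}
    ls = native_leaves(h)
    assert ls.provenance[2] == "layer_collapsed"
    assert ls.provenance[5] == "native_leaf"


def test_collapse_no_match_is_identity(layered_hierarchy):
    h = collapse_layers(layered_hierarchy, ["no such layer pattern"])
    assert set(h.regions) == set(layered_hierarchy.regions)


def test_collapse_six_layers_alias_count():
    regions = [Region(1, "R", "Root", "gray", None), Region(2, "V1", "Visual area", "gray", 1)]
    for i in range(6):
        regions.append(
            Region(10 + i, f"V1l{i}", f"Visual area, layer {i + 1}", "gray", 2)
        )
    h = collapse_layers(AtlasHierarchy("v", regions), [", layer"])
    assert h.is_leaf(2)
    assert len(h.aliases) == 6
    assert set(h.aliases.values()) == {2}


def test_collapse_never_touches_nonlayer_ids(rng):
    h = make_random_hierarchy(40, rng)
    out = collapse_layers(h, ["layer 4"])  # no such names in the fixture
    assert set(out.regions) == set(h.regions)


def test_collapse_pattern_matching_root_errors(layered_hierarchy):
    with pytest.raises(HierarchyError, match="root"):
        collapse_layers(layered_hierarchy, ["Whole brain"])


# ---------------------------------------------------------------- promotion
def _promotable():
    return AtlasHierarchy(
        "promo",
        [
            Region(1, "R", "Root", "gray", None),
            Region(2, "RSP", "Retrosplenial area", "gray", 1),
            Region(3, "RSPv", "Retrosplenial area, ventral part", "gray", 2),
            Region(4, "RSPd", "Retrosplenial area, dorsal part", "gray", 2),
            Region(5, "X", "Other area", "gray", 1),
        ],
    )


def test_promote_whole_sibling_group():
    h = _promotable()
    ls = native_leaves(h)
    out = promote_to_parent(ls, h, {3, 4})
    assert out.region_ids == {2, 5}
    assert out.provenance[2] == "promoted_parent"
    out.validate_antichain(h)


def test_promote_partial_siblings_errors():
    h = _promotable()
    with pytest.raises(HierarchyError, match="partition"):
        promote_to_parent(native_leaves(h), h, {3})


def test_promote_unknown_member_errors():
    h = _promotable()
    with pytest.raises(ValueError, match="not in leaf set"):
        promote_to_parent(native_leaves(h), h, {2})


# ---------------------------------------------------------------- interpolation
def _primary_secondary():
    primary = AtlasHierarchy(
        "allen",
        [
            Region(1, "R", "Root", "gray", None),
            Region(2, "P", "Parent region", "gray", 1),
            Region(3, "Q", "Region Q", "gray", 1),
            Region(4, "Qa", "Q sub a", "gray", 3),
            Region(5, "Qb", "Q sub b", "gray", 3),
        ],
    )
    secondary = AtlasHierarchy(
        "paxinos",
        [
            Region(1, "R", "Root", "gray", None),
            Region(2, "P", "Parent region", "gray", 1),
            Region(6, "s1", "P sub one", "gray", 2),
            Region(7, "s2", "P sub two", "gray", 2),
            Region(3, "Q", "Region Q", "gray", 1),
            Region(8, "Qx", "Q other sub", "gray", 3),
        ],
    )
    return primary, secondary


def test_interpolate_adopts_secondary_leaves_under_primary_parent():
    primary, secondary = _primary_secondary()
    ls = interpolate_leaf_sets(primary, secondary)
    adopted_names = {ls.adopted_regions[r].name for r in ls.adopted_regions}
    assert adopted_names == {"P sub one", "P sub two"}
    assert 2 not in ls.region_ids  # replaced by adopted children (case 1)
    assert all(ls.provenance[r] == "interpolated" for r in ls.adopted_regions)


def test_interpolate_conflict_keeps_primary_leaves():
    # Q is parcelled Qa/Qb in primary and Qx in secondary: primary wins (case 3)
    primary, secondary = _primary_secondary()
    ls = interpolate_leaf_sets(primary, secondary)
    assert {4, 5} <= ls.region_ids
    assert "Qx" not in {r.acronym for r in ls.adopted_regions.values()}


def test_interpolate_identical_atlases_is_native(rng):
    h = make_random_hierarchy(30, rng)
    ls = interpolate_leaf_sets(h, h)
    assert ls.region_ids == native_leaves(h).region_ids
    assert not ls.adopted_regions


def test_interpolate_records_unmatched_secondary():
    primary, secondary = _primary_secondary()
    extra = AtlasHierarchy(
        "paxinos2",
        list(secondary.regions.values())
        + [Region(99, "ZZ", "Totally different name", "gray", 1)],
    )
    ls = interpolate_leaf_sets(primary, extra)
    assert 99 in ls.unmatched_secondary


# ---------------------------------------------------------------- transplant
def test_transplant_identity(rng):
    h = make_random_hierarchy(40, rng)
    out = transplant_hierarchy(h, native_leaves(h))
    assert set(out.regions) == set(h.regions)


def test_transplant_drops_leaf_keeps_internal(tiny_hierarchy):
    ls = LeafSet("tiny", frozenset({2}))
    out = transplant_hierarchy(tiny_hierarchy, ls)
    assert set(out.regions) == {1, 2}
    assert out.children[1] == (2,)


def test_transplant_empty_intersection_errors(tiny_hierarchy):
    with pytest.raises(HierarchyError):
        transplant_hierarchy(tiny_hierarchy, LeafSet("x", frozenset({99})))


@pytest.mark.parametrize("seed", range(5))
def test_transplant_random_subset_exhaustive(seed):
    rng = np.random.default_rng(seed)
    h = make_random_hierarchy(120, rng)
    leaves = sorted(h.leaf_ids())
    subset = frozenset(
        rng.choice(leaves, size=max(1, len(leaves) // 2), replace=False).tolist()
    )
    out = transplant_hierarchy(h, LeafSet("s", subset))
    # leaf set of result equals the subset
    assert out.leaf_ids() == subset
    # every retained node has >=1 retained leaf descendant (or is one)
    for rid in out.regions:
        desc = out.descendants(rid) | {rid}
        assert desc & subset
    # idempotence
    again = transplant_hierarchy(out, LeafSet("s", subset))
    assert set(again.regions) == set(out.regions)


def test_transplant_then_native_leaves_round_trip(rng):
    h = make_random_hierarchy(60, rng)
    leaves = sorted(h.leaf_ids())
    subset = frozenset(leaves[::2])
    out = transplant_hierarchy(h, LeafSet("s", subset))
    assert native_leaves(out).region_ids == subset


# ---------------------------------------------------------------- paths, DOT
def test_path_to_root_examples(tiny_hierarchy):
    assert [r.id for r in path_to_root(tiny_hierarchy, 1)] == [1]
    assert [r.id for r in path_to_root(tiny_hierarchy, 2)] == [2, 1]


def test_path_matches_parent_walk(rng):
    h = make_random_hierarchy(50, rng)
    for rid in list(h.regions)[::7]:
        walk = [rid]
        while h[walk[-1]].parent_id is not None:
            walk.append(h[walk[-1]].parent_id)
        assert [r.id for r in path_to_root(h, rid)] == walk


def test_path_unknown_id_errors(tiny_hierarchy):
    with pytest.raises(KeyError):
        path_to_root(tiny_hierarchy, 42)


def test_dot_export_mentions_all_edges(layered_hierarchy):
    dot = to_dot(layered_hierarchy)
    assert dot.startswith("digraph")
    assert dot.count("->") == len(layered_hierarchy) - 1
    ventricles = AtlasHierarchy(
        "v",
        [
            Region(1, "R", "Root", "gray", None),
            Region(2, "VS", "Ventricular systems", "ventricle", 1),
            Region(3, "A", "Area A", "gray", 1),
        ],
    )
    assert "VS" not in to_dot(ventricles, gray_only=True)


# ---------------------------------------------------------------- antichain property
@pytest.mark.parametrize("seed", range(8))
def test_leaf_sets_are_antichains(seed):
    rng = np.random.default_rng(seed)
    h = make_random_hierarchy(80, rng)
    ls = native_leaves(h)
    present = ls.region_ids
    for rid in present:
        assert not (present & set(h.ancestors(rid)))
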