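"""Relation typing, summaries, name matching and CSV round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atlasconcord.correspondence import (
    CorrespondenceEdge,
    classify_relations,
    count_with_correspondence,
    declared_type_mismatches,
    name_match_candidates,
    name_similarity,
    read_correspondence_csv,
    summarize,
    swap_sides,
    write_correspondence_csv,
)

# The published excerpt of hand-curated mouse/marmoset correspondences,
# with its printed relation codes.
TABLE1_LEAVES_A = [
    "MEA", "FRP", "PVHf", "PVHlp", "PVHmpv", "AMBd", "AMBv",
    "PBm", "PBmm", "MEV", "DN", "LSS",
]
TABLE1_LEAVES_B = [
    "ME", "A10", "A8C", "A8aD", "A8aV", "A8b", "PaPo", "AmbC", "AmbL",
    "MPB", "Me5", "Lat", "LatPC", "VLLa",
]
TABLE1_EDGES = (
    [CorrespondenceEdge("MEA", "ME")]
    + [CorrespondenceEdge("FRP", b) for b in ["A10", "A8C", "A8aD", "A8aV", "A8b"]]
    + [CorrespondenceEdge(a, "PaPo") for a in ["PVHf", "PVHlp", "PVHmpv"]]
    + [CorrespondenceEdge(a, b) for a in ["AMBd", "AMBv"] for b in ["AmbC", "AmbL"]]
    + [CorrespondenceEdge(a, "MPB") for a in ["PBm", "PBmm"]]
    + [CorrespondenceEdge("MEV", "Me5")]
    + [CorrespondenceEdge("DN", b) for b in ["Lat", "LatPC"]]
)
TABLE1_EXPECTED = {
    "MEA": "I", "FRP": "II", "PVHf": "III", "PVHlp": "III", "PVHmpv": "III",
    "AMBd": "IV", "AMBv": "IV", "PBm": "III", "PBmm": "III", "MEV": "I",
    "DN": "II", "LSS": "O",
}


def brute_force_components(edges, leaves_a, leaves_b):
    """Independent oracle: exhaustive reachability over the bipartite graph."""
    nodes = [("a", x) for x in leaves_a] + [("b", y) for y in leaves_b]
    adj = {n: set() for n in nodes}
    for e in edges:
        if e.side_a is None or e.side_b is None:
            continue
        adj[("a", e.side_a)].add(("b", e.side_b))
        adj[("b", e.side_b)].add(("a", e.side_a))
    seen, comps = set(), []
    for n in nodes:
        if n in seen:
            continue
        comp, frontier = {n}, [n]
        while frontier:
            cur = frontier.pop()
            for other in adj[cur]:
                if other not in comp:
                    comp.add(other)
                    frontier.append(other)
        seen |= comp
        comps.append(
            (
                frozenset(x for s, x in comp if s == "a"),
                frozenset(x for s, x in comp if s == "b"),
            )
        )
    return comps


def test_table1_excerpt_codes_recovered():
    comps = classify_relations(TABLE1_EDGES, TABLE1_LEAVES_A, TABLE1_LEAVES_B)
    computed = {a: c.relation_type for c in comps for a in c.side_a}
    assert computed == TABLE1_EXPECTED
    vlla = next(c for c in comps if "VLLa" in c.side_b)
    assert vlla.relation_type == "O" and not vlla.side_a


def test_empty_edges_all_O():
    comps = classify_relations([], ["a1", "a2"], ["b1"])
    assert all(c.relation_type == "O" for c in comps)
    assert len(comps) == 3
    assert count_with_correspondence(comps) == (0, 0)


def test_endpoint_outside_leaf_set_named():
    with pytest.raises(ValueError, match="XX"):
        classify_relations([CorrespondenceEdge("XX", "b1")], ["a1"], ["b1"])


def test_duplicate_edge_rejected():
    e = CorrespondenceEdge("a1", "b1")
    with pytest.raises(ValueError, match="duplicate"):
        classify_relations([e, CorrespondenceEdge("a1", "b1", note="again")],
                           ["a1"], ["b1"])


@pytest.mark.parametrize("seed", range(6))
def test_classification_matches_reachability_oracle(seed):
    rng = np.random.default_rng(seed)
    la = [f"a{i}" for i in range(30)]
    lb = [f"b{i}" for i in range(30)]
    pairs = set()
    while len(pairs) < 40:
        pairs.add((la[rng.integers(30)], lb[rng.integers(30)]))
    edges = [CorrespondenceEdge(a, b) for a, b in pairs]
    comps = classify_relations(edges, la, lb)
    expected = set(brute_force_components(edges, la, lb))
    assert {(c.side_a, c.side_b) for c in comps} == expected
    # cardinality rules
    for c in comps:
        na, nb = len(c.side_a), len(c.side_b)
        t = c.relation_type
        if na == 0 or nb == 0:
            assert t == "O"
        if t == "I":
            assert (na, nb) == (1, 1)
        if t == "II":
            assert na == 1 and nb > 1
        if t == "III":
            assert na > 1 and nb == 1
        if t == "IV":
            assert na > 1 and nb > 1


def test_adding_edge_never_increases_components(rng):
    la = [f"a{i}" for i in range(10)]
    lb = [f"b{i}" for i in range(10)]
    edges = []
    prev = len(classify_relations(edges, la, lb))
    for i in range(15):
        edges.append(
            CorrespondenceEdge(la[int(rng.integers(10))], lb[int(rng.integers(10))], note=str(i))
        )
        try:
            n = len(classify_relations(edges, la, lb))
        except ValueError:  # duplicate pair drawn
            edges.pop()
            continue
        assert n <= prev
        prev = n


# ---------------------------------------------------------------- swap
def test_swap_exchanges_II_III_and_is_involutive():
    comps = classify_relations(TABLE1_EDGES, TABLE1_LEAVES_A, TABLE1_LEAVES_B)
    swapped = swap_sides(comps)
    types = sorted(c.relation_type for c in comps)
    swapped_types = sorted(c.relation_type for c in swapped)
    assert types.count("II") == swapped_types.count("III")
    assert types.count("III") == swapped_types.count("II")
    assert types.count("I") == swapped_types.count("I")
    back = swap_sides(swapped)
    assert {(c.side_a, c.side_b) for c in back} == {(c.side_a, c.side_b) for c in comps}


# ---------------------------------------------------------------- summary
def test_summarize_planted_fixture():
    # 2x I, 1x II(1:3), 3x O per side over 10 A-leaves (2+1+3 + filler O)
    la = [f"a{i}" for i in range(6)]
    lb = [f"b{i}" for i in range(8)]
    edges = [
        CorrespondenceEdge("a0", "b0"),
        CorrespondenceEdge("a1", "b1"),
        CorrespondenceEdge("a2", "b2"),
        CorrespondenceEdge("a2", "b3"),
        CorrespondenceEdge("a2", "b4"),
    ]
    comps = classify_relations(edges, la, lb)
    s = summarize(comps, la, lb)
    assert s.count("I", "a") == 2 and s.count("I", "b") == 2
    assert s.count("II", "a") == 1 and s.count("II", "b") == 3
    assert s.count("O", "a") == 3 and s.count("O", "b") == 3
    assert s.pct("O", "a") == 50.0
    # partition invariant
    assert sum(s.count(t, "a") for t in s.rows) == len(la)
    assert sum(s.count(t, "b") for t in s.rows) == len(lb)


def test_summarize_all_O_is_100_percent():
    comps = classify_relations([], ["a1"], ["b1", "b2"])
    s = summarize(comps, ["a1"], ["b1", "b2"])
    assert s.pct("O", "a") == 100.0 and s.pct("O", "b") == 100.0


def test_summarize_half_up_rounding():
    # 268 of 627 must print as 42.74 (not 42.73)
    la = [f"a{i}" for i in range(627)]
    lb = [f"b{i}" for i in range(627)]
    edges = [CorrespondenceEdge(la[i], lb[i]) for i in range(268)]
    s = summarize(classify_relations(edges, la, lb), la, lb)
    assert s.pct("I", "a") == 42.74


def test_starred_components_get_separate_rows():
    la, lb = ["a1", "a2"], ["b1", "b2"]
    edges = [
        CorrespondenceEdge("a1", "b1", uncertain=True),
        CorrespondenceEdge("a2", "b2"),
    ]
    comps = classify_relations(edges, la, lb)
    s = summarize(comps, la, lb)
    assert s.count("I*", "a") == 1 and s.count("I", "a") == 1


def test_star_contagion_within_component():
    edges = [
        CorrespondenceEdge("a1", "b1"),
        CorrespondenceEdge("a1", "b2", uncertain=True),
    ]
    (comp,) = [
        c
        for c in classify_relations(edges, ["a1"], ["b1", "b2"])
        if c.side_a
    ]
    assert comp.type_label == "II*"


def test_declared_mismatch_checker():
    comps = classify_relations(TABLE1_EDGES, TABLE1_LEAVES_A, TABLE1_LEAVES_B)
    declared = dict(TABLE1_EXPECTED)
    declared["MEA"] = "II"  # plant a disagreement
    bad = declared_type_mismatches(comps, declared)
    assert set(bad) == {"MEA"}
    assert bad["MEA"] == ("II", "I")


# ---------------------------------------------------------------- similarity
def test_reordered_nomenclature_scores_high():
    s = name_similarity("triangular septal nucleus", "triangular nucleus of septum")
    assert s >= 0.8


def test_identical_names_score_one():
    assert name_similarity("Dentate nucleus", "dentate Nucleus.") == 1.0


def test_dissimilar_names_rejected_at_default_threshold():
    out = name_match_candidates(["cerebellum"], ["olfactory bulb"], threshold=0.8)
    assert out == []


def test_candidates_ranked_descending():
    out = name_match_candidates(
        ["medial amygdalar nucleus"],
        ["medial amygdaloid nucleus", "medial nucleus"],
        threshold=0.3,
    )
    assert [b for _, b, _ in out][0] == "medial amygdaloid nucleus"
    scores = [s for _, _, s in out]
    assert scores == sorted(scores, reverse=True)


@settings(max_examples=50, deadline=None)
@given(st.text(" abcdefgh", min_size=1, max_size=20), st.text(" abcdefgh", min_size=1, max_size=20))
def test_similarity_symmetric_and_bounded(a, b):
    s = name_similarity(a, b)
    assert 0.0 <= s <= 1.0
    assert s == name_similarity(b, a)


# ---------------------------------------------------------------- CSV
def test_csv_round_trip_small(tmp_path):
    edges = {
        CorrespondenceEdge("MEA", "ME", note="curated"),
        CorrespondenceEdge("FRP", "A10", uncertain=True),
        CorrespondenceEdge("LSS", None),
        CorrespondenceEdge(None, "VLLa"),
    }
    p = tmp_path / "edges.csv"
    write_correspondence_csv(edges, p)
    assert read_correspondence_csv(p) == edges


def test_csv_round_trip_random(tmp_path, rng):
    edges = {
        CorrespondenceEdge(f"a{rng.integers(1000)}", f"b{i}", bool(rng.integers(2)), f"n{i}")
        for i in range(100)
    }
    p = tmp_path / "edges.csv"
    write_correspondence_csv(edges, p)
    assert read_correspondence_csv(p) == edges


def test_csv_unknown_acronym_names_line(tmp_path):
    p = tmp_path / "edges.csv"
    p.write_text("side_a_acronym,side_b_acronym,uncertain,note\nMEA,ME,0,\nZZZ,ME,0,\n")
    with pytest.raises(ValueError, match=r"ZZZ"):
        read_correspondence_csv(p, ["MEA"], ["ME"])
    with pytest.raises(ValueError, match=r":3"):
        read_correspondence_csv(p, ["MEA"], ["ME"])
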