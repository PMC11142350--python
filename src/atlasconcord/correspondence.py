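"""Typed bipartite correspondences between two species' leaf-level regions.

Cross-species homology candidates between mouse and marmoset leaf-level
regions form a bipartite graph.  Its connected components fall into a small
taxonomy by side cardinalities:

====  ==========================================================
O     a region with no counterpart in the other species
I     one-to-one
II    one side-A region : n side-B regions (finer parcellation in B)
III   n side-A regions : one side-B region
IV    many-to-many
====  ==========================================================

with a star (``I*``, ``IV*``...) flagging components whose correspondence is
uncertain.  By convention side A is the mouse and side B the marmoset, so a
``II`` reads "one mouse region maps to several marmoset regions".

Regions are identified by their acronym strings throughout; leaf sets are
plain sets of acronyms (see :func:`acronym_leaves` for conversion from an
ontology-level :class:`~atlasconcord.ontology.LeafSet`).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from ._util import percent
from .ontology import AtlasHierarchy, LeafSet

__all__ = [
    "CorrespondenceEdge",
    "RelationComponent",
    "CorrespondenceSummary",
    "classify_relations",
    "swap_sides",
    "summarize",
    "count_with_correspondence",
    "name_similarity",
    "name_match_candidates",
    "read_correspondence_csv",
    "write_correspondence_csv",
    "declared_type_mismatches",
    "acronym_leaves",
]


@dataclass(frozen=True)
class CorrespondenceEdge:
    """A single curated link between a side-A and a side-B leaf region.

    One endpoint may be ``None``: such a row explicitly declares that the
    other endpoint has no counterpart (an explicit Type-O/U declaration)
    rather than linking two regions.
    """

    side_a: str | None
    side_b: str | None
    uncertain: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.side_a is None and self.side_b is None:
            raise ValueError("edge needs at least one endpoint")


@dataclass(frozen=True)
class RelationComponent:
    """One connected component of the correspondence graph."""

    side_a: frozenset[str]
    side_b: frozenset[str]
    starred: bool = False
    edges: tuple[CorrespondenceEdge, ...] = ()

    @property
    def relation_type(self) -> str:
        na, nb = len(self.side_a), len(self.side_b)
        if na == 0 or nb == 0:
            return "O"
        if na == 1 and nb == 1:
            return "I"
        if na == 1:
            return "II"
        if nb == 1:
            return "III"
        return "IV"

    @property
    def type_label(self) -> str:
        """Relation type with the uncertainty star, e.g. ``I*``."""
        return self.relation_type + ("*" if self.starred else "")

    @property
    def notes(self) -> tuple[str, ...]:
        return tuple(e.note for e in self.edges if e.note)


def acronym_leaves(ls: LeafSet, h: AtlasHierarchy) -> frozenset[str]:
    """Leaf-set members as acronym strings (including adopted regions)."""
    out = {h[rid].acronym for rid in ls.region_ids if rid in h}
    out |= {r.acronym for rid, r in ls.adopted_regions.items() if rid in ls.region_ids}
    return frozenset(out)


def classify_relations(
    edges: Iterable[CorrespondenceEdge],
    leaves_a: Iterable[str],
    leaves_b: Iterable[str],
) -> list[RelationComponent]:
    """Partition both leaf sets into typed relation components.

    Every leaf appears in exactly one component; leaves untouched by any
    edge become singleton Type-O components.  A component is starred iff any
    of its edges is flagged uncertain (uncertainty is contagious within a
    component).
    """
    set_a, set_b = frozenset(leaves_a), frozenset(leaves_b)
    edges = list(edges)
    for e in edges:
        if e.side_a is not None and e.side_a not in set_a:
            raise ValueError(f"edge endpoint {e.side_a!r} not in side-A leaf set")
        if e.side_b is not None and e.side_b not in set_b:
            raise ValueError(f"edge endpoint {e.side_b!r} not in side-B leaf set")

    g: nx.Graph = nx.Graph()
    g.add_nodes_from(("a", x) for x in set_a)
    g.add_nodes_from(("b", y) for y in set_b)
    declarations: dict[tuple[str, str], list[CorrespondenceEdge]] = {}
    seen: set[tuple[str | None, str | None]] = set()
    for e in edges:
        if (e.side_a, e.side_b) in seen:
            raise ValueError(f"duplicate edge ({e.side_a!r}, {e.side_b!r})")
        seen.add((e.side_a, e.side_b))
        if e.side_a is None:
            declarations.setdefault(("b", e.side_b), []).append(e)  # type: ignore[arg-type]
        elif e.side_b is None:
            declarations.setdefault(("a", e.side_a), []).append(e)
        else:
            g.add_edge(("a", e.side_a), ("b", e.side_b), edge=e)

    components: list[RelationComponent] = []
    for nodes in nx.connected_components(g):
        ca = frozenset(x for side, x in nodes if side == "a")
        cb = frozenset(x for side, x in nodes if side == "b")
        comp_edges = tuple(
            g.edges[u, v]["edge"] for u, v in g.subgraph(nodes).edges
        )
        decl = [d for n in nodes for d in declarations.get(n, [])]
        all_edges = tuple(comp_edges) + tuple(decl)
        starred = any(e.uncertain for e in all_edges)
        components.append(RelationComponent(ca, cb, starred, all_edges))
    components.sort(key=lambda c: (min(c.side_a | c.side_b),))
    return components


def swap_sides(components: Iterable[RelationComponent]) -> list[RelationComponent]:
    """Exchange the A/B roles (mouse-to-marmoset view becomes the reverse)."""
    return [
        RelationComponent(
            c.side_b,
            c.side_a,
            c.starred,
            tuple(
                CorrespondenceEdge(e.side_b, e.side_a, e.uncertain, e.note)
                for e in c.edges
            ),
        )
        for c in components
    ]


_ROW_ORDER = ["O", "I", "II", "III", "IV", "O*", "I*", "II*", "III*", "IV*"]


@dataclass(frozen=True)
class CorrespondenceSummary:
    """Per-type region counts and percentages for each side, table style."""

    rows: Mapping[str, tuple[int, float, int, float]]  # label -> (n_a, %a, n_b, %b)
    total_a: int
    total_b: int
    decimals: int = 2

    def count(self, label: str, side: str = "a") -> int:
        return self.rows[label][0 if side == "a" else 2]

    def pct(self, label: str, side: str = "a") -> float:
        return self.rows[label][1 if side == "a" else 3]

    def to_frame(self):
        """The summary as a pandas DataFrame, one row per relation type."""
        import pandas as pd

        order = [r for r in _ROW_ORDER if r in self.rows] + [
            r for r in self.rows if r not in _ROW_ORDER
        ]
        df = pd.DataFrame(
            [(lab, *self.rows[lab]) for lab in order],
            columns=["type", "count_a", "percent_a", "count_b", "percent_b"],
        )
        total = pd.DataFrame(
            [("Total", self.total_a, 100.0, self.total_b, 100.0)], columns=df.columns
        )
        return pd.concat([total, df], ignore_index=True)

    def to_text(self) -> str:
        df = self.to_frame()
        return df.to_string(index=False)


def summarize(
    components: Iterable[RelationComponent],
    leaves_a: Iterable[str],
    leaves_b: Iterable[str],
    decimals: int = 2,
) -> CorrespondenceSummary:
    """Tabulate region counts and half-up-rounded percentages per type.

    Starred components are reported in separate rows (``I*``, ``IV*``, ...),
    and counts per side sum to the side's leaf-set size.
    """
    set_a, set_b = frozenset(leaves_a), frozenset(leaves_b)
    counts: dict[str, list[int]] = {}
    covered_a: set[str] = set()
    covered_b: set[str] = set()
    for c in components:
        row = counts.setdefault(c.type_label, [0, 0])
        row[0] += len(c.side_a)
        row[1] += len(c.side_b)
        covered_a |= c.side_a
        covered_b |= c.side_b
    if covered_a != set_a or covered_b != set_b:
        raise ValueError(
            "components do not partition the leaf sets "
            f"(missing A: {sorted(set_a - covered_a)[:5]}, "
            f"missing B: {sorted(set_b - covered_b)[:5]})"
        )
    rows = {
        lab: (
            na,
            percent(na, len(set_a), decimals),
            nb,
            percent(nb, len(set_b), decimals),
        )
        for lab, (na, nb) in counts.items()
    }
    return CorrespondenceSummary(rows, len(set_a), len(set_b), decimals)


def count_with_correspondence(
    components: Iterable[RelationComponent],
) -> tuple[int, int]:
    """Regions per side that belong to any non-O component (certain or not)."""
    na = nb = 0
    for c in components:
        if c.relation_type != "O":
            na += len(c.side_a)
            nb += len(c.side_b)
    return na, nb


# ---------------------------------------------------------------------------
# nomenclature similarity
# ---------------------------------------------------------------------------

_STOPWORDS = {"of", "the", "and"}


def _normalize(name: str) -> str:
    tokens = re.sub(r"[^a-z0-9 ]+", " ", name.lower()).split()
    return " ".join(sorted(t for t in tokens if t not in _STOPWORDS))


def name_similarity(a: str, b: str) -> float:
    """Word-order-insensitive name similarity in [0, 1].

    Names are lowercased, stripped of punctuation and short stopwords, and
    token-sorted before sequence matching, so re-ordered nomenclature such
    as "triangular septal nucleus" / "triangular nucleus of septum" scores
    highly.  Symmetric by construction; 1.0 for identical normalized names.
    """
    na, nb = _normalize(a), _normalize(b)
    if na == nb:
        return 1.0
    return max(
        SequenceMatcher(None, na, nb).ratio(), SequenceMatcher(None, nb, na).ratio()
    )


def name_match_candidates(
    names_a: Sequence[str],
    names_b: Sequence[str],
    threshold: float = 0.8,
) -> list[tuple[str, str, float]]:
    """Candidate cross-species pairs by nomenclature similarity, best first.

    This reproduces the "initial guess" stage of correspondence curation:
    every pair scoring at least ``threshold`` is returned, ranked by
    descending similarity (name order breaks ties).  Candidates are a
    starting point for expert curation, not final correspondences.
    """
    if not names_a or not names_b:
        raise ValueError("both name lists must be nonempty")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = [
        (a, b, s)
        for a in names_a
        for b in names_b
        if (s := name_similarity(a, b)) >= threshold
    ]
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_CSV_HEADER = ["side_a_acronym", "side_b_acronym", "uncertain", "note"]


def write_correspondence_csv(
    edges: Iterable[CorrespondenceEdge], path: str | Path
) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_HEADER)
        for e in sorted(edges, key=lambda e: (e.side_a or "", e.side_b or "")):
            w.writerow([e.side_a or "", e.side_b or "", int(e.uncertain), e.note])


def read_correspondence_csv(
    path: str | Path,
    leaves_a: Iterable[str] | None = None,
    leaves_b: Iterable[str] | None = None,
) -> set[CorrespondenceEdge]:
    """Read curated correspondence rows; an empty side marks an explicit O.

    When leaf sets are supplied every acronym is validated against them and
    an unknown acronym raises naming it and its line number.
    """
    set_a = frozenset(leaves_a) if leaves_a is not None else None
    set_b = frozenset(leaves_b) if leaves_b is not None else None
    edges: set[CorrespondenceEdge] = set()
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(_CSV_HEADER[:2]) <= set(reader.fieldnames):
            raise ValueError(f"{path}: missing header columns {_CSV_HEADER[:2]}")
        for lineno, row in enumerate(reader, start=2):
            a = (row.get("side_a_acronym") or "").strip() or None
            b = (row.get("side_b_acronym") or "").strip() or None
            raw_u = (row.get("uncertain") or "0").strip().lower()
            if raw_u not in {"0", "1", "true", "false", ""}:
                raise ValueError(f"{path}:{lineno}: bad uncertain flag {raw_u!r}")
            if a is None and b is None:
                raise ValueError(f"{path}:{lineno}: row has no endpoints")
            if set_a is not None and a is not None and a not in set_a:
                raise ValueError(
                    f"{path}:{lineno}: acronym {a!r} not in side-A leaf set"
                )
            if set_b is not None and b is not None and b not in set_b:
                raise ValueError(
                    f"{path}:{lineno}: acronym {b!r} not in side-B leaf set"
                )
            edges.add(
                CorrespondenceEdge(a, b, raw_u in {"1", "true"}, row.get("note") or "")
            )
    return edges


def declared_type_mismatches(
    components: Iterable[RelationComponent],
    declared: Mapping[str, str],
    side: str = "a",
) -> dict[str, tuple[str, str]]:
    """Check hand-assigned codes against the computed classification.

    ``declared`` maps region acronym -> declared code (e.g. ``"II"``).
    Returns ``{acronym: (declared, computed)}`` for every disagreement,
    comparing both with and without the uncertainty star so that a
    component mixing certain and uncertain edges is flagged only when
    neither reading matches.
    """
    out: dict[str, tuple[str, str]] = {}
    for c in components:
        members = c.side_a if side == "a" else c.side_b
        for acr in members:
            want = declared.get(acr)
            if want is None:
                continue
            if want not in (c.relation_type, c.type_label):
                out[acr] = (want, c.type_label)
    return out
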