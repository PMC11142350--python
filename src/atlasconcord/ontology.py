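"""Hierarchical brain-atlas ontologies and leaf-level region extraction.

A brain atlas names regions and arranges them in a rooted tree: the root is
the whole brain and successive levels group ever finer compartments.  Across
species (and even across atlases of one species) the *grouping* differs far
more than the most granular compartments do, so cross-atlas comparison is
anchored on a flat *leaf set* — an antichain of regions that partitions the
brain.  This module loads hierarchies from the two ubiquitous on-disk
dialects (Allen-style nested JSON and flat parent-child CSV), derives leaf
sets under the standard curation rules (cortical-layer collapse, promotion
of a parent one level above an over-fine parcellation, interpolation between
two atlases of the same species), and "transplants" any hierarchy onto a
chosen leaf set by pruning it to those leaves and their ancestors.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Region",
    "AtlasHierarchy",
    "LeafSet",
    "HierarchyError",
    "load_hierarchy",
    "native_leaves",
    "collapse_layers",
    "promote_to_parent",
    "interpolate_leaf_sets",
    "transplant_hierarchy",
    "path_to_root",
    "to_dot",
    "DEFAULT_LAYER_PATTERNS",
]

TISSUE_CLASSES = ("gray", "white", "ventricle", "unspecified")

#: Default cortical-layer name patterns (case-insensitive substrings).
DEFAULT_LAYER_PATTERNS = [", layer"] + [
    f"layer {n}" for n in ("1", "2", "2/3", "3", "4", "5", "6", "6a", "6b")
]


class HierarchyError(ValueError):
    """Structural problem in an atlas hierarchy (cycle, orphan, duplicate id...)."""


@dataclass(frozen=True)
class Region:
    """One named brain compartment.

    Parameters
    ----------
    id
        Numeric label, unique within one atlas.
    acronym
        Short identifier (e.g. ``MEA``); nonempty.
    name
        Full name (e.g. ``Medial amygdalar nucleus``); nonempty.
    tissue_class
        ``gray``, ``white``, ``ventricle`` or ``unspecified``.
    parent_id
        Numeric label of the parent region, or ``None`` for the root.
    """

    id: int
    acronym: str
    name: str
    tissue_class: str = "unspecified"
    parent_id: int | None = None

    def __post_init__(self) -> None:
        if not self.acronym:
            raise ValueError(f"region {self.id}: empty acronym")
        if not self.name:
            raise ValueError(f"region {self.id}: empty name")
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(
                f"region {self.id}: tissue_class {self.tissue_class!r} "
                f"not one of {TISSUE_CLASSES}"
            )


class AtlasHierarchy:
    """A validated rooted tree of :class:`Region` objects.

    ``aliases`` records ids of removed regions (e.g. collapsed cortical
    layers) mapped onto the surviving region that absorbed them.
    """

    def __init__(
        self,
        atlas_name: str,
        regions: Iterable[Region],
        species: str = "other",
        aliases: Mapping[int, int] | None = None,
    ) -> None:
        self.atlas_name = atlas_name
        self.species = species
        self.regions: dict[int, Region] = {}
        for r in regions:
            if r.id in self.regions:
                raise HierarchyError(f"duplicate region id {r.id}")
            self.regions[r.id] = r
        if not self.regions:
            raise HierarchyError("empty hierarchy")

        roots = [r.id for r in self.regions.values() if r.parent_id is None]
        if len(roots) != 1:
            raise HierarchyError(f"expected exactly one root, found {sorted(roots)}")
        self.root_id: int = roots[0]

        self.children: dict[int, tuple[int, ...]] = {rid: () for rid in self.regions}
        kids: dict[int, list[int]] = {rid: [] for rid in self.regions}
        for r in self.regions.values():
            if r.parent_id is None:
                continue
            if r.parent_id not in self.regions:
                raise HierarchyError(
                    f"region {r.id} lists absent parent {r.parent_id}"
                )
            kids[r.parent_id].append(r.id)
        for rid, ch in kids.items():
            self.children[rid] = tuple(sorted(ch))

        # connectivity check: every region must reach the root (no cycles)
        reached = set()
        stack = [self.root_id]
        while stack:
            rid = stack.pop()
            reached.add(rid)
            stack.extend(self.children[rid])
        if reached != set(self.regions):
            stranded = sorted(set(self.regions) - reached)
            raise HierarchyError(f"cycle or disconnected regions: {stranded}")

        self.aliases: dict[int, int] = dict(aliases or {})
        self.by_acronym: dict[str, Region] = {r.acronym: r for r in self.regions.values()}

    # -- convenience ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.regions)

    def __contains__(self, region_id: int) -> bool:
        return region_id in self.regions

    def __getitem__(self, region_id: int) -> Region:
        try:
            return self.regions[region_id]
        except KeyError:
            raise KeyError(
                f"region id {region_id} not in atlas {self.atlas_name!r}"
            ) from None

    @property
    def root(self) -> Region:
        return self.regions[self.root_id]

    def is_leaf(self, region_id: int) -> bool:
        return not self.children[region_id]

    def leaf_ids(self) -> frozenset[int]:
        return frozenset(rid for rid in self.regions if self.is_leaf(rid))

    def descendants(self, region_id: int) -> frozenset[int]:
        """All strict descendants of ``region_id``."""
        out: set[int] = set()
        stack = list(self.children[region_id])
        while stack:
            rid = stack.pop()
            out.add(rid)
            stack.extend(self.children[rid])
        return frozenset(out)

    def ancestors(self, region_id: int) -> tuple[int, ...]:
        """Strict ancestors of ``region_id``, nearest first."""
        out: list[int] = []
        rid = self.regions[region_id].parent_id
        while rid is not None:
            out.append(rid)
            rid = self.regions[rid].parent_id
        return tuple(out)


@dataclass(frozen=True)
class LeafSet:
    """An antichain of region ids partitioning (part of) a brain.

    ``provenance`` records how each member entered the set: ``native_leaf``,
    ``layer_collapsed``, ``promoted_parent`` or ``interpolated``.  Leaf sets
    produced by :func:`interpolate_leaf_sets` may carry regions adopted from
    the secondary atlas under fresh ids (``adopted_regions``).
    """

    atlas_name: str
    region_ids: frozenset[int]
    provenance: Mapping[int, str] = field(default_factory=dict)
    adopted_regions: Mapping[int, Region] = field(default_factory=dict)
    unmatched_secondary: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        missing = self.region_ids - set(self.provenance)
        if missing:
            prov = dict(self.provenance)
            prov.update({rid: "native_leaf" for rid in missing})
            object.__setattr__(self, "provenance", prov)

    def __len__(self) -> int:
        return len(self.region_ids)

    def __contains__(self, region_id: int) -> bool:
        return region_id in self.region_ids

    def validate_antichain(self, h: AtlasHierarchy) -> None:
        """Raise if any member is an ancestor of another member of ``h``."""
        present = self.region_ids & set(h.regions)
        for rid in present:
            bad = present & set(h.ancestors(rid))
            if bad:
                raise HierarchyError(
                    f"leaf set not an antichain: {sorted(bad)} are ancestors of {rid}"
                )


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _regions_from_nested(node: dict, parent_id: int | None, out: list[Region]) -> None:
    out.append(
        Region(
            id=int(node["id"]),
            acronym=str(node["acronym"]),
            name=str(node["name"]),
            tissue_class=str(node.get("tissue_class", "unspecified")),
            parent_id=parent_id,
        )
    )
    for child in node.get("children", []):
        _regions_from_nested(child, int(node["id"]), out)


def load_hierarchy(
    path: str | Path,
    format: str | None = None,
    atlas_name: str | None = None,
    species: str = "other",
) -> AtlasHierarchy:
    """Load an atlas ontology from disk.

    Parameters
    ----------
    path
        File to read.
    format
        ``nested_json`` (Allen-style ``children`` arrays, possibly under a
        ``msg`` envelope) or ``parent_child_csv`` (header
        ``id,acronym,name,parent_id[,tissue_class]``).  Inferred from the
        file suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = "nested_json" if path.suffix.lower() == ".json" else "parent_child_csv"
    name = atlas_name or path.stem

    regions: list[Region] = []
    if format == "nested_json":
        data = json.loads(path.read_text())
        if isinstance(data, dict) and "msg" in data:  # Allen API envelope
            data = data["msg"][0]
        _regions_from_nested(data, None, regions)
    elif format == "parent_child_csv":
        with path.open(newline="") as fh:
            for lineno, row in enumerate(csv.DictReader(fh), start=2):
                raw_parent = (row.get("parent_id") or "").strip()
                try:
                    regions.append(
                        Region(
                            id=int(row["id"]),
                            acronym=row["acronym"].strip(),
                            name=row["name"].strip(),
                            tissue_class=(row.get("tissue_class") or "unspecified").strip()
                            or "unspecified",
                            parent_id=int(raw_parent) if raw_parent else None,
                        )
                    )
                except (KeyError, ValueError) as exc:
                    raise HierarchyError(f"{path}:{lineno}: malformed row ({exc})") from exc
    else:
        raise ValueError(f"unknown hierarchy format {format!r}")
    return AtlasHierarchy(name, regions, species=species)


def save_hierarchy_csv(h: AtlasHierarchy, path: str | Path) -> None:
    """Write the flat parent-child CSV dialect."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "acronym", "name", "parent_id", "tissue_class"])
        for rid in sorted(h.regions):
            r = h.regions[rid]
            w.writerow(
                [r.id, r.acronym, r.name, "" if r.parent_id is None else r.parent_id, r.tissue_class]
            )


# ---------------------------------------------------------------------------
# leaf-set construction
# ---------------------------------------------------------------------------

def native_leaves(h: AtlasHierarchy) -> LeafSet:
    """The childless regions of ``h`` as a leaf set.

    A leaf that absorbed collapsed descendants (see :func:`collapse_layers`)
    is tagged ``layer_collapsed``; all others ``native_leaf``.
    """
    absorbed = set(h.aliases.values())
    ids = h.leaf_ids()
    prov = {
        rid: ("layer_collapsed" if rid in absorbed else "native_leaf") for rid in ids
    }
    return LeafSet(h.atlas_name, ids, prov)


def collapse_layers(
    h: AtlasHierarchy, layer_patterns: Sequence[str] = DEFAULT_LAYER_PATTERNS
) -> AtlasHierarchy:
    """Remove cortical-layer subdivisions, folding them into their parent area.

    Any region whose *name* matches one of ``layer_patterns``
    (case-insensitive substring or regex) is removed together with its
    descendants; all removed ids become aliases of the nearest surviving
    ancestor.  A parent whose children are all removed becomes a leaf.
    """
    if not layer_patterns:
        raise ValueError("layer_patterns must be nonempty")
    pats = [re.compile(p, re.IGNORECASE) for p in layer_patterns]

    def matches(r: Region) -> bool:
        return any(p.search(r.name) for p in pats)

    doomed: set[int] = set()
    for r in h.regions.values():
        if matches(r):
            if r.id == h.root_id:
                raise HierarchyError(
                    f"layer pattern matches the root region {r.acronym!r}"
                )
            doomed.add(r.id)
            doomed |= h.descendants(r.id)

    aliases = dict(h.aliases)
    for rid in doomed:
        anc = next(a for a in h.ancestors(rid) if a not in doomed)
        aliases[rid] = anc
    survivors = [h.regions[rid] for rid in h.regions if rid not in doomed]
    return AtlasHierarchy(h.atlas_name, survivors, species=h.species, aliases=aliases)


def promote_to_parent(
    ls: LeafSet, h: AtlasHierarchy, region_ids_to_promote: Iterable[int]
) -> LeafSet:
    """Replace over-fine leaves by their common parent, one level up.

    Promotion is only valid sibling-group-wise: for every parent involved,
    *all* of its descendants present in ``ls`` must be promoted together,
    otherwise the parent would sit above a remaining member and the set
    would stop being a partition.
    """
    promote = set(region_ids_to_promote)
    outside = promote - ls.region_ids
    if outside:
        raise ValueError(f"regions not in leaf set: {sorted(outside)}")

    by_parent: dict[int, set[int]] = {}
    for rid in promote:
        pid = h[rid].parent_id
        if pid is None:
            raise HierarchyError("cannot promote the root")
        by_parent.setdefault(pid, set()).add(rid)

    new_ids = set(ls.region_ids)
    prov = dict(ls.provenance)
    for pid, group in by_parent.items():
        covered = ls.region_ids & h.descendants(pid)
        if covered != group:
            raise HierarchyError(
                f"promoting {sorted(group)} under parent {pid} would break the "
                f"partition: leaf-set members {sorted(covered - group)} also "
                f"descend from {pid}"
            )
        new_ids -= group
        for rid in group:
            prov.pop(rid, None)
        new_ids.add(pid)
        prov[pid] = "promoted_parent"
    result = LeafSet(ls.atlas_name, frozenset(new_ids), prov,
                     ls.adopted_regions, ls.unmatched_secondary)
    result.validate_antichain(h)
    return result


def interpolate_leaf_sets(
    primary: AtlasHierarchy,
    secondary: AtlasHierarchy,
    name_links: Mapping[str, str] | None = None,
) -> LeafSet:
    """Unify the leaf level of two atlases of the same species.

    ``name_links`` maps secondary region *names* onto primary region names;
    exact name matches are always linked.  Three cases are resolved:

    1. the primary atlas has only a parent where the secondary parcels
       finer — the secondary's leaves under the linked region are adopted
       (provenance ``interpolated``, fresh ids beyond the primary's range);
    2. the secondary has only a parent where the primary parcels finer —
       the primary's leaves are kept;
    3. both parcel a region differently at leaf level — the primary's
       leaves win (the primary is the atlas that carries the volumetric
       segmentation, so its regions take primacy).

    Secondary regions with no link into the primary are recorded in
    ``unmatched_secondary`` rather than raising.
    """
    links = {r.name: r.name for r in secondary.regions.values()
             if r.name in {p.name for p in primary.regions.values()}}
    if name_links:
        links.update(name_links)

    primary_by_name = {r.name: r for r in primary.regions.values()}
    sec_to_pri: dict[int, int] = {}
    for sec_name, pri_name in links.items():
        s = next((r for r in secondary.regions.values() if r.name == sec_name), None)
        p = primary_by_name.get(pri_name)
        if s is not None and p is not None:
            sec_to_pri[s.id] = p.id
    pri_to_sec = {p: s for s, p in sec_to_pri.items()}

    base = native_leaves(primary)
    ids = set(base.region_ids)
    prov = dict(base.provenance)
    adopted: dict[int, Region] = {}
    next_id = max(primary.regions) + 1
    adopted_sec_ids: set[int] = set()

    for pid in sorted(base.region_ids):
        sid = pri_to_sec.get(pid)
        if sid is None or secondary.is_leaf(sid):
            continue  # cases 2/3 (or unlinked): keep the primary leaf
        # case 1: the primary leaf corresponds to a secondary *parent*;
        # adopt the secondary's leaves beneath it
        sub_leaves = sorted(
            d for d in secondary.descendants(sid) if secondary.is_leaf(d)
        )
        ids.discard(pid)
        prov.pop(pid, None)
        for sleaf in sub_leaves:
            r = secondary[sleaf]
            new = Region(next_id, r.acronym, r.name, r.tissue_class, parent_id=None)
            adopted[next_id] = new
            ids.add(next_id)
            prov[next_id] = "interpolated"
            adopted_sec_ids.add(sleaf)
            next_id += 1

    unmatched = tuple(
        sorted(
            sid
            for sid in secondary.leaf_ids()
            if sid not in adopted_sec_ids and sid not in sec_to_pri
        )
    )
    return LeafSet(
        f"{primary.atlas_name}+{secondary.atlas_name}",
        frozenset(ids),
        prov,
        adopted_regions=adopted,
        unmatched_secondary=unmatched,
    )


# ---------------------------------------------------------------------------
# transplantation and paths
# ---------------------------------------------------------------------------

def transplant_hierarchy(
    h: AtlasHierarchy,
    leaves: LeafSet,
    id_map: Mapping[int, int] | None = None,
) -> AtlasHierarchy:
    """Superimpose ``h``'s grouping onto a fixed leaf set.

    The result contains exactly the leaf-set members present in ``h`` (after
    applying ``id_map``, which translates leaf-set ids into ``h`` ids) plus
    all their ancestors.  Leaves of ``h`` without a counterpart in the leaf
    set are dropped, as are internal nodes left with no surviving leaf
    descendant.
    """
    mapped = {id_map.get(rid, rid) if id_map else rid for rid in leaves.region_ids}
    targets = mapped & set(h.regions)
    if not targets:
        raise HierarchyError(
            f"no leaf-set member matches a region of atlas {h.atlas_name!r}"
        )
    for rid in targets:
        above = targets & set(h.ancestors(rid))
        if above:
            raise HierarchyError(
                f"mapped leaf set is not an antichain in {h.atlas_name!r}: "
                f"{sorted(above)} are ancestors of {rid}"
            )
    keep = set(targets)
    for rid in targets:
        keep.update(h.ancestors(rid))
    survivors = []
    for rid in sorted(keep):
        r = h.regions[rid]
        if rid in targets and h.children[rid]:
            # an internal node standing in for its pruned subtree becomes a leaf
            survivors.append(replace(r))
        else:
            survivors.append(r)
    aliases = {a: t for a, t in h.aliases.items() if t in keep}
    return AtlasHierarchy(h.atlas_name, survivors, species=h.species, aliases=aliases)


def path_to_root(h: AtlasHierarchy, region_id: int) -> list[Region]:
    """The chain of regions from ``region_id`` up to the root, inclusive."""
    return [h[region_id]] + [h[rid] for rid in h.ancestors(region_id)]


def to_dot(
    h: AtlasHierarchy,
    gray_only: bool = False,
    colors: Mapping[int, str] | None = None,
) -> str:
    """GraphViz DOT rendering of the hierarchy tree.

    ``gray_only`` drops non-gray regions (white matter and ventricles are
    conventionally omitted from plotted atlas trees); ``colors`` fills named
    nodes, letting corresponding regions share colors across figures.
    """
    keep = set(h.regions)
    if gray_only:
        keep = {
            rid
            for rid in h.regions
            if h.regions[rid].tissue_class in ("gray", "unspecified")
        }
        keep.add(h.root_id)
    lines = [f'digraph "{h.atlas_name}" {{', "  rankdir=LR;", "  node [shape=box];"]
    for rid in sorted(keep):
        r = h.regions[rid]
        style = ""
        if colors and rid in colors:
            style = f', style=filled, fillcolor="{colors[rid]}"'
        lines.append(f'  n{rid} [label="{r.acronym}\\n{r.name}"{style}];')
    for rid in sorted(keep):
        pid = h.regions[rid].parent_id
        if pid is not None and pid in keep:
            lines.append(f"  n{pid} -> n{rid};")
    lines.append("}")
    return "\n".join(lines) + "\n"
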