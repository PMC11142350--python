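"""Region lookup across a reconciled atlas pair.

Given both species' hierarchies, the classified correspondence components
and (optionally) labeled volumes, a query resolves a free-text region
reference, reports its counterparts in the other species with the relation
type, walks both ancestor chains, and can export coronal slice images plus
DOT trees with matched colors for corresponding regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .correspondence import RelationComponent
from .ontology import AtlasHierarchy, Region, path_to_root, to_dot
from .volumetric import LabeledVolume, label_volumes

__all__ = [
    "QueryResult",
    "RegionNotFoundError",
    "resolve_region",
    "query",
    "export_views",
]


class RegionNotFoundError(KeyError):
    """No region matches the query text; carries the nearest suggestions."""

    def __init__(self, text: str, suggestions: Sequence[str]):
        self.text = text
        self.suggestions = tuple(suggestions)
        super().__init__(
            f"no region matches {text!r}; nearest: {', '.join(suggestions) or '(none)'}"
        )


@dataclass(frozen=True)
class QueryResult:
    """Everything known about one queried leaf region."""

    query_region: Region
    side: str  # "a" or "b"
    relation_type: str | None
    counterpart_regions: tuple[Region, ...]
    path_home: tuple[Region, ...]
    paths_counterpart: tuple[tuple[Region, ...], ...]
    volumes_mm3: Mapping[str, float] = field(default_factory=dict)
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "query": self.query_region.acronym,
            "side": self.side,
            "relation_type": self.relation_type,
            "counterparts": [r.acronym for r in self.counterpart_regions],
            "path_home": [r.acronym for r in self.path_home],
            "paths_counterpart": [
                [r.acronym for r in p] for p in self.paths_counterpart
            ],
            "volumes_mm3": dict(self.volumes_mm3),
            "notes": list(self.notes),
        }


def _similarity(a: str, b: str) -> float:
    from .correspondence import name_similarity

    return name_similarity(a, b)


def resolve_region(
    text: str,
    hierarchy: AtlasHierarchy,
    floor: float = 0.5,
) -> Region | list[Region]:
    """Resolve free text to a region of ``hierarchy``.

    An exact acronym match (case-insensitive) wins outright; otherwise
    case-insensitive substring matches on name or acronym, then
    name-similarity candidates above ``floor``, are ranked.  A unique
    candidate is auto-selected; several are returned as a list; none raises
    :class:`RegionNotFoundError` carrying the three nearest names.
    """
    if not text:
        raise ValueError("empty query text")
    low = text.lower()
    for r in hierarchy.regions.values():
        if r.acronym.lower() == low:
            return r
    substr = [
        r
        for r in hierarchy.regions.values()
        if low in r.name.lower() or low in r.acronym.lower()
    ]
    if substr:
        candidates = sorted(substr, key=lambda r: (len(r.name), r.acronym))
    else:
        scored = sorted(
            ((_similarity(text, r.name), r) for r in hierarchy.regions.values()),
            key=lambda t: (-t[0], t[1].acronym),
        )
        candidates = [r for s, r in scored if s >= floor]
        if not candidates:
            raise RegionNotFoundError(text, [r.name for _, r in scored[:3]])
    if len(candidates) == 1:
        return candidates[0]
    return candidates


def _component_of(
    acronym: str, components: Iterable[RelationComponent], side: str
) -> RelationComponent | None:
    for c in components:
        members = c.side_a if side == "a" else c.side_b
        if acronym in members:
            return c
    return None


def query(
    region: Region,
    side: str,
    components: Iterable[RelationComponent],
    hierarchy_home: AtlasHierarchy,
    hierarchy_other: AtlasHierarchy,
    volume_home: LabeledVolume | None = None,
    volume_other: LabeledVolume | None = None,
) -> QueryResult | list[QueryResult]:
    """Report the cross-species correspondence of ``region``.

    Leaf regions yield one :class:`QueryResult`; an internal region expands
    to its constituent leaves and returns one result per leaf.  Regions of
    type O (or found in no component) report no counterparts, no
    counterpart paths and no counterpart volumes.
    """
    if region.id not in hierarchy_home:
        raise KeyError(
            f"region {region.acronym!r} not in atlas {hierarchy_home.atlas_name!r}"
        )
    components = list(components)
    if not hierarchy_home.is_leaf(region.id):
        leaves = sorted(
            (
                rid
                for rid in hierarchy_home.descendants(region.id)
                if hierarchy_home.is_leaf(rid)
            ),
        )
        return [
            query(
                hierarchy_home[rid],
                side,
                components,
                hierarchy_home,
                hierarchy_other,
                volume_home,
                volume_other,
            )  # type: ignore[misc]
            for rid in leaves
        ]

    comp = _component_of(region.acronym, components, side)
    relation = comp.type_label if comp is not None else None
    counterparts: tuple[Region, ...] = ()
    paths_other: tuple[tuple[Region, ...], ...] = ()
    notes: tuple[str, ...] = ()
    if comp is not None and comp.relation_type != "O":
        other_acrs = sorted(comp.side_b if side == "a" else comp.side_a)
        counterparts = tuple(
            hierarchy_other.by_acronym[a]
            for a in other_acrs
            if a in hierarchy_other.by_acronym
        )
        paths_other = tuple(
            tuple(path_to_root(hierarchy_other, r.id)) for r in counterparts
        )
        notes = comp.notes

    volumes: dict[str, float] = {}
    for vol, regions in ((volume_home, (region,)), (volume_other, counterparts)):
        if vol is None:
            continue
        vols = label_volumes(vol)
        acr_to_label = {a: l for l, a in vol.label_map.items()}
        for r in regions:
            lab = acr_to_label.get(r.acronym)
            if lab is not None and lab in vols:
                volumes[r.acronym] = vols[lab]

    return QueryResult(
        query_region=region,
        side=side,
        relation_type=relation,
        counterpart_regions=counterparts,
        path_home=tuple(path_to_root(hierarchy_home, region.id)),
        paths_counterpart=paths_other,
        volumes_mm3=volumes,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

_PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#17becf",
]


def centroid_slice(volume: LabeledVolume, labels: Iterable[int], axis: int = 1) -> int:
    """Deterministic slice index: floor of the mean voxel index along ``axis``."""
    mask = np.isin(volume.labels, list(labels))
    if not mask.any():
        raise ValueError("none of the requested labels appear in the volume")
    return int(np.floor(np.argwhere(mask)[:, axis].mean()))


def _slice_figure(
    volume: LabeledVolume,
    highlight: Mapping[int, str],
    axis: int,
    out_path: Path,
    title: str,
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    idx = centroid_slice(volume, list(highlight), axis)
    plane = np.take(volume.labels, idx, axis=axis)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(plane != volume.background_label, cmap="gray", vmin=0, vmax=2)
    for label, color in highlight.items():
        mask = plane == label
        if mask.any():
            overlay = np.zeros(plane.shape + (4,))
            overlay[mask] = matplotlib.colors.to_rgba(color, alpha=0.9)
            ax.imshow(overlay)
    # scale bar: 1 mm in voxels along the image x-axis
    remaining = [a for a in range(3) if a != axis]
    dx = volume.voxel_size[remaining[1]]
    bar_vox = 1.0 / dx
    ax.plot([2, 2 + bar_vox], [plane.shape[0] - 3] * 2, "w-", lw=3)
    ax.text(2, plane.shape[0] - 5, "1 mm", color="w", fontsize=8)
    ax.set_title(title)
    ax.set_axis_off()
    fig.savefig(out_path, dpi=100, bbox_inches="tight")
    plt.close(fig)


def export_views(
    result: QueryResult,
    out_dir: str | Path,
    volume_home: LabeledVolume | None = None,
    volume_other: LabeledVolume | None = None,
    hierarchy_home: AtlasHierarchy | None = None,
    hierarchy_other: AtlasHierarchy | None = None,
    coronal_axis: int = 1,
) -> list[Path]:
    """Write coronal slice images and DOT ancestor trees for a query result.

    The home species always gets its exports; the counterpart species only
    when a correspondence exists (types O/U produce home-side output only).
    Corresponding regions share colors across all emitted files.  Returns
    the written paths; a region unannotated in its volume is skipped with a
    note rather than failing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    home_acr = result.query_region.acronym

    colors = {home_acr: _PALETTE[0]}
    for i, r in enumerate(result.counterpart_regions):
        colors[r.acronym] = _PALETTE[(i + 1) % len(_PALETTE)]

    has_counterpart = bool(result.counterpart_regions)
    jobs: list[tuple[str, LabeledVolume | None, AtlasHierarchy | None, list[Region]]] = [
        ("home", volume_home, hierarchy_home, [result.query_region])
    ]
    if has_counterpart:
        jobs.append(
            ("counterpart", volume_other, hierarchy_other, list(result.counterpart_regions))
        )

    for tag, vol, hier, regions in jobs:
        if vol is not None:
            acr_to_label = {a: l for l, a in vol.label_map.items()}
            highlight = {
                acr_to_label[r.acronym]: colors[r.acronym]
                for r in regions
                if r.acronym in acr_to_label
            }
            present = {
                l for l in highlight if (vol.labels == l).any()
            }
            highlight = {l: c for l, c in highlight.items() if l in present}
            if highlight:
                p = out_dir / f"{home_acr}_{tag}_coronal.png"
                _slice_figure(vol, highlight, coronal_axis, p, f"{home_acr} ({tag})")
                written.append(p)
        if hier is not None:
            ids = {
                hier.by_acronym[r.acronym].id: colors[r.acronym]
                for r in regions
                if r.acronym in hier.by_acronym
            }
            chain: set[int] = set()
            for rid in ids:
                chain.add(rid)
                chain.update(hier.ancestors(rid))
            sub = AtlasHierarchy(
                hier.atlas_name,
                [hier.regions[rid] for rid in sorted(chain)],
                species=hier.species,
            )
            p = out_dir / f"{home_acr}_{tag}_tree.dot"
            p.write_text(to_dot(sub, colors=ids))
            written.append(p)
    return written
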