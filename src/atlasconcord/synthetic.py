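"""Self-contained two-species atlas fixtures with known ground truth.

Every other part of the toolkit is exercisable without downloading any real
atlas: this module fabricates a pair of species-specific hierarchies over
planted leaf sets, blob-shaped 3D label fields realizing those leaves, a
"refinement" volume subdividing chosen primary blobs, and a correspondence
edge set whose relation types are known by construction.

The fixtures emulate the *statistical* structure of real atlas pairs — a
configurable mix of O/I/II/III/IV components, divergent hierarchical
groupings per species, uncertain components, partial refinement — not
anatomical morphology: blobs are non-touching axis-aligned boxes so that
every volumetric ground truth is exact.  An optional ``noisy_borders`` mode
dilates refinement labels by one voxel to stress-test concordance
thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import round_half_up
from .correspondence import CorrespondenceEdge, classify_relations
from .ontology import AtlasHierarchy, Region
from .volumetric import LabeledVolume

__all__ = [
    "ComponentSpec",
    "FixtureConfig",
    "SyntheticAtlasPair",
    "normalize_type_mix",
    "edges_from_mix",
    "generate_pair",
    "plant_table2_mix",
    "table2_component_plan",
    "table3_component_plan",
    "TABLE2_COUNTS",
    "TABLE3_COUNTS",
]

#: Published per-type leaf-region counts (side A = mouse, side B = marmoset)
#: for the nomenclature comparison; used to plant realistic fixtures.
TABLE2_COUNTS = {
    "a": {"O": 161, "I": 268, "II": 45, "III": 104, "IV": 28, "I*": 12, "IV*": 9},
    "b": {"O": 59, "I": 268, "II": 135, "III": 33, "IV": 52, "I*": 12, "IV*": 10},
}

#: Published per-type counts of *volumetrically annotated* leaf regions.
TABLE3_COUNTS = {
    "a": {"O": 121, "I": 132, "II": 22, "III": 35, "IV": 22, "IV*": 5},
    "b": {"O": 64, "I": 132, "II": 69, "III": 17, "IV": 34, "IV*": 3},
}


@dataclass(frozen=True)
class ComponentSpec:
    """One planned relation component: ``n_a`` A-leaves vs ``n_b`` B-leaves."""

    kind: str  # O_a, O_b, I, II, III, IV
    n_a: int
    n_b: int
    starred: bool = False

    def __post_init__(self) -> None:
        expected = {
            "O_a": self.n_a >= 1 and self.n_b == 0,
            "O_b": self.n_a == 0 and self.n_b >= 1,
            "I": self.n_a == 1 and self.n_b == 1,
            "II": self.n_a == 1 and self.n_b > 1,
            "III": self.n_a > 1 and self.n_b == 1,
            "IV": self.n_a > 1 and self.n_b > 1,
        }
        if self.kind not in expected:
            raise ValueError(f"unknown component kind {self.kind!r}")
        if not expected[self.kind]:
            raise ValueError(
                f"cardinalities ({self.n_a}, {self.n_b}) invalid for kind {self.kind}"
            )

    @property
    def type_label(self) -> str:
        base = "O" if self.kind in ("O_a", "O_b") else self.kind
        return base + ("*" if self.starred else "")


_DEFAULT_SHAPES = {"II": (1, 2), "III": (2, 1), "IV": (2, 2)}


def normalize_type_mix(
    mix: Mapping[str, object] | Sequence[ComponentSpec],
) -> list[ComponentSpec]:
    """Expand a compact type-mix mapping into explicit component specs.

    A mapping uses keys ``O_a``, ``O_b``, ``I``, ``II``, ``III``, ``IV``
    (star suffix allowed, e.g. ``"I*"``) with values either a component
    count (many-sided kinds default to 1:2 / 2:1 / 2:2) or a list of side
    cardinalities: ``{"II": [3, 5]}`` plants a 1:3 and a 1:5 component.
    """
    if not isinstance(mix, Mapping):
        return list(mix)
    specs: list[ComponentSpec] = []
    for key in sorted(mix):
        starred = key.endswith("*")
        kind = key.rstrip("*")
        value = mix[key]
        if kind in ("O_a", "O_b", "I"):
            count = int(value)  # type: ignore[arg-type]
            na, nb = {"O_a": (1, 0), "O_b": (0, 1), "I": (1, 1)}[kind]
            specs.extend(ComponentSpec(kind, na, nb, starred) for _ in range(count))
        elif kind in ("II", "III", "IV"):
            if isinstance(value, int):
                shapes: list[tuple[int, int]] = [_DEFAULT_SHAPES[kind]] * value
            else:
                shapes = []
                for item in value:  # type: ignore[union-attr]
                    if kind == "II":
                        shapes.append((1, int(item)))  # type: ignore[arg-type]
                    elif kind == "III":
                        shapes.append((int(item), 1))  # type: ignore[arg-type]
                    else:
                        m, n = item  # type: ignore[misc]
                        shapes.append((int(m), int(n)))
            specs.extend(ComponentSpec(kind, m, n, starred) for m, n in shapes)
        else:
            raise ValueError(f"unknown type-mix key {key!r}")
    return specs


def edges_from_mix(
    specs: Sequence[ComponentSpec] | Mapping[str, object],
) -> tuple[set[CorrespondenceEdge], list[str], list[str], dict[str, str]]:
    """Realize a component plan as edges over fresh acronym leaf sets.

    Returns ``(edges, leaves_a, leaves_b, truth_types)`` where leaves are
    acronyms ``A0001...`` / ``B0001...`` and ``truth_types`` maps every leaf
    to its planted type label.  Many-many components are realized as
    complete bipartite subgraphs so they stay connected and unambiguous.
    """
    specs = normalize_type_mix(specs)
    edges: set[CorrespondenceEdge] = set()
    leaves_a: list[str] = []
    leaves_b: list[str] = []
    truth: dict[str, str] = {}

    def new_a() -> str:
        leaves_a.append(f"A{len(leaves_a) + 1:04d}")
        return leaves_a[-1]

    def new_b() -> str:
        leaves_b.append(f"B{len(leaves_b) + 1:04d}")
        return leaves_b[-1]

    for spec in specs:
        side_a = [new_a() for _ in range(spec.n_a)]
        side_b = [new_b() for _ in range(spec.n_b)]
        for acr in side_a + side_b:
            truth[acr] = spec.type_label
        if spec.kind == "I":
            edges.add(CorrespondenceEdge(side_a[0], side_b[0], spec.starred))
        elif spec.kind == "II":
            for b in side_b:
                edges.add(CorrespondenceEdge(side_a[0], b, spec.starred))
        elif spec.kind == "III":
            for a in side_a:
                edges.add(CorrespondenceEdge(a, side_b[0], spec.starred))
        elif spec.kind == "IV":
            for a in side_a:
                for b in side_b:
                    edges.add(CorrespondenceEdge(a, b, spec.starred))
        # O components: leaves stay isolated
    return edges, leaves_a, leaves_b, truth


def _scaled(count: int, scale: float) -> int:
    n = int(round_half_up(count * scale, 0))
    if count > 0 and n == 0:
        warnings.warn(
            f"scale {scale} rounds a planted count of {count} down to zero",
            stacklevel=3,
        )
    return n


def table2_component_plan(scale: float = 1.0) -> list[ComponentSpec]:
    """A component plan realizing the published nomenclature-level mix.

    At ``scale=1`` the per-side per-type leaf counts equal the printed
    breakdown exactly (side A 161/268/45/104/28/12/9 of 627; side B
    59/268/135/33/52/12/10 of 569).  The published table fixes side totals,
    not component sizes; the decomposition used here is the canonical one
    documented with the package (e.g. the 104:33 many-to-one mass splits
    into 28 components of 3:1 and 5 of 4:1).
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    plan: list[ComponentSpec] = []
    plan += [ComponentSpec("O_a", 1, 0)] * _scaled(161, scale)
    plan += [ComponentSpec("O_b", 0, 1)] * _scaled(59, scale)
    plan += [ComponentSpec("I", 1, 1)] * _scaled(268, scale)
    plan += [ComponentSpec("I", 1, 1, starred=True)] * _scaled(12, scale)
    plan += [ComponentSpec("II", 1, 3)] * _scaled(45, scale)
    plan += [ComponentSpec("III", 3, 1)] * _scaled(28, scale)
    plan += [ComponentSpec("III", 4, 1)] * _scaled(5, scale)
    plan += [ComponentSpec("IV", 2, 4)] * _scaled(10, scale)
    plan += [ComponentSpec("IV", 2, 3)] * _scaled(4, scale)
    star_shapes = [(2, 2), (2, 2), (2, 3), (3, 3)]
    plan += [
        ComponentSpec("IV", m, n, starred=True)
        for m, n in star_shapes[: _scaled(4, scale)]
    ]
    return plan


def table3_component_plan() -> list[ComponentSpec]:
    """A component plan realizing the published volumetric-leaf mix.

    Side totals: A 121/132/22/35/22/5 of 337; B 64/132/69/17/34/3 of 319.
    """
    plan: list[ComponentSpec] = []
    plan += [ComponentSpec("O_a", 1, 0)] * 121
    plan += [ComponentSpec("O_b", 0, 1)] * 64
    plan += [ComponentSpec("I", 1, 1)] * 132
    plan += [ComponentSpec("II", 1, 3)] * 19
    plan += [ComponentSpec("II", 1, 4)] * 3
    plan += [ComponentSpec("III", 2, 1)] * 16
    plan += [ComponentSpec("III", 3, 1)] * 1
    plan += [ComponentSpec("IV", 2, 3)] * 10
    plan += [ComponentSpec("IV", 2, 4)] * 1
    plan += [ComponentSpec("IV", 5, 3, starred=True)]
    return plan


@dataclass
class FixtureConfig:
    """Everything needed to generate one reproducible two-species fixture."""

    type_mix: Mapping[str, object] | Sequence[ComponentSpec] = field(
        default_factory=lambda: {"I": 4, "II": 2, "III": 1, "IV": 1, "O_a": 2, "O_b": 2}
    )
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    uncertain_fraction: float = 0.0
    hierarchy_depth: int = 3
    refinement_split: Mapping[str, int] | int = 2
    noisy_borders: bool = False
    seed: int = 0
    n_leaves_a: int | None = None
    n_leaves_b: int | None = None


@dataclass
class SyntheticAtlasPair:
    """A generated fixture with its complete ground truth."""

    hierarchy_a: AtlasHierarchy
    hierarchy_b: AtlasHierarchy
    volume_a: LabeledVolume
    volume_b: LabeledVolume
    refinement_volume: LabeledVolume
    truth_edges: set[CorrespondenceEdge]
    truth_types: dict[str, str]
    truth_refinement_map: dict[int, int]
    config: FixtureConfig


def _random_hierarchy(
    name: str, leaf_acronyms: Sequence[str], depth: int, rng: np.random.Generator,
    species: str,
) -> AtlasHierarchy:
    """Random agglomerative grouping of the leaves into a rooted tree.

    Distinct random streams per species give genuinely different groupings
    over (conceptually) shared leaves, mirroring how expert hierarchies of
    the same brain diverge above the leaf level.
    """
    regions = [
        Region(i + 1, acr, f"Region {acr}", "gray", parent_id=None)
        for i, acr in enumerate(leaf_acronyms)
    ]
    next_id = len(regions) + 1
    current = [r.id for r in regions]
    parent_of: dict[int, int] = {}
    level = 0
    while len(current) > 1 and level < depth - 1:
        order = list(current)
        rng.shuffle(order)
        groups: list[list[int]] = []
        i = 0
        while i < len(order):
            k = int(rng.integers(2, 5))
            groups.append(order[i : i + k])
            i += k
        if len(groups) == 1 and level < depth - 2:
            pass  # single group: becomes the root next round
        nxt: list[int] = []
        for g in groups:
            gid = next_id
            next_id += 1
            regions.append(
                Region(gid, f"G{name[-1]}{gid}", f"Group {name} {gid}", "gray", None)
            )
            for child in g:
                parent_of[child] = gid
            nxt.append(gid)
        current = nxt
        level += 1
    root_id = next_id
    regions.append(Region(root_id, f"ROOT{name[-1]}", f"Brain {name}", "gray", None))
    for node in current:
        parent_of[node] = root_id
    final = [
        Region(r.id, r.acronym, r.name, r.tissue_class, parent_of.get(r.id))
        for r in regions
    ]
    return AtlasHierarchy(name, final, species=species)


def _pack_blobs(
    n: int,
    grid_shape: tuple[int, int, int],
    rng: np.random.Generator,
) -> list[tuple[slice, slice, slice]]:
    """Place ``n`` non-touching boxes on a lattice over the grid."""
    dims = [1, 1, 1]
    while dims[0] * dims[1] * dims[2] < n:
        dims[int(np.argmin(dims))] += 1
    cells = [g // d for g, d in zip(grid_shape, dims)]
    if min(cells) < 3:
        raise ValueError(
            f"grid {grid_shape} cannot host {n} non-touching blobs; "
            f"use a larger grid"
        )
    out = []
    order = [
        (i, j, k)
        for i in range(dims[0])
        for j in range(dims[1])
        for k in range(dims[2])
    ][:n]
    for cell in order:
        box = []
        for axis in range(3):
            lo = cell[axis] * cells[axis] + 1
            hi_max = (cell[axis] + 1) * cells[axis] - 1
            size = int(rng.integers(2, hi_max - lo + 1)) if hi_max - lo > 2 else hi_max - lo
            box.append(slice(lo, lo + size))
        out.append(tuple(box))
    return out


def generate_pair(cfg: FixtureConfig) -> SyntheticAtlasPair:
    """Generate a deterministic two-species fixture from ``cfg``.

    The correspondence ground truth is checked for self-consistency before
    returning: running the relation classifier on the planted edges must
    reproduce the planted types exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    specs = normalize_type_mix(cfg.type_mix)
    if cfg.uncertain_fraction > 0:
        specs = [
            ComponentSpec(
                s.kind,
                s.n_a,
                s.n_b,
                s.starred
                or (s.kind not in ("O_a", "O_b") and rng.random() < cfg.uncertain_fraction),
            )
            for s in specs
        ]
    edges, leaves_a, leaves_b, truth_types = edges_from_mix(specs)
    if cfg.n_leaves_a is not None and len(leaves_a) != cfg.n_leaves_a:
        raise ValueError(
            f"type_mix implies {len(leaves_a)} side-A leaves, not {cfg.n_leaves_a}"
        )
    if cfg.n_leaves_b is not None and len(leaves_b) != cfg.n_leaves_b:
        raise ValueError(
            f"type_mix implies {len(leaves_b)} side-B leaves, not {cfg.n_leaves_b}"
        )

    # distinct substreams: hierarchies diverge, volumes are independent
    h_a = _random_hierarchy(
        "SynthA", leaves_a, cfg.hierarchy_depth, np.random.default_rng(cfg.seed * 2 + 1),
        species="mouse",
    )
    h_b = _random_hierarchy(
        "SynthB", leaves_b, cfg.hierarchy_depth, np.random.default_rng(cfg.seed * 2 + 2),
        species="marmoset",
    )

    def build_volume(h: AtlasHierarchy, acronyms: Sequence[str]) -> LabeledVolume:
        arr = np.zeros(cfg.grid_shape, dtype=np.int32)
        boxes = _pack_blobs(len(acronyms), cfg.grid_shape, rng)
        label_map: dict[int, str] = {}
        for acr, box in zip(acronyms, boxes):
            rid = h.by_acronym[acr].id
            arr[box] = rid
            label_map[rid] = acr
        return LabeledVolume(arr, cfg.voxel_size, label_map)

    volume_a = build_volume(h_a, leaves_a)
    volume_b = build_volume(h_b, leaves_b)

    # refinement volume: subdivide chosen side-B blobs into sublabel slabs
    split: dict[str, int]
    if isinstance(cfg.refinement_split, int):
        k = min(len(leaves_b), max(0, cfg.refinement_split))
        split = {acr: 2 for acr in leaves_b[:k]}
    else:
        split = {acr: int(n) for acr, n in cfg.refinement_split.items()}
    ref = np.zeros(cfg.grid_shape, dtype=np.int32)
    ref_map: dict[int, str] = {}
    truth_refinement: dict[int, int] = {}
    next_sub = max(volume_b.label_map, default=0) + 1
    for acr, n_sub in split.items():
        if acr not in h_b.by_acronym:
            raise ValueError(f"refinement_split names unknown region {acr!r}")
        parent_label = h_b.by_acronym[acr].id
        mask = volume_b.labels == parent_label
        idx = np.argwhere(mask)
        if idx.size == 0:
            continue
        axis = int(np.argmax(idx.max(axis=0) - idx.min(axis=0)))
        coords = idx[:, axis]
        # slab boundaries by coordinate quantiles keep sublabels non-empty
        edges_ax = np.quantile(coords, np.linspace(0, 1, n_sub + 1))
        for s in range(n_sub):
            lo, hi = edges_ax[s], edges_ax[s + 1]
            sel = (coords >= lo) & ((coords < hi) | (s == n_sub - 1))
            sub_idx = idx[sel]
            ref[tuple(sub_idx.T)] = next_sub
            ref_map[next_sub] = f"{acr}.{s + 1}"
            truth_refinement[next_sub] = parent_label
            next_sub += 1
    if cfg.noisy_borders and truth_refinement:
        from scipy import ndimage

        for sub in sorted(truth_refinement):
            grown = ndimage.binary_dilation(ref == sub)
            ref[grown & (ref == 0)] = sub
    refinement_volume = LabeledVolume(ref, cfg.voxel_size, ref_map)

    computed = classify_relations(edges, leaves_a, leaves_b)
    computed_types = {
        acr: c.type_label for c in computed for acr in (c.side_a | c.side_b)
    }
    if computed_types != truth_types:
        raise AssertionError("generated fixture failed self-consistency check")

    return SyntheticAtlasPair(
        h_a,
        h_b,
        volume_a,
        volume_b,
        refinement_volume,
        edges,
        truth_types,
        truth_refinement,
        cfg,
    )


def plant_table2_mix(scale: float = 1.0, seed: int = 0) -> FixtureConfig:
    """A fixture config reproducing the published per-type proportions.

    At ``scale=1`` the side-A counts are exactly the published ones
    (161 O, 268 I, 45 II, 104 III, 28 IV, 12 I*, 9 IV* over 627 leaves);
    smaller scales shrink every component group with half-up rounding.
    """
    plan = table2_component_plan(scale)
    n_a = sum(s.n_a for s in plan)
    n_b = sum(s.n_b for s in plan)
    return FixtureConfig(
        type_mix=plan,
        grid_shape=(48, 48, 48) if max(n_a, n_b) <= 640 else (64, 64, 64),
        seed=seed,
        n_leaves_a=n_a,
        n_leaves_b=n_b,
    )
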