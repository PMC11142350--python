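"""Overlap-driven merging of co-registered labeled segmentations.

A primary whole-brain segmentation (e.g. a marmoset reference parcellation
that only annotates coarse territories in places) can be refined by
specialist atlases that subdivide some of its labels — one source for
cortex, another for subcortical structures.  Given already co-registered
volumes on one grid, the merge proceeds by:

1. counting voxel overlap between every (secondary, primary) label pair;
2. row-normalizing the counts into conditional probabilities
   P(primary label | secondary label);
3. assigning each secondary label to its maximum-concordance primary label,
   restricted to a declared scope of primary labels eligible for refinement;
4. relabeling, inside each assigned primary label only, the voxels carrying
   the corresponding secondary label.

Secondary voxels overhanging outside their assigned primary label keep the
primary label (the conservative automated rule; overhang volume is
reported).  Registration itself is out of scope: inputs must share shape
and voxel size.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .volumetric import LabeledVolume

__all__ = [
    "ConcordanceMatrix",
    "RefinementPlan",
    "overlap_matrix",
    "conditional_probabilities",
    "max_concordance",
    "bipartite_graph",
    "bipartite_dot",
    "write_plan_csv",
    "apply_refinement",
    "merge_multi",
    "default_offset",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcordanceMatrix:
    """Voxel-overlap counts between a secondary and a primary segmentation.

    ``overlap_counts[i, j]`` is the number of voxels carrying secondary
    label ``secondary_labels[i]`` and primary label ``primary_labels[j]``.
    ``cond_prob`` (filled by :func:`conditional_probabilities`) holds
    P(primary | secondary) per row; rows with no overlap stay all-zero.
    """

    primary_labels: tuple[int, ...]
    secondary_labels: tuple[int, ...]
    overlap_counts: np.ndarray
    cond_prob: np.ndarray | None = None

    def __post_init__(self) -> None:
        expected = (len(self.secondary_labels), len(self.primary_labels))
        if self.overlap_counts.shape != expected:
            raise ValueError(
                f"overlap_counts shape {self.overlap_counts.shape} != {expected}"
            )
        if (self.overlap_counts < 0).any():
            raise ValueError("overlap counts must be nonnegative")

    def unmapped_secondary(self) -> tuple[int, ...]:
        """Secondary labels with zero overlap against every primary label."""
        zero = self.overlap_counts.sum(axis=1) == 0
        return tuple(l for l, z in zip(self.secondary_labels, zero) if z)


def overlap_matrix(primary: LabeledVolume, secondary: LabeledVolume) -> ConcordanceMatrix:
    """Joint voxel counts for every (secondary, primary) label pair.

    Background is excluded on both sides; labels are enumerated from what is
    actually present in each array, so a secondary label supported only over
    primary background still appears (as an all-zero row).
    """
    if primary.labels.shape != secondary.labels.shape:
        raise ValueError(
            f"volumes are not on a common grid: primary shape "
            f"{primary.labels.shape} vs secondary shape {secondary.labels.shape}"
        )
    if primary.voxel_size != secondary.voxel_size:
        raise ValueError(
            f"voxel size mismatch: {primary.voxel_size} vs {secondary.voxel_size}"
        )
    pri_labels = tuple(int(l) for l in primary.present_labels())
    sec_labels = tuple(int(l) for l in secondary.present_labels())
    pri_index = {l: j for j, l in enumerate(pri_labels)}
    sec_index = {l: i for i, l in enumerate(sec_labels)}

    counts = np.zeros((len(sec_labels), len(pri_labels)), dtype=np.int64)
    p = primary.labels.ravel()
    s = secondary.labels.ravel()
    both = (p != primary.background_label) & (s != secondary.background_label)
    pairs, n = np.unique(
        np.stack([s[both], p[both]], axis=1), axis=0, return_counts=True
    )
    for (sl, pl), c in zip(pairs, n):
        counts[sec_index[int(sl)], pri_index[int(pl)]] = int(c)
    return ConcordanceMatrix(pri_labels, sec_labels, counts)


def conditional_probabilities(m: ConcordanceMatrix) -> ConcordanceMatrix:
    """Row-normalize overlap counts into P(primary label | secondary label)."""
    totals = m.overlap_counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(totals > 0, m.overlap_counts / totals, 0.0)
    for sl in m.unmapped_secondary():
        log.info("secondary label %d overlaps no primary label (unmapped)", sl)
    return ConcordanceMatrix(m.primary_labels, m.secondary_labels, m.overlap_counts, prob)


@dataclass(frozen=True)
class RefinementPlan:
    """Which secondary labels refine which in-scope primary labels.

    ``assignments`` maps each refining secondary label to exactly one
    primary label inside ``scope``.  Dropped secondary labels are reported
    by reason: argmax outside scope, concordance below threshold, or no
    overlap at all.
    """

    scope: frozenset[int]
    assignments: Mapping[int, int]
    source_name: str = ""
    out_of_scope: tuple[int, ...] = ()
    below_threshold: tuple[int, ...] = ()
    unmapped: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        bad = {p for p in self.assignments.values() if p not in self.scope}
        if bad:
            raise ValueError(f"assigned primary labels outside scope: {sorted(bad)}")


def max_concordance(
    m: ConcordanceMatrix,
    scope: Iterable[int],
    min_probability: float = 0.5,
    source_name: str = "",
) -> RefinementPlan:
    """Assign each secondary label to its maximum-concordance primary label.

    Assignments whose argmax falls outside ``scope`` are dropped (the
    bipartite graph is subsetted to the labels this source is trusted to
    refine), as are assignments below ``min_probability`` — those would
    otherwise need manual proofreading.  Ties on probability are broken by
    larger raw overlap count, then smaller primary label id, and logged.
    """
    if m.cond_prob is None:
        m = conditional_probabilities(m)
    scope_set = frozenset(int(l) for l in scope)
    assignments: dict[int, int] = {}
    out_of_scope: list[int] = []
    below: list[int] = []
    unmapped: list[int] = []
    for i, sl in enumerate(m.secondary_labels):
        row = m.cond_prob[i]
        if not row.any():
            unmapped.append(sl)
            continue
        best = row.max()
        tied = [j for j in range(len(row)) if row[j] == best]
        if len(tied) > 1:
            counts = m.overlap_counts[i]
            top = max(counts[j] for j in tied)
            tied = [j for j in tied if counts[j] == top]
            winner = min(tied, key=lambda j: m.primary_labels[j])
            log.warning(
                "secondary label %d ties on max concordance; choosing primary %d",
                sl,
                m.primary_labels[winner],
            )
        else:
            winner = tied[0]
        target = m.primary_labels[winner]
        if best < min_probability:
            below.append(sl)
        elif target not in scope_set:
            out_of_scope.append(sl)
        else:
            assignments[sl] = target
    return RefinementPlan(
        scope_set,
        assignments,
        source_name,
        tuple(out_of_scope),
        tuple(below),
        tuple(unmapped),
    )


def bipartite_graph(plan: RefinementPlan) -> list[tuple[int, int]]:
    """The plan as (secondary label, assigned primary label) edges."""
    return sorted(plan.assignments.items())


def bipartite_dot(plan: RefinementPlan) -> str:
    """DOT rendering of the refinement bipartite graph for inspection."""
    name = plan.source_name or "refinement"
    lines = [f'digraph "{name}" {{', "  rankdir=LR;"]
    for sl, pl in bipartite_graph(plan):
        lines.append(f'  "s{sl}" [label="sec {sl}"];')
        lines.append(f'  "p{pl}" [label="pri {pl}", shape=box];')
        lines.append(f'  "s{sl}" -> "p{pl}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_plan_csv(plan: RefinementPlan, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["secondary_label", "primary_label", "source"])
        for sl, pl in bipartite_graph(plan):
            w.writerow([sl, pl, plan.source_name])


def default_offset(*volumes: LabeledVolume) -> int:
    """Smallest power of ten exceeding every label id in the given volumes.

    Offsetting secondary labels by a round power of ten keeps merged ids
    readable (e.g. 1000 + 37) while guaranteeing no collision.
    """
    top = 1
    for v in volumes:
        present = v.present_labels()
        if present.size:
            top = max(top, int(present.max()))
        if v.label_map:
            top = max(top, max(v.label_map))
    offset = 10
    while offset <= top:
        offset *= 10
    return offset


def apply_refinement(
    primary: LabeledVolume,
    secondary: LabeledVolume,
    plan: RefinementPlan,
    label_offset: int | None = None,
) -> LabeledVolume:
    """Relabel, inside each assigned primary label, the refining secondary label.

    A voxel takes (offset + secondary label) iff its secondary label is
    assigned in the plan *and* its primary label equals that assignment;
    every other voxel — including secondary overhang outside the assigned
    primary label — keeps the primary label.  Secondary labels are
    renumbered by ``label_offset`` (default: :func:`default_offset`) and the
    output label map unions both atlases' entries with a source tag.
    """
    if primary.labels.shape != secondary.labels.shape:
        raise ValueError(
            f"volumes are not on a common grid: {primary.labels.shape} "
            f"vs {secondary.labels.shape}"
        )
    offset = default_offset(primary, secondary) if label_offset is None else label_offset
    sec_present = secondary.present_labels()
    if sec_present.size:
        lo = offset + int(sec_present.min())
        collisions = set(primary.label_map) & {
            offset + int(s) for s in sec_present
        }
        if lo <= 0 or collisions:
            raise ValueError(
                f"label offset {offset} collides with primary label ids "
                f"{sorted(collisions)[:5]}"
            )

    out = primary.labels.copy()
    overhang_voxels = 0
    for sl, pl in plan.assignments.items():
        sec_mask = secondary.labels == sl
        inside = sec_mask & (primary.labels == pl)
        out[inside] = offset + sl
        overhang_voxels += int(sec_mask.sum() - inside.sum())
    if overhang_voxels:
        log.info(
            "%d secondary voxels overhang their assigned primary label and keep "
            "the primary label (%.4f mm^3)",
            overhang_voxels,
            overhang_voxels * primary.voxel_volume_mm3,
        )

    label_map = dict(primary.label_map)
    sources = dict(primary.sources or {l: "primary" for l in primary.label_map})
    for sl, pl in plan.assignments.items():
        label_map[offset + sl] = secondary.acronym(sl)
        sources[offset + sl] = plan.source_name or "secondary"
    return LabeledVolume(
        out, primary.voxel_size, label_map, primary.background_label, sources
    )


def merge_multi(
    primary: LabeledVolume,
    refinements: Sequence[tuple[LabeledVolume, Iterable[int], str]],
    min_probability: float = 0.5,
    label_offsets: Mapping[str, int] | None = None,
) -> tuple[LabeledVolume, list[RefinementPlan]]:
    """Merge several refinement sources with pairwise-disjoint scopes.

    Each entry of ``refinements`` is ``(volume, scope, source_name)``.  Every
    plan is computed against the *original* primary volume, then applied
    sequentially; because scopes are disjoint the result is independent of
    application order.  Label offsets are keyed by source name (default:
    consecutive powers-of-ten blocks assigned in sorted source-name order,
    so the output does not depend on list order either).
    """
    scopes = [frozenset(int(l) for l in scope) for _, scope, _ in refinements]
    for i in range(len(scopes)):
        for j in range(i + 1, len(scopes)):
            clash = scopes[i] & scopes[j]
            if clash:
                raise ValueError(
                    f"refinement scopes overlap on primary labels {sorted(clash)[:5]} "
                    f"({refinements[i][2]!r} vs {refinements[j][2]!r})"
                )
    names = [name for _, _, name in refinements]
    if len(set(names)) != len(names):
        raise ValueError(f"refinement source names must be unique: {names}")

    if label_offsets is None:
        base = default_offset(primary, *(v for v, _, _ in refinements))
        label_offsets = {
            name: base * (k + 1) for k, name in enumerate(sorted(names))
        }

    plans: list[RefinementPlan] = []
    merged = primary
    for (volume, _, name), scope in zip(refinements, scopes):
        plan = max_concordance(
            conditional_probabilities(overlap_matrix(primary, volume)),
            scope,
            min_probability=min_probability,
            source_name=name,
        )
        plans.append(plan)
        merged = apply_refinement(merged, volume, plan, label_offsets[name])
    return merged, plans
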