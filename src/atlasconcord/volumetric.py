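"""Volumes, gray-matter fractions and per-relation-type volumetric breakdowns.

Works on co-registered 3D integer label fields (e.g. the 25 µm isotropic
mouse common-coordinate annotation, or a merged marmoset segmentation).
Physical volume is always ``voxel count x voxel volume`` — no partial-volume
modeling — and volumes are consumed as-is in voxel space (no reorientation).
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from ._util import percent, round_half_up
from .correspondence import RelationComponent
from .ontology import AtlasHierarchy

__all__ = [
    "LabeledVolume",
    "VolumeBreakdown",
    "label_volumes",
    "gray_fraction",
    "volume_by_relation_type",
    "cortical_fractions",
    "read_labeled_volume",
    "write_labeled_volume",
    "write_label_map_csv",
]

log = logging.getLogger(__name__)


@dataclass
class LabeledVolume:
    """A 3D integer label field with physical voxel spacing.

    ``label_map`` maps numeric labels to region acronyms; ``sources``
    optionally records which source atlas contributed each label after a
    merge.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    label_map: dict[int, str] = field(default_factory=dict)
    background_label: int = 0
    sources: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integer-typed, got {self.labels.dtype}")
        if len(self.voxel_size) != 3 or any(d <= 0 for d in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive extents, got {self.voxel_size}")
        self.voxel_size = tuple(float(d) for d in self.voxel_size)

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def present_labels(self) -> np.ndarray:
        """Sorted nonbackground labels actually present in the array."""
        u = np.unique(self.labels)
        return u[u != self.background_label]

    def unknown_labels(self) -> list[int]:
        """Labels present in the array but missing from ``label_map``."""
        return [int(l) for l in self.present_labels() if int(l) not in self.label_map]

    def acronym(self, label: int) -> str:
        return self.label_map.get(label, str(label))


def label_volumes(v: LabeledVolume) -> dict[int, float]:
    """Physical volume (mm^3) per nonbackground label."""
    labels, counts = np.unique(v.labels, return_counts=True)
    vv = v.voxel_volume_mm3
    return {
        int(l): float(c) * vv
        for l, c in zip(labels, counts)
        if int(l) != v.background_label
    }


def _tissue_class(v: LabeledVolume, h: AtlasHierarchy, label: int) -> str:
    acr = v.label_map.get(label)
    region = h.by_acronym.get(acr) if acr is not None else None
    return region.tissue_class if region is not None else "unspecified"


def gray_fraction(
    v: LabeledVolume, h: AtlasHierarchy, unspecified_as_gray: bool = True
) -> float:
    """Gray-class labeled volume over all labeled volume.

    Labels whose region carries no tissue class are counted as gray by
    default (and logged), since unannotated atlas labels are overwhelmingly
    gray-matter parcels; pass ``unspecified_as_gray=False`` to exclude them.
    """
    vols = label_volumes(v)
    if not vols:
        raise ValueError("volume contains no nonbackground labels")
    gray = 0.0
    for label, vol in vols.items():
        tc = _tissue_class(v, h, label)
        if tc == "unspecified":
            log.info("label %d (%s) has unspecified tissue class", label, v.acronym(label))
            if unspecified_as_gray:
                gray += vol
        elif tc == "gray":
            gray += vol
    return gray / sum(vols.values())


@dataclass(frozen=True)
class VolumeBreakdown:
    """Per-relation-type counts and volume shares for one labeled atlas.

    ``rows`` maps type label -> (region count, percent of labeled leaf
    regions, percent of labeled gray volume).  The gray-volume denominator
    includes *general labels* — gray labels naming non-leaf territories
    (e.g. a bare "Cerebellum" label) that contribute volume but have no
    correspondence row of their own.  ``total_gray_pct`` is the share of all
    labeled volume that is gray (the table's Total row); both denominators
    are reported explicitly.
    """

    rows: Mapping[str, tuple[int, float, float]]
    total_leaf_regions: int
    total_gray_pct: float
    labeled_gray_volume_mm3: float
    all_labeled_volume_mm3: float
    general_label_volume_mm3: float
    missing_regions: tuple[str, ...] = ()

    def count(self, label: str) -> int:
        return self.rows[label][0]

    def pct_regions(self, label: str) -> float:
        return self.rows[label][1]

    def pct_volume(self, label: str) -> float:
        return self.rows[label][2]

    def to_frame(self):
        import pandas as pd

        order = ["O", "I", "II", "III", "IV", "O*", "I*", "II*", "III*", "IV*"]
        labs = [r for r in order if r in self.rows] + [
            r for r in self.rows if r not in order
        ]
        df = pd.DataFrame(
            [(lab, *self.rows[lab]) for lab in labs],
            columns=["type", "count", "pct_regions", "pct_volume"],
        )
        total = pd.DataFrame(
            [("Total", self.total_leaf_regions, 100.0, self.total_gray_pct)],
            columns=df.columns,
        )
        return pd.concat([total, df], ignore_index=True)


def volume_by_relation_type(
    v: LabeledVolume,
    components: Iterable[RelationComponent],
    leaves: Iterable[str],
    h: AtlasHierarchy,
    side: str = "a",
    decimals: int = 2,
) -> VolumeBreakdown:
    """Tabulate, per correspondence type, region counts and gray-volume shares.

    ``leaves`` is the side's leaf-region acronym set; its type assignments
    come from ``components``.  Leaf regions absent from the volume (never
    annotated) are excluded from the counts and listed in
    ``missing_regions``.  Per-type volume percentages are taken of all
    labeled *gray* volume including general labels; the Total row's
    percentage is the gray share of all labeled volume.
    """
    leaf_set = frozenset(leaves)
    type_of: dict[str, str] = {}
    for c in components:
        for acr in c.side_a if side == "a" else c.side_b:
            type_of[acr] = c.type_label

    vols = label_volumes(v)
    acr_to_label = {acr: lab for lab, acr in v.label_map.items()}

    all_labeled = sum(vols.values())
    gray_vol = 0.0
    general_vol = 0.0
    leaf_rows: dict[str, list[float]] = {}
    labeled_leaves: set[str] = set()
    for label, vol in vols.items():
        acr = v.label_map.get(label)
        tc = _tissue_class(v, h, label)
        is_gray = tc in ("gray", "unspecified")
        if not is_gray:
            continue
        gray_vol += vol
        if acr in leaf_set:
            labeled_leaves.add(acr)
            t = type_of.get(acr, "O")
            row = leaf_rows.setdefault(t, [0, 0.0])
            row[0] += 1
            row[1] += vol
        else:
            general_vol += vol

    missing = tuple(
        sorted(
            acr
            for acr in leaf_set
            if acr not in labeled_leaves
            and (acr not in acr_to_label or acr_to_label[acr] not in vols)
        )
    )
    if missing:
        log.info(
            "%d leaf regions have no annotation in the volume and are excluded: %s",
            len(missing),
            ", ".join(missing[:10]),
        )

    n_leaf = len(labeled_leaves)
    rows = {
        lab: (
            int(n),
            percent(n, n_leaf, decimals),
            percent(vol, gray_vol, decimals),
        )
        for lab, (n, vol) in leaf_rows.items()
    }
    return VolumeBreakdown(
        rows=rows,
        total_leaf_regions=n_leaf,
        total_gray_pct=percent(gray_vol, all_labeled, decimals),
        labeled_gray_volume_mm3=gray_vol,
        all_labeled_volume_mm3=all_labeled,
        general_label_volume_mm3=general_vol,
        missing_regions=missing,
    )


def cortical_fractions(
    v: LabeledVolume,
    cortical_labels: Iterable[int],
    grouping: Mapping[int, str] | None = None,
) -> dict[str, float]:
    """Fractional composition of the cortex by named label groups.

    Fractions are of cortical volume only and sum to 1; cortical labels not
    covered by ``grouping`` fall into an ``"other"`` group.  Scale-free:
    invariant under uniform voxel-size rescaling.
    """
    cortical = set(int(l) for l in cortical_labels)
    if not cortical:
        raise ValueError("cortical_labels must be nonempty")
    grouping = dict(grouping or {})
    vols = label_volumes(v)
    totals: dict[str, float] = {}
    cortex_total = 0.0
    for label in cortical:
        vol = vols.get(label, 0.0)
        cortex_total += vol
        group = grouping.get(label, "other")
        totals[group] = totals.get(group, 0.0) + vol
    if cortex_total == 0:
        raise ValueError("no cortical label carries any voxels")
    return {g: t / cortex_total for g, t in totals.items()}


# ---------------------------------------------------------------------------
# NIfTI + label-map IO
# ---------------------------------------------------------------------------

def write_labeled_volume(
    v: LabeledVolume, path: str | Path, label_map_path: str | Path | None = None
) -> None:
    """Write a NIfTI-1 label volume (spacing in the header) + label-map CSV."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag(list(v.voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(v.labels, dtype=np.int32), affine)
    img.header.set_zooms(v.voxel_size)
    nib.save(img, str(path))
    if label_map_path is None:
        label_map_path = path.with_suffix("").with_suffix("")  # strip .nii(.gz)
        label_map_path = label_map_path.parent / (label_map_path.name + "_labels.csv")
    write_label_map_csv(v.label_map, label_map_path, v.sources)


def write_label_map_csv(
    label_map: Mapping[int, str],
    path: str | Path,
    sources: Mapping[int, str] | None = None,
) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "acronym", "source"] if sources else ["label", "acronym"])
        for label in sorted(label_map):
            row = [label, label_map[label]]
            if sources:
                row.append(sources.get(label, ""))
            w.writerow(row)


def read_label_map_csv(path: str | Path) -> dict[int, str]:
    out: dict[int, str] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            out[int(row["label"])] = row["acronym"]
    return out


def read_labeled_volume(
    path: str | Path,
    label_map_path: str | Path | None = None,
    background_label: int = 0,
) -> LabeledVolume:
    """Read a NIfTI-1 integer label volume; spacing comes from header zooms.

    A missing companion label map produces a warning and an identity map
    (each label names itself); float-typed data is an error.
    """
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(
            f"{path}: label volumes must be integer-typed, got {data.dtype}"
        )
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])

    if label_map_path is None:
        candidate = path.with_suffix("").with_suffix("")
        candidate = candidate.parent / (candidate.name + "_labels.csv")
        label_map_path = candidate if candidate.exists() else None
    if label_map_path is None:
        warnings.warn(
            f"{path}: no companion label map found; using identity map", stacklevel=2
        )
        u = np.unique(data)
        label_map = {int(l): str(int(l)) for l in u if int(l) != background_label}
    else:
        label_map = read_label_map_csv(label_map_path)
    return LabeledVolume(data, zooms, label_map, background_label)
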