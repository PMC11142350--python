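# Methods

## The reconciliation model

Two atlases of two species are each represented as a rooted tree of named
regions (`Region`: numeric id, acronym, full name, tissue class, parent).
The package's central object of comparison is not the tree but an
*antichain* of its regions — a leaf set that partitions (part of) the
brain.  All cross-species statements are made between two leaf sets; any
hierarchy can afterwards be superimposed on a leaf set by pruning
(transplantation), which makes the choice of grouping criteria orthogonal
to the homology bookkeeping.

Leaf-set curation follows three mechanisms, each exposed as an explicit
operation rather than baked-in policy, because the curated choices are
input data, not something the software can infer:

- **Layer collapse** — regions whose *name* matches a layer pattern
  (case-insensitive substring/regex; defaults `", layer"`, `"layer 1"` …
  `"layer 6b"`) are removed with their subtrees and recorded as aliases of
  the nearest surviving ancestor.  Matching on names rather than ids is
  deliberate: layer nomenclature is highly regular across atlases while
  ids are not.
- **Promotion** — replacing an over-fine sibling group by its parent.
  Promotion is only accepted sibling-group-wise (every leaf-set member
  descending from the parent must be promoted together); anything less
  breaks the partition property, which downstream code relies on.
- **Interpolation** between two atlases of one species — given a
  name-link map, the primary atlas's leaves win except where the primary
  has only a parent of the secondary's finer parcels, in which case those
  parcels are adopted under fresh ids with provenance `interpolated`.  The
  primary is by convention the atlas carrying the volumetric segmentation.

## Correspondence typing

Curated edges between leaf regions form a bipartite graph; relation codes
are a *computed property* of its connected components (O / I / II / III /
IV by side cardinalities).  This inverts the manual workflow — where codes
are assigned per row by hand — and a consistency checker
(`declared_type_mismatches`) flags any hand-assigned code that disagrees
with the computed one.  Where a component mixes certain and uncertain
edges the checker accepts either the starred or unstarred reading, since
the reporting convention for that case is genuinely underdetermined; the
summarizer itself uses conservative contagion (a component is starred if
*any* edge is uncertain).

Percentages are rounded half-up (not banker's rounding) to match how such
tables are conventionally printed; the published breakdown (e.g. 268/627 →
42.74%) reproduces exactly under this convention at 2 decimals.

Name-similarity candidates (the "initial guess" stage) use a
word-order-insensitive metric: lowercase, strip punctuation, drop
{of, the, and}, sort tokens, then difflib sequence-ratio, symmetrized by
taking the max over both argument orders.  The default threshold of 0.8
accepts reordered nomenclature ("triangular septal nucleus" vs "triangular
nucleus of septum" scores 0.92) while rejecting unrelated names.  The
metric is a screening heuristic; its candidates are inputs to curation,
never final correspondences.

## Volumetric accounting

Physical volume is voxel count × voxel volume, always; no partial-volume
modeling, no reorientation (inputs are assumed co-registered and are used
in voxel space).  Two denominators appear in the per-type breakdown and
both are reported explicitly:

- the **Total row** percentage is gray-class labeled volume over *all*
  labeled volume (white matter and ventricles in the denominator);
- **per-type** volume percentages are over labeled *gray* volume
  including "general" labels — gray labels naming non-leaf territories,
  which contribute volume but no correspondence row.  General labels are
  derived from the hierarchy: gray labels not in the supplied leaf set.

Labels whose region carries no tissue class count as gray by default (and
are logged); unannotated leaf regions are excluded from counts and listed
in a coverage report rather than raising, since real reference volumes
never annotate the full nomenclature.

## Segmentation merging

Given a primary volume and a refinement volume on the same grid, overlap
counts O(s, p) are row-normalized into conditional probabilities
P(p | s).  Each secondary label maps to its argmax primary label, subject
to:

- **scope** — assignments whose argmax falls outside the declared set of
  refinable primary labels are dropped (each specialist source is trusted
  only in its territory, and scopes of multiple sources must be disjoint);
- **threshold** — assignments with max probability below 0.5 (default)
  are dropped and reported; these are the cases that would otherwise need
  manual proofreading, which is out of scope for the automated pipeline;
- **ties** — broken by larger raw overlap count, then smaller primary
  label id, and logged.  Ties are a measure-zero event on real data but
  must be deterministic for reproducibility.

Relabeling is doubly scoped: a voxel takes the (offset) secondary label
only where its secondary label is assigned *and* its primary label equals
the assignment.  Secondary overhang therefore keeps the primary label —
the conservative automated stand-in for manual proofreading — and its
volume is logged.  Consequences proved in the tests: the labeled voxel
set never changes, each refined label's voxels are exactly its sublabels
plus residue, and `merge_multi` is order-invariant for disjoint scopes
(label offsets are keyed to sorted source names, not list position, so
even output ids are order-independent).

## Synthetic fixtures

The generator plants a configurable component mix (`type_mix`), realizes
A/B leaf sets and edges from it (complete bipartite within many-many
components), builds per-species hierarchies by random agglomeration from
*distinct* seed streams (so transplant tests exercise genuinely different
trees), and lays out each leaf as an axis-aligned box on a lattice with a
one-voxel gap.  Non-touching, voxel-aligned blobs make every volumetric
ground truth exact — planted volumes equal computed volumes to the float
product, and refinement sublabels (coordinate-quantile slabs of a parent
blob) are 100% contained, so concordance recovery has an exact target.
An optional `noisy_borders` mode dilates sublabels by one voxel to stress
the containment threshold.

Defaults: 48³ grid, 0.1 mm isotropic voxels, hierarchy depth 3, a small
mixed component plan, refinement splitting of the first few B-side leaves.
`table2_component_plan` / `table3_component_plan` reproduce the published
per-type counts exactly at scale 1 (the published tables fix side totals,
not component sizes; the canonical decompositions used are documented in
the docstrings).  Every generated fixture is self-checked: classifying the
planted edges must reproduce the planted types.

What the fixtures do **not** emulate: anatomical morphology, touching or
interdigitated boundaries, registration error, partial-volume mixing, or
imbalanced blob sizes.  Passing tests therefore demonstrate the
correctness of the bookkeeping and the merge logic under clean geometry,
not robustness to registration artifacts — the latter is exactly what the
manual-proofreading step of a real pipeline addresses.

## Query layer

Free-text resolution prefers exact acronym match, then unique
case-insensitive substring, then name-similarity ranking with a 0.5
floor; ambiguity returns candidates, absence raises with the three
nearest names.  Queries are pure functions of loaded state.  Slice
exports use the coronal axis declared in configuration (default: second
array axis — NIfTI orientation handling is deliberately minimal) and a
deterministic slice: floor of the mean voxel index of the queried labels
along that axis.  Type-O queries emit home-species views only.  3D
rendering is out of scope; 2D slices plus DOT trees with matched colors
across species replace it.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale by design:
classification/summary at the full published mix (627 + 569 leaves, ~700
edges), volumetric breakdowns on one-voxel-per-region or ≤32³ volumes
against per-voxel brute-force oracles, and merge recovery over 50 seeded
48³ fixtures.  The published volume-percentage column and cortical
fractions require the real reference volumes and are therefore covered by
planted-arithmetic property tests instead of value reproduction.
Floating-point tolerances: conditional-probability rows sum to 1 within
1e-12; printed percentages are compared exactly after half-up rounding to
2 decimals.
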