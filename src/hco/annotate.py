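"""From connectivity matrices to semantic annotations.

The pipeline mirrors how seed-based probabilistic tractography output is
summarized and encoded: voxel-wise connectivity is averaged into region-wise
matrices (one per white-matter seed mask, rows = target-mask-1 cortical
parcels, columns = all other parcels and subcortical regions), log-transformed,
row-normalized, thresholded into binary matrices, and finally turned into an
ABox: every parcel becomes a gray-matter-part individual hanging off a
subject-scoped partonomy chain (parcel -> gray matter of gyrus -> gyrus ->
further ancestors), nearest-neighbor parcels are linked ``continuous_with``,
and every surviving matrix cell produces one ``MR_Route`` individual
``tracto_connect``-ing its two endpoints plus a direct ``mr_connection``
between them.  Routes from a matrix seeded in a named fiber bundle are made
regional parts of the subject's bundle individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    ABox,
    CONSTITUTIONAL_PART_OF,
    CONTINUOUS_WITH,
    GRAY_MATTER_PART,
    IntegrityError,
    MR_CONNECTION,
    MR_ROUTE,
    REGIONAL_PART_OF,
    TRACTO_CONNECTS,
    TBox,
    TermName,
    hco,
)


class AnnotationError(IntegrityError):
    """Inconsistent parcellation/matrix inputs."""


# ---------------------------------------------------------------------------
# Input containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParcelInfo:
    parcel_id: int
    region_term: TermName      # enclosing gyrus/region class
    hemisphere: str            # left | right | midline


@dataclass
class Parcellation:
    subject_id: str
    parcels: tuple = ()                 # ParcelInfo, unique parcel_ids
    extra_regions: tuple = ()           # (region_id: str, region_term)
    #: region class -> further ancestor steps ((property, class), ...) hung
    #: off the per-subject region individual, innermost ancestor first
    partonomy_hints: dict = field(default_factory=dict)

    def validate(self) -> None:
        ids = [p.parcel_id for p in self.parcels]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AnnotationError(
                f"duplicate parcel ids in subject {self.subject_id}: {dupes}")
        rids = [r for r, _ in self.extra_regions]
        if len(rids) != len(set(rids)):
            raise AnnotationError(
                f"duplicate extra-region ids in subject {self.subject_id}")


@dataclass
class Adjacency:
    """Unordered nearest-neighbor pairs of parcel/region identifiers."""

    edges: set = field(default_factory=set)

    def add(self, a: str, b: str) -> None:
        if a == b:
            raise AnnotationError(f"self-adjacency on {a}")
        self.edges.add((min(a, b), max(a, b)))

    def validate(self, known_labels: set) -> None:
        for a, b in self.edges:
            if a == b:
                raise AnnotationError(f"self-adjacency on {a}")
            for end in (a, b):
                if end not in known_labels:
                    raise AnnotationError(f"adjacency endpoint {end!r} not in "
                                          "parcellation")


@dataclass
class RegionMatrix:
    """Labeled non-negative connectivity matrix for one seed mask."""

    row_labels: tuple
    col_labels: tuple
    values: np.ndarray
    seed_label: Optional[TermName] = None  # bundle class, None for rest-of-WM

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise AnnotationError(
                f"matrix shape {self.values.shape} does not match labels "
                f"({len(self.row_labels)} x {len(self.col_labels)})")
        if len(set(self.row_labels)) != len(self.row_labels) \
                or len(set(self.col_labels)) != len(self.col_labels):
            raise AnnotationError("matrix labels must be unique")
        if np.any(self.values < 0):
            raise AnnotationError("connectivity values must be non-negative")


@dataclass
class BinaryMatrix(RegionMatrix):
    def __post_init__(self):
        super().__post_init__()
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise AnnotationError("binary matrix must contain only 0/1")


@dataclass(frozen=True)
class AnnotationConfig:
    threshold: float = 0.7
    log_transform: str = "log1p_natural"
    row_normalization: str = "divide_by_row_max"
    node_name_template: str = "{subject}_gray_matter_of_{region}_{parcel_id}"
    route_name_template: str = "{subject}_mr_route_{counter}"

    def __post_init__(self):
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must lie in (0, 1]")
        if self.log_transform != "log1p_natural":
            raise ValueError(f"unknown log transform {self.log_transform!r}")
        if self.row_normalization != "divide_by_row_max":
            raise ValueError(
                f"unknown row normalization {self.row_normalization!r}")


# ---------------------------------------------------------------------------
# Matrix post-processing
# ---------------------------------------------------------------------------

def aggregate_voxelwise(voxel_matrix: RegionMatrix,
                        voxel_to_region: dict) -> RegionMatrix:
    """Average a voxel-wise matrix into a region-wise matrix.

    Entry (R, C) is the arithmetic mean of the voxel-wise values over all
    pairs of voxels (r in R, c in C).  Every voxel label must map to exactly
    one region; a region with no voxels is an error.
    """
    for axis_labels in (voxel_matrix.row_labels, voxel_matrix.col_labels):
        for v in axis_labels:
            if v not in voxel_to_region:
                raise AnnotationError(f"voxel {v!r} is not mapped to a region")

    def groups(labels):
        out = {}
        for idx, v in enumerate(labels):
            out.setdefault(voxel_to_region[v], []).append(idx)
        for region, idxs in out.items():
            if not idxs:
                raise AnnotationError(f"region {region!r} has no voxels")
        return out

    row_groups = groups(voxel_matrix.row_labels)
    col_groups = groups(voxel_matrix.col_labels)
    row_regions = sorted(row_groups)
    col_regions = sorted(col_groups)
    values = np.empty((len(row_regions), len(col_regions)))
    for i, rr in enumerate(row_regions):
        block = voxel_matrix.values[row_groups[rr], :]
        for j, cc in enumerate(col_regions):
            values[i, j] = block[:, col_groups[cc]].mean()
    return RegionMatrix(row_labels=tuple(row_regions),
                        col_labels=tuple(col_regions),
                        values=values,
                        seed_label=voxel_matrix.seed_label)


def binarize_matrix(m: RegionMatrix,
                    config: AnnotationConfig = AnnotationConfig()
                    ) -> BinaryMatrix:
    """ln(1+x), divide each row by its maximum, threshold at ``config.threshold``.

    The comparison is ``>=`` so the row maximum (normalized value 1.0) always
    survives; all-zero rows stay all-zero.  Not scale-invariant: rescaling a
    row changes the log-ratios, which is intended — the threshold reads as
    "at least 70% of the strongest log-connectivity in the row".
    """
    if np.any(m.values < 0):
        raise AnnotationError("negative connectivity value")
    logged = np.log1p(m.values)
    row_max = logged.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(row_max > 0, logged / np.where(row_max == 0, 1.0,
                                                             row_max), 0.0)
    binary = (normalized >= config.threshold).astype(float)
    return BinaryMatrix(row_labels=m.row_labels, col_labels=m.col_labels,
                        values=binary, seed_label=m.seed_label)


# ---------------------------------------------------------------------------
# ABox generation
# ---------------------------------------------------------------------------

def _slug(term: TermName) -> str:
    return term.name.lower()


class _SubjectNamer:
    """Lazily creates the subject-scoped anatomical individuals."""

    def __init__(self, subject_id: str, tbox: TBox, abox: ABox,
                 partonomy_hints: dict):
        self.subject = subject_id
        self.tbox = tbox
        self.abox = abox
        self.hints = partonomy_hints
        self._regions: dict = {}

    def _require_class(self, term: TermName) -> None:
        if term not in self.tbox.classes:
            raise AnnotationError(f"region class {term} is not declared "
                                  "in the TBox")

    def apply_hints(self, ind: TermName, region_term: TermName) -> None:
        """Hang the hint ancestor chain of ``region_term`` off ``ind``."""
        prev = ind
        for prop, ancestor in self.hints.get(region_term, ()):
            if prop not in self.tbox.properties:
                raise AnnotationError(f"hint property {prop} not declared")
            self._require_class(ancestor)
            anc_ind = hco(f"{self.subject}_{_slug(ancestor)}")
            self.abox.add_type(anc_ind, ancestor)
            self.abox.add_role(prop, prev, anc_ind)
            prev = anc_ind

    def region_individual(self, region_term: TermName) -> TermName:
        """Per-subject individual of a named region class, plus its hints."""
        if region_term in self._regions:
            return self._regions[region_term]
        self._require_class(region_term)
        ind = hco(f"{self.subject}_{_slug(region_term)}")
        self.abox.add_type(ind, region_term)
        self._regions[region_term] = ind
        self.apply_hints(ind, region_term)
        return ind

    def gray_matter_individual(self, region_term: TermName) -> TermName:
        gm = hco(f"{self.subject}_gray_matter_of_{_slug(region_term)}")
        if gm not in self.abox.individuals:
            self.abox.add_type(gm, GRAY_MATTER_PART)
            self.abox.add_role(CONSTITUTIONAL_PART_OF, gm,
                               self.region_individual(region_term))
        return gm


def annotate_subject(parcellation: Parcellation,
                     adjacency: Adjacency,
                     matrices: Sequence[BinaryMatrix],
                     tbox: TBox,
                     config: AnnotationConfig = AnnotationConfig()) -> ABox:
    """Encode one subject's parcellation and binary matrices as an ABox.

    Only the asserted facts are produced (one ``continuous_with`` direction
    per neighbor pair, no ``MR_Node`` typing, no inverse/transitive images);
    symmetry, inverses, part-of closure and realization are the reasoner's
    job.  Route individuals are numbered across matrices in input order and
    row-major within a matrix, so names are reproducible.
    """
    parcellation.validate()
    abox = ABox()
    subject = parcellation.subject_id
    namer = _SubjectNamer(subject, tbox, abox, parcellation.partonomy_hints)

    label_to_individual: dict = {}
    for p in parcellation.parcels:
        name = config.node_name_template.format(
            subject=subject, region=_slug(p.region_term),
            parcel_id=p.parcel_id, counter="")
        ind = hco(name)
        abox.add_type(ind, GRAY_MATTER_PART)
        abox.add_role(REGIONAL_PART_OF, ind,
                      namer.gray_matter_individual(p.region_term))
        label_to_individual[str(p.parcel_id)] = ind
    for region_id, region_term in parcellation.extra_regions:
        if region_term not in tbox.classes:
            raise AnnotationError(f"region class {region_term} is not "
                                  "declared in the TBox")
        ind = hco(f"{subject}_{region_id}")
        abox.add_type(ind, GRAY_MATTER_PART)
        abox.add_type(ind, region_term)
        namer.apply_hints(ind, region_term)
        label_to_individual[region_id] = ind

    adjacency.validate(set(label_to_individual))
    for a, b in sorted(adjacency.edges):
        abox.add_role(CONTINUOUS_WITH, label_to_individual[a],
                      label_to_individual[b])

    counter = 0
    for matrix in matrices:
        for label in matrix.row_labels + matrix.col_labels:
            if label not in label_to_individual:
                raise AnnotationError(
                    f"matrix label {label!r} not in parcellation of "
                    f"{subject}")
        bundle_ind = None
        if matrix.seed_label is not None:
            bundle_ind = namer.region_individual(matrix.seed_label)
        rows, cols = np.nonzero(matrix.values)
        for r, c in zip(rows.tolist(), cols.tolist()):
            i_lab, j_lab = matrix.row_labels[r], matrix.col_labels[c]
            if i_lab == j_lab:
                raise AnnotationError(
                    f"matrix cell links {i_lab!r} to itself")
            i_ind = label_to_individual[i_lab]
            j_ind = label_to_individual[j_lab]
            counter += 1
            route = hco(config.route_name_template.format(
                subject=subject, counter=counter, region="", parcel_id=""))
            abox.add_type(route, MR_ROUTE)
            abox.add_role(MR_CONNECTION, i_ind, j_ind)
            abox.add_role(TRACTO_CONNECTS, route, i_ind)
            abox.add_role(TRACTO_CONNECTS, route, j_ind)
            if bundle_ind is not None:
                abox.add_role(REGIONAL_PART_OF, route, bundle_ind)

    abox.validate(tbox)
    return abox


def route_count(abox: ABox) -> int:
    """Number of MR_Route individuals asserted in an ABox."""
    return sum(1 for _, cls in abox.type_assertions if cls == MR_ROUTE)
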