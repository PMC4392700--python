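"""Synthetic fixtures: a miniature anatomy ontology and planted cohorts.

The real reference anatomy ontology (tens of thousands of classes) and real
diffusion MRI are deliberately out of reach here; instead this module builds

* :func:`generate_mini_fma` — a deterministic, few-dozen-entity frame-style
  partonomy graph covering every anatomical term the competency queries and
  the annotation pipeline touch (gyri, lobes, segments, hemispheres, the
  neuraxis chain, 20 white-matter tract classes, subcortical structures), plus
  one metaclass-flagged entity and a ``Human_body`` hub for exclusion tests;
* :func:`generate_cohort` — per-subject parcellations (1000 cortical parcels
  nested in gyri, 15 subcortical/brainstem regions), ring adjacency per gyrus,
  and 22 seed-mask connectivity matrices (11 medial-premotor target rows x
  1004 columns) with *planted* connectivity patterns: SMA-like parcels wired
  to the corticospinal tract and the precentral gyrus, pre-SMA-like parcels
  wired to medial parietal and orbitobasal frontal cortex, one bundle route
  from a superior-frontal to a temporal parcel, and Bernoulli noise elsewhere.

Planted values are the row maximum of their matrix row and noise is drawn
strictly below the value that would survive thresholding in a planted row, so
with zero noise the query answers *provably* equal the planted truth, and
with small noise they can only grow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .annotate import Adjacency, Parcellation, ParcelInfo, RegionMatrix
from .frames import SUBCLASS_OF, FrameGraph, make_config, extract_view
from .model import (
    CONSTITUTIONAL_PART,
    CONSTITUTIONAL_PART_OF,
    REGIONAL_PART,
    REGIONAL_PART_OF,
    ATTRIBUTED_CONTINUOUS_WITH,
    TBox,
    TermName,
    build_hco_schema,
    fma,
    merge_tbox,
)
from .translate import translate_frame_to_dl


# ---------------------------------------------------------------------------
# Mini anatomy ontology
# ---------------------------------------------------------------------------

GYRI_BY_LOBE = {
    "Right_frontal_lobe": ["Right_precentral_gyrus",
                           "Right_superior_frontal_gyrus",
                           "Right_middle_frontal_gyrus",
                           "Right_lateral_orbital_gyrus"],
    "Left_frontal_lobe": ["Left_precentral_gyrus",
                          "Left_superior_frontal_gyrus",
                          "Left_middle_frontal_gyrus"],
    "Right_parietal_lobe": ["Right_postcentral_gyrus", "Right_precuneus",
                            "Right_supramarginal_gyrus"],
    "Left_parietal_lobe": ["Left_postcentral_gyrus", "Left_precuneus"],
    "Right_temporal_lobe": ["Right_inferior_temporal_gyrus",
                            "Right_middle_temporal_gyrus"],
    "Left_temporal_lobe": ["Left_inferior_temporal_gyrus",
                           "Left_middle_temporal_gyrus"],
    "Right_occipital_lobe": ["Right_lingual_gyrus"],
    "Left_occipital_lobe": ["Left_lingual_gyrus"],
}

SEGMENTS = {
    # segment -> (property stem, whole)
    "Cortex_of_right_parietal_lobe": ("constitutional", "Right_parietal_lobe"),
    "Medial_segment_of_cerebral_hemisphere":
        ("regional", "Right_cerebral_hemisphere"),
    "Orbitobasal_segment_of_right_frontal_lobe":
        ("regional", "Right_frontal_lobe"),
}

#: 20 tract labels in the style of the JHU tractography atlas: nine name
#: stems, bilateral except the two commissural forceps.
TRACT_STEMS_BILATERAL = [
    "anterior_radiation_of_thalamus",
    "corticospinal_tract_of_brain",
    "anterior_segment_of_cingulum_bundle",
    "inferior_occipitofrontal_fasciculus",
    "inferior_longitudinal_fasciculus",
    "uncinate_fasciculus",
    "superior_longitudinal_fasciculus",
    "temporal_part_of_superior_longitudinal_fasciculus",
    "posterior_segment_of_cingulum_bundle",
]
TRACT_COMMISSURAL = ["Anterior_forceps_of_corpus_callosum",
                     "Posterior_forceps_of_corpus_callosum"]


def tract_class_names() -> list:
    names = []
    for stem in TRACT_STEMS_BILATERAL:
        for side in ("Right", "Left"):
            names.append(f"{side}_{stem}")
    names.extend(TRACT_COMMISSURAL)
    return names


SUBCORTICAL_STEMS = ["thalamus", "caudate_nucleus", "putamen",
                     "globus_pallidus", "nucleus_accumbens", "amygdala",
                     "hippocampus"]


def subcortical_region_terms() -> list:
    """The 15 non-cortical regions: 7 bilateral structures plus brainstem."""
    out = []
    for stem in SUBCORTICAL_STEMS:
        for side in ("Right", "Left"):
            out.append(fma(f"{side}_{stem}"))
    out.append(fma("Brainstem"))
    return out


METACLASS_ENTITY = fma("Anatomical_entity_template")
HUMAN_BODY = fma("Human_body")


@dataclass(frozen=True)
class MiniFMAFixture:
    graph: FrameGraph
    manifest: dict


def generate_mini_fma() -> MiniFMAFixture:
    """Deterministic miniature anatomy frame graph (no randomness).

    Partonomy edges are stored in both directions (child
    ``regional/constitutional_part_of`` whole, and whole
    ``regional/constitutional_part`` child), as a frame-style source stores
    both slots.  Exactly one entity is metaclass-flagged.
    """
    g = FrameGraph()

    def part(child: str, whole: str, kind: str = "regional") -> None:
        c, w = fma(child), fma(whole)
        if kind == "regional":
            g.add_triple(c, REGIONAL_PART_OF, w)
            g.add_triple(w, REGIONAL_PART, c)
        else:
            g.add_triple(c, CONSTITUTIONAL_PART_OF, w)
            g.add_triple(w, CONSTITUTIONAL_PART, c)

    def isa(sub: str, sup: str) -> None:
        g.add_triple(fma(sub), SUBCLASS_OF, fma(sup))

    # neuraxis spine of the partonomy
    part("Nervous_system", "Human_body", "constitutional")
    part("Neuraxis", "Nervous_system", "regional")
    part("Brain", "Neuraxis", "regional")
    part("Telencephalon", "Brain", "regional")
    part("Brainstem", "Brain", "regional")
    for side in ("Right", "Left"):
        part(f"{side}_cerebral_hemisphere", "Telencephalon", "regional")
        part(f"White_matter_of_{side.lower()}_cerebral_hemisphere",
             f"{side}_cerebral_hemisphere", "constitutional")
    part("Corpus_callosum", "Telencephalon", "regional")

    for lobe, gyri in GYRI_BY_LOBE.items():
        side = "Right" if lobe.startswith("Right") else "Left"
        part(lobe, f"{side}_cerebral_hemisphere", "regional")
        for gyrus in gyri:
            part(gyrus, lobe, "regional")
            isa(gyrus, "Gyrus")
        isa(lobe, "Lobe_of_cerebral_hemisphere")

    for segment, (kind, whole) in SEGMENTS.items():
        part(segment, whole, kind)

    # one worked gray-matter constitutional chain (frame translation example)
    part("Gray_matter_of_right_precentral_gyrus", "Right_precentral_gyrus",
         "constitutional")
    isa("Gray_matter_of_right_precentral_gyrus", "Gray_matter_of_neuraxis")

    for name in tract_class_names():
        if name in TRACT_COMMISSURAL:
            part(name, "Corpus_callosum", "regional")
        else:
            side = "right" if name.startswith("Right") else "left"
            part(name, f"White_matter_of_{side}_cerebral_hemisphere",
                 "regional")
        isa(name, "Neural_tract")
    isa("Neural_tract", "Anatomical_structure")
    isa("Gyrus", "Anatomical_structure")
    isa("Lobe_of_cerebral_hemisphere", "Anatomical_structure")
    for side in ("Right", "Left"):
        isa(f"White_matter_of_{side.lower()}_cerebral_hemisphere",
            "White_matter_of_neuraxis")

    for term in subcortical_region_terms():
        if term.name == "Brainstem":
            continue
        side = "Right" if term.name.startswith("Right") else "Left"
        part(term.name, f"{side}_cerebral_hemisphere", "regional")

    # lateral adjacency: central sulcus neighbors, plus one partner that
    # enters the view only through one-step lateral expansion
    g.add_triple(fma("Right_precentral_gyrus"), ATTRIBUTED_CONTINUOUS_WITH,
                 fma("Right_postcentral_gyrus"))
    g.add_triple(fma("Right_supramarginal_gyrus"),
                 ATTRIBUTED_CONTINUOUS_WITH, fma("Right_postcentral_gyrus"))

    # exactly one metaclass-flagged entity, sitting on the subsumption chain
    g.add_triple(fma("Gyrus"), SUBCLASS_OF, METACLASS_ENTITY)
    g.metaclass_flags.add(METACLASS_ENTITY)

    g.validate()
    manifest = {
        "n_entities": len(g.entities),
        "n_triples": len(g.triples),
        "n_metaclasses": len(g.metaclass_flags),
        "gyri": sorted(gy for gyri in GYRI_BY_LOBE.values() for gy in gyri),
        "tracts": sorted(tract_class_names()),
        "segments": sorted(SEGMENTS),
        "subcortical": sorted(t.name for t in subcortical_region_terms()),
    }
    return MiniFMAFixture(graph=g, manifest=manifest)


def default_seeds() -> frozenset:
    """The most specific mapped terms: gyri, segments, tracts, subcortical."""
    fx_terms = ([gy for gyri in GYRI_BY_LOBE.values() for gy in gyri]
                + list(SEGMENTS) + tract_class_names()
                + ["Gray_matter_of_right_precentral_gyrus"])
    seeds = {fma(t) for t in fx_terms} | set(subcortical_region_terms())
    return frozenset(seeds)


def build_reference_tbox(exclude_human_body: bool = True) -> TBox:
    """Mini anatomy view, translated to DL and merged with the HCO schema."""
    fixture = generate_mini_fma()
    exclusions = frozenset({HUMAN_BODY}) if exclude_human_body else frozenset()
    view = extract_view(fixture.graph,
                        make_config(default_seeds(), exclusions=exclusions))
    translated = translate_frame_to_dl(view).tbox
    return merge_tbox(translated, build_hco_schema())


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: the 11 medial-premotor parcel identifiers of the first target mask
MASK1_PARCEL_IDS = (20, 12, 32, 9, 17, 13, 42, 18, 24, 25, 38)

#: pre-binarization connectivity planted at truth cells (row maximum)
PLANTED_VALUE = 1000.0
#: noise ceiling: strictly below the value that survives a 0.7 ln-ratio
#: threshold against the planted value (exp(0.7*ln(1+1000)) - 1 ~ 125.2)
NOISE_LOW, NOISE_HIGH = 1.0, 120.0


@dataclass(frozen=True)
class PlantedDesign:
    """Which mask parcels carry which planted connectivity pattern."""

    sma_ids: tuple = (9, 17)         # corticospinal / precentral pattern
    pre_sma_ids: tuple = (12, 32)    # medial parietal / orbitobasal pattern
    neighbor_id: int = 20            # wired to a neighbor of the precentral
    bundle_id: int = 42              # wired through the planted fiber bundle
    bundle_term: TermName = fma("Right_superior_longitudinal_fasciculus")

    def __post_init__(self):
        groups = [set(self.sma_ids), set(self.pre_sma_ids),
                  {self.neighbor_id}, {self.bundle_id}]
        seen: set = set()
        for gset in groups:
            if gset & seen:
                raise ValueError("planted parcel sets must be disjoint")
            seen |= gset


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 5
    n_parcels: int = 1000
    mask1_parcel_count: int = 11
    extra_region_terms: tuple = field(
        default_factory=lambda: tuple(subcortical_region_terms()))
    #: one entry per seed-mask matrix: a bundle class or None (rest of WM)
    seed_masks: tuple = field(
        default_factory=lambda: tuple(fma(n) for n in tract_class_names())
        + (None, None))
    planted: PlantedDesign = field(default_factory=PlantedDesign)
    noise_rate: float = 0.002
    rng_seed: int = 0

    def __post_init__(self):
        if self.mask1_parcel_count > self.n_parcels:
            raise ValueError("mask1_parcel_count exceeds n_parcels")
        if not (0.0 <= self.noise_rate < 1.0):
            raise ValueError("noise_rate must lie in [0, 1)")
        if self.mask1_parcel_count != len(MASK1_PARCEL_IDS) \
                and self.mask1_parcel_count > self.n_parcels:
            raise ValueError("invalid mask1_parcel_count")

    @property
    def n_columns(self) -> int:
        return (self.n_parcels - self.mask1_parcel_count
                + len(self.extra_region_terms))


@dataclass
class SubjectBundle:
    parcellation: Parcellation
    adjacency: Adjacency
    matrices: list
    truth: dict


# gyri that receive non-mask parcels, cycled deterministically
_COHORT_GYRI = [
    "Right_superior_frontal_gyrus", "Right_precentral_gyrus",
    "Right_middle_frontal_gyrus", "Right_lateral_orbital_gyrus",
    "Right_postcentral_gyrus", "Right_precuneus",
    "Right_supramarginal_gyrus", "Right_inferior_temporal_gyrus",
    "Right_middle_temporal_gyrus", "Right_lingual_gyrus",
    "Left_superior_frontal_gyrus", "Left_precentral_gyrus",
    "Left_middle_frontal_gyrus", "Left_postcentral_gyrus",
    "Left_precuneus", "Left_inferior_temporal_gyrus",
    "Left_middle_temporal_gyrus", "Left_lingual_gyrus",
]

#: annotation-level ancestor chains hung off each region individual
DEFAULT_PARTONOMY_HINTS = {
    fma("Right_superior_frontal_gyrus"):
        ((REGIONAL_PART_OF, fma("Right_frontal_lobe")),
         (REGIONAL_PART_OF, fma("Right_cerebral_hemisphere"))),
    fma("Right_precentral_gyrus"):
        ((REGIONAL_PART_OF, fma("Right_frontal_lobe")),),
    fma("Right_lateral_orbital_gyrus"):
        ((REGIONAL_PART_OF, fma("Orbitobasal_segment_of_right_frontal_lobe")),
         (REGIONAL_PART_OF, fma("Right_frontal_lobe"))),
    fma("Right_precuneus"):
        ((REGIONAL_PART_OF, fma("Cortex_of_right_parietal_lobe")),
         (REGIONAL_PART_OF, fma("Medial_segment_of_cerebral_hemisphere")),
         (REGIONAL_PART_OF, fma("Right_parietal_lobe"))),
    fma("Right_postcentral_gyrus"):
        ((REGIONAL_PART_OF, fma("Right_parietal_lobe")),),
    fma("Right_supramarginal_gyrus"):
        ((REGIONAL_PART_OF, fma("Right_parietal_lobe")),),
    fma("Right_inferior_temporal_gyrus"):
        ((REGIONAL_PART_OF, fma("Right_temporal_lobe")),),
    fma("Right_middle_temporal_gyrus"):
        ((REGIONAL_PART_OF, fma("Right_temporal_lobe")),),
    fma("Right_lingual_gyrus"):
        ((REGIONAL_PART_OF, fma("Right_occipital_lobe")),),
    fma("Left_superior_frontal_gyrus"):
        ((REGIONAL_PART_OF, fma("Left_frontal_lobe")),),
    fma("Left_precentral_gyrus"):
        ((REGIONAL_PART_OF, fma("Left_frontal_lobe")),),
    fma("Brainstem"):
        ((REGIONAL_PART_OF, fma("Brain")),),
}


def _hemisphere(region: TermName) -> str:
    if region.name.startswith("Right"):
        return "right"
    if region.name.startswith("Left"):
        return "left"
    return "midline"


def _build_parcellation(subject_id: str, config: CohortConfig):
    """Deterministic parcel/gyrus layout shared by all subjects.

    Returns the parcellation plus the per-gyrus parcel-id lists used for
    adjacency rings and planted-target selection.
    """
    mask_ids = list(MASK1_PARCEL_IDS[:config.mask1_parcel_count])
    if config.mask1_parcel_count > len(MASK1_PARCEL_IDS):
        extra_needed = config.mask1_parcel_count - len(MASK1_PARCEL_IDS)
        pool = [i for i in range(1, config.n_parcels + 1)
                if i not in mask_ids]
        mask_ids.extend(pool[:extra_needed])
    non_mask = [i for i in range(1, config.n_parcels + 1)
                if i not in set(mask_ids)]

    rsfg = fma("Right_superior_frontal_gyrus")
    by_gyrus: dict = {g: [] for g in _COHORT_GYRI}
    parcels = [ParcelInfo(pid, rsfg, "right") for pid in mask_ids]
    by_gyrus["Right_superior_frontal_gyrus"] = list(mask_ids)
    for idx, pid in enumerate(non_mask):
        gyrus = _COHORT_GYRI[idx % len(_COHORT_GYRI)]
        term = fma(gyrus)
        parcels.append(ParcelInfo(pid, term, _hemisphere(term)))
        by_gyrus[gyrus].append(pid)

    extra = tuple((term.name.lower(), term)
                  for term in config.extra_region_terms)
    hints = dict(DEFAULT_PARTONOMY_HINTS)
    parc = Parcellation(subject_id=subject_id, parcels=tuple(parcels),
                        extra_regions=extra, partonomy_hints=hints)
    parc.validate()
    return parc, by_gyrus, mask_ids, non_mask


def generate_cohort(config: CohortConfig = CohortConfig()) -> list:
    """Generate the synthetic cohort (one :class:`SubjectBundle` per subject).

    Reproducible: the random generator is seeded per subject and per matrix
    from ``config.rng_seed`` via integer seed sequences, so identical configs
    yield bitwise-identical bundles on any platform.
    """
    design = config.planted
    bundles = []
    for s_idx in range(config.n_subjects):
        subject_id = f"s{s_idx + 1}"
        parc, by_gyrus, mask_ids, non_mask = _build_parcellation(
            subject_id, config)

        # ring adjacency within each gyrus, over sorted parcel ids
        adjacency = Adjacency()
        for gyrus, pids in by_gyrus.items():
            ring = sorted(pids)
            if len(ring) >= 2:
                for a, b in zip(ring, ring[1:]):
                    adjacency.add(str(a), str(b))
                if len(ring) >= 3:
                    adjacency.add(str(ring[-1]), str(ring[0]))

        # planted targets: deterministic picks inside the relevant gyri
        def pick(gyrus: str, k: int = 0) -> int:
            pids = sorted(p for p in by_gyrus[gyrus] if p not in mask_ids)
            if len(pids) <= k:
                raise ValueError(
                    f"n_parcels={config.n_parcels} is too small to plant "
                    f"connectivity patterns (gyrus {gyrus} has {len(pids)} "
                    "parcels)")
            return pids[k]

        precentral_a = pick("Right_precentral_gyrus", 0)
        precentral_b = pick("Right_precentral_gyrus", 1)
        precuneus_t = pick("Right_precuneus", 0)
        orbital_t = pick("Right_lateral_orbital_gyrus", 0)
        postcentral_t = pick("Right_postcentral_gyrus", 0)
        temporal_t = pick("Right_inferior_temporal_gyrus", 0)
        # the neighbor chain for the widened motor query: a postcentral
        # parcel planted adjacent to a precentral parcel
        adjacency.add(str(postcentral_t), str(precentral_b))

        col_labels = tuple(str(p) for p in non_mask) \
            + tuple(term.name.lower() for term in config.extra_region_terms)
        row_labels = tuple(str(p) for p in mask_ids)
        row_index = {lab: i for i, lab in enumerate(row_labels)}
        col_index = {lab: i for i, lab in enumerate(col_labels)}

        cst = fma("Right_corticospinal_tract_of_brain")
        planted_cells: dict = {}   # seed label (or None slot index) -> cells
        sma_a, sma_b = design.sma_ids[0], design.sma_ids[1]
        planted_cells[cst] = [(str(sma_b), "brainstem")]
        planted_cells[design.bundle_term] = [(str(design.bundle_id),
                                              str(temporal_t))]
        unlabeled_cells = [
            [(str(sma_a), str(precentral_a)),
             (str(design.neighbor_id), str(postcentral_t))],
            [(str(design.pre_sma_ids[0]), str(precuneus_t)),
             (str(design.pre_sma_ids[1]), str(orbital_t))],
        ]

        matrices = []
        unlabeled_seen = 0
        root = np.random.SeedSequence([int(config.rng_seed), s_idx])
        mat_seeds = root.spawn(len(config.seed_masks))
        for m_idx, seed_label in enumerate(config.seed_masks):
            rng = np.random.default_rng(mat_seeds[m_idx])
            values = np.zeros((len(row_labels), len(col_labels)))
            if config.noise_rate > 0:
                noise_mask = rng.random(values.shape) < config.noise_rate
                values[noise_mask] = rng.uniform(NOISE_LOW, NOISE_HIGH,
                                                 noise_mask.sum())
            if seed_label is None:
                cells = unlabeled_cells[unlabeled_seen] \
                    if unlabeled_seen < len(unlabeled_cells) else []
                unlabeled_seen += 1
            else:
                cells = planted_cells.get(seed_label, [])
            for r_lab, c_lab in cells:
                values[row_index[r_lab], col_index[c_lab]] = PLANTED_VALUE
            matrices.append(RegionMatrix(row_labels=row_labels,
                                         col_labels=col_labels,
                                         values=values,
                                         seed_label=seed_label))

        truth = {
            "subject_id": subject_id,
            "sma_parcels": sorted(design.sma_ids),
            "pre_sma_parcels": sorted(design.pre_sma_ids),
            "motor_extended_parcels": sorted(set(design.sma_ids)
                                             | {design.neighbor_id}),
            "bundle_terms": [str(design.bundle_term)],
            "bundle_individual": f"hco:{subject_id}_"
                                 f"{design.bundle_term.name.lower()}",
            "connected_region_terms": sorted({
                "Right_precentral_gyrus", "Right_precuneus",
                "Right_lateral_orbital_gyrus", "Right_postcentral_gyrus",
                "Right_inferior_temporal_gyrus", "Brainstem"}),
        }
        bundles.append(SubjectBundle(parcellation=parc, adjacency=adjacency,
                                     matrices=matrices, truth=truth))
    return bundles


def parcel_individual_name(subject_id: str, parcel_id: int,
                           region: TermName = fma(
                               "Right_superior_frontal_gyrus")) -> str:
    """Name of a parcel individual under the default annotation templates."""
    return f"hco:{subject_id}_gray_matter_of_{region.name.lower()}_{parcel_id}"
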