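"""End-to-end convenience wrappers: bundle -> ABox -> saturation -> answers."""

from __future__ import annotations

import re

from .annotate import AnnotationConfig, annotate_subject, binarize_matrix
from .model import KnowledgeBase, TBox
from .queries import answer_query, competency_query, QueryResult
from .reasoner import SaturatedKB, saturate
from .synthetic import SubjectBundle

_PARCEL_ID_RE = re.compile(r"_(\d+)$")


def annotate_bundle(bundle: SubjectBundle, tbox: TBox,
                    config: AnnotationConfig = AnnotationConfig()
                    ) -> KnowledgeBase:
    """Binarize a subject's matrices and annotate them into a KnowledgeBase."""
    binary = [binarize_matrix(m, config) for m in bundle.matrices]
    abox = annotate_subject(bundle.parcellation, bundle.adjacency, binary,
                            tbox, config)
    return KnowledgeBase(tbox=tbox, abox=abox)


def saturate_bundle(bundle: SubjectBundle, tbox: TBox,
                    config: AnnotationConfig = AnnotationConfig()
                    ) -> SaturatedKB:
    return saturate(annotate_bundle(bundle, tbox, config))


def competency_answers(s: SaturatedKB) -> dict:
    """All four competency-query results against one saturated KB."""
    return {n: answer_query(competency_query(n), s) for n in (1, 2, 3, 4)}


def parcel_ids(result: QueryResult) -> list:
    """Trailing integer identifiers of parcel-shaped answer individuals."""
    out = []
    for ind in result.answers:
        m = _PARCEL_ID_RE.search(ind.name)
        if m:
            out.append(int(m.group(1)))
    return sorted(out)
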