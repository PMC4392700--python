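"""Cross-subject overlap of connected-region term sets.

Given, per subject, the set of anatomical terms found connected to a target
region (here: the right medial premotor cortex), the overlap report states
which fraction of the union of terms is shared by at least k subjects.  The
published five-subject table is shipped verbatim as a text fixture; term
comparison is exact string equality — no case folding, and truncated variants
of a term (which occur in the published table) remain distinct terms.
"""

from __future__ import annotations

import csv
import hashlib
from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources

from .model import (
    FixtureError,
    HcoError,
    MR_CONNECTION,
    PART_OF,
    REGIONAL_PART_OF,
    CONSTITUTIONAL_PART_OF,
    TermName,
    UnknownTermError,
)
from .reasoner import SaturatedKB

_TABLE4_RESOURCE = "table4.tsv"
_TABLE4_SHA256 = \
    "deef77000b0c6b74b88c0423828d3ba2995e5390d4f9a31020c7fd7727eb2c4f"
_TABLE4_COLUMNS = ("gyri_left_hemisphere", "gyri_right_hemisphere",
                   "other_brain_regions")


def _table4_bytes() -> bytes:
    try:
        payload = (resources.files("hco") / "data"
                   / _TABLE4_RESOURCE).read_bytes()
    except FileNotFoundError as err:
        raise FixtureError("table4 fixture is missing") from err
    digest = hashlib.sha256(payload).hexdigest()
    if digest != _TABLE4_SHA256:
        raise FixtureError(
            f"table4 fixture is corrupted (sha256 {digest[:12]}..)")
    return payload


def load_table4_table() -> dict:
    """The published table, column-structured: subject -> column -> term set."""
    rows = csv.DictReader(_table4_bytes().decode().splitlines(),
                          delimiter="\t")
    out = {}
    for row in rows:
        out[row["subject_id"]] = {
            col: frozenset(t.strip() for t in row[col].split(",")
                           if t.strip())
            for col in _TABLE4_COLUMNS
        }
    return out


def load_table4_fixture() -> dict:
    """Per-subject union of the published connected-region terms.

    Splits cells on commas, trims whitespace, and applies no other
    normalization whatsoever.
    """
    return {subject: set().union(*cols.values())
            for subject, cols in load_table4_table().items()}


@dataclass(frozen=True)
class OverlapReport:
    total_terms: int
    counts: dict      # k -> number of terms present in >= k subjects
    fractions: dict   # k -> 100 * counts[k] / total_terms (full precision)

    def display(self, k: int) -> float:
        """Fraction at level k, rounded half-up to one decimal."""
        return float(Decimal(self.fractions[k]).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP))


def overlap_fractions(sets: dict, levels=(5, 4, 3)) -> OverlapReport:
    """Fraction of the term union present in at least k subjects, per level.

    Deterministic; raises on an empty union.  ``fractions`` is monotonically
    non-increasing in k, and level 1 is always 100.0 on non-empty input.
    """
    if not sets:
        raise HcoError("no subjects given")
    n_subjects = len(sets)
    for k in levels:
        if not (1 <= k <= n_subjects):
            raise HcoError(f"overlap level {k} outside 1..{n_subjects}")
    membership = Counter()
    for terms in sets.values():
        for term in terms:
            if not isinstance(term, str) or not term or term != term.strip():
                raise HcoError(f"bad term string {term!r}")
            membership[term] += 1
    total = len(membership)
    if total == 0:
        raise HcoError("term union is empty; overlap fractions undefined")
    counts = {k: sum(1 for v in membership.values() if v >= k)
              for k in levels}
    fractions = {k: 100.0 * counts[k] / total for k in levels}
    return OverlapReport(total_terms=total, counts=counts,
                         fractions=fractions)


def derive_term_sets(s: SaturatedKB, target_class: TermName) -> dict:
    """Lift each subject's connections to a target region to region terms.

    An individual is *in the target* when it is ``part_of`` some individual
    typed ``target_class``; every individual ``mr_connection``-ed to a target
    individual contributes the name of its enclosing named region class
    (a parcel's gyrus, a subcortical region's own class).  Relies on the
    annotation pipeline's conventions: parcels reach their region individual
    via an asserted ``regional_part_of`` then ``constitutional_part_of`` step,
    and subject identifiers prefix individual names up to the first ``_``.
    """
    if target_class not in s.kb.tbox.classes:
        raise UnknownTermError(f"unknown target class {target_class}")
    target_typed = {i for i, c in s.derived_types if c == target_class}
    in_target = {j for p, j, t in s.derived_roles
                 if p == PART_OF and t in target_typed}

    abox = s.kb.abox
    fma_types: dict = {}
    for ind, cls in abox.type_assertions:
        if cls.namespace == "fma":
            fma_types.setdefault(ind, set()).add(cls)
    rpo_out: dict = {}
    cpo_out: dict = {}
    for p, i, j in abox.role_assertions:
        if p == REGIONAL_PART_OF:
            rpo_out.setdefault(i, set()).add(j)
        elif p == CONSTITUTIONAL_PART_OF:
            cpo_out.setdefault(i, set()).add(j)

    def region_terms_of(ind: TermName) -> set:
        if ind in fma_types:
            return {c.name for c in fma_types[ind]}
        terms = set()
        for gm in rpo_out.get(ind, ()):
            for region in cpo_out.get(gm, ()):
                terms |= {c.name for c in fma_types.get(region, ())}
        return terms

    out: dict = {}
    for p, i, j in s.derived_roles:
        if p != MR_CONNECTION or j not in in_target:
            continue
        subject = i.name.split("_", 1)[0]
        out.setdefault(subject, set()).update(region_terms_of(i))
    return out
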