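"""Plain-text (TSV/YAML/JSON) interchange for cohort inputs.

One directory per subject: a parcellation table, an extra-regions table, an
adjacency edge list, one TSV per seed-mask connectivity matrix plus a YAML
manifest naming each matrix's seed bundle, and the planted truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .annotate import Adjacency, Parcellation, ParcelInfo, RegionMatrix
from .model import TermName
from .synthetic import DEFAULT_PARTONOMY_HINTS, SubjectBundle


def write_matrix_tsv(matrix: RegionMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=list(matrix.row_labels),
                      columns=list(matrix.col_labels))
    # %.17g round-trips IEEE doubles exactly through the text format
    df.to_csv(path, sep="\t", index_label="label", float_format="%.17g")


def read_matrix_tsv(path, seed_label: Optional[TermName] = None
                    ) -> RegionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str},
                     float_precision="round_trip")
    return RegionMatrix(row_labels=tuple(str(i) for i in df.index),
                        col_labels=tuple(str(c) for c in df.columns),
                        values=df.to_numpy(dtype=float),
                        seed_label=seed_label)


def write_subject_dir(bundle: SubjectBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    parc = bundle.parcellation
    pd.DataFrame(
        [(parc.subject_id, p.parcel_id, str(p.region_term), p.hemisphere)
         for p in parc.parcels],
        columns=["subject_id", "parcel_id", "region_term", "hemisphere"],
    ).to_csv(out / "parcellation.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(parc.subject_id, rid, str(term))
         for rid, term in parc.extra_regions],
        columns=["subject_id", "region_id", "region_term"],
    ).to_csv(out / "extra_regions.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(bundle.adjacency.edges), columns=["a", "b"]
                 ).to_csv(out / "adjacency.tsv", sep="\t", index=False)
    manifest = []
    for idx, matrix in enumerate(bundle.matrices):
        fname = f"matrix_{idx:02d}.tsv"
        write_matrix_tsv(matrix, out / fname)
        manifest.append({"file": fname,
                         "seed_label": None if matrix.seed_label is None
                         else str(matrix.seed_label)})
    (out / "manifest.yaml").write_text(
        yaml.safe_dump({"matrices": manifest}, sort_keys=False))
    (out / "truth.json").write_text(json.dumps(bundle.truth, indent=2,
                                               sort_keys=True) + "\n")


def read_parcellation(parcellation_tsv, extra_regions_tsv=None,
                      partonomy_hints: Optional[dict] = None) -> Parcellation:
    df = pd.read_csv(parcellation_tsv, sep="\t")
    subjects = sorted(set(df["subject_id"].astype(str)))
    if len(subjects) != 1:
        raise ValueError(f"expected one subject per table, got {subjects}")
    parcels = tuple(
        ParcelInfo(int(row.parcel_id), TermName.parse(str(row.region_term)),
                   str(row.hemisphere))
        for row in df.itertuples())
    extra = ()
    if extra_regions_tsv is not None and Path(extra_regions_tsv).exists():
        edf = pd.read_csv(extra_regions_tsv, sep="\t")
        extra = tuple((str(row.region_id),
                       TermName.parse(str(row.region_term)))
                      for row in edf.itertuples())
    hints = DEFAULT_PARTONOMY_HINTS if partonomy_hints is None \
        else partonomy_hints
    return Parcellation(subject_id=subjects[0], parcels=parcels,
                        extra_regions=extra, partonomy_hints=dict(hints))


def read_adjacency(adjacency_tsv) -> Adjacency:
    adj = Adjacency()
    df = pd.read_csv(adjacency_tsv, sep="\t")
    for row in df.itertuples():
        adj.add(str(row.a), str(row.b))
    return adj


def read_matrices(matrices_dir, manifest_yaml) -> list:
    manifest = yaml.safe_load(Path(manifest_yaml).read_text())
    out = []
    for entry in manifest["matrices"]:
        seed = entry.get("seed_label")
        out.append(read_matrix_tsv(
            Path(matrices_dir) / entry["file"],
            None if seed in (None, "") else TermName.parse(seed)))
    return out


def read_subject_dir(subject_dir) -> SubjectBundle:
    d = Path(subject_dir)
    parc = read_parcellation(d / "parcellation.tsv", d / "extra_regions.tsv")
    adjacency = read_adjacency(d / "adjacency.tsv")
    matrices = read_matrices(d, d / "manifest.yaml")
    truth_file = d / "truth.json"
    truth = json.loads(truth_file.read_text()) if truth_file.exists() else {}
    return SubjectBundle(parcellation=parc, adjacency=adjacency,
                         matrices=matrices, truth=truth)
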