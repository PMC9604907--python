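"""Delimited-text readers and writers for every pipeline artefact.

Everything is tab-separated with a header row.  An abundance matrix is a
bundle of four files sharing a stem: ``<stem>_values.tsv``,
``<stem>_status.tsv``, ``<stem>_samples.tsv`` and ``<stem>_features.tsv``.
Peak tables travel as one long table with columns sample_id, role,
sequence_index, compound_id, retention_time_min, area.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, PeakTable

FLOAT_FMT = "%.10g"


def write_table(frame: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
    return path


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_matrix(matrix: AbundanceMatrix, stem) -> list[Path]:
    stem = Path(stem)
    return [
        write_table(matrix.values, stem.with_name(stem.name + "_values.tsv")),
        write_table(matrix.status, stem.with_name(stem.name + "_status.tsv")),
        write_table(matrix.sample_meta, stem.with_name(stem.name + "_samples.tsv")),
        write_table(matrix.feature_meta, stem.with_name(stem.name + "_features.tsv")),
    ]


def read_matrix(stem) -> AbundanceMatrix:
    stem = Path(stem)
    values = read_table(stem.with_name(stem.name + "_values.tsv")).astype(float)
    status = read_table(stem.with_name(stem.name + "_status.tsv"))
    samples = read_table(stem.with_name(stem.name + "_samples.tsv"))
    features_path = stem.with_name(stem.name + "_features.tsv")
    features = read_table(features_path) if features_path.exists() else None
    return AbundanceMatrix(values, status, samples, features)


def write_peak_tables(tables: list[PeakTable], path) -> Path:
    rows = []
    for t in tables:
        frame = t.peaks.copy()
        frame.insert(0, "sample_id", t.sample_id)
        frame.insert(1, "role", t.role)
        frame.insert(2, "sequence_index", t.sequence_index)
        rows.append(frame)
    long = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["sample_id", "role", "sequence_index", "compound_id", "retention_time_min", "area"]
    )
    return write_table(long, path, index=False)


def read_peak_tables(path) -> list[PeakTable]:
    long = pd.read_csv(path, sep="\t", keep_default_na=True)
    long["compound_id"] = long["compound_id"].fillna("")
    tables = []
    for (sid, role, seq), group in long.groupby(
        ["sample_id", "role", "sequence_index"], sort=False
    ):
        tables.append(
            PeakTable(
                sample_id=str(sid),
                role=str(role),
                sequence_index=int(seq),
                peaks=group[["compound_id", "retention_time_min", "area"]].reset_index(drop=True),
            )
        )
    return tables


def write_truth(truth, path) -> Path:
    """Ground-truth sidecar as JSON (small: tens of KB)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "feature_meta": truth.feature_meta.reset_index().to_dict(orient="list"),
        "subject_effects": {
            "index": list(truth.subject_effects.index),
            "columns": list(truth.subject_effects.columns),
            "data": np.round(truth.subject_effects.to_numpy(), 6).tolist(),
        },
        "batch_shifts": truth.batch_shifts.round(6).to_dict(),
        "t2_latent": truth.t2_latent.round(6).to_dict(),
        "warps": {
            str(k): {"observed": list(np.round(w.observed, 6)),
                     "reference": list(np.round(w.reference, 6))}
            for k, w in (truth.warps or {}).items()
        },
    }
    path.write_text(json.dumps(payload, indent=1))
    return path
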