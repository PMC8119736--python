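"""Plain-text readers/writers for recordings, matrices and cohorts.

Recordings are TSV (rows = samples, columns = ``ch<index>_<band>`` labels)
with a ``*.meta.json`` sidecar carrying stage, sampling rate, subject and
group. Connectivity matrices are labelled TSV with a JSON sidecar for kind,
chromophore, subject and group. A cohort directory holds one recording per
subject plus a ``manifest.json`` echoing the generating spec and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .recording import Recording
from .synthetic import CohortSpec, SyntheticCohort


def _sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".meta.json")


def write_recording(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.row_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "stage": rec.stage,
        "fs_hz": rec.fs_hz,
        "n_channels": rec.n_channels,
        "wavelengths_nm": list(rec.wavelengths_nm),
        "meta": rec.meta,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1), encoding="utf-8")
    return path


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text(encoding="utf-8"))
    df = pd.read_csv(path, sep="\t")
    return Recording(
        subject_id=meta["subject_id"],
        group=meta["group"],
        stage=meta["stage"],
        data=df.to_numpy().T,
        fs_hz=meta["fs_hz"],
        n_channels=meta["n_channels"],
        wavelengths_nm=tuple(meta["wavelengths_nm"]),
        meta=meta.get("meta", {}),
    )


def write_matrix(mat: ConnectivityMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(mat.values, index=mat.labels, columns=mat.labels)
    df.to_csv(path, sep="\t", float_format="%.10g")
    meta = {
        "kind": mat.kind,
        "chromophore": mat.chromophore,
        "subject_id": mat.subject_id,
        "group": mat.group,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1), encoding="utf-8")
    return path


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text(encoding="utf-8"))
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(
        labels=[str(c) for c in df.columns],
        values=df.to_numpy(),
        kind=meta["kind"],
        chromophore=meta["chromophore"],
        subject_id=meta.get("subject_id"),
        group=meta.get("group"),
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for rec in cohort.recordings:
        p = write_recording(rec, out_dir / f"{rec.subject_id}_intensity.tsv")
        files[rec.subject_id] = p.name
    manifest = {
        "spec": dataclasses.asdict(cohort.spec),
        "seed": cohort.spec.seed,
        "subjects": [
            {"subject_id": r.subject_id, "group": r.group, "file": files[r.subject_id]}
            for r in cohort.recordings
        ],
        "artifact_log": {k: [list(e) for e in v] for k, v in cohort.artifact_log.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return out_dir


def read_cohort_recordings(in_dir: str | Path) -> tuple[list[Recording], dict]:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text(encoding="utf-8"))
    recs = [read_recording(in_dir / entry["file"]) for entry in manifest["subjects"]]
    return recs, manifest


def spec_from_dict(d: dict) -> CohortSpec:
    fields = {f.name for f in dataclasses.fields(CohortSpec)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown cohort spec keys: {sorted(unknown)}")
    return CohortSpec(**d)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
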