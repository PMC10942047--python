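"""TSV / PNG / YAML readers and writers with validation.

Conventions: UTF-8, LF line endings, tab-separated tables with one header
line; lines beginning with ``#`` are metadata comments (every writer stamps
the config digest when one is supplied).  Annotation rows are re-validated
on read: binary fields must be 0/1 and the merged call and group are
recomputed from the individual reader calls, never trusted.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .posterior import DiagnosisGroup
from .synthetic import AnnotationRecord, SubjectTruth

ANNOTATION_COLUMNS = [
    "subject_id", "finding", "r1_stage1", "r2_stage1", "merged_stage1",
    "r1_stage2", "r2_stage2", "group",
]
PREDICTION_COLUMNS = ["subject_id", "finding", "model_index", "logit"]


def config_digest(obj) -> str:
    """Stable sha256 digest of a JSON-serializable config mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path, digest: Optional[str]) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if digest:
            fh.write(f"# config_digest: {digest}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_annotations(records: Sequence[AnnotationRecord], path,
                      digest: Optional[str] = None) -> None:
    rows = []
    for rec in records:
        for finding, (r1, r2, s1, s2) in rec.calls.items():
            rows.append({
                "subject_id": rec.subject_id,
                "finding": finding,
                "r1_stage1": r1,
                "r2_stage1": r2,
                "merged_stage1": rec.merged_first(finding),
                "r1_stage2": s1,
                "r2_stage2": s2,
                "group": str(rec.group(finding)),
            })
    _write_tsv(pd.DataFrame(rows, columns=ANNOTATION_COLUMNS), path, digest)


def read_annotations(path) -> List[AnnotationRecord]:
    """Parse and validate the annotation table; errors carry line numbers."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    calls: Dict[str, Dict[str, tuple]] = {}
    order: List[str] = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        line = pos  # header is line 1 (after any comment lines)
        try:
            bits = tuple(int(getattr(row, c)) for c in
                         ("r1_stage1", "r2_stage1", "r1_stage2", "r2_stage2"))
        except (TypeError, ValueError):
            raise ValueError(f"{path}:{line}: reader calls must be integers")
        if any(b not in (0, 1) for b in bits):
            raise ValueError(f"{path}:{line}: reader calls must be 0 or 1")
        merged = "P" if (bits[0] or bits[1]) else "N"
        if row.merged_stage1 != merged:
            raise ValueError(
                f"{path}:{line}: merged_stage1={row.merged_stage1!r} inconsistent "
                f"with reader calls (union rule gives {merged!r})"
            )
        expected_group = str(DiagnosisGroup.from_calls(*bits))
        if row.group != expected_group:
            raise ValueError(
                f"{path}:{line}: group={row.group!r} inconsistent with calls "
                f"(recomputed {expected_group!r})"
            )
        if row.subject_id not in calls:
            calls[row.subject_id] = {}
            order.append(row.subject_id)
        calls[row.subject_id][row.finding] = bits
    return [AnnotationRecord(subject_id=s, calls=calls[s]) for s in order]


def write_truths(truths: Sequence[SubjectTruth], path,
                 digest: Optional[str] = None) -> None:
    rows = []
    for t in truths:
        for finding in t.p:
            rows.append({
                "subject_id": t.subject_id,
                "finding": finding,
                "severity": repr(t.severity[finding]),
                "p": repr(t.p[finding]),
            })
    _write_tsv(pd.DataFrame(rows, columns=["subject_id", "finding", "severity", "p"]),
               path, digest)


def read_truths(path) -> List[SubjectTruth]:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    out: Dict[str, Dict[str, Dict[str, float]]] = {}
    order: List[str] = []
    for row in df.itertuples(index=False):
        if row.subject_id not in out:
            out[row.subject_id] = {"severity": {}, "p": {}}
            order.append(row.subject_id)
        out[row.subject_id]["severity"][row.finding] = float(row.severity)
        out[row.subject_id]["p"][row.finding] = float(row.p)
    return [SubjectTruth(subject_id=s, severity=out[s]["severity"], p=out[s]["p"])
            for s in order]


def write_predictions(predictions: pd.DataFrame, path,
                      digest: Optional[str] = None) -> None:
    _write_tsv(predictions[PREDICTION_COLUMNS], path, digest)


def read_predictions(path) -> pd.DataFrame:
    """Read the (subject, finding, model) logit grid; validate completeness."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"subject_id": str, "finding": str})
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if df["logit"].isna().any() or not np.isfinite(df["logit"]).all():
        bad = df.index[~np.isfinite(df["logit"].fillna(np.nan))][0]
        raise ValueError(f"{path}: non-finite logit at data row {bad + 1}")
    dup = df.duplicated(subset=["subject_id", "finding", "model_index"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate cell (subject={r.subject_id}, finding={r.finding}, "
            f"model={r.model_index})"
        )
    models = sorted(df["model_index"].unique())
    for (sid, finding), grp in df.groupby(["subject_id", "finding"]):
        have = set(grp["model_index"])
        lack = [m for m in models if m not in have]
        if lack:
            raise ValueError(
                f"{path}: incomplete grid — subject {sid}, finding {finding} "
                f"missing model(s) {lack}"
            )
    return df


def write_images(images: np.ndarray, subject_ids: Sequence[str], out_dir,
                 sidecar: Optional[dict] = None) -> None:
    """8-bit grayscale PNGs named <subject_id>.png plus a YAML sidecar."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sid, img in zip(subject_ids, images):
        arr = np.clip(img, 0.0, 1.0)
        Image.fromarray((arr * 255).round().astype(np.uint8), mode="L").save(
            out_dir / f"{sid}.png"
        )
    if sidecar is not None:
        with open(out_dir / "images.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(sidecar, fh, sort_keys=True)


def read_image(path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float) / 255.0
    return arr


def write_yaml(obj: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
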