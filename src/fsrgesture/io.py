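"""On-disk formats: recording CSV, timeline JSON, database CSV, model JSON.

All formats are plain text, round-trip losslessly (floats are written with
shortest-repr precision) and are validated strictly on read, with parse
errors reporting the offending line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import TrainedModel
from .errors import ParseError
from .features import GestureDatabase, feature_columns
from .labels import GestureLabel, SensorChannel
from .recording import RawRecording, TimelineEntry
from .segmentation import Normalization, Segment

RECORDING_HEADER = "time_s,fsr1_kg,fsr2_kg,fsr3_kg"
SEGMENTS_HEADER = "start_sample,end_sample,channel,label"


# ------------------------------------------------------------------ recordings

def write_recording(path: str | Path, rec: RawRecording) -> None:
    """Write a recording as CSV (header ``time_s,fsr1_kg,fsr2_kg,fsr3_kg``);
    the timeline, if any, goes to a ``.timeline.json`` sidecar."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "time_s": np.arange(rec.n_samples) / rec.sampling_rate,
            "fsr1_kg": rec.forces[0],
            "fsr2_kg": rec.forces[1],
            "fsr3_kg": rec.forces[2],
        }
    )
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    if rec.timeline:
        write_timeline(path.with_suffix(".timeline.json"), rec.timeline)


def write_timeline(path: str | Path, timeline: list[TimelineEntry]) -> None:
    entries = [
        {
            "start_sample": t.start_sample,
            "end_sample": t.end_sample,
            "label": t.label.name.lower(),
        }
        for t in timeline
    ]
    Path(path).write_text(json.dumps(entries, indent=1) + "\n")


def read_timeline(path: str | Path) -> list[TimelineEntry]:
    entries = json.loads(Path(path).read_text())
    return [
        TimelineEntry(
            int(e["start_sample"]),
            int(e["end_sample"]),
            GestureLabel.from_name(e["label"]),
        )
        for e in entries
    ]


def read_recording(
    path: str | Path, subject_id: str = "", load_timeline: bool = True
) -> RawRecording:
    """Read a recording CSV (sampling rate inferred from the time column)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if header != RECORDING_HEADER:
            raise ParseError(
                f"expected header {RECORDING_HEADER!r}, got {header!r}", line=1
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise ParseError(
                    f"expected 4 columns, got {len(parts)}", line=lineno
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise ParseError(f"non-numeric value in {line!r}", line=lineno) from None
    if len(rows) < 2:
        raise ParseError("recording needs at least two samples")
    data = np.asarray(rows)
    dt = np.median(np.diff(data[:, 0]))
    if dt <= 0:
        raise ParseError("time column is not increasing")
    timeline: list[TimelineEntry] = []
    sidecar = path.with_suffix(".timeline.json")
    if load_timeline and sidecar.exists():
        timeline = read_timeline(sidecar)
    return RawRecording(
        data[:, 1:4].T, float(round(1.0 / dt)), timeline, subject_id=subject_id
    )


# ------------------------------------------------------------------- segments

def write_segments(path: str | Path, segments: list[Segment]) -> None:
    with Path(path).open("w") as fh:
        fh.write(SEGMENTS_HEADER + "\n")
        for s in segments:
            channel = int(s.source_channel) if s.source_channel else ""
            label = s.label.name.lower() if s.label is not None else ""
            fh.write(f"{s.start_sample},{s.end_sample},{channel},{label}\n")


def read_segments(path: str | Path) -> list[Segment]:
    segments = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n")
        if header != SEGMENTS_HEADER:
            raise ParseError(
                f"expected header {SEGMENTS_HEADER!r}, got {header!r}", line=1
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise ParseError(f"expected 4 columns, got {len(parts)}", line=lineno)
            start, end, channel, label = parts
            segments.append(
                Segment(
                    int(start),
                    int(end),
                    GestureLabel.from_name(label) if label else None,
                    SensorChannel(int(channel)) if channel else None,
                )
            )
    return segments


# ------------------------------------------------------------------ databases

def write_database(path: str | Path, db: GestureDatabase) -> None:
    """Database CSV: masked feature columns, label name, subject_id."""
    frame = db.frame.copy()
    frame["label"] = [GestureLabel(c).name.lower() for c in frame["label"]]
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_database(path: str | Path) -> GestureDatabase:
    frame = pd.read_csv(path, float_precision="round_trip")
    cols = [c for c in frame.columns if c not in ("label", "subject_id")]
    mask = sorted(
        {int(c[3]) for c in cols if c.startswith("fsr") and len(c) > 3}
    )
    expected = feature_columns(mask)
    if "label" not in frame.columns or sorted(cols) != sorted(expected):
        raise ParseError(
            f"database columns {list(frame.columns)} do not match the "
            f"mean/SD-per-sensor layout"
        )
    frame["label"] = [GestureLabel.from_name(v).code for v in frame["label"]]
    subjects = frame["subject_id"].unique() if "subject_id" in frame else []
    subject_id = str(subjects[0]) if len(subjects) == 1 else "combined"
    return GestureDatabase(frame, subject_id, tuple(mask))


# --------------------------------------------------------------------- models

def _to_jsonable(value):
    if isinstance(value, np.ndarray):
        return {"__array__": value.tolist()}
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value


def _from_jsonable(value):
    if isinstance(value, dict) and "__array__" in value:
        return np.asarray(value["__array__"])
    return value


def write_model(path: str | Path, model: TrainedModel) -> None:
    if model.kind == "plugin":
        raise ValueError("plugin models are not serializable")
    payload = {
        "kind": model.kind,
        "classes": model.classes.tolist(),
        "feature_names": model.feature_names,
        "params": {k: _to_jsonable(v) for k, v in model.params.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_model(path: str | Path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    return TrainedModel(
        payload["kind"],
        np.asarray(payload["classes"], dtype=int),
        list(payload["feature_names"]),
        {k: _from_jsonable(v) for k, v in payload["params"].items()},
    )


# -------------------------------------------------------------- normalization

def write_normalization(path: str | Path, norm: Normalization) -> None:
    Path(path).write_text(
        json.dumps({"offsets": list(norm.offsets), "scale": norm.scale}) + "\n"
    )


def read_normalization(path: str | Path) -> Normalization:
    payload = json.loads(Path(path).read_text())
    return Normalization(tuple(payload["offsets"]), float(payload["scale"]))


# ------------------------------------------------------------------ decisions

def write_decisions(path: str | Path, decisions) -> None:
    """Decisions CSV: ``window_index,label,byte_code``."""
    with Path(path).open("w") as fh:
        fh.write("window_index,label,byte_code\n")
        for d in decisions:
            fh.write(f"{d.window_index},{d.label.name.lower()},{d.byte_code}\n")
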