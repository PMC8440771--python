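"""Delimited-text readers/writers for intermediate pipeline artifacts.

All tables are tab-separated with a ``#``-prefixed metadata header carrying
the config hash and seed, so every output is traceable to the run that
produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .oculomotor import SREMEvent, SurvivalRecord
from .recording import ArtifactMask

__all__ = [
    "config_hash", "write_table", "read_table",
    "write_intervals", "read_intervals",
    "write_events", "read_events",
    "write_survival", "read_survival",
    "write_ground_truth", "read_ground_truth",
]


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(config) -> str:
    """Short stable hash of a configuration object."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path,
                metadata: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g",
                  lineterminator="\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_intervals(mask: ArtifactMask, path: str | Path,
                    metadata: dict | None = None) -> Path:
    df = pd.DataFrame(mask.intervals, columns=["start_s", "end_s"])
    meta = {"recording_duration_s": mask.recording_duration_s,
            **(metadata or {})}
    return write_table(df, path, meta)


def read_intervals(path: str | Path) -> np.ndarray:
    df = read_table(path)
    return df[["start_s", "end_s"]].to_numpy().reshape(-1, 2)


def write_events(events: list[SREMEvent], path: str | Path,
                 metadata: dict | None = None) -> Path:
    df = pd.DataFrame(
        [(e.onset_s, e.duration_s, e.antiphase_score) for e in events],
        columns=["onset_s", "duration_s", "antiphase_score"])
    return write_table(df, path, metadata)


def read_events(path: str | Path) -> list[SREMEvent]:
    df = read_table(path)
    return [SREMEvent(r.onset_s, r.duration_s, r.antiphase_score)
            for r in df.itertuples()]


def write_survival(records: list[SurvivalRecord], path: str | Path,
                   metadata: dict | None = None) -> Path:
    df = pd.DataFrame(
        [(r.subject, r.condition, r.time_s, r.event) for r in records],
        columns=["subject", "condition", "time_s", "event"])
    return write_table(df, path, metadata)


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    df = read_table(path)
    return [SurvivalRecord(str(r.subject), str(r.condition),
                           float(r.time_s), int(r.event))
            for r in df.itertuples()]


def write_ground_truth(truth, path: str | Path) -> Path:
    """Ground-truth sidecar as structured JSON text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "srem_events": {f"{s}|{c}": v
                        for (s, c), v in truth.srem_events.items()},
        "srem_counts": {f"{s}|{c}": v
                        for (s, c), v in truth.srem_counts.items()},
        "artifact_intervals": {f"{s}|{c}": v
                               for (s, c), v in truth.artifact_intervals.items()},
        "sleep_hours": truth.sleep_hours,
        "frailty": truth.frailty,
        "band_coupling": truth.band_coupling,
    }
    path.write_text(json.dumps(_jsonable(payload), indent=1))
    return path


def read_ground_truth(path: str | Path):
    from .synthdata import GroundTruth

    raw = json.loads(Path(path).read_text())

    def unkey(d, cast):
        return {tuple(k.split("|")): cast(v) for k, v in d.items()}

    return GroundTruth(
        srem_events=unkey(raw["srem_events"],
                          lambda v: [tuple(x) for x in v]),
        srem_counts=unkey(raw["srem_counts"], int),
        artifact_intervals=unkey(raw["artifact_intervals"],
                                 lambda v: [tuple(x) for x in v]),
        sleep_hours=raw["sleep_hours"],
        frailty=raw["frailty"],
        band_coupling=raw["band_coupling"],
    )
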