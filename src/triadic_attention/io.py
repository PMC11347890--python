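"""File formats: sequence CSV, events CSV/JSON, profile and report JSON,
run configuration (YAML/JSON), and cohort directories.

All frame indices on disk are 0-based; spans are inclusive on both ends.
Outputs are deterministic for a given input: JSON keys are sorted and
floats are written at full precision (round-trip lossless).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import ContactEvent, ExclusionEpisode
from .orientation import (
    FocusLabel,
    NoDataError,
    OrientationSequence,
    RegionLayout,
    labels_from_strings,
    labels_to_strings,
)
from .profiles import SessionProfile
from .simulate import Cohort

logger = logging.getLogger("triadic_attention")

__all__ = [
    "RunConfig",
    "read_sequence_csv",
    "write_sequence_csv",
    "read_labels_csv",
    "write_labels_csv",
    "events_to_frame",
    "write_events",
    "write_profile_json",
    "read_profile_json",
    "write_json",
    "write_cohort",
]


@dataclass
class RunConfig:
    """Resolved pipeline configuration (layout, detection, analysis)."""

    interviewer_a_center_deg: float = 0.0
    interviewer_b_center_deg: float = 45.0
    half_width_deg: float = 15.0
    frame_period_s: float = 0.75
    min_contact_len: int = 3
    window_len: int = 20
    majority: int = 15
    sd_multiplier: float = 2.0
    max_domains: int = 3
    alpha: float = 0.05
    normative_reference: str | None = None
    seed: int = 0

    def layout(self) -> RegionLayout:
        return RegionLayout(
            interviewer_a_center=self.interviewer_a_center_deg,
            interviewer_b_center=self.interviewer_b_center_deg,
            half_width=self.half_width_deg,
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        if data is None:
            data = {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def read_sequence_csv(path, frame_period: float = 0.75) -> OrientationSequence:
    """Read a `frame,yaw_deg` CSV; frames must be 0-based and strictly increasing."""
    df = pd.read_csv(path)
    required = {"frame", "yaw_deg"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected header with columns {sorted(required)}, got {list(df.columns)}")
    if len(df) == 0:
        raise NoDataError(f"{path}: no frames")
    frames = df["frame"].to_numpy()
    diffs = np.diff(frames)
    bad = np.flatnonzero(diffs <= 0)
    if frames[0] != 0:
        raise ValueError(f"{path}: row 2: frame indices must start at 0 (got {frames[0]})")
    if bad.size:
        row = int(bad[0]) + 3  # 1-based file line: header + 1-based index + 1
        raise ValueError(f"{path}: row {row}: frame indices must be strictly increasing")
    return OrientationSequence(yaw=df["yaw_deg"].to_numpy(dtype=float), frame_period=frame_period)


def write_sequence_csv(path, seq: OrientationSequence) -> None:
    df = pd.DataFrame({"frame": np.arange(len(seq)), "yaw_deg": seq.yaw})
    df.to_csv(path, index=False)


def write_labels_csv(path, labels) -> None:
    df = pd.DataFrame({"frame": np.arange(len(labels)), "label": labels_to_strings(labels)})
    df.to_csv(path, index=False)


def read_labels_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: expected a 'label' column")
    return labels_from_strings(df["label"].tolist())


def events_to_frame(contacts: list[ContactEvent], exclusions: list[ExclusionEpisode]) -> pd.DataFrame:
    rows = [
        {
            "type": "contact",
            "target_or_excluded": ev.target.name,
            "start_frame": ev.start_frame,
            "end_frame": ev.end_frame,
            "duration_frames": ev.duration_frames,
        }
        for ev in contacts
    ] + [
        {
            "type": "exclusion",
            "target_or_excluded": ep.excluded.name,
            "start_frame": ep.start_frame,
            "end_frame": ep.end_frame,
            "duration_frames": ep.duration_frames,
        }
        for ep in exclusions
    ]
    return pd.DataFrame(
        rows, columns=["type", "target_or_excluded", "start_frame", "end_frame", "duration_frames"]
    )


def write_events(path, contacts, exclusions) -> None:
    path = Path(path)
    df = events_to_frame(contacts, exclusions)
    if path.suffix == ".json":
        path.write_text(df.to_json(orient="records", indent=2))
    else:
        df.to_csv(path, index=False)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_profile_json(path, profile: SessionProfile) -> None:
    d = profile.to_dict()
    if isinstance(d["AvgCon"], float) and np.isnan(d["AvgCon"]):
        d["AvgCon"] = None  # JSON has no NaN; undefined mean contact duration
    write_json(path, d)


def read_profile_json(path) -> SessionProfile:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("AvgCon") is None:
        d["AvgCon"] = float("nan")
    return SessionProfile.from_dict(d)


def write_cohort(out_dir, cohort: Cohort) -> None:
    """Write a cohort as per-session label CSVs plus a manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cohort.seed, "frame_period_s": cohort.frame_period, "sessions": []}
    for p in cohort.participants:
        for session, labels, params in (
            (1, p.labels_session1, p.params_session1),
            (2, p.labels_session2, p.params_session2),
        ):
            fname = f"{p.participant}_s{session}.csv"
            write_labels_csv(out / fname, labels)
            manifest["sessions"].append(
                {
                    "participant": p.participant,
                    "group": p.group,
                    "session": session,
                    "file": fname,
                    "params": asdict(params),
                }
            )
    write_json(out / "manifest.json", manifest)
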