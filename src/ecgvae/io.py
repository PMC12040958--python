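"""Readers and writers for the package's small tabular/array interchange formats.

Everything is plain text (CSV with JSON sidecars) except the beats container,
which is a NumPy ``.npz`` holding the beat tensor, the condition matrix, and
the condition schema as an embedded JSON string.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .cvae import ConditionSchema
from .geometry import ELECTRODE_NAMES, ElectrodeLayout, HeartPose, Plane3D
from .preprocess import LEAD_NAMES, EcgRecord
from .survival import SurvivalRecord

__all__ = [
    "read_planes", "write_planes",
    "read_layouts", "write_layouts",
    "poses_to_frame", "write_poses", "read_poses",
    "read_survival", "write_survival",
    "save_beats", "load_beats",
    "read_ecg_csv", "write_ecg_csv",
]

PLANE_NAMES = ("SAX", "2CH", "4CH")


def read_planes(path) -> Dict[str, Dict[str, Plane3D]]:
    """Plane table CSV -> {subject_id: {plane_name: Plane3D}}.

    Columns: subject_id, plane in {SAX, 2CH, 4CH}, normal_x..z, point_x..z.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    out: Dict[str, Dict[str, Plane3D]] = {}
    for _, row in df.iterrows():
        plane = Plane3D(
            [row["normal_x"], row["normal_y"], row["normal_z"]],
            [row["point_x"], row["point_y"], row["point_z"]],
        )
        out.setdefault(row["subject_id"], {})[row["plane"]] = plane
    return out


def write_planes(planes: Dict[str, Dict[str, Plane3D]], path) -> None:
    rows = []
    for sid, by_name in planes.items():
        for name, p in by_name.items():
            rows.append({
                "subject_id": sid, "plane": name,
                "normal_x": p.normal[0], "normal_y": p.normal[1], "normal_z": p.normal[2],
                "point_x": p.point[0], "point_y": p.point[1], "point_z": p.point[2],
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_layouts(path) -> Dict[str, ElectrodeLayout]:
    """Electrode CSV -> {subject_id: ElectrodeLayout}.

    Columns: subject_id, electrode, x, y, z, frame.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    out: Dict[str, ElectrodeLayout] = {}
    for sid, group in df.groupby("subject_id"):
        frames = group["frame"].unique()
        if len(frames) != 1:
            raise ValueError(f"mixed frames for subject {sid}")
        coords = {r["electrode"]: [r["x"], r["y"], r["z"]] for _, r in group.iterrows()}
        out[sid] = ElectrodeLayout(coords, frame=frames[0])
    return out


def write_layouts(layouts: Dict[str, ElectrodeLayout], path) -> None:
    rows = []
    for sid, layout in layouts.items():
        for name in ELECTRODE_NAMES:
            x, y, z = layout.coords[name]
            rows.append({"subject_id": sid, "electrode": name,
                         "x": x, "y": y, "z": z, "frame": layout.frame})
    pd.DataFrame(rows).to_csv(path, index=False)


def poses_to_frame(poses: Dict[str, HeartPose]) -> pd.DataFrame:
    rows = []
    for sid, pose in poses.items():
        row = {"subject_id": sid,
               "pos_x": pose.position[0], "pos_y": pose.position[1], "pos_z": pose.position[2],
               "alpha": pose.euler[0], "beta": pose.euler[1], "gamma": pose.euler[2]}
        for axis_name, vec in (("eX", pose.eX), ("eY", pose.eY), ("eZ", pose.eZ)):
            for comp, val in zip("xyz", vec):
                row[f"{axis_name}_{comp}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def write_poses(poses: Dict[str, HeartPose], path) -> None:
    poses_to_frame(poses).to_csv(path, index=False)


def read_poses(path) -> Dict[str, HeartPose]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    out = {}
    for _, r in df.iterrows():
        out[r["subject_id"]] = HeartPose(
            [r["pos_x"], r["pos_y"], r["pos_z"]],
            [r["eX_x"], r["eX_y"], r["eX_z"]],
            [r["eY_x"], r["eY_y"], r["eY_z"]],
            [r["eZ_x"], r["eZ_y"], r["eZ_z"]],
            (r["alpha"], r["beta"], r["gamma"]),
        )
    return out


def read_survival(path) -> List[SurvivalRecord]:
    """Survival CSV (subject_id, time_days, event, subtype) -> records."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    return [
        SurvivalRecord(
            r["subject_id"], float(r["time_days"]), int(r["event"]),
            None if pd.isna(r.get("subtype")) else r["subtype"],
        )
        for _, r in df.iterrows()
    ]


def write_survival(records: Sequence[SurvivalRecord], path) -> None:
    pd.DataFrame({
        "subject_id": [r.subject_id for r in records],
        "time_days": [r.time for r in records],
        "event": [r.event for r in records],
        "subtype": [r.subtype for r in records],
    }).to_csv(path, index=False)


def save_beats(path, beats: np.ndarray, conds: np.ndarray,
               schema: ConditionSchema, subject_ids: Sequence[str]) -> None:
    """Beats container: arrays plus the condition schema as embedded JSON."""
    np.savez(
        path,
        beats=np.asarray(beats, dtype=float),
        conds=np.asarray(conds, dtype=float),
        schema=np.frombuffer(json.dumps(list(schema.blocks)).encode(), dtype=np.uint8),
        subject_ids=np.asarray(list(subject_ids), dtype=str),
    )


def load_beats(path) -> Tuple[np.ndarray, np.ndarray, ConditionSchema, List[str]]:
    with np.load(path) as data:
        schema = ConditionSchema(tuple(json.loads(bytes(data["schema"]).decode())))
        return (
            data["beats"].copy(),
            data["conds"].copy(),
            schema,
            [str(s) for s in data["subject_ids"]],
        )


def write_ecg_csv(rec: EcgRecord, csv_path) -> None:
    """Per-subject record: one CSV column per lead + a JSON sidecar for fs."""
    csv_path = Path(csv_path)
    pd.DataFrame(rec.signals.T, columns=list(rec.lead_order)).to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "fs": rec.fs, "subject_id": rec.subject_id, "lead_order": list(rec.lead_order),
    }))


def read_ecg_csv(csv_path) -> EcgRecord:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = {"fs": 500.0, "subject_id": csv_path.stem, "lead_order": list(LEAD_NAMES)}
    sidecar = csv_path.with_suffix(".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    signals = df[meta["lead_order"]].to_numpy().T
    return EcgRecord(signals, fs=meta["fs"], subject_id=meta["subject_id"],
                     lead_order=tuple(meta["lead_order"]))
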