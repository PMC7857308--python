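"""File formats: TRC marker files, force-plate CSV, STL meshes, JSON landmarks.

Internal units are SI (m, N, N*m).  TRC files store marker coordinates in
mm per the format convention and are converted at this boundary; force CSVs
carry N / m / N*m directly; STL meshes are written in mm.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .synth import GaitCondition, TrialDataset

_FORCE_COLUMNS = ["time", "Fx", "Fy", "Fz", "COPx", "COPy", "COPz", "Tz"]


def write_trc(path, trial: TrialDataset):
    """Write marker trajectories as a TRC file (mm)."""
    path = Path(path)
    names = sorted(trial.markers)
    n = trial.n_frames
    rate = trial.marker_rate
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{rate:g}\t{rate:g}\t{n}\t{len(names)}\tmm\t{rate:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\t\n")
        fh.write("\t\t" + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}"
                                    for i in range(len(names))) + "\n")
        data = np.hstack([np.asarray(trial.markers[m]) * 1000.0 for m in names])
        for i in range(n):
            row = "\t".join(f"{x:.6f}" for x in data[i])
            fh.write(f"{i+1}\t{i/rate:.6f}\t{row}\n")


def read_trc(path):
    """Read a TRC file; returns (markers dict in m, rate)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("PathFileType"):
        raise ValueError(f"{path}: not a TRC file (missing PathFileType header)")
    meta = lines[2].split("\t")
    rate, n, nmark, units = float(meta[0]), int(meta[2]), int(meta[3]), meta[4]
    if units not in ("mm", "m"):
        raise ValueError(f"{path}: unsupported TRC units {units!r}")
    factor = 0.001 if units == "mm" else 1.0
    names = [s for s in lines[3].split("\t")[2:] if s]
    if len(names) != nmark:
        raise ValueError(f"{path}: header lists {nmark} markers, found {len(names)}")
    rows = [list(map(float, ln.split("\t")[2:])) for ln in lines[5:5 + n] if ln.strip()]
    data = np.array(rows) * factor
    markers = {m: data[:, 3 * i:3 * i + 3].copy() for i, m in enumerate(names)}
    return markers, rate


def write_forces_csv(path, trial: TrialDataset, plate: str):
    rec = trial.grf[plate]
    nf = len(rec["force"])
    t = np.arange(nf) / trial.force_rate
    df = pd.DataFrame({
        "time": t,
        "Fx": rec["force"][:, 0], "Fy": rec["force"][:, 1], "Fz": rec["force"][:, 2],
        "COPx": rec["cop"][:, 0], "COPy": rec["cop"][:, 1], "COPz": rec["cop"][:, 2],
        "Tz": rec["free_moment"],
    })
    df.to_csv(path, index=False, float_format="%.8g")


def read_forces_csv(path):
    """Returns ({"force","cop","free_moment"}, rate)."""
    df = pd.read_csv(path)
    missing = [c for c in _FORCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: force CSV missing columns {missing}")
    t = df["time"].to_numpy()
    rate = 1.0 / np.median(np.diff(t))
    return {
        "force": df[["Fx", "Fy", "Fz"]].to_numpy(),
        "cop": df[["COPx", "COPy", "COPz"]].to_numpy(),
        "free_moment": df["Tz"].to_numpy(),
    }, float(round(rate))


def write_stl(path, mesh: trimesh.Trimesh):
    """ASCII STL in mm."""
    m = mesh.copy()
    m.vertices = m.vertices * 1000.0
    m.export(path, file_type="stl_ascii")


def read_stl(path) -> trimesh.Trimesh:
    m = trimesh.load(str(path), file_type="stl", process=False)
    m.vertices = m.vertices / 1000.0
    return m


def write_landmarks_json(path, landmarks: dict):
    """{bone: {landmark: [x, y, z]}} in meters."""
    payload = {bone: {k: list(map(float, np.asarray(v)))
                      for k, v in lms.items()}
               for bone, lms in landmarks.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_landmarks_json(path) -> dict:
    data = json.loads(Path(path).read_text())
    out = {}
    for bone, lms in data.items():
        out[bone] = {}
        for k, v in lms.items():
            arr = np.asarray(v, dtype=float)
            if arr.shape != (3,):
                raise ValueError(f"{path}: landmark {bone}/{k} is not a 3-vector")
            out[bone][k] = arr
    return out


def write_trial(directory, trial: TrialDataset, name: str):
    """Write a trial as TRC + per-plate force CSV + events JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_trc(directory / f"{name}.trc", trial)
    for plate in trial.grf:
        write_forces_csv(directory / f"{name}_{plate}.csv", trial, plate)
    meta = {"condition": trial.condition.name,
            "wedge_angle": trial.condition.wedge_angle,
            "foot_progression_offset": trial.condition.foot_progression_offset,
            "step_width_offset": trial.condition.step_width_offset,
            "events": trial.events, "marker_rate": trial.marker_rate,
            "force_rate": trial.force_rate}
    (directory / f"{name}_meta.json").write_text(json.dumps(meta, indent=1))


def read_trial(directory, name: str) -> TrialDataset:
    directory = Path(directory)
    trc = directory / f"{name}.trc"
    if not trc.exists():
        raise FileNotFoundError(f"trial file not found: {trc}")
    markers, rate = read_trc(trc)
    meta = json.loads((directory / f"{name}_meta.json").read_text())
    grf = {}
    for p in sorted(directory.glob(f"{name}_plate*.csv")):
        plate = p.stem.split("_")[-1]
        grf[plate], force_rate = read_forces_csv(p)
    cond = GaitCondition(meta["condition"], wedge_angle=meta["wedge_angle"],
                         foot_progression_offset=meta["foot_progression_offset"],
                         step_width_offset=meta["step_width_offset"])
    return TrialDataset(markers=markers, marker_rate=meta["marker_rate"],
                        grf=grf, force_rate=meta["force_rate"], condition=cond,
                        events=meta.get("events", {}))
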