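"""Readers and writers for meshes, manifests, landmarks, and results.

On-disk conventions: triangle meshes as PLY/STL/OBJ (via trimesh), point
clouds as CSV with an ``x,y,z`` header, landmarks as JSON, sequences as a
manifest CSV listing per-frame files, results as JSON plus report CSVs.
All file coordinates are scanner-space millimetres; local-frame outputs
are labelled as such.  Human-readable report CSVs are rounded to 0.05 mm;
machine JSON never is.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .geometry import (
    FrameData,
    KneeSequence,
    LandmarkSet,
    SurfaceModel,
    build_surface,
    surface_from_mesh,
)

MESH_SUFFIXES = {".ply", ".stl", ".obj"}


def round_to(value, step: float = 0.05):
    """Round to the reporting granularity (0.05 mm by default)."""
    return np.round(np.asarray(value, dtype=float) / step) * step


def read_point_cloud(path) -> np.ndarray:
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        xyz = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"{path}: point cloud CSV needs x,y,z columns") from exc
    return xyz


def write_point_cloud(path, points) -> None:
    pd.DataFrame(np.asarray(points, dtype=float), columns=["x", "y", "z"]).to_csv(
        path, index=False
    )


def read_surface(path, alpha: float | None = None) -> SurfaceModel:
    """Load a femoral surface from a mesh file or a point-cloud CSV."""
    path = Path(path)
    if path.suffix.lower() in MESH_SUFFIXES:
        mesh = trimesh.load(str(path), force="mesh")
        return surface_from_mesh(mesh.vertices, mesh.faces)
    return build_surface(read_point_cloud(path), alpha=alpha)


def write_surface(path, surface: SurfaceModel) -> None:
    mesh = trimesh.Trimesh(
        vertices=surface.vertices, faces=surface.triangles, process=False
    )
    mesh.export(str(path))


def read_landmarks(path) -> LandmarkSet:
    """Landmark JSON: keys MFC, LFC, RA, S_point (each [x,y,z] mm), side."""
    with open(path) as fh:
        data = json.load(fh)
    try:
        return LandmarkSet(
            mfc=data["MFC"], lfc=data["LFC"], ra=data["RA"],
            s_point=data["S_point"], side=data.get("side", "right"),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing landmark key {exc}") from exc


def write_landmarks(path, landmarks: LandmarkSet) -> None:
    data = {
        "MFC": landmarks.mfc.tolist(),
        "LFC": landmarks.lfc.tolist(),
        "RA": landmarks.ra.tolist(),
        "S_point": landmarks.s_point.tolist(),
        "side": landmarks.side,
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


def read_sequence(manifest_path, alpha: float | None = None) -> KneeSequence:
    """Load a knee sequence from a manifest CSV.

    Columns: ``frame_index, femur_file, patella_file`` and optionally
    ``flexion_angle`` (degrees), ``subject_id``, ``side``.  File paths are
    resolved relative to the manifest.  Identical femur files are loaded
    once and shared across frames.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"frame_index", "femur_file", "patella_file"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{manifest_path}: manifest missing columns {sorted(missing)}")
    if df["frame_index"].duplicated().any():
        dup = df.loc[df["frame_index"].duplicated(), "frame_index"].iloc[0]
        raise ValueError(f"{manifest_path}: duplicate frame_index {dup}")
    if not df["frame_index"].is_monotonic_increasing:
        warnings.warn(f"{manifest_path}: frames out of order; sorting", stacklevel=2)
        df = df.sort_values("frame_index")

    root = manifest_path.parent
    surface_cache: dict[str, SurfaceModel] = {}
    frames = []
    for _, row in df.iterrows():
        fpath = root / str(row["femur_file"])
        ppath = root / str(row["patella_file"])
        for p in (fpath, ppath):
            if not p.exists():
                raise FileNotFoundError(
                    f"{manifest_path}: frame {row['frame_index']} references "
                    f"missing file {p}"
                )
        key = str(fpath)
        if key not in surface_cache:
            surface_cache[key] = read_surface(fpath, alpha=alpha)
        angle = row.get("flexion_angle")
        frames.append(
            FrameData(
                frame_index=int(row["frame_index"]),
                femur=surface_cache[key],
                patella_points=read_point_cloud(ppath),
                flexion_angle=None if angle is None or pd.isna(angle) else float(angle),
            )
        )
    subject = str(df["subject_id"].iloc[0]) if "subject_id" in df.columns else "unknown"
    side = str(df["side"].iloc[0]) if "side" in df.columns else "right"
    return KneeSequence(subject_id=subject, side=side, frames=frames)


def read_cohort(path) -> pd.DataFrame:
    """Cohort CSV with paired coordinates Sx..Sz, Ix..Iz per subject."""
    df = pd.read_csv(path)
    needed = ["Sx", "Sy", "Sz", "Ix", "Iy", "Iz"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort CSV missing columns {missing}")
    if df[needed].isna().any().any():
        raise ValueError(f"{path}: cohort CSV has incomplete paired rows")
    return df


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(out_dir, result_json: dict, config: dict, tables: dict | None = None):
    """Write a run's JSON result, its config, and report CSVs.

    ``tables`` maps file stems to DataFrames; numeric columns in report
    CSVs are rounded to the 0.05 mm reporting granularity.  Every file
    embeds or sits beside the config hash for provenance.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = dict(config)
    config["config_hash"] = config_hash(config)
    result_json = dict(result_json)
    result_json["config_hash"] = config["config_hash"]
    with open(out_dir / "result.json", "w") as fh:
        json.dump(result_json, fh, indent=2, default=_json_default)
    with open(out_dir / "config.json", "w") as fh:
        json.dump(config, fh, indent=2, default=_json_default)
    written = [out_dir / "result.json", out_dir / "config.json"]
    for stem, df in (tables or {}).items():
        df = df.copy()
        for c in df.columns:
            if pd.api.types.is_float_dtype(df[c]):
                df[c] = round_to(df[c].to_numpy())
        path = out_dir / f"{stem}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    return written


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
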