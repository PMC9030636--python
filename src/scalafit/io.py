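"""File formats: meshes (PLY/STL/OBJ), landmark and transform JSON/CSV,
electrode-array CSV, rater tables, calls, and the bank manifest.

Units are millimetres and degrees everywhere; categories are serialized as
"ST"/"INT"/"SV".  Template meshes are written as binary little-endian PLY
with per-vertex ``angle_deg`` and ``width_frac`` properties plus a JSON
sidecar carrying landmarks, index value, side and label; STL/OBJ exports
carry geometry only.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .agreement import DEFAULT_CATEGORIES, RaterTable
from .classify import ArrayCall
from .errors import InputFormatError
from .geometry import CochlearLandmarks, ElectrodeArray, MembraneTemplate
from .registration import SimilarityTransform

__all__ = [
    "save_template", "load_template", "write_mesh",
    "write_landmarks_json", "read_landmarks_json",
    "write_landmarks_csv", "read_landmarks_csv",
    "write_array_csv", "read_array_csv",
    "write_transform_json", "read_transform_json",
    "write_ratings_long", "write_ratings_wide", "read_ratings",
    "write_calls_csv", "write_summary_json",
    "save_bank", "load_bank",
]

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# meshes / templates


def write_mesh(template: MembraneTemplate, path: PathLike) -> None:
    """Export the template mesh by extension (.ply binary, .stl, .obj)."""
    import trimesh

    path = Path(path)
    mesh = trimesh.Trimesh(vertices=template.vertices, faces=template.faces,
                           process=False)
    if path.suffix.lower() == ".ply":
        mesh.vertex_attributes["angle_deg"] = template.angular_coord
        if template.width_frac is not None:
            mesh.vertex_attributes["width_frac"] = template.width_frac
        mesh.export(path, encoding="binary")
    elif path.suffix.lower() in (".stl", ".obj"):
        mesh.export(path)
    else:
        raise InputFormatError(f"unsupported mesh format: {path.suffix}")


def save_template(template: MembraneTemplate, mesh_path: PathLike,
                  meta_path: Optional[PathLike] = None) -> Path:
    """Write a template as PLY + JSON sidecar; returns the sidecar path."""
    mesh_path = Path(mesh_path)
    if mesh_path.suffix.lower() != ".ply":
        raise InputFormatError("templates must be saved as .ply to keep "
                               "angular coordinates")
    write_mesh(template, mesh_path)
    meta_path = Path(meta_path) if meta_path else mesh_path.with_suffix(".json")
    meta = {
        "side": template.side,
        "label": template.label,
        "index_value": template.index_value,
        "landmarks": None if template.landmarks is None else {
            n: [float(v) for v in getattr(template.landmarks, n)]
            for n in CochlearLandmarks.NAMES},
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return meta_path


def load_template(mesh_path: PathLike,
                  meta_path: Optional[PathLike] = None) -> MembraneTemplate:
    """Load a template written by :func:`save_template`.

    Checks normal orientation (scala-vestibuli side must be +z-leaning in
    the canonical frame) and flips inconsistent face windings.
    """
    import trimesh

    mesh_path = Path(mesh_path)
    mesh = trimesh.load(mesh_path, process=False)
    raw = mesh.metadata.get("_ply_raw", {}).get("vertex", {}).get("data")
    names = raw.dtype.names if raw is not None else ()
    if raw is None or "angle_deg" not in names:
        raise InputFormatError(
            f"{mesh_path}: no per-vertex angle_deg property; not a saved template")
    angular = np.asarray(raw["angle_deg"], dtype=float)
    wfrac = np.asarray(raw["width_frac"], float) if "width_frac" in names else None

    meta_path = Path(meta_path) if meta_path else mesh_path.with_suffix(".json")
    landmarks = index_value = None
    side, label = "right", mesh_path.stem
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        side = meta.get("side", side)
        label = meta.get("label", label)
        index_value = meta.get("index_value")
        if meta.get("landmarks"):
            landmarks = CochlearLandmarks(**{k: np.array(v) for k, v in
                                             meta["landmarks"].items()})
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    fn = np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                  verts[faces[:, 2]] - verts[faces[:, 0]])
    if np.median(fn[:, 2]) < 0:          # normals flipped on disk
        faces = faces[:, ::-1]
    return MembraneTemplate(verts, faces, angular, wfrac, landmarks,
                            index_value, side, label)


# ---------------------------------------------------------------------------
# landmarks


def write_landmarks_json(landmarks: CochlearLandmarks, path: PathLike) -> None:
    data = {n: [float(v) for v in getattr(landmarks, n)]
            for n in CochlearLandmarks.NAMES}
    Path(path).write_text(json.dumps(data, indent=2))


def read_landmarks_json(path: PathLike) -> CochlearLandmarks:
    try:
        data = json.loads(Path(path).read_text())
        return CochlearLandmarks(**{n: np.asarray(data[n], float)
                                    for n in CochlearLandmarks.NAMES})
    except (KeyError, json.JSONDecodeError) as exc:
        raise InputFormatError(f"{path}: malformed landmark JSON ({exc})") from exc


def write_landmarks_csv(landmarks: CochlearLandmarks, path: PathLike) -> None:
    rows = [{"name": n, "x": p[0], "y": p[1], "z": p[2]}
            for n in CochlearLandmarks.NAMES
            for p in [getattr(landmarks, n)]]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks_csv(path: PathLike) -> CochlearLandmarks:
    df = pd.read_csv(path)
    required = {"name", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise InputFormatError(f"{path}: landmark CSV needs columns {sorted(required)}")
    pts = {}
    for line, row in df.iterrows():
        pts[str(row["name"])] = np.array([row["x"], row["y"], row["z"]], float)
        if not np.all(np.isfinite(pts[str(row['name'])])):
            raise InputFormatError(f"{path}: non-finite coordinate at row {line + 2}")
    missing = set(CochlearLandmarks.NAMES) - set(pts)
    if missing:
        raise InputFormatError(f"{path}: missing landmark rows {sorted(missing)}")
    return CochlearLandmarks(**{n: pts[n] for n in CochlearLandmarks.NAMES})


# ---------------------------------------------------------------------------
# electrode arrays


def write_array_csv(array: ElectrodeArray, path: PathLike) -> None:
    """Most basal electrode first: electrode_index,x,y,z,diameter_mm."""
    df = pd.DataFrame(array.centers, columns=["x", "y", "z"])
    df.insert(0, "electrode_index", np.arange(1, array.n_electrodes + 1))
    df["diameter_mm"] = array.contact_diameter
    df.to_csv(path, index=False)


def read_array_csv(path: PathLike, model_name: str = "") -> ElectrodeArray:
    df = pd.read_csv(path)
    required = {"electrode_index", "x", "y", "z", "diameter_mm"}
    if not required.issubset(df.columns):
        raise InputFormatError(f"{path}: array CSV needs columns {sorted(required)}")
    df = df.sort_values("electrode_index")
    centers = df[["x", "y", "z"]].to_numpy(float)
    for i, row in enumerate(centers):
        if not np.all(np.isfinite(row)):
            raise InputFormatError(f"{path}: non-finite coordinate at row {i + 2}")
    diam = df["diameter_mm"].to_numpy(float)
    if not np.allclose(diam, diam[0]):
        raise InputFormatError(f"{path}: diameter_mm must be constant per array")
    return ElectrodeArray(centers, float(diam[0]), model_name)


# ---------------------------------------------------------------------------
# transforms


def write_transform_json(transform: SimilarityTransform, path: PathLike) -> None:
    data = {
        "rotation": [float(v) for v in transform.rotation.ravel()],
        "scale": float(transform.scale),
        "translation": [float(v) for v in transform.translation],
        "rms_residual_mm": float(transform.rms_residual),
    }
    Path(path).write_text(json.dumps(data, indent=2))


def read_transform_json(path: PathLike) -> SimilarityTransform:
    try:
        data = json.loads(Path(path).read_text())
        return SimilarityTransform(
            np.asarray(data["rotation"], float).reshape(3, 3),
            float(data["scale"]),
            np.asarray(data["translation"], float),
            float(data.get("rms_residual_mm", 0.0)),
        )
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise InputFormatError(f"{path}: malformed transform JSON ({exc})") from exc


# ---------------------------------------------------------------------------
# rater tables


def write_ratings_long(table: RaterTable, path: PathLike) -> None:
    """Long form: electrode_id,rater_id,category (one row per rating)."""
    rows = []
    labels = table.item_labels or [f"e{i + 1}" for i in range(table.n_items)]
    for i, label in enumerate(labels):
        rater = 1
        for j, cat in enumerate(table.categories):
            for _ in range(int(table.counts[i, j])):
                rows.append({"electrode_id": label, "rater_id": f"r{rater}",
                             "category": cat})
                rater += 1
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ratings_wide(assignments, item_labels, rater_labels,
                       path: PathLike) -> None:
    """Wide form: electrode_id plus one category column per rater."""
    df = pd.DataFrame(np.asarray(assignments), columns=list(rater_labels))
    df.insert(0, "electrode_id", list(item_labels))
    df.to_csv(path, index=False)


def read_ratings(path: PathLike,
                 categories=DEFAULT_CATEGORIES) -> RaterTable:
    """Read a rater table from long or wide CSV (detected by columns)."""
    df = pd.read_csv(path)
    cats = tuple(categories)
    if {"electrode_id", "rater_id", "category"}.issubset(df.columns):
        bad = set(df["category"].astype(str)) - set(cats)
        if bad:
            raise InputFormatError(
                f"{path}: unknown category labels {sorted(bad)}; valid: {list(cats)}")
        pivot = (df.assign(category=df["category"].astype(str))
                 .pivot_table(index="electrode_id", columns="category",
                              values="rater_id", aggfunc="count", fill_value=0))
        pivot = pivot.reindex(columns=list(cats), fill_value=0)
        return RaterTable(pivot.to_numpy(), cats, tuple(map(str, pivot.index)))
    if "electrode_id" in df.columns and df.shape[1] >= 3:
        raters = [c for c in df.columns if c != "electrode_id"]
        arr = df[raters].astype(str).to_numpy()
        return RaterTable.from_assignments(arr, cats,
                                           tuple(map(str, df["electrode_id"])))
    raise InputFormatError(
        f"{path}: expected long columns (electrode_id, rater_id, category) "
        "or wide (electrode_id + one column per rater)")


# ---------------------------------------------------------------------------
# calls, summaries, bank manifest


def write_calls_csv(call: ArrayCall, path: PathLike) -> None:
    call.to_dataframe().to_csv(path, index=False)


def write_summary_json(summary: dict, path: PathLike) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(summary, indent=2, default=default))


def save_bank(bank, out_dir: PathLike) -> Path:
    """Write every bank template plus a YAML manifest; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for side in ("right", "left"):
        for i, tmpl in enumerate(bank.templates(side)):
            stem = f"template_{side}_{i + 1}"
            save_template(tmpl, out_dir / f"{stem}.ply")
            entries.append({
                "mesh": f"{stem}.ply",
                "meta": f"{stem}.json",
                "index_value": float(tmpl.index_value),
                "side": side,
            })
    manifest = {
        "index_kind": bank.index_kind,
        "selection_percentiles": list(bank.selection_percentiles),
        "reference_mean": float(bank.reference_mean),
        "reference_sd": float(bank.reference_sd),
        "templates": entries,
    }
    path = out_dir / "bank.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def load_bank(manifest_path: PathLike):
    from .morphometry import TemplateBank

    manifest_path = Path(manifest_path)
    try:
        manifest = yaml.safe_load(manifest_path.read_text())
        base = manifest_path.parent
        sides = {"right": [], "left": []}
        for entry in manifest["templates"]:
            tmpl = load_template(base / entry["mesh"], base / entry["meta"])
            tmpl.index_value = float(entry["index_value"])
            sides[entry["side"]].append(tmpl)
        for side in sides:
            sides[side].sort(key=lambda t: t.index_value)
        return TemplateBank(
            tuple(sides["right"]), tuple(sides["left"]),
            manifest["index_kind"],
            tuple(manifest["selection_percentiles"]),
            float(manifest["reference_mean"]), float(manifest["reference_sd"]))
    except (KeyError, TypeError, yaml.YAMLError) as exc:
        raise InputFormatError(f"{manifest_path}: malformed bank manifest "
                               f"({exc})") from exc
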