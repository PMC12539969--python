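"""Readers and writers for the pipeline's file formats.

Meshes travel as PLY (ASCII by default, binary little-endian on request),
occupancy volumes as multi-page TIFF (uint8, {0, 255}), landmark inputs as
JSON, tables as UTF-8 CSV with a header row and "." decimals, and run
configurations as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh
import yaml

from .errors import FormatError, SchemaError

__all__ = [
    "read_mesh", "write_mesh", "read_landmarks", "write_landmarks",
    "read_table", "write_table", "read_volume", "write_volume",
    "read_config", "PAIRS_SCHEMA", "SIZE_SCHEMA",
]


def read_mesh(path) -> trimesh.Trimesh:
    """Load a PLY surface; raises :class:`FormatError` on malformed files."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mesh file not found: {path}")
    try:
        mesh = trimesh.load(path, file_type="ply", process=False)
    except Exception as exc:
        raise FormatError(f"cannot parse PLY file {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.vertices) == 0:
        raise FormatError(f"no triangulated surface in {path}")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path, binary: bool = False):
    """Write a PLY surface (ASCII by default for text-friendly diffs)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = trimesh.exchange.ply.export_ply(
        mesh, encoding="binary_little_endian" if binary else "ascii")
    path.write_bytes(data)


def write_landmarks(path, C, D, siphonoglyph_points, dorsal_reference=None):
    """Write the per-specimen landmark-input JSON."""
    obj = {
        "C": np.asarray(C, float).tolist(),
        "D": np.asarray(D, float).tolist(),
        "siphonoglyph_points": np.asarray(siphonoglyph_points, float).tolist(),
    }
    if dorsal_reference is not None:
        obj["dorsal_reference"] = np.asarray(dorsal_reference, float).tolist()
    Path(path).write_text(json.dumps(obj, indent=1))


def read_landmarks(path) -> dict:
    """Read landmark-input JSON: C, D, siphonoglyph_points (+ optional
    dorsal_reference), all as float arrays."""
    try:
        obj = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse landmark JSON {path}: {exc}") from exc
    out = {}
    for key in ("C", "D", "siphonoglyph_points"):
        if key not in obj:
            raise SchemaError(f"landmark JSON missing field {key!r}")
        out[key] = np.asarray(obj[key], dtype=float)
    if "dorsal_reference" in obj:
        out["dorsal_reference"] = np.asarray(obj["dorsal_reference"], dtype=float)
    return out


#: required column -> required dtype kind ('f' numeric, 'b' boolean, 'O' text)
PAIRS_SCHEMA = {"pair_id": "O", "taxon": "O", "d13C": "f", "d15N": "f"}
SIZE_SCHEMA = {
    "specimen_id": "O", "species": "O", "sex": "O", "ovigerous": "b",
    "symbiotic_category": "O", "shield_length": "f", "source": "O",
}


def read_table(path, schema: dict | None = None) -> pd.DataFrame:
    """Read a CSV table, validating it against a column schema.

    Missing required columns raise :class:`SchemaError` naming the column;
    non-numeric entries in numeric columns raise with the offending row
    index.  Unknown columns are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"table not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse CSV {path}: {exc}") from exc
    if schema:
        for col, kind in schema.items():
            if col not in df.columns:
                raise SchemaError(f"{path}: missing required column {col!r}")
            if kind == "f":
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = df.index[coerced.isna() & df[col].notna()]
                if len(bad):
                    raise SchemaError(
                        f"{path}: non-numeric value in column {col!r} "
                        f"at row(s) {list(bad[:5])}")
                df[col] = coerced
            elif kind == "b":
                df[col] = df[col].astype(bool)
    return df


def write_table(df: pd.DataFrame, path):
    """Write a CSV table (UTF-8, header row, '.' decimal)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_volume(volume: np.ndarray, path):
    """Write a binary occupancy volume as a multi-page uint8 TIFF."""
    vol = np.asarray(volume, dtype=np.uint8)
    tifffile.imwrite(Path(path), vol, photometric="minisblack")


def read_volume(path) -> np.ndarray:
    try:
        return tifffile.imread(Path(path))
    except Exception as exc:
        raise FormatError(f"cannot read TIFF volume {path}: {exc}") from exc


def read_config(path) -> dict:
    """Read a YAML run configuration into a plain dict."""
    try:
        obj = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise FormatError(f"cannot parse YAML config {path}: {exc}") from exc
    if not isinstance(obj, dict):
        raise SchemaError("config YAML must be a mapping")
    return obj
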