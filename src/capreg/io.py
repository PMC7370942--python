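"""Readers/writers for the pipeline's file formats.

Point clouds travel as PLY (ascii or binary-little-endian, per-vertex
uchar red/green/blue); coordinate tables as UTF-8 CSV with a header row,
mm units, the package-wide RAS-like axes.  PLY parsing/serialisation is
delegated to trimesh; a lightweight header scan in front of it produces
precise errors (offending header line, missing colour properties).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml
from PIL import Image

from .errors import (
    InvalidParameterError,
    MissingColorError,
    PlyParseError,
)
from .types import (
    ColoredPointCloud,
    Frame,
    LabeledFiducialSet,
    StickerDetection2D,
)

__all__ = [
    "PipelineConfig",
    "read_point_cloud",
    "write_point_cloud",
    "read_fiducials_csv",
    "write_fiducials_csv",
    "read_model_cap_table",
    "write_model_cap_table",
    "read_channels_csv",
    "write_channels_csv",
    "read_frame",
    "write_frame",
    "write_detections_csv",
    "default_reference_mni_path",
]


def default_reference_mni_path() -> Path:
    """Shipped editable table of standard 10-20 scalp fiducial positions
    in MNI space (Nz, AL, AR, Cz)."""
    import importlib.resources
    ref = importlib.resources.files("capreg.data") / "reference_mni.csv"
    with importlib.resources.as_file(ref) as path:
        return Path(path)


# ---------------------------------------------------------------------------
# PLY point clouds


def _scan_ply_header(path: Path) -> None:
    """Validate the PLY header, raising precise errors before parsing."""
    with open(path, "rb") as fh:
        first = fh.readline().strip()
        if first != b"ply":
            raise PlyParseError("not a PLY file (missing 'ply' magic)",
                                line_number=1, line=first.decode("latin-1"))
        has_vertex = False
        properties: list[str] = []
        fmt = None
        for lineno in range(2, 200):
            raw = fh.readline()
            if not raw:
                raise PlyParseError("header ended before end_header",
                                    line_number=lineno, line="")
            line = raw.decode("latin-1").strip()
            if line.startswith("format"):
                parts = line.split()
                if len(parts) < 2 or parts[1] not in (
                        "ascii", "binary_little_endian"):
                    raise PlyParseError("unsupported PLY format",
                                        line_number=lineno, line=line)
                fmt = parts[1]
            elif line.startswith("element vertex"):
                has_vertex = True
            elif line.startswith("element"):
                has_vertex = False
            elif line.startswith("property") and has_vertex:
                properties.append(line.split()[-1])
            elif line == "end_header":
                break
        else:
            raise PlyParseError("header too long / end_header not found")
        if fmt is None:
            raise PlyParseError("PLY header lacks a format line")
        missing = {"red", "green", "blue"} - set(properties)
        if missing:
            raise MissingColorError(
                f"PLY lacks per-vertex colour properties: {sorted(missing)}")


def read_point_cloud(path) -> ColoredPointCloud:
    """Read an ascii or binary-little-endian PLY with per-vertex RGB."""
    path = Path(path)
    if not path.exists():
        raise InvalidParameterError(f"no such file: {path}")
    _scan_ply_header(path)
    try:
        obj = trimesh.load(str(path), process=False)
    except Exception as exc:  # trimesh raises assorted types
        raise PlyParseError(f"failed to parse PLY body: {exc}") from exc
    positions = np.asarray(obj.vertices, dtype=float)
    colors = np.asarray(obj.colors if hasattr(obj, "colors")
                        else obj.visual.vertex_colors)
    if colors.size == 0:
        raise MissingColorError("PLY parsed without vertex colours")
    return ColoredPointCloud(positions=positions,
                             colors=colors[:, :3].astype(np.uint8))


def write_point_cloud(cloud: ColoredPointCloud, path,
                      encoding: str = "binary") -> Path:
    """Write a cloud as PLY (``encoding``: 'binary' little-endian or
    'ascii')."""
    if encoding not in ("binary", "ascii"):
        raise InvalidParameterError("encoding must be 'binary' or 'ascii'")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rgba = np.column_stack([cloud.colors,
                            np.full(len(cloud), 255, np.uint8)])
    pc = trimesh.PointCloud(cloud.positions, colors=rgba)
    pc.export(str(path), encoding=encoding)
    return path


# ---------------------------------------------------------------------------
# CSV tables


def read_fiducials_csv(path) -> LabeledFiducialSet:
    """Read a labelled-fiducial table (columns label,x,y,z)."""
    table = pd.read_csv(path)
    return LabeledFiducialSet({
        row["label"]: np.array([row["x"], row["y"], row["z"]], float)
        for _, row in table.iterrows()})


def write_fiducials_csv(fiducials: LabeledFiducialSet, path,
                        cost: float | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [{"label": l, "x": p[0], "y": p[1], "z": p[2],
             **({"cost": cost} if cost is not None else {})}
            for l, p in fiducials.items()]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_model_cap_table(path):
    """Read a model-cap table (kind,id,x,y,z; kind in fiducial / source /
    detector / channel).  Returns (LabeledFiducialSet, probes dict) where
    every non-fiducial row is a probe."""
    table = pd.read_csv(path)
    required = {"kind", "id", "x", "y", "z"}
    if not required <= set(table.columns):
        raise InvalidParameterError(
            f"model cap table needs columns {sorted(required)}")
    fiducials = {}
    probes = {}
    for _, row in table.iterrows():
        p = np.array([row["x"], row["y"], row["z"]], float)
        if row["kind"] == "fiducial":
            fiducials[row["id"]] = p
        else:
            probes[str(row["id"])] = p
    return LabeledFiducialSet(fiducials), probes


def write_model_cap_table(fiducials: LabeledFiducialSet, probes, path,
                          kind: str = "channel") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [{"kind": "fiducial", "id": l, "x": p[0], "y": p[1], "z": p[2]}
            for l, p in fiducials.items()]
    rows += [{"kind": kind, "id": i, "x": p[0], "y": p[1], "z": p[2]}
             for i, p in sorted(probes.items())]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_channels_csv(path) -> dict[str, np.ndarray]:
    table = pd.read_csv(path)
    return {str(row["channel"]): np.array([row["x"], row["y"], row["z"]],
                                          float)
            for _, row in table.iterrows()}


def write_channels_csv(channel_positions: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [{"channel": c, "x": p[0], "y": p[1], "z": p[2]}
            for c, p in sorted(channel_positions.items())]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_detections_csv(detections_by_frame, path) -> Path:
    """detections_by_frame: iterable of (frame_index, [StickerDetection2D])."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for frame_index, dets in detections_by_frame:
        for d in dets:
            rows.append({"frame_index": frame_index,
                         "row": d.center_px[0], "col": d.center_px[1],
                         "radius": d.radius_px, "pixel_count": d.pixel_count})
    pd.DataFrame(rows, columns=["frame_index", "row", "col", "radius",
                                "pixel_count"]).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Frames


def read_frame(path, frame_index: int = 0, timestamp_s: float = 0.0) -> Frame:
    pixels = np.asarray(Image.open(path).convert("RGB"))
    return Frame(pixels=pixels, frame_index=frame_index,
                 timestamp_s=timestamp_s)


def write_frame(frame: Frame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(frame.pixels).save(path)
    return path


# ---------------------------------------------------------------------------
# Configuration


@dataclasses.dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Hues are fractions of the hue circle in [0, 1); lengths in mm.
    """

    model_cap_path: str
    point_cloud_path: str | None = None
    reference_mni_path: str | None = None
    sticker_hue: float = 1.0 / 3.0
    hue_tol: float = 0.15
    link_radius_mm: float = 10.0
    min_cluster_size: int = 5
    reject_threshold: float = 0.98
    free_vertical_scale: bool = False
    seed: int = 0
    output_dir: str = "capreg-out"

    def __post_init__(self):
        if not 0.0 <= self.sticker_hue < 1.0:
            raise InvalidParameterError("sticker_hue must lie in [0, 1)")
        if not 0.0 < self.hue_tol < 0.5:
            raise InvalidParameterError("hue_tol must lie in (0, 0.5)")
        if self.link_radius_mm <= 0:
            raise InvalidParameterError("link_radius_mm must be positive")
        if self.min_cluster_size < 1:
            raise InvalidParameterError("min_cluster_size must be >= 1")
        if not 0.0 < self.reject_threshold <= 1.0:
            raise InvalidParameterError("reject_threshold must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Stable hash of the configuration, logged by every run."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
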