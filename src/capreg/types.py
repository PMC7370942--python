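"""Domain containers shared across the pipeline.

Labels follow the nine-fiducial layout: three head (anatomical) stickers —
Nz (nasion), AL / AR (left / right preauricular) — and six cap stickers
near Cz, Pz, Iz and the front / left / right cap edges (roughly Fpz, T7,
T8 of the 10-20 system). Cz is placed by the experimenter at the correct
scalp position, so it serves double duty: it is a cap marker but is also
used together with Nz/AL/AR when fitting the head-to-MNI transform.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping

import numpy as np

from .errors import (
    ContractViolationError,
    InvalidParameterError,
)
from .geometry import CapTransform

#: Canonical label order used for weight-matrix columns and CSV output.
FIDUCIAL_LABELS = ("Nz", "AL", "AR", "Cz", "Pz", "Iz", "FRONT", "LEFT", "RIGHT")
HEAD_LABELS = ("Nz", "AL", "AR")
CAP_LABELS = ("Cz", "Pz", "Iz", "FRONT", "LEFT", "RIGHT")
#: Labels used to fit the head-to-MNI transform.
REGISTRATION_LABELS = ("Nz", "AL", "AR", "Cz")


class LabeledFiducialSet:
    """Named 3-D fiducial points in mm.

    A full set has all nine labels; a registration-grade subset has at
    least five (the cap layout carries six cap stickers for redundancy).
    """

    def __init__(self, points: Mapping[str, np.ndarray]):
        clean: dict[str, np.ndarray] = {}
        for label, p in points.items():
            label = str(label)
            if label not in FIDUCIAL_LABELS:
                raise InvalidParameterError(
                    f"unknown fiducial label {label!r}; expected one of "
                    f"{FIDUCIAL_LABELS}")
            if label in clean:
                raise InvalidParameterError(f"duplicate label {label!r}")
            arr = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(arr)):
                raise InvalidParameterError(f"non-finite point for {label!r}")
            clean[label] = arr
        self._points = clean

    @property
    def points(self) -> dict[str, np.ndarray]:
        return dict(self._points)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(l for l in FIDUCIAL_LABELS if l in self._points)

    def __contains__(self, label: str) -> bool:
        return label in self._points

    def __len__(self) -> int:
        return len(self._points)

    def __getitem__(self, label: str) -> np.ndarray:
        return self._points[label]

    def items(self):
        return ((l, self._points[l]) for l in self.labels)

    def is_complete(self) -> bool:
        return len(self._points) == len(FIDUCIAL_LABELS)

    def as_array(self, labels=None) -> np.ndarray:
        """Stack the requested labels (default: all present, canonical
        order) into an (k, 3) array."""
        labels = self.labels if labels is None else tuple(labels)
        missing = [l for l in labels if l not in self._points]
        if missing:
            raise KeyError(f"missing fiducials: {missing}")
        return np.array([self._points[l] for l in labels])

    def subset(self, labels) -> "LabeledFiducialSet":
        return LabeledFiducialSet({l: self._points[l] for l in labels})

    def transformed(self, transform: CapTransform) -> "LabeledFiducialSet":
        return LabeledFiducialSet(
            {l: transform.apply(p) for l, p in self.items()})

    def __repr__(self):
        return f"LabeledFiducialSet({sorted(self._points)})"


@dataclasses.dataclass
class ColoredPointCloud:
    """Vertices with per-vertex RGB — the stand-in for an SfM
    reconstruction of the cap-mounted head."""

    positions: np.ndarray  # (n, 3) float mm
    colors: np.ndarray     # (n, 3) uint8

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
        if len(self.positions) != len(self.colors):
            raise ContractViolationError(
                "positions and colors must have equal length")
        if len(self.positions) and not np.all(np.isfinite(self.positions)):
            raise InvalidParameterError("positions must be finite")

    def __len__(self):
        return len(self.positions)


@dataclasses.dataclass
class GroundTruthScene:
    """A synthetic head with known fiducial and probe positions.

    ``applied_transform`` is the cap-on-head transform used to generate the
    scene (identity for the model head itself).
    """

    head_vertices: np.ndarray
    true_fiducials: LabeledFiducialSet
    true_probes: dict[str, np.ndarray]
    applied_transform: CapTransform
    seed: int
    semi_axes: tuple[float, float, float] | None = None

    def __post_init__(self):
        self.head_vertices = np.asarray(self.head_vertices,
                                        dtype=float).reshape(-1, 3)
        self.true_probes = {str(k): np.asarray(v, float).reshape(3)
                            for k, v in self.true_probes.items()}


@dataclasses.dataclass
class Frame:
    """One RGB video frame."""

    pixels: np.ndarray  # (H, W, 3) uint8
    frame_index: int = 0
    timestamp_s: float = 0.0

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InvalidParameterError("pixels must be (H, W, 3)")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise InvalidParameterError("frame must be at least 16x16")
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def shape(self):
        return self.pixels.shape[:2]


@dataclasses.dataclass(frozen=True)
class StickerDetection2D:
    """One detected fiducial sticker in pixel space.

    ``radius_px`` already includes the 20% margin around the exact minimum
    enclosing circle of the connected component.
    """

    center_px: tuple[float, float]  # (row, col)
    radius_px: float
    pixel_count: int
    mean_hue: float

    def __post_init__(self):
        if self.pixel_count < 5:
            raise InvalidParameterError("sticker clusters have >= 5 pixels")
        if self.radius_px <= 0:
            raise InvalidParameterError("radius must be positive")


@dataclasses.dataclass
class CropMask:
    """Binary keep-mask for one frame plus the kept-pixel fraction."""

    mask: np.ndarray
    kept_fraction: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if abs(self.kept_fraction - float(self.mask.mean())) > 1e-12:
            raise ContractViolationError(
                "kept_fraction must equal the mask mean")


@dataclasses.dataclass
class LabelingResult:
    """Outcome of RANSAC fiducial labeling."""

    fiducials: LabeledFiducialSet
    fit_cost_mm: float
    transform: CapTransform
    n_points_used: int

    def __post_init__(self):
        if self.fit_cost_mm < 0:
            raise InvalidParameterError("fit cost cannot be negative")


@dataclasses.dataclass
class ModelCap:
    """The pre-registered reference cap.

    ``weights`` holds one barycentric row per probe (columns in
    ``fiducial_order``); each row sums to 1, so probe interpolation is
    equivariant under any affine map of the fiducials.
    """

    fiducials: LabeledFiducialSet
    probes: dict[str, np.ndarray]
    weights: np.ndarray  # (n_probes, 9)
    probe_ids: tuple[str, ...]
    fiducial_order: tuple[str, ...] = FIDUCIAL_LABELS

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.probe_ids),
                                  len(self.fiducial_order)):
            raise ContractViolationError("weight matrix shape mismatch")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-9):
            raise ContractViolationError("weight rows must sum to 1")


@dataclasses.dataclass
class SessionMeasurement:
    """Per-channel MNI positions from one method in one session — the unit
    all validity/reliability statistics operate on."""

    method: str  # "video" | "digitizer"
    session_id: str
    channel_positions: dict[str, np.ndarray]

    def __post_init__(self):
        clean = {}
        for cid, p in self.channel_positions.items():
            arr = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(arr)):
                raise InvalidParameterError(f"non-finite position for {cid}")
            clean[str(cid)] = arr
        self.channel_positions = clean

    @property
    def channel_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.channel_positions))

    def as_array(self, channel_ids=None) -> np.ndarray:
        ids = self.channel_ids if channel_ids is None else channel_ids
        return np.array([self.channel_positions[c] for c in ids])


#: Contract for a pluggable cap segmenter: Frame -> (H, W) boolean mask.
CapSegmenter = Callable[[Frame], np.ndarray]
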