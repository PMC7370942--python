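"""Frame cropping: white balance, sticker detection, cap segmentation,
face polygon, mask composition and frame rejection.

The crop isolates the cap-mounted head before 3-D reconstruction so that
head motion reads as camera motion.  Sticker detection follows the hue
rule: every 8-connected cluster of at least five pixels whose hue lies
within ``hue_tol`` of the sticker hue (wrapping around the hue circle) is
a sticker; its circle is the exact minimum enclosing circle of the
cluster inflated by a 20% margin.  Frames where more than
``reject_threshold`` (default 98%) of the pixels are blackened are
dropped.

Cap segmentation is pluggable: any callable mapping a Frame to an (H, W)
boolean mask is accepted (a trained CNN in production); the built-in
fallback thresholds the two cap-pattern hue bands.  Face-landmark
acquisition is likewise external — ``face_polygon`` consumes named
landmark pixels.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.measure import label as cc_label

from .errors import (
    ContractViolationError,
    DegenerateInputError,
    DegeneratePolygonError,
    IncompleteLandmarksError,
    InvalidParameterError,
)
from .geometry import min_enclosing_circle
from .types import CapSegmenter, CropMask, Frame, StickerDetection2D

__all__ = [
    "CIRCLE_MARGIN",
    "DEFAULT_REJECT_THRESHOLD",
    "white_balance",
    "detect_stickers",
    "segment_cap",
    "face_polygon",
    "compose_and_apply",
    "reject_frame",
]

#: Margin added around each sticker cluster's minimum enclosing circle.
CIRCLE_MARGIN = 1.2
#: A frame is rejected when more than this fraction of it is blackened.
DEFAULT_REJECT_THRESHOLD = 0.98
#: Hue bands (centre, tolerance) of the two cap-pattern colours.
DEFAULT_CAP_HUE_BANDS = ((0.99, 0.06), (0.62, 0.08))
_REQUIRED_LANDMARKS = ("nose", "left_eye_edge", "right_eye_edge", "forehead")


def _hue_distance(hue: np.ndarray, reference: float) -> np.ndarray:
    """Circular distance on the normalised hue circle [0, 1)."""
    d = np.abs(hue - reference) % 1.0
    return np.minimum(d, 1.0 - d)


def white_balance(frame: Frame) -> Frame:
    """Gray-world white balance: scale each channel so its mean matches
    the global gray mean; clip to [0, 255].

    Idempotent up to integer rounding.  All-black input is degenerate.
    """
    pixels = frame.pixels.astype(float)
    means = pixels.reshape(-1, 3).mean(axis=0)
    if np.all(means == 0):
        raise DegenerateInputError("cannot white-balance an all-black frame")
    gray = means.mean()
    gains = np.where(means > 0, gray / np.maximum(means, 1e-12), 1.0)
    balanced = np.clip(pixels * gains, 0, 255)
    return Frame(pixels=np.round(balanced).astype(np.uint8),
                 frame_index=frame.frame_index,
                 timestamp_s=frame.timestamp_s)


def detect_stickers(frame: Frame, sticker_hue: float,
                    hue_tol: float = 0.15,
                    min_pixels: int = 5) -> list[StickerDetection2D]:
    """Find fiducial-sticker clusters by hue.

    Pixels whose hue is within ``hue_tol`` of ``sticker_hue`` (both as
    fractions of the hue circle, wrap-around) are grouped by
    8-connectivity; components of at least ``min_pixels`` pixels yield one
    detection each, circled by the exact minimum enclosing circle with a
    20% radius margin.  Detections are ordered by centre (row, col).
    """
    if not 0.0 < hue_tol < 0.5:
        raise InvalidParameterError("hue_tol must lie in (0, 0.5)")
    if not 0.0 <= sticker_hue < 1.0:
        raise InvalidParameterError("sticker_hue must lie in [0, 1)")

    hsv = rgb2hsv(frame.pixels)
    in_hue = _hue_distance(hsv[..., 0], sticker_hue) <= hue_tol
    if not in_hue.any():
        return []

    labels, n = cc_label(in_hue, connectivity=2, return_num=True)
    detections = []
    for comp in range(1, n + 1):
        coords = np.argwhere(labels == comp)
        if len(coords) < min_pixels:
            continue
        center, radius = min_enclosing_circle(coords.astype(float))
        mean_hue = _circular_mean_hue(hsv[..., 0][labels == comp])
        detections.append(StickerDetection2D(
            center_px=(float(center[0]), float(center[1])),
            radius_px=float(radius) * CIRCLE_MARGIN,
            pixel_count=int(len(coords)),
            mean_hue=mean_hue,
        ))
    detections.sort(key=lambda d: d.center_px)
    return detections


def _circular_mean_hue(hues: np.ndarray) -> float:
    angles = np.asarray(hues, float) * 2 * np.pi
    mean = np.arctan2(np.sin(angles).mean(), np.cos(angles).mean())
    return float((mean / (2 * np.pi)) % 1.0)


def segment_cap(frame: Frame, segmenter: CapSegmenter | None = None,
                cap_hue_bands=DEFAULT_CAP_HUE_BANDS,
                min_saturation: float = 0.25) -> np.ndarray:
    """Binary cap mask.

    With ``segmenter`` given, delegates and validates the returned mask
    against the contract (boolean, frame-shaped).  The fallback marks
    pixels whose hue falls in either cap-pattern hue band and whose
    saturation clears ``min_saturation`` (rejecting gray/black pixels,
    whose hue is meaningless).
    """
    if segmenter is not None:
        mask = np.asarray(segmenter(frame))
        if mask.shape != frame.shape:
            raise ContractViolationError(
                f"segmenter returned shape {mask.shape}, expected {frame.shape}")
        return mask.astype(bool)

    hsv = rgb2hsv(frame.pixels)
    hue, sat = hsv[..., 0], hsv[..., 1]
    mask = np.zeros(frame.shape, dtype=bool)
    for centre, tol in cap_hue_bands:
        mask |= _hue_distance(hue, centre) <= tol
    return mask & (sat >= min_saturation)


def face_polygon(landmarks, shape) -> np.ndarray:
    """Filled convex polygon through the nose, external eye edges and
    forehead landmarks (pixel (row, col) coordinates)."""
    missing = [k for k in _REQUIRED_LANDMARKS if k not in landmarks]
    if missing:
        raise IncompleteLandmarksError(f"missing landmarks: {missing}")
    pts = np.array([np.asarray(landmarks[k], float).reshape(2)
                    for k in _REQUIRED_LANDMARKS])
    centre = pts.mean(axis=0)
    spread = pts - centre
    # convex ordering by angle; degenerate if the polygon has ~zero area
    order = np.argsort(np.arctan2(spread[:, 0], spread[:, 1]))
    poly = pts[order]
    area = 0.5 * abs(np.sum(poly[:, 1] * np.roll(poly[:, 0], -1)
                            - np.roll(poly[:, 1], -1) * poly[:, 0]))
    if area < 0.5:
        raise DegeneratePolygonError(
            "face landmarks are collinear or coincident")
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=shape)
    mask[rr, cc] = True
    return mask


def compose_and_apply(frame: Frame, cap_mask: np.ndarray,
                      face_mask: np.ndarray | None = None,
                      stickers: list[StickerDetection2D] = (),
                      ) -> tuple[Frame, CropMask]:
    """Union the cap mask, face polygon and sticker circles; blacken
    everything outside; report the kept fraction."""
    keep = np.asarray(cap_mask).astype(bool)
    if keep.shape != frame.shape:
        raise ContractViolationError("cap mask size mismatch")
    if face_mask is not None:
        face_mask = np.asarray(face_mask).astype(bool)
        if face_mask.shape != frame.shape:
            raise ContractViolationError("face mask size mismatch")
        keep = keep | face_mask
    else:
        keep = keep.copy()
    for det in stickers:
        rr, cc = draw_disk(det.center_px, det.radius_px, shape=frame.shape)
        keep[rr, cc] = True
    pixels = np.where(keep[..., None], frame.pixels, 0).astype(np.uint8)
    out = Frame(pixels=pixels, frame_index=frame.frame_index,
                timestamp_s=frame.timestamp_s)
    return out, CropMask(mask=keep, kept_fraction=float(keep.mean()))


def reject_frame(mask: CropMask,
                 threshold: float = DEFAULT_REJECT_THRESHOLD) -> bool:
    """True iff strictly more than ``threshold`` of the frame is blackened
    (a frame exactly at the threshold is kept)."""
    if not 0.0 < threshold <= 1.0:
        raise InvalidParameterError("threshold must lie in (0, 1]")
    return (1.0 - mask.kept_fraction) > threshold
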