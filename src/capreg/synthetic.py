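"""Synthetic scenes: ground-truth heads, cap placements, colored point
clouds, patterned cap textures, and rendered frames.

The generator replaces real video recordings so every downstream stage can
be tested against analytic ground truth.  The head is an ellipsoid (the
real reference capture uses a plastic head); the nine fiducials sit at
canonical 10-20-like directions read from a shipped table and projected
onto the ellipsoid surface, so all ground-truth coordinates are available
in closed form.

Axis convention (shared package-wide): +x left-right (subject's right),
+y anterior-posterior (anterior), +z vertical (superior), origin at the
head centre, millimetres.
"""

from __future__ import annotations

import dataclasses
import importlib.resources

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .errors import (
    IncompleteSceneError,
    InvalidCameraError,
    InvalidParameterError,
)
from .geometry import CapTransform, euler_rotation
from .types import (
    CAP_LABELS,
    FIDUCIAL_LABELS,
    ColoredPointCloud,
    Frame,
    GroundTruthScene,
    LabeledFiducialSet,
)

__all__ = [
    "DEFAULT_STICKER_COLOR",
    "DEFAULT_CAP_COLORS",
    "RenderedFrame",
    "canonical_directions",
    "make_model_head",
    "simulate_subject",
    "perlin_pattern",
    "render_frames",
]

#: Saturated green, the sticker colour used on the physical caps.
DEFAULT_STICKER_COLOR = (0, 255, 0)
#: The two cap-pattern colours (red / blue patterned connector sheets).
DEFAULT_CAP_COLORS = ((200, 30, 40), (30, 60, 200))
DEFAULT_BACKGROUND_COLOR = (245, 245, 245)

#: Probes are placed between these fiducial pairs (direction = normalised
#: sum of the two canonical directions, projected onto the ellipsoid).
_PROBE_PAIRS = (
    ("Cz", "FRONT"), ("Cz", "Pz"), ("Cz", "LEFT"), ("Cz", "RIGHT"),
    ("Cz", "Iz"), ("Pz", "Iz"), ("Pz", "LEFT"), ("Pz", "RIGHT"),
    ("FRONT", "LEFT"), ("FRONT", "RIGHT"), ("FRONT", "Nz"), ("Iz", "LEFT"),
)


def sample_cap_misplacement(rng: np.random.Generator,
                            max_twist_deg: float = 30.0,
                            max_tilt_deg: float = 10.0,
                            scale_range=(0.9, 1.1)):
    """Draw one realistic cap-misplacement condition.

    A soft cap's dominant placement error is a twist about the vertical
    axis (up to ``max_twist_deg``); pitch and roll are mechanically
    limited by the cap hugging the head (``max_tilt_deg``).  AP and LR
    scales are uniform over ``scale_range``.  Returns
    ``(rotation_deg_xyz, scale_ap, scale_lr)``.
    """
    rotation = np.array([rng.uniform(-max_tilt_deg, max_tilt_deg),
                         rng.uniform(-max_tilt_deg, max_tilt_deg),
                         rng.uniform(-max_twist_deg, max_twist_deg)])
    scale_ap, scale_lr = rng.uniform(*scale_range, size=2)
    return rotation, float(scale_ap), float(scale_lr)


def canonical_directions() -> dict[str, np.ndarray]:
    """Unit-sphere directions of the nine fiducials (shipped table)."""
    ref = importlib.resources.files("capreg.data") / "canonical_fiducials.csv"
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path)
    out = {}
    for _, row in table.iterrows():
        d = np.array([row["dx"], row["dy"], row["dz"]], dtype=float)
        out[str(row["label"])] = d / np.linalg.norm(d)
    missing = set(FIDUCIAL_LABELS) - set(out)
    if missing:
        raise InvalidParameterError(f"direction table missing {missing}")
    return out


def _ellipsoid_point(direction: np.ndarray, semi_axes: np.ndarray) -> np.ndarray:
    """Surface point of the axis-aligned ellipsoid along ``direction``."""
    d = np.asarray(direction, float)
    scale = np.sqrt(np.sum((d / semi_axes) ** 2, axis=-1, keepdims=True))
    return d / scale


def make_model_head(semi_axes=(80.0, 95.0, 90.0), n_surface_points: int = 2000,
                    seed: int = 0) -> GroundTruthScene:
    """Build the reference ("model cap") scene: an ellipsoidal head with
    nine labelled fiducials and twelve probes on its surface.

    ``semi_axes`` are the (x, y, z) = (LR, AP, vertical) semi-axes in mm.
    Deterministic for a given seed.
    """
    axes = np.asarray(semi_axes, dtype=float)
    if axes.shape != (3,) or np.any(axes <= 0):
        raise InvalidParameterError("semi_axes must be three positive lengths")
    if n_surface_points < 100:
        raise InvalidParameterError("n_surface_points must be >= 100")

    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_surface_points, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    head_vertices = _ellipsoid_point(dirs, axes)

    directions = canonical_directions()
    fiducials = LabeledFiducialSet(
        {lab: _ellipsoid_point(d, axes) for lab, d in directions.items()})

    probes = {}
    for i, (a, b) in enumerate(_PROBE_PAIRS, start=1):
        d = directions[a] + directions[b]
        d /= np.linalg.norm(d)
        probes[f"CH{i:02d}"] = _ellipsoid_point(d, axes)

    return GroundTruthScene(
        head_vertices=head_vertices,
        true_fiducials=fiducials,
        true_probes=probes,
        applied_transform=CapTransform.identity(),
        seed=seed,
        semi_axes=tuple(axes),
    )


def simulate_subject(scene: GroundTruthScene, rotation_deg=(0.0, 0.0, 0.0),
                     scale_ap: float = 1.0, scale_lr: float = 1.0,
                     noise_sd_mm: float = 0.5, points_per_sticker: int = 200,
                     seed: int = 0,
                     sticker_color=DEFAULT_STICKER_COLOR,
                     cap_colors=DEFAULT_CAP_COLORS,
                     ) -> tuple[ColoredPointCloud, GroundTruthScene]:
    """Place the cap on a subject and emit the reconstructed point cloud.

    The cap (its six markers and all probes) rotates rigidly and scales
    along the anterior-posterior and left-right axes about the head
    centre; the three head fiducials stay put.  Every fiducial is emitted
    as a cluster of ``points_per_sticker`` sticker-coloured vertices with
    isotropic Gaussian noise of sd ``noise_sd_mm``; head vertices are
    emitted in the two cap-pattern colours with the same noise.

    Returns the cloud and a new scene carrying the transformed ground
    truth (``applied_transform`` records the cap transform).
    """
    if noise_sd_mm < 0:
        raise InvalidParameterError("noise_sd_mm must be >= 0")
    if points_per_sticker < 5:
        raise InvalidParameterError("points_per_sticker must be >= 5")
    if scale_ap <= 0 or scale_lr <= 0:
        raise InvalidParameterError("scales must be positive")
    if not scene.true_fiducials.is_complete():
        missing = set(FIDUCIAL_LABELS) - set(scene.true_fiducials.labels)
        raise IncompleteSceneError(f"scene lacks fiducials: {sorted(missing)}")

    transform = CapTransform(rotation=euler_rotation(rotation_deg),
                             scale_ap=scale_ap, scale_lr=scale_lr)

    moved = {}
    for label, p in scene.true_fiducials.items():
        moved[label] = transform.apply(p) if label in CAP_LABELS else p.copy()
    true_fiducials = LabeledFiducialSet(moved)
    true_probes = {k: transform.apply(p)
                   for k, p in scene.true_probes.items()}

    rng = np.random.default_rng(seed)
    positions = [scene.head_vertices
                 + rng.normal(scale=noise_sd_mm or 0.0,
                              size=scene.head_vertices.shape)
                 if noise_sd_mm > 0 else scene.head_vertices.copy()]
    pattern = rng.integers(0, 2, size=len(scene.head_vertices))
    colors = [np.where(pattern[:, None] == 0,
                       np.array(cap_colors[0], np.uint8),
                       np.array(cap_colors[1], np.uint8))]
    for label in FIDUCIAL_LABELS:
        centre = true_fiducials[label]
        cluster = np.tile(centre, (points_per_sticker, 1))
        if noise_sd_mm > 0:
            cluster = cluster + rng.normal(scale=noise_sd_mm,
                                           size=cluster.shape)
        positions.append(cluster)
        colors.append(np.tile(np.array(sticker_color, np.uint8),
                              (points_per_sticker, 1)))

    cloud = ColoredPointCloud(positions=np.vstack(positions),
                              colors=np.vstack(colors))
    out_scene = GroundTruthScene(
        head_vertices=scene.head_vertices.copy(),
        true_fiducials=true_fiducials,
        true_probes=true_probes,
        applied_transform=transform,
        seed=seed,
        semi_axes=scene.semi_axes,
    )
    return cloud, out_scene


# ---------------------------------------------------------------------------
# Perlin-style cap pattern


def _gradient_noise(height: int, width: int, cells: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Single octave of 2-D lattice gradient noise on an H x W raster."""
    theta = rng.uniform(0.0, 2 * np.pi, size=(cells + 1, cells + 1))
    grads = np.stack([np.cos(theta), np.sin(theta)], axis=-1)

    ys = (np.arange(height) + 0.5) / height * cells
    xs = (np.arange(width) + 0.5) / width * cells
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    y0 = np.clip(np.floor(gy).astype(int), 0, cells - 1)
    x0 = np.clip(np.floor(gx).astype(int), 0, cells - 1)
    fy = gy - y0
    fx = gx - x0

    def corner_dot(dy, dx):
        g = grads[y0 + dy, x0 + dx]
        return g[..., 0] * (fx - dx) + g[..., 1] * (fy - dy)

    def fade(t):
        return t * t * t * (t * (t * 6 - 15) + 10)

    uy, ux = fade(fy), fade(fx)
    top = corner_dot(0, 0) * (1 - ux) + corner_dot(0, 1) * ux
    bot = corner_dot(1, 0) * (1 - ux) + corner_dot(1, 1) * ux
    return top * (1 - uy) + bot * uy


def perlin_pattern(width_px: int, height_px: int, threshold: float = 0.5,
                   seed: int = 0, colors=DEFAULT_CAP_COLORS,
                   octaves: int = 4, base_cells: int = 8) -> np.ndarray:
    """Two-colour gradient-noise cap pattern.

    Multi-octave gradient noise is min-max normalised to [0, 1] and
    thresholded into the two pattern colours.  Deterministic per seed.
    Returns an (H, W, 3) uint8 image.
    """
    if width_px < 16 or height_px < 16:
        raise InvalidParameterError("pattern dimensions must be >= 16 px")
    if not 0.0 < threshold < 1.0:
        raise InvalidParameterError("threshold must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    field = np.zeros((height_px, width_px))
    amplitude, total = 1.0, 0.0
    for octave in range(octaves):
        cells = base_cells * (2 ** octave)
        field += amplitude * _gradient_noise(height_px, width_px, cells, rng)
        total += amplitude
        amplitude *= 0.5
    field /= total
    lo, hi = field.min(), field.max()
    field = (field - lo) / (hi - lo) if hi > lo else np.full_like(field, 0.5)

    image = np.where(field[..., None] < threshold,
                     np.array(colors[0], np.uint8),
                     np.array(colors[1], np.uint8))
    return image.astype(np.uint8)


# ---------------------------------------------------------------------------
# Frame rendering


@dataclasses.dataclass
class RenderedFrame:
    """A rendered frame plus its ground-truth sticker pixel centres
    (label -> (row, col)) for the fiducials visible from that camera."""

    frame: Frame
    sticker_centers: dict[str, tuple[float, float]]
    camera_position: np.ndarray


def _camera_basis(camera: np.ndarray, look_at: np.ndarray):
    forward = look_at - camera
    norm = np.linalg.norm(forward)
    if norm < 1e-9:
        raise InvalidCameraError("camera coincides with its look-at point")
    forward /= norm
    up = np.array([0.0, 0.0, 1.0])
    if abs(forward @ up) > 0.99:
        up = np.array([0.0, 1.0, 0.0])
    right = np.cross(forward, up)
    right /= np.linalg.norm(right)
    true_up = np.cross(right, forward)
    return right, true_up, forward


def render_frames(scene: GroundTruthScene, camera_positions,
                  image_size: int = 256,
                  sticker_color=DEFAULT_STICKER_COLOR,
                  cap_color=DEFAULT_CAP_COLORS[0],
                  background_color=DEFAULT_BACKGROUND_COLOR,
                  sticker_diameter_mm: float = 10.0,
                  look_at=(0.0, 0.0, 0.0)) -> list[RenderedFrame]:
    """Render simple pinhole-projection frames of the scene.

    Head vertices are splatted as small cap-coloured disks over a light
    background; fiducials facing the camera (radial visibility test on the
    convex head) are drawn last as filled sticker-coloured disks of at
    least 3 px radius.  Cameras must lie outside the head's bounding
    sphere.
    """
    cameras = np.atleast_2d(np.asarray(camera_positions, float))
    if len(cameras) < 1:
        raise InvalidCameraError("need at least one camera")
    look_at = np.asarray(look_at, float).reshape(3)

    all_pts = np.vstack([scene.head_vertices,
                         scene.true_fiducials.as_array()])
    bound = float(np.linalg.norm(all_pts, axis=1).max())
    for cam in cameras:
        if np.linalg.norm(cam) <= bound:
            raise InvalidCameraError(
                f"camera {cam} lies inside the bounding sphere (r={bound:.1f})")

    out = []
    cx = cy = image_size / 2.0
    for idx, cam in enumerate(cameras):
        right, true_up, forward = _camera_basis(cam, look_at)
        dist = float(np.linalg.norm(cam - look_at))
        f_px = 0.35 * image_size * dist / bound

        def project(points):
            rel = np.atleast_2d(points) - cam
            x = rel @ right
            y = rel @ -true_up  # image rows grow downward
            z = rel @ forward
            with np.errstate(divide="ignore", invalid="ignore"):
                col = cx + f_px * x / z
                row = cy + f_px * y / z
            return row, col, z

        pixels = np.tile(np.array(background_color, np.uint8),
                         (image_size, image_size, 1))
        row, col, z = project(scene.head_vertices)
        ok = (z > 0) & np.isfinite(row) & np.isfinite(col)
        splat = max(2, int(round(0.012 * image_size)))
        for r, c in zip(row[ok], col[ok]):
            rr, cc = draw_disk((r, c), splat, shape=pixels.shape[:2])
            pixels[rr, cc] = cap_color

        centers: dict[str, tuple[float, float]] = {}
        for label, p in scene.true_fiducials.items():
            if (p / max(np.linalg.norm(p), 1e-9)) @ (cam - p) <= 0:
                continue  # facing away from this camera
            r, c, zz = project(p)
            r, c, zz = float(r[0]), float(c[0]), float(zz[0])
            if zz <= 0 or not (0 <= r < image_size and 0 <= c < image_size):
                continue
            r_px = max(3.0, f_px * (sticker_diameter_mm / 2.0) / zz)
            rr, cc = draw_disk((r, c), r_px, shape=pixels.shape[:2])
            pixels[rr, cc] = sticker_color
            centers[label] = (r, c)

        out.append(RenderedFrame(
            frame=Frame(pixels=pixels, frame_index=idx,
                        timestamp_s=idx / 240.0),
            sticker_centers=centers,
            camera_position=cam.copy(),
        ))
    return out
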