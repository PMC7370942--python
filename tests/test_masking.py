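"""Frame cropping rules: hue thresholding, minimum enclosing circles,
mask composition, frame rejection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import ConvexHull
from skimage.draw import disk as draw_disk

from capreg.errors import (
    ContractViolationError,
    DegenerateInputError,
    DegeneratePolygonError,
    IncompleteLandmarksError,
    InvalidParameterError,
)
from capreg.masking import (
    compose_and_apply,
    detect_stickers,
    face_polygon,
    reject_frame,
    segment_cap,
    white_balance,
)
from capreg.types import CropMask, Frame

GREEN = (0, 200, 0)          # hue 1/3
GREEN_HUE = 1.0 / 3.0


def blank(h=128, w=128, color=(30, 30, 30)):
    return np.tile(np.array(color, np.uint8), (h, w, 1))


def plant_disk(pixels, center, radius, color=GREEN):
    rr, cc = draw_disk(center, radius, shape=pixels.shape[:2])
    pixels[rr, cc] = color
    return pixels


def brute_force_mec(points):
    """Independent exact minimum enclosing circle: try every circle
    through two (diametral) and three hull points, keep the smallest that
    contains everything."""
    pts = np.asarray(points, float)
    hull = pts[ConvexHull(pts).vertices] if len(pts) > 3 else pts
    best = None
    m = len(hull)

    def covers(c, r):
        return np.all(np.linalg.norm(pts - c, axis=1) <= r + 1e-7)

    for i in range(m):
        for j in range(i + 1, m):
            c = (hull[i] + hull[j]) / 2
            r = np.linalg.norm(hull[i] - c)
            if covers(c, r) and (best is None or r < best[1]):
                best = (c, r)
            for k in range(j + 1, m):
                ax, ay = hull[i]
                bx, by = hull[j]
                cx, cy = hull[k]
                d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
                if abs(d) < 1e-12:
                    continue
                ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
                      + (cx**2 + cy**2) * (ay - by)) / d
                uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
                      + (cx**2 + cy**2) * (bx - ax)) / d
                c = np.array([ux, uy])
                r = np.linalg.norm(hull[i] - c)
                if covers(c, r) and (best is None or r < best[1]):
                    best = (c, r)
    return best


class TestWhiteBalance:
    def test_uniform_gray_unchanged(self):
        f = Frame(blank(color=(120, 120, 120)))
        assert np.array_equal(white_balance(f).pixels, f.pixels)

    def test_channel_means_equalized_gray_world_oracle(self):
        px = blank(64, 64, (100, 50, 25)).astype(float)
        out = white_balance(Frame(px.astype(np.uint8)))
        means = out.pixels.reshape(-1, 3).mean(axis=0)
        # gray-world oracle: all means equal the global gray mean
        gray = (100 + 50 + 25) / 3
        assert np.all(np.abs(means - gray) <= 1.0)

    def test_idempotent_up_to_rounding(self, rng):
        # moderate values so the gains do not clip at 255
        px = rng.integers(20, 120, size=(64, 64, 3)).astype(np.uint8)
        once = white_balance(Frame(px))
        twice = white_balance(once)
        diff = np.abs(once.pixels.astype(int) - twice.pixels.astype(int))
        assert diff.max() <= 1

    def test_all_black_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            white_balance(Frame(blank(color=(0, 0, 0))))


class TestDetectStickers:
    def test_four_pixel_cluster_ignored_five_detected(self):
        px = blank()
        px[10, 10:14] = GREEN            # 4 connected pixels
        assert detect_stickers(Frame(px), GREEN_HUE) == []
        px[10, 14] = GREEN               # now 5
        dets = detect_stickers(Frame(px), GREEN_HUE)
        assert len(dets) == 1 and dets[0].pixel_count == 5

    def test_no_inhue_pixels_empty(self):
        assert detect_stickers(Frame(blank()), GREEN_HUE) == []

    def test_three_planted_disks_against_bruteforce_circle_oracle(self):
        centers = [(30, 30), (30, 90), (90, 60)]
        px = blank(128, 128)
        for c in centers:
            # radius just over 5 so the boundary pixels at distance 5 are
            # part of the raster (skimage's disk is exclusive)
            plant_disk(px, c, 5.01)
        dets = detect_stickers(Frame(px), GREEN_HUE)
        assert len(dets) == 3
        for det, c in zip(dets, sorted(centers)):
            assert np.hypot(det.center_px[0] - c[0],
                            det.center_px[1] - c[1]) <= 1.0
            assert abs(det.radius_px - 1.2 * 5) <= 0.1 * 1.2 * 5
            # exact-circle cross-check on the component's pixels
            comp = np.argwhere(
                (np.abs(px[..., 1].astype(int) - 200) < 10)
                & (np.hypot(*(np.indices(px.shape[:2])
                              - np.array(c)[:, None, None])) < 8))
            mec_c, mec_r = brute_force_mec(comp.astype(float))
            assert np.hypot(det.center_px[0] - mec_c[0],
                            det.center_px[1] - mec_c[1]) < 1e-6
            assert abs(det.radius_px - 1.2 * mec_r) < 1e-6

    @given(dr=st.integers(-15, 15), dc=st.integers(-15, 15))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_translation_equivariance(self, dr, dc):
        base = blank(96, 96)
        plant_disk(base, (48, 48), 5)
        moved = blank(96, 96)
        plant_disk(moved, (48 + dr, 48 + dc), 5)
        d0 = detect_stickers(Frame(base), GREEN_HUE)[0]
        d1 = detect_stickers(Frame(moved), GREEN_HUE)[0]
        assert d1.center_px[0] - d0.center_px[0] == pytest.approx(dr, abs=1e-9)
        assert d1.center_px[1] - d0.center_px[1] == pytest.approx(dc, abs=1e-9)

    def test_hue_comparison_wraps_around(self):
        px = blank()
        plant_disk(px, (50, 50), 5, color=(255, 10, 30))  # hue ~0.986
        dets = detect_stickers(Frame(px), sticker_hue=0.01, hue_tol=0.05)
        assert len(dets) == 1

    def test_invalid_tolerance(self):
        with pytest.raises(InvalidParameterError):
            detect_stickers(Frame(blank()), GREEN_HUE, hue_tol=0.6)


class TestSegmentCap:
    def test_planted_silhouette_recall_precision(self, rng):
        px = blank(128, 128, color=(210, 210, 210))  # gray background
        truth = np.zeros((128, 128), bool)
        truth[30:100, 20:110] = True
        pat = rng.integers(0, 2, size=truth.sum())
        colors = np.where(pat[:, None] == 0, (200, 30, 40), (30, 60, 200))
        px[truth] = colors
        mask = segment_cap(Frame(px))
        tp = (mask & truth).sum()
        assert tp / truth.sum() >= 0.99          # recall
        assert tp / max(mask.sum(), 1) >= 0.99   # precision

    def test_no_cap_hue_gives_empty_mask(self):
        assert not segment_cap(Frame(blank(color=(128, 128, 128)))).any()

    def test_stub_segmenter_passthrough_and_contract(self):
        f = Frame(blank())
        ones = segment_cap(f, segmenter=lambda fr: np.ones(fr.shape, bool))
        assert ones.all()
        with pytest.raises(ContractViolationError):
            segment_cap(f, segmenter=lambda fr: np.ones((4, 4), bool))


class TestFacePolygon:
    def test_square_landmarks_area_matches_analytic(self):
        lm = {"nose": (80, 20), "left_eye_edge": (20, 20),
              "right_eye_edge": (20, 80), "forehead": (80, 80)}
        mask = face_polygon(lm, (128, 128))
        # 60x60 square: allow boundary-pixel slack
        assert abs(mask.sum() - 60 * 60) <= 4 * 60 + 4

    def test_identical_landmarks_degenerate(self):
        lm = {k: (50, 50) for k in
              ("nose", "left_eye_edge", "right_eye_edge", "forehead")}
        with pytest.raises(DegeneratePolygonError):
            face_polygon(lm, (128, 128))

    def test_collinear_landmarks_degenerate(self):
        lm = {"nose": (10, 10), "left_eye_edge": (20, 20),
              "right_eye_edge": (30, 30), "forehead": (40, 40)}
        with pytest.raises(DegeneratePolygonError):
            face_polygon(lm, (128, 128))

    def test_translation_equivariance(self):
        lm = {"nose": (60, 30), "left_eye_edge": (30, 20),
              "right_eye_edge": (30, 60), "forehead": (15, 40)}
        moved = {k: (v[0] + 10, v[1] + 10) for k, v in lm.items()}
        a = face_polygon(lm, (128, 128))
        b = face_polygon(moved, (128, 128))
        assert np.array_equal(np.roll(np.roll(a, 10, 0), 10, 1), b)

    def test_missing_landmark(self):
        with pytest.raises(IncompleteLandmarksError):
            face_polygon({"nose": (1, 1)}, (64, 64))


class TestComposeAndReject:
    def test_all_one_cap_mask_keeps_everything(self):
        f = Frame(blank(color=(77, 99, 111)))
        out, mask = compose_and_apply(f, np.ones(f.shape, bool))
        assert np.array_equal(out.pixels, f.pixels)
        assert mask.kept_fraction == 1.0

    def test_empty_masks_blacken_everything(self):
        f = Frame(blank(color=(77, 99, 111)))
        out, mask = compose_and_apply(f, np.zeros(f.shape, bool))
        assert not out.pixels.any()
        assert mask.kept_fraction == 0.0

    def test_single_sticker_circle_kept_fraction(self):
        f = Frame(blank(128, 128))
        from capreg.types import StickerDetection2D
        det = StickerDetection2D(center_px=(64.0, 64.0), radius_px=1.2 * 10,
                                 pixel_count=300, mean_hue=GREEN_HUE)
        _, mask = compose_and_apply(f, np.zeros(f.shape, bool),
                                    stickers=[det])
        expected = np.pi * (1.2 * 10) ** 2 / (128 * 128)
        # pixelation error of a radius-12 disk is O(perimeter) pixels
        slack = 2 * np.pi * (1.2 * 10 + 1) / (128 * 128)
        assert abs(mask.kept_fraction - expected) <= slack

    def test_never_enlarges_beyond_union(self, rng):
        f = Frame(rng.integers(1, 255, size=(64, 64, 3)).astype(np.uint8))
        cap = rng.random((64, 64)) < 0.3
        face = rng.random((64, 64)) < 0.1
        out, mask = compose_and_apply(f, cap, face)
        nonblack = out.pixels.any(axis=-1)
        assert not (nonblack & ~(cap | face)).any()
        assert np.array_equal(mask.mask, cap | face)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ContractViolationError):
            compose_and_apply(Frame(blank()), np.ones((4, 4), bool))

    @pytest.mark.parametrize("kept,rejected", [
        (0.019, True),   # blackened 0.981 > 0.98
        (0.020, False),  # blackened exactly 0.980: boundary is exclusive
        (1.0, False),
    ])
    def test_rejection_boundary(self, kept, rejected):
        h = w = 100  # 10000 px so fractions are exact hundredths
        mask = np.zeros((h, w), bool)
        mask.ravel()[:int(round(kept * h * w))] = True
        cm = CropMask(mask=mask, kept_fraction=float(mask.mean()))
        assert reject_frame(cm, 0.98) is rejected

    def test_invalid_threshold(self):
        cm = CropMask(mask=np.ones((4, 4), bool), kept_fraction=1.0)
        with pytest.raises(InvalidParameterError):
            reject_frame(cm, 0.0)
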