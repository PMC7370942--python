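"""Fiducial recovery from the colored point cloud.

Two stages: (1) single-linkage clustering of sticker-coloured vertices
yields unlabelled 3-D centroids; (2) a RANSAC-style hypothesis search
assigns the nine fiducial names by matching the centroids against the
model-cap layout.

The labeling search enumerates hypotheses of the form (unordered centroid
triple, ordered model-label triple).  For each hypothesis a closed-form
three-point similarity transform (rotation + uniform scale + translation)
maps the model triple onto the centroid triple; the remaining model
fiducials are pushed through it and scored by the cost of the optimal
one-to-one assignment to the remaining centroids.  The minimum-cost
hypothesis wins; ties break toward the lexicographically smallest label
triple.  All hypotheses are enumerated exhaustively when there are at
most nine centroids; otherwise centroid triples are sampled with a seeded
generator.  A cheap vectorised lower bound (sum of per-point nearest
distances, which can only undershoot the assignment cost) orders the
hypotheses so that exact assignment costs are only evaluated until the
bound exceeds the best cost found — the result equals full enumeration.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage.color import rgb2hsv

from .errors import (
    InsufficientPointsError,
    InvalidParameterError,
    LabelingFailureError,
)
from .geometry import CapTransform, umeyama_batch
from .types import ColoredPointCloud, LabeledFiducialSet, LabelingResult

__all__ = ["extract_fiducial_clusters", "label_fiducials"]

_TIE_EPS = 1e-12


def extract_fiducial_clusters(cloud: ColoredPointCloud, sticker_hue: float,
                              hue_tol: float = 0.15,
                              link_radius_mm: float = 10.0,
                              min_cluster_size: int = 5) -> list[np.ndarray]:
    """Centroids of single-linkage clusters of sticker-coloured vertices.

    Vertices whose hue is within ``hue_tol`` of ``sticker_hue`` are linked
    whenever they are at most ``link_radius_mm`` apart; connected groups
    of at least ``min_cluster_size`` vertices yield one centroid each.
    Centroids are returned sorted by coordinates for determinism.
    """
    if link_radius_mm <= 0:
        raise InvalidParameterError("link_radius_mm must be positive")
    if min_cluster_size < 1:
        raise InvalidParameterError("min_cluster_size must be >= 1")
    if len(cloud) == 0:
        return []

    hsv = rgb2hsv(cloud.colors.reshape(-1, 1, 3)).reshape(-1, 3)
    d = np.abs(hsv[:, 0] - sticker_hue) % 1.0
    in_hue = np.minimum(d, 1.0 - d) <= hue_tol
    pts = cloud.positions[in_hue]
    if len(pts) == 0:
        return []

    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=link_radius_mm, output_type="ndarray")
    n = len(pts)
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                     shape=(n, n))
    _, comp = connected_components(adj, directed=False)

    centroids = []
    for c in range(comp.max() + 1):
        members = pts[comp == c]
        if len(members) >= min_cluster_size:
            centroids.append(members.mean(axis=0))
    centroids.sort(key=lambda p: tuple(p))
    return centroids


def _collinear(triples: np.ndarray, rel_tol: float = 1e-6) -> np.ndarray:
    """Boolean mask of (m, 3, 3) triples that are (nearly) collinear."""
    a = triples[:, 1] - triples[:, 0]
    b = triples[:, 2] - triples[:, 0]
    cross = np.cross(a, b)
    scale = (np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
    return np.linalg.norm(cross, axis=1) <= rel_tol * np.maximum(scale, 1e-12)


def label_fiducials(centroids, model: LabeledFiducialSet,
                    max_iterations: int = 2000,
                    seed: int = 0) -> LabelingResult:
    """Assign the nine fiducial labels to cluster centroids by RANSAC
    against the model-cap layout.

    Requires at least five centroids (the sticker layout's redundancy
    margin).  Returns the labelled fiducials, the residual matching cost,
    the winning similarity transform (model -> centroid space) and the
    number of points used.
    """
    pts = np.asarray([np.asarray(c, float).reshape(3) for c in centroids])
    n = len(pts)
    if n < 5:
        raise InsufficientPointsError(
            f"need at least 5 centroids for labeling, got {n}")
    if len(model) != 9:
        raise InvalidParameterError("model must contain all 9 fiducials")

    labels = tuple(sorted(model.labels))  # lexicographic enumeration order
    model_pts = model.as_array(labels)    # (9, 3)

    lab_triples = np.array(list(permutations(range(9), 3)))  # (504, 3) lex
    all_idx = np.arange(9)
    lab_remaining = np.array([np.setdiff1d(all_idx, t)
                              for t in lab_triples])          # (504, 6)

    if n <= 9:
        cen_triples = np.array(list(combinations(range(n), 3)))
    else:
        rng = np.random.default_rng(seed)
        all_triples = np.array(list(combinations(range(n), 3)))
        take = min(max_iterations, len(all_triples))
        pick = rng.choice(len(all_triples), size=take, replace=False)
        cen_triples = all_triples[np.sort(pick)]

    cen_ok = ~_collinear(pts[cen_triples])
    cen_triples = cen_triples[cen_ok]
    lab_ok = ~_collinear(model_pts[lab_triples])
    lab_triples_v = lab_triples[lab_ok]
    lab_remaining_v = lab_remaining[lab_ok]
    lab_orig_index = np.flatnonzero(lab_ok)
    if len(cen_triples) == 0 or len(lab_triples_v) == 0:
        raise LabelingFailureError("all labeling hypotheses are degenerate")

    C, L = len(cen_triples), len(lab_triples_v)
    n_rem = n - 3
    rem_mask_all = np.ones((C, n), dtype=bool)
    rem_mask_all[np.arange(C)[:, None], cen_triples] = False

    rem_model = model_pts[lab_remaining_v]                    # (L, 6, 3)

    # process centroid triples in blocks to bound peak memory; the
    # branch-and-bound is exact regardless of block size because a
    # hypothesis is only skipped when its lower bound exceeds the best
    # cost found so far (which only decreases).
    block = max(1, int(4_000_000 // (L * max(n_rem, 1))))
    best_cost = np.inf
    best = None  # (key, (R, s, t), c_idx, l_idx, rows, cols)
    for c0 in range(0, C, block):
        cen_blk = cen_triples[c0:c0 + block]
        B = len(cen_blk)
        # hypothesis grid within the block: index m = c * L + l
        src = np.tile(model_pts[lab_triples_v], (B, 1, 1))
        dst = np.repeat(pts[cen_blk], L, axis=0)
        R, s, t = umeyama_batch(src, dst)

        rem_model_full = np.broadcast_to(
            rem_model, (B, L, 6, 3)).reshape(B * L, 6, 3)
        moved = s[:, None, None] * np.einsum(
            "mij,mkj->mki", R, rem_model_full) + t[:, None, :]

        rem_mask = rem_mask_all[c0:c0 + block]
        rem_cen = pts[np.argwhere(rem_mask)[:, 1].reshape(B, n_rem)]
        rem_cen_full = np.repeat(rem_cen, L, axis=0)          # (B*L, n-3, 3)

        dists = np.linalg.norm(
            moved[:, :, None, :] - rem_cen_full[:, None, :, :], axis=-1)
        # lower bound on the assignment cost: per-point nearest neighbours
        # along the side that is fully matched
        if n_rem <= 6:
            bound = dists.min(axis=1).sum(axis=1)
        else:
            bound = dists.min(axis=2).sum(axis=1)

        for m in np.argsort(bound, kind="stable"):
            if bound[m] > best_cost + _TIE_EPS:
                break
            rows, cols = linear_sum_assignment(dists[m])
            cost = float(dists[m][rows, cols].sum())
            c_idx, l_idx = divmod(int(m), L)
            c_idx += c0
            key = (cost, int(lab_orig_index[l_idx]), c_idx)
            if best is None or cost < best_cost - _TIE_EPS or (
                    abs(cost - best_cost) <= _TIE_EPS and key < best[0]):
                best_cost = cost
                best = (key, (R[m], float(s[m]), t[m]),
                        c_idx, l_idx, rows, cols)

    if best is None:
        raise LabelingFailureError("no valid labeling hypothesis")

    _, (R_b, s_b, t_b), c_idx, l_idx, rows, cols = best
    assignment: dict[str, np.ndarray] = {}
    for k in range(3):
        assignment[labels[lab_triples_v[l_idx][k]]] = pts[cen_triples[c_idx][k]]
    rem_cen_idx = np.flatnonzero(rem_mask_all[c_idx])
    for r_i, c_i in zip(rows, cols):
        lab = labels[lab_remaining_v[l_idx][r_i]]
        assignment[lab] = pts[rem_cen_idx[c_i]]

    transform = CapTransform(rotation=R_b, scale_ap=s_b,
                             scale_lr=s_b, scale_vert=s_b,
                             translation=t_b)
    return LabelingResult(
        fiducials=LabeledFiducialSet(assignment),
        fit_cost_mm=best_cost,
        transform=transform,
        n_points_used=3 + len(rows),
    )
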