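"""Cap-to-head registration and MNI channel projection.

The pre-registration step expresses every probe p_j of the model cap as a
sum-to-one weighted combination of the nine fiducials f_i,

    p_j = sum_i w_ij f_i,   sum_i w_ij = 1,

solved per probe as the minimum-norm solution of the underdetermined
4-equation system (three coordinates plus the sum constraint) in nine
unknowns.  Because the rows sum to one, the interpolation commutes with
any affine map of the fiducials — so projecting the subject's fiducials
into MNI space and applying the same weights yields the channel positions
in MNI space directly.

The head-to-MNI transform is fit on the four head-anchored fiducials
(Nz, AL, AR and Cz — Cz is a cap marker placed at the correct scalp
position) as a rotation + translation + independent anterior-posterior
and left-right scales; the vertical scale stays fixed at 1 unless freed.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateModelError,
    IncompleteModelError,
    InsufficientFiducialsError,
    InvalidParameterError,
    MissingFiducialError,
)
from .geometry import CapTransform, umeyama
from .types import (
    FIDUCIAL_LABELS,
    REGISTRATION_LABELS,
    LabeledFiducialSet,
    ModelCap,
    SessionMeasurement,
)

__all__ = [
    "register_model_cap",
    "fit_head_transform",
    "project_channels",
    "solve_barycentric_weights",
]

_MIN_FIDUCIALS = 5  # five cap+head points suffice; six carried for redundancy


def solve_barycentric_weights(fiducials: np.ndarray,
                              probes: np.ndarray) -> np.ndarray:
    """Minimum-norm sum-to-one weights expressing each probe as a
    combination of the fiducials.

    fiducials: (k, 3); probes: (p, 3).  Returns (p, k) weight rows.
    Raises if the fiducial configuration is affinely degenerate (the
    system loses rank and cannot pin down three coordinates).
    """
    F = np.asarray(fiducials, float)
    P = np.atleast_2d(np.asarray(probes, float))
    k = len(F)
    A = np.vstack([F.T, np.ones((1, k))])            # (4, k)
    if np.linalg.matrix_rank(A, tol=1e-8) < 4:
        raise DegenerateModelError(
            "fiducial configuration is affinely degenerate (coplanar in a "
            "lower-dimensional sense); cannot solve barycentric weights")
    B = np.vstack([P.T, np.ones((1, len(P)))])       # (4, p)
    W, *_ = np.linalg.lstsq(A, B, rcond=None)        # min-norm solution
    W = W.T                                          # (p, k)
    resid = W @ F - P
    max_resid = float(np.abs(resid).max()) if resid.size else 0.0
    if max_resid > 1e-6:
        raise DegenerateModelError(
            f"weight solve residual {max_resid:.2e} mm exceeds 1e-6")
    return W


def register_model_cap(fiducials: LabeledFiducialSet,
                       probes: dict[str, np.ndarray]) -> ModelCap:
    """Build the reference ModelCap: solve the barycentric weight row of
    every probe against the full nine-fiducial set."""
    if not fiducials.is_complete():
        missing = set(FIDUCIAL_LABELS) - set(fiducials.labels)
        raise IncompleteModelError(
            f"model cap needs all 9 fiducials; missing {sorted(missing)}")
    if not probes:
        raise InvalidParameterError("model cap needs at least one probe")

    order = FIDUCIAL_LABELS
    F = fiducials.as_array(order)
    probe_ids = tuple(sorted(probes))
    P = np.array([np.asarray(probes[i], float).reshape(3)
                  for i in probe_ids])
    W = solve_barycentric_weights(F, P)
    return ModelCap(fiducials=fiducials,
                    probes={i: P[j] for j, i in enumerate(probe_ids)},
                    weights=W, probe_ids=probe_ids, fiducial_order=order)


def _pack_transform(params, free_vertical):
    rotvec = params[:3]
    s_lr, s_ap = np.exp(params[3]), np.exp(params[4])
    if free_vertical:
        s_vert = np.exp(params[5])
        t = params[6:9]
    else:
        s_vert = 1.0
        t = params[5:8]
    R = Rotation.from_rotvec(rotvec).as_matrix()
    return CapTransform(rotation=R, scale_ap=s_ap, scale_lr=s_lr,
                        scale_vert=s_vert, translation=t)


def fit_head_transform(subject_head: LabeledFiducialSet,
                       reference_mni: LabeledFiducialSet,
                       free_vertical: bool = False) -> CapTransform:
    """Least-squares rotation + translation + AP/LR scaling mapping the
    subject's head fiducials (Nz, AL, AR, Cz) onto their MNI reference.

    The vertical scale is fixed at 1 unless ``free_vertical``.  The
    returned transform carries the RMS fit residual in ``residual_mm``.
    """
    for fs, name in ((subject_head, "subject"), (reference_mni, "reference")):
        missing = [l for l in REGISTRATION_LABELS if l not in fs]
        if missing:
            raise MissingFiducialError(
                f"{name} set lacks registration fiducials {missing}")

    X = subject_head.as_array(REGISTRATION_LABELS)
    Y = reference_mni.as_array(REGISTRATION_LABELS)

    # initialise from the closed-form similarity fit
    R0, s0, t0 = umeyama(X, Y)
    x0 = np.concatenate([
        Rotation.from_matrix(R0).as_rotvec(),
        [np.log(s0), np.log(s0)],
        [np.log(s0)] if free_vertical else [],
        t0,
    ])

    def residuals(params):
        return (_pack_transform(params, free_vertical).apply(X) - Y).ravel()

    sol = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15,
                        gtol=1e-15, max_nfev=2000)
    transform = _pack_transform(sol.x, free_vertical)
    rms = float(np.sqrt(np.mean(np.sum(
        (transform.apply(X) - Y) ** 2, axis=1))))
    return CapTransform(rotation=transform.rotation,
                        scale_ap=transform.scale_ap,
                        scale_lr=transform.scale_lr,
                        scale_vert=transform.scale_vert,
                        translation=transform.translation,
                        residual_mm=rms)


def project_channels(model: ModelCap,
                     subject_fiducials: LabeledFiducialSet,
                     head_transform: CapTransform,
                     method: str = "video",
                     session_id: str = "session-1") -> SessionMeasurement:
    """Interpolate channel positions in MNI space.

    Subject fiducials are mapped through ``head_transform`` and the model
    cap's barycentric weight rows are applied.  When some of the nine
    fiducials were not recovered (at least five must be), the weights are
    re-solved on the available subset of the *model* fiducials, which
    preserves the sum-to-one (affine-equivariance) property.
    """
    available = [l for l in model.fiducial_order if l in subject_fiducials]
    if len(available) < _MIN_FIDUCIALS:
        raise InsufficientFiducialsError(
            f"need at least {_MIN_FIDUCIALS} fiducials, got {len(available)}")

    if len(available) == len(model.fiducial_order):
        W = model.weights
    else:
        F_model = model.fiducials.as_array(available)
        P = np.array([model.probes[i] for i in model.probe_ids])
        W = solve_barycentric_weights(F_model, P)

    F_mni = head_transform.apply(subject_fiducials.as_array(available))
    channels = W @ F_mni
    return SessionMeasurement(
        method=method, session_id=session_id,
        channel_positions={cid: channels[j]
                           for j, cid in enumerate(model.probe_ids)})
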