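"""Validity / reliability analytics over per-channel session measurements.

All quantities are geometric (Euclidean distances, shift vectors, angles
between shifts), so they are invariant under a common rigid transform of
every measurement.  Summaries follow the mean ± SD over subjects
convention (channel values are averaged within a subject first).

The shift-size regression pools channels and fits ordinary least squares
(method B's shift sizes on method A's) with the slope's F test on
(1, n-2) degrees of freedom; this replaces a subject-level mixed-effects
model, a simplification noted in every report the package writes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .errors import (
    DegenerateRegressionError,
    DegenerateTestError,
    DomainError,
    InsufficientDataError,
    NoOverlapError,
)
from .types import SessionMeasurement

__all__ = [
    "ChannelDistanceReport",
    "ShiftPair",
    "channel_distances",
    "distance_summary",
    "shift_analysis",
    "ks_uniform_test",
    "paired_t_test",
    "shift_size_regression",
]

OLS_NOTE = ("shift-size association fitted by pooled OLS with an F test of "
            "the slope on (1, n-2) df (no subject-level random effects)")


@dataclasses.dataclass
class ChannelDistanceReport:
    """Per-channel distances between two measurements plus the
    subject-level summary (grand mean = mean of per-subject means)."""

    per_channel_mm: dict[str, float]
    per_subject_mean_mm: list[float]
    grand_mean_mm: float
    grand_sd_mm: float
    missing_in_a: tuple[str, ...] = ()
    missing_in_b: tuple[str, ...] = ()


@dataclasses.dataclass
class ShiftPair:
    """Between-session shift of one channel under two methods and the
    spatial angle between the two shift vectors (None when either shift
    has zero length, in which case the angle is undefined)."""

    channel: str
    shift_a: np.ndarray
    shift_b: np.ndarray
    angle_deg: float | None

    @property
    def size_a_mm(self) -> float:
        return float(np.linalg.norm(self.shift_a))

    @property
    def size_b_mm(self) -> float:
        return float(np.linalg.norm(self.shift_b))


def _shared_channels(*measurements: SessionMeasurement) -> list[str]:
    sets = [set(m.channel_positions) for m in measurements]
    shared = sorted(set.intersection(*sets))
    if not shared:
        raise NoOverlapError("measurements share no channel ids")
    return shared


def channel_distances(a: SessionMeasurement,
                      b: SessionMeasurement) -> ChannelDistanceReport:
    """Euclidean distance between the two estimates of every shared
    channel.  Channels present on only one side are reported separately,
    never silently dropped."""
    shared = _shared_channels(a, b)
    da = a.as_array(shared)
    db = b.as_array(shared)
    dist = np.linalg.norm(da - db, axis=1)
    per_channel = {c: float(d) for c, d in zip(shared, dist)}
    mean = float(dist.mean())
    return ChannelDistanceReport(
        per_channel_mm=per_channel,
        per_subject_mean_mm=[mean],
        grand_mean_mm=mean,
        grand_sd_mm=float("nan"),
        missing_in_a=tuple(sorted(set(b.channel_positions)
                                  - set(a.channel_positions))),
        missing_in_b=tuple(sorted(set(a.channel_positions)
                                  - set(b.channel_positions))),
    )


def distance_summary(pairs) -> ChannelDistanceReport:
    """Aggregate per-subject measurement pairs into one report.

    ``pairs`` is a sequence of (a, b) SessionMeasurement tuples, one per
    subject.  The grand mean is the mean of per-subject mean distances;
    the grand SD is the SD (ddof=1) across subjects.
    """
    reports = [channel_distances(a, b) for a, b in pairs]
    subject_means = [r.grand_mean_mm for r in reports]
    per_channel: dict[str, float] = {}
    for i, r in enumerate(reports):
        for c, d in r.per_channel_mm.items():
            per_channel[f"s{i + 1}:{c}"] = d
    return ChannelDistanceReport(
        per_channel_mm=per_channel,
        per_subject_mean_mm=subject_means,
        grand_mean_mm=float(np.mean(subject_means)),
        grand_sd_mm=float(np.std(subject_means, ddof=1))
        if len(subject_means) > 1 else float("nan"),
        missing_in_a=tuple(m for r in reports for m in r.missing_in_a),
        missing_in_b=tuple(m for r in reports for m in r.missing_in_b),
    )


def shift_analysis(method_a: tuple[SessionMeasurement, SessionMeasurement],
                   method_b: tuple[SessionMeasurement, SessionMeasurement],
                   ) -> list[ShiftPair]:
    """Per-channel between-session shift vectors under each method and
    the spatial angle between them (degrees in [0, 180])."""
    a1, a2 = method_a
    b1, b2 = method_b
    shared = _shared_channels(a1, a2, b1, b2)
    sa = a2.as_array(shared) - a1.as_array(shared)
    sb = b2.as_array(shared) - b1.as_array(shared)
    na = np.linalg.norm(sa, axis=1)
    nb = np.linalg.norm(sb, axis=1)
    out = []
    for i, c in enumerate(shared):
        if na[i] > 0 and nb[i] > 0:
            cosine = np.clip(sa[i] @ sb[i] / (na[i] * nb[i]), -1.0, 1.0)
            angle = float(np.degrees(np.arccos(cosine)))
        else:
            angle = None
        out.append(ShiftPair(channel=c, shift_a=sa[i], shift_b=sb[i],
                             angle_deg=angle))
    return out


def ks_uniform_test(angles_deg) -> tuple[float, float]:
    """One-sample Kolmogorov–Smirnov statistic of the angle sample
    against the uniform distribution on [0, 180]; p-value from the
    asymptotic KS distribution."""
    x = np.asarray(angles_deg, float)
    if x.size < 1:
        raise InsufficientDataError("need at least one angle")
    if np.any((x < 0) | (x > 180)):
        raise DomainError("angles must lie in [0, 180] degrees")
    res = sps.kstest(x, sps.uniform(loc=0, scale=180).cdf, mode="asymp")
    return float(res.statistic), float(res.pvalue)


def paired_t_test(x, y) -> tuple[float, int, float]:
    """Two-sided paired t test: t = mean(d) / (sd(d)/sqrt(n)) with
    d = x - y and df = n - 1."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise InsufficientDataError("samples must have equal length")
    n = x.size
    if n < 2:
        raise InsufficientDataError("paired t test needs n >= 2")
    d = x - y
    if np.ptp(d) == 0:
        raise DegenerateTestError(
            "differences are all identical; t is undefined")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), n - 1, float(res.pvalue)


def shift_size_regression(sizes_a, sizes_b):
    """OLS of method-B shift sizes on method-A shift sizes.

    Returns (slope, intercept, F, (1, n-2), p) where F tests the slope.
    """
    a = np.asarray(sizes_a, float)
    b = np.asarray(sizes_b, float)
    if a.shape != b.shape or a.size < 3:
        raise InsufficientDataError(
            "regression needs equal-length samples with n >= 3")
    if np.ptp(a) == 0:
        raise DegenerateRegressionError("predictor has zero variance")
    with np.errstate(divide="ignore", invalid="ignore"):
        fit = sm.OLS(b, sm.add_constant(a)).fit()
    intercept, slope = fit.params
    return (float(slope), float(intercept), float(fit.fvalue),
            (1, a.size - 2), float(fit.f_pvalue))
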