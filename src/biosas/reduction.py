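"""Frame reduction: azimuthal integration, diode-weighted averaging,
2D subtraction and uncertainty propagation.

Time-averaging of frames and azimuthal integration do not commute when
frames are normalized individually: the plain mean of normalized curves
differs from integrating the monitor-weighted average of the raw frames
whenever monitors are unequal.  Averaging here is therefore always the
ratio of sums, sum_k F_k / sum_k d_k, never the mean of per-frame ratios,
and :func:`weighted_average_curves` provides the 1D weighting that
reproduces the 2D route exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sas_model import FrameStack, Geometry, ScatteringCurve

__all__ = [
    "AveragedFrame",
    "azimuthal_integrate",
    "integrate_frame",
    "average_frames",
    "subtract_frames",
    "weighted_average_curves",
    "sigma_weighted_average_curves",
]


@dataclass(frozen=True)
class AveragedFrame:
    """A monitor-normalized averaged 2D frame with per-pixel variance."""

    values: np.ndarray        # counts per unit monitor
    variance: np.ndarray
    geometry: Geometry
    total_monitor: float
    n_frames_used: int
    accepted_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if np.any(self.variance < 0):
            raise ValueError("variance must be non-negative")
        if self.n_frames_used != len(self.accepted_ids) or self.n_frames_used < 1:
            raise ValueError("n_frames_used must equal len(accepted_ids) >= 1")


def azimuthal_integrate(frame_values: np.ndarray,
                        variance: np.ndarray | None,
                        geometry: Geometry,
                        n_bins: int = 200) -> ScatteringCurve:
    """Azimuthally integrate a 2D frame into a 1D curve.

    Pixels are grouped into equal-width q bins spanning [0, q_corner];
    each bin reports the arithmetic mean of its pixel values and
    sigma = sqrt(sum variance) / N_pixels.  Empty bins are dropped so the
    output grid is always strictly increasing (downstream CorMap requires
    exact grid matches, which NaN-filled bins would break).
    """
    qmap = geometry.q_map()
    mask = geometry.mask if geometry.mask is not None else np.zeros(geometry.shape, bool)
    valid = ~mask
    if not np.any(valid):
        raise ValueError("all pixels masked; nothing to integrate")
    q_corner = float(qmap.max())
    edges = np.linspace(0.0, q_corner, n_bins + 1)
    idx = np.clip(np.digitize(qmap[valid], edges) - 1, 0, n_bins - 1)
    values = np.asarray(frame_values, dtype=float)[valid]
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=values, minlength=n_bins)
    nonempty = counts > 0
    if not np.any(nonempty):
        raise ValueError("all q bins empty")
    centers = 0.5 * (edges[:-1] + edges[1:])
    I = sums[nonempty] / counts[nonempty]
    sigma = None
    if variance is not None:
        var = np.asarray(variance, dtype=float)[valid]
        var_sums = np.bincount(idx, weights=var, minlength=n_bins)
        # +1 variance floor on zero-count bins avoids sigma = 0 artifacts
        var_sums = np.where((var_sums == 0) & nonempty, 1.0, var_sums)
        sigma = np.sqrt(var_sums[nonempty]) / counts[nonempty]
    return ScatteringCurve(centers[nonempty], I, sigma)


def integrate_frame(stack: FrameStack, k: int, n_bins: int = 200) -> ScatteringCurve:
    """Integrate a single frame of a stack, normalized by its monitor.

    Per-pixel variance is the Poisson estimate Var[F] = F, propagated
    through the monitor normalization.
    """
    F = np.asarray(stack.frames[k], dtype=float)
    d = stack.monitor[k]
    return azimuthal_integrate(F / d, F / d**2, stack.geometry, n_bins)


def average_frames(stack: FrameStack, accepted_ids: Sequence[int]) -> AveragedFrame:
    """Diode-weighted pixel-wise average of the accepted frames.

    values = sum_k F_k / sum_k d_k and, with Poisson statistics
    (Var[F] = E[F]), variance = sum_k F_k / (sum_k d_k)^2.  This is the
    ratio of sums — NOT the mean of per-frame ratios — which is what
    weighting by the beam-stop diode intensity means.
    """
    ids = list(accepted_ids)
    if not ids:
        raise ValueError("accepted_ids must be non-empty")
    sel = np.asarray(ids, dtype=int)
    d = stack.monitor[sel]
    if np.any(d <= 0):
        raise ValueError("monitor must be positive")
    F_sum = np.asarray(stack.frames[sel], dtype=float).sum(axis=0)
    d_sum = float(d.sum())
    return AveragedFrame(
        values=F_sum / d_sum,
        variance=F_sum / d_sum**2,
        geometry=stack.geometry,
        total_monitor=d_sum,
        n_frames_used=len(ids),
        accepted_ids=tuple(int(i) for i in ids),
    )


def subtract_frames(sample_avg: AveragedFrame, buffer_avg: AveragedFrame) -> AveragedFrame:
    """Pixel-wise subtraction of averaged frames; variances add."""
    if sample_avg.values.shape != buffer_avg.values.shape:
        raise ValueError("frame shapes differ")
    return AveragedFrame(
        values=sample_avg.values - buffer_avg.values,
        variance=sample_avg.variance + buffer_avg.variance,
        geometry=sample_avg.geometry,
        total_monitor=sample_avg.total_monitor,
        n_frames_used=sample_avg.n_frames_used,
        accepted_ids=sample_avg.accepted_ids,
    )


def _common_grid(curves: Sequence[ScatteringCurve]) -> np.ndarray:
    q = curves[0].q
    for c in curves[1:]:
        if c.q.shape != q.shape or not np.array_equal(c.q, q):
            raise ValueError("curves must share an identical q grid")
    return q


def weighted_average_curves(curves: Sequence[ScatteringCurve],
                            monitors: Sequence[float]) -> ScatteringCurve:
    """Monitor-weighted average of normalized 1D curves.

    I = sum_k d_k I_k / sum_k d_k and sigma^2 = sum d_k^2 sigma_k^2 /
    (sum d_k)^2.  On curves integrated from raw frames this reproduces
    the 2D average-then-integrate route exactly; a plain mean does not
    when monitors are unequal.
    """
    if len(curves) == 0:
        raise ValueError("need at least one curve")
    d = np.asarray(monitors, dtype=float)
    if d.shape != (len(curves),) or np.any(d <= 0):
        raise ValueError("need one positive monitor per curve")
    q = _common_grid(curves)
    I_mat = np.vstack([c.I for c in curves])
    d_sum = d.sum()
    I = (d[:, None] * I_mat).sum(axis=0) / d_sum
    sigma = None
    if all(c.sigma is not None for c in curves):
        s_mat = np.vstack([c.sigma for c in curves])
        sigma = np.sqrt((d[:, None] ** 2 * s_mat**2).sum(axis=0)) / d_sum
    return ScatteringCurve(q, I, sigma)


def sigma_weighted_average_curves(curves: Sequence[ScatteringCurve]) -> ScatteringCurve:
    """Inverse-variance weighted average of curves on a common grid.

    Used by the SEC-SAXS pipeline, where averaging is done on integrated
    curves with their azimuthal-integration uncertainties; this 1D route
    is an approximation of the exact 2D averaging.
    """
    if len(curves) < 1:
        raise ValueError("need at least one curve")
    q = _common_grid(curves)
    if any(c.sigma is None for c in curves):
        raise ValueError("sigma-weighted averaging requires uncertainties")
    I_mat = np.vstack([c.I for c in curves])
    s_mat = np.vstack([c.sigma for c in curves])
    w = 1.0 / np.clip(s_mat, 1e-300, None) ** 2
    w_sum = w.sum(axis=0)
    I = (w * I_mat).sum(axis=0) / w_sum
    sigma = np.sqrt(1.0 / w_sum)
    return ScatteringCurve(q, I, sigma)
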