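"""Guinier-region analysis: radius of gyration and forward intensity.

At low q the scattering of a monodisperse particle follows
``ln I(q) = ln I0 - (q Rg)^2 / 3``, valid roughly for q*Rg < 1.3.  Three
estimators are provided:

* :func:`auto_guinier` — exhaustive window search scored by fit quality,
  window length and low-q coverage (in the spirit of BioXTAS-RAW).
* :func:`auto_rg_consensus` — fits all admissible windows and returns the
  inverse-variance-weighted mean of the largest consistent cluster,
  trading the single best window for robustness.
* :func:`auto_gpa` — Guinier-peak analysis: a nonlinear fit of
  ``q I0 exp(-q^2 Rg^2/3)`` around the peak of q*I(q), fast enough for
  chromatography mode where thousands of curves are analysed.

All three agree exactly on data of pure Guinier form; on real curves they
differ slightly, as any two implementations of this problem do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .sas_model import ScatteringCurve

__all__ = [
    "GuinierResult",
    "fit_guinier_window",
    "auto_guinier",
    "auto_rg_consensus",
    "auto_gpa",
    "MIN_WINDOW",
    "QMAX_RG_LIMIT",
    "QMIN_RG_LIMIT",
]

#: minimum number of points in a Guinier window
MIN_WINDOW = 10
#: upper validity bound of the Guinier approximation
QMAX_RG_LIMIT = 1.3
#: admissibility bound on the window start (guards against beam-stop shadow
#: and aggregation upturns at the very lowest q)
QMIN_RG_LIMIT = 1.0
#: a window must span a measurable decay (ln I drop of ~0.08) to count as
#: a Guinier region at all; rejects flat or featureless curves
QMAX_RG_FLOOR = 0.5

#: composite score weights for auto_guinier (fit R^2, window length
#: fraction, bonus for reaching low q)
SCORE_WEIGHTS = (0.6, 0.3, 0.1)


class GuinierError(ValueError):
    """No admissible Guinier region or degenerate input."""


@dataclass(frozen=True)
class GuinierResult:
    Rg: float                 # nm
    sigma_Rg: float
    I0: float
    sigma_I0: float
    window: tuple[int, int]   # half-open index range into the input curve
    qmin_Rg: float
    qmax_Rg: float
    quality: float            # [0, 1]
    aggregated: bool = False  # True when the low-q behaviour is inconsistent
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid:
            if not (self.Rg > 0):
                raise ValueError("valid result requires Rg > 0")
            if self.window[1] - self.window[0] < 3:
                raise ValueError("window too short")


def _weights(curve: ScatteringCurve, idx: np.ndarray) -> np.ndarray:
    """Regression weights for ln(I): w = (I/sigma)^2 by the delta method."""
    if curve.sigma is None:
        return np.ones(idx.size)
    s = curve.sigma[idx]
    w = np.where(s > 0, (curve.I[idx] / np.where(s > 0, s, 1.0)) ** 2, 0.0)
    if not np.any(w > 0):
        return np.ones(idx.size)
    return w


def fit_guinier_window(curve: ScatteringCurve, window: tuple[int, int]) -> GuinierResult:
    """Weighted linear fit of ln I vs q^2 on the given half-open window.

    Points with I <= 0 are excluded; at least 3 must remain.  A
    non-negative slope cannot be a Guinier region and yields a flagged
    (aggregated/invalid) result instead of silent NaNs.
    """
    start, end = int(window[0]), int(window[1])
    idx = np.arange(start, end)
    if idx.size < 3:
        raise GuinierError("window must contain at least 3 points")
    idx = idx[curve.I[idx] > 0]
    if idx.size < 3:
        raise GuinierError("fewer than 3 points with I > 0 in window")
    x = curve.q[idx] ** 2
    y = np.log(curve.I[idx])
    w = _weights(curve, idx)

    Sw = np.sum(w)
    Swx = np.sum(w * x)
    Swy = np.sum(w * y)
    Swxx = np.sum(w * x * x)
    Swxy = np.sum(w * x * y)
    det = Sw * Swxx - Swx**2
    if det <= 0:
        raise GuinierError("degenerate q grid in window")
    slope = (Sw * Swxy - Swx * Swy) / det
    intercept = (Swy - slope * Swx) / Sw
    var_slope = Sw / det
    var_intercept = Swxx / det

    I0 = float(np.exp(intercept))
    if slope >= 0:
        return GuinierResult(
            Rg=float("nan"), sigma_Rg=float("nan"), I0=I0,
            sigma_I0=I0 * float(np.sqrt(var_intercept)),
            window=(start, end), qmin_Rg=float("nan"), qmax_Rg=float("nan"),
            quality=0.0, aggregated=True, valid=False,
        )
    Rg = float(np.sqrt(-3.0 * slope))
    sigma_Rg = float(np.sqrt(var_slope) * 3.0 / (2.0 * Rg))
    resid = y - intercept - slope * x
    ss_res = float(np.sum(w * resid**2))
    ybar = Swy / Sw
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return GuinierResult(
        Rg=Rg, sigma_Rg=sigma_Rg, I0=I0,
        sigma_I0=I0 * float(np.sqrt(var_intercept)),
        window=(start, end),
        qmin_Rg=float(curve.q[idx[0]] * Rg),
        qmax_Rg=float(curve.q[idx[-1]] * Rg),
        quality=float(np.clip(r2, 0.0, 1.0)),
    )


def _low_q_extent(curve: ScatteringCurve, min_window: int) -> int:
    """Index bound of the candidate low-q region (q*Rg_rough <~ 1.5)."""
    n = len(curve)
    pilot_end = max(2 * min_window, n // 10)
    try:
        pilot = fit_guinier_window(curve, (0, min(pilot_end, n)))
        if pilot.valid:
            n_low = int(np.searchsorted(curve.q, 1.5 / pilot.Rg, side="right"))
            return int(np.clip(n_low, 3 * min_window, n))
    except GuinierError:
        pass
    return min(n, 400)


def _scan_windows(curve: ScatteringCurve, min_window: int = MIN_WINDOW):
    """Fit every candidate window via prefix sums; return admissible fits.

    Returns (starts, ends, Rg, var_Rg, I0, r2) for windows satisfying:
    length >= min_window, all I > 0, negative slope, qmax*Rg <= 1.3 and
    qmin*Rg < 1.0 with the window's own (self-consistent) Rg.
    """
    n_low = _low_q_extent(curve, min_window)
    q = curve.q[:n_low]
    I = curve.I[:n_low]
    good = I > 0
    x = np.where(good, q**2, 0.0)
    y = np.where(good, np.log(np.where(good, I, 1.0)), 0.0)
    if curve.sigma is not None:
        s = curve.sigma[:n_low]
        w = np.where(good & (s > 0), (I / np.where(s > 0, s, 1.0)) ** 2, 0.0)
    else:
        w = good.astype(float)

    def ps(a):
        return np.concatenate(([0.0], np.cumsum(a)))

    Pw, Pwx, Pwy = ps(w), ps(w * x), ps(w * y)
    Pwxx, Pwxy, Pwyy = ps(w * x * x), ps(w * x * y), ps(w * y * y)
    Pbad = np.concatenate(([0], np.cumsum(~good)))

    starts_all, lengths = [], []
    i_idx, j_idx = np.meshgrid(np.arange(n_low + 1), np.arange(n_low + 1), indexing="ij")
    mask = (j_idx - i_idx) >= min_window
    i, j = i_idx[mask], j_idx[mask]
    bad = (Pbad[j] - Pbad[i]) > 0
    i, j = i[~bad], j[~bad]
    if i.size == 0:
        return (np.empty(0, int),) * 2 + (np.empty(0),) * 4

    Sw = Pw[j] - Pw[i]
    Swx = Pwx[j] - Pwx[i]
    Swy = Pwy[j] - Pwy[i]
    Swxx = Pwxx[j] - Pwxx[i]
    Swxy = Pwxy[j] - Pwxy[i]
    Swyy = Pwyy[j] - Pwyy[i]
    det = Sw * Swxx - Swx**2
    ok = det > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(ok, (Sw * Swxy - Swx * Swy) / det, np.nan)
        var_slope = np.where(ok, Sw / det, np.nan)
    ok &= slope < 0
    Rg = np.sqrt(np.where(ok, -3.0 * slope, np.nan))
    qmin = q[np.clip(i, 0, n_low - 1)]
    qmax = q[np.clip(j - 1, 0, n_low - 1)]
    ok &= (qmax * Rg <= QMAX_RG_LIMIT) & (qmin * Rg < QMIN_RG_LIMIT)
    ok &= qmax * Rg >= QMAX_RG_FLOOR
    if curve.sigma is not None:
        # with real uncertainties, demand a significantly negative slope
        # (rejects spurious "regions" fitted on background-subtracted noise)
        with np.errstate(invalid="ignore"):
            ok &= -slope >= 2.0 * np.sqrt(var_slope)
    if not np.any(ok):
        return (np.empty(0, int),) * 2 + (np.empty(0),) * 4
    i, j = i[ok], j[ok]
    Sw, Swx, Swy, Swxx, Swxy, Swyy = (a[ok] for a in (Sw, Swx, Swy, Swxx, Swxy, Swyy))
    slope, var_slope, Rg = slope[ok], var_slope[ok], Rg[ok]
    intercept = (Swy - slope * Swx) / Sw
    I0 = np.exp(intercept)
    # weighted R^2 from the sufficient statistics
    ss_res = (Swyy + slope**2 * Swxx + intercept**2 * Sw
              + 2 * slope * intercept * Swx - 2 * slope * Swxy - 2 * intercept * Swy)
    ss_tot = Swyy - Swy**2 / Sw
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    var_Rg = var_slope * (3.0 / (2.0 * Rg)) ** 2
    return i, j, Rg, var_Rg, I0, np.clip(r2, 0.0, 1.0)


def auto_guinier(curve: ScatteringCurve, min_window: int = MIN_WINDOW) -> GuinierResult:
    """Exhaustive Guinier-window search.

    Every window of at least ``min_window`` points whose self-consistent
    fit satisfies qmax*Rg <= 1.3 and qmin*Rg < 1.0 is scored by a fixed
    composite (R^2: 0.6, relative window length: 0.3, low-qmin bonus:
    0.1); the best window's fit is returned.
    """
    if len(curve) < 2 * min_window:
        raise GuinierError("curve too short for a Guinier search")
    i, j, Rg, var_Rg, I0, r2 = _scan_windows(curve, min_window)
    if i.size == 0:
        raise GuinierError("no admissible Guinier region found")
    length = (j - i).astype(float)
    qmin_rg = curve.q[i] * Rg
    score = (SCORE_WEIGHTS[0] * r2
             + SCORE_WEIGHTS[1] * length / length.max()
             + SCORE_WEIGHTS[2] * (1.0 - qmin_rg / QMIN_RG_LIMIT))
    best = int(np.argmax(score))
    result = fit_guinier_window(curve, (int(i[best]), int(j[best])))
    total = sum(SCORE_WEIGHTS)
    return GuinierResult(
        **{**result.__dict__, "quality": float(np.clip(score[best] / total, 0, 1))}
    )


def auto_rg_consensus(curve: ScatteringCurve, min_window: int = MIN_WINDOW,
                      rel_tol: float = 0.02) -> GuinierResult:
    """Consensus Guinier fit over all admissible windows.

    All admissible window fits are grouped on Rg: the consensus cluster
    is the densest band of relative half-width ``rel_tol`` (the Rg value
    consistent with the largest number of windows), whose members are
    combined by inverse-variance weighting.  The reported window is the
    union of the cluster's windows (trimmed to keep qmax*Rg <= 1.3) and
    the quality is the cluster's share of all admissible windows.
    """
    if len(curve) < 2 * min_window:
        raise GuinierError("curve too short for a Guinier search")
    i, j, Rg, var_Rg, I0, r2 = _scan_windows(curve, min_window)
    if i.size == 0:
        raise GuinierError("no admissible Guinier region found")
    order = np.argsort(Rg)
    Rg_s = Rg[order]
    lo = np.searchsorted(Rg_s, Rg_s * (1.0 - rel_tol), side="left")
    hi = np.searchsorted(Rg_s, Rg_s * (1.0 + rel_tol), side="right")
    kbest = int(np.argmax(hi - lo))   # densest band; ties -> smallest Rg
    members = order[lo[kbest]:hi[kbest]]

    wv = 1.0 / np.maximum(var_Rg[members], 1e-300)
    Rg_c = float(np.sum(wv * Rg[members]) / np.sum(wv))
    sigma_Rg = float(np.sqrt(1.0 / np.sum(wv)))
    I0_c = float(np.sum(wv * I0[members]) / np.sum(wv))
    sigma_I0 = float(np.std(I0[members])) if members.size > 1 else 0.0
    start = int(np.min(i[members]))
    end = int(np.max(j[members]))
    # trim the union so the reported window still satisfies the qRg bound
    while end - start > min_window and curve.q[end - 1] * Rg_c > QMAX_RG_LIMIT:
        end -= 1
    quality = float(members.size / Rg.size)
    return GuinierResult(
        Rg=Rg_c, sigma_Rg=sigma_Rg, I0=I0_c, sigma_I0=sigma_I0,
        window=(start, end),
        qmin_Rg=float(curve.q[start] * Rg_c),
        qmax_Rg=float(curve.q[end - 1] * Rg_c),
        quality=quality,
    )


def _gpa_model(q, I0, Rg):
    return q * I0 * np.exp(-(q * Rg) ** 2 / 3.0)


def auto_gpa(curve: ScatteringCurve, x_range: tuple[float, float] = (0.2, 2.0)) -> GuinierResult:
    """Guinier-peak analysis.

    q*I(q) of a Guinier-form curve peaks at q*Rg = sqrt(3/2); fitting
    ``q I0 exp(-q^2 Rg^2/3)`` on a window around the empirical peak gives
    Rg and I0 from a single nonlinear fit.  Fast and well suited to
    chromatography mode, at some cost in robustness.
    """
    q, I = curve.q, curve.I
    pos = I > 0
    if pos.sum() < 5:
        raise GuinierError("too few positive intensities for GPA")
    y = np.where(pos, q * I, 0.0)
    ipk = int(np.argmax(y))
    if ipk == 0 or ipk == len(q) - 1:
        raise GuinierError("GPA peak not bracketed by the q grid")
    qpk = q[ipk]
    Rg0 = np.sqrt(1.5) / qpk
    I00 = y[ipk] * np.exp(0.5) / qpk
    lo, hi = x_range[0] / Rg0, x_range[1] / Rg0
    sel = (q >= lo) & (q <= hi) & pos
    if sel.sum() < 5:
        raise GuinierError("GPA fit window too small")
    sigma = None
    if curve.sigma is not None:
        s = q[sel] * curve.sigma[sel]
        if np.all(s > 0):
            sigma = s
    popt, pcov = curve_fit(
        _gpa_model, q[sel], y[sel], p0=(I00, Rg0), sigma=sigma,
        absolute_sigma=sigma is not None, maxfev=10000,
    )
    I0_fit, Rg_fit = float(popt[0]), float(abs(popt[1]))
    if not np.isfinite(Rg_fit) or Rg_fit <= 0:
        raise GuinierError("GPA fit did not converge to a positive Rg")
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    if not np.isfinite(perr[1]) or perr[1] > 0.5 * Rg_fit:
        raise GuinierError("GPA fit not significant (sigma_Rg > Rg/2)")
    idx = np.flatnonzero(sel)
    return GuinierResult(
        Rg=Rg_fit, sigma_Rg=float(perr[1]), I0=I0_fit, sigma_I0=float(perr[0]),
        window=(int(idx[0]), int(idx[-1] + 1)),
        qmin_Rg=float(q[idx[0]] * Rg_fit),
        qmax_Rg=float(q[idx[-1]] * Rg_fit),
        quality=1.0,
    )
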