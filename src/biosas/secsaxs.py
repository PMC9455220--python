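"""SEC-SAXS (inline chromatography) analysis.

A SEC-SAXS acquisition is a long series of integrated curves recorded
while the sample elutes from a size-exclusion column.  The analysis
proceeds in stages: (1) assemble the full chromatogram from partial
acquisition files, tolerating missing blocks; (2) estimate the number of
spectral components by SVD with the Gavish–Donoho optimal singular-value
threshold; (3) factor the chromatogram by non-negative matrix
factorization into elution profiles times component spectra; (4) select
the frames most similar to the first singular vector (mostly buffer) by
the CorMap test and average them; (5) locate elution peaks on the
buffer-subtracted total-scattering trace; (6) run the full SAS analysis
(Guinier, Kratky, invariants, BIFT) on each averaged fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.signal import find_peaks_cwt, medfilt
from sklearn.decomposition import NMF

from . import bift as bift_mod
from . import guinier as guinier_mod
from . import invariants as invariants_mod
from .cormap import longest_run, prob_longest_run_ge
from .reduction import sigma_weighted_average_curves
from .sas_model import ScatteringCurve
from .synthgen import PartialChromatogram

__all__ = [
    "Chromatogram",
    "DecompositionResult",
    "FractionResult",
    "assemble_chromatogram",
    "svd_rank",
    "nmf_components",
    "select_buffer",
    "find_fractions",
    "analyze_fraction",
]


@dataclass(frozen=True)
class Chromatogram:
    """Frames x q-channels matrix of integrated intensities with a mask."""

    M: np.ndarray               # (n_frames, n_q)
    sigma: np.ndarray           # same shape
    q: np.ndarray
    frame_mask: np.ndarray      # True = frame present, False = missing block

    def __post_init__(self) -> None:
        if self.M.shape != self.sigma.shape or self.M.shape != (len(self.frame_mask), len(self.q)):
            raise ValueError("inconsistent chromatogram shapes")

    @property
    def n_frames(self) -> int:
        return self.M.shape[0]

    def frame_curve(self, i: int) -> ScatteringCurve:
        return ScatteringCurve(self.q, self.M[i], self.sigma[i])

    def unmasked_indices(self) -> np.ndarray:
        return np.flatnonzero(self.frame_mask)


@dataclass(frozen=True)
class DecompositionResult:
    rank: int
    singular_values: np.ndarray
    first_singular_vector: np.ndarray      # q-profile, mean-positive sign
    nmf_chromatograms: np.ndarray | None = None   # W, frames x k
    nmf_spectra: np.ndarray | None = None         # H, k x q
    threshold: float = 0.0
    n_clipped: int = 0

    def __post_init__(self) -> None:
        if self.nmf_chromatograms is not None and np.any(self.nmf_chromatograms < 0):
            raise ValueError("W must be non-negative")
        if self.nmf_spectra is not None and np.any(self.nmf_spectra < 0):
            raise ValueError("H must be non-negative")


@dataclass(frozen=True)
class FractionResult:
    frame_range: tuple[int, int]          # half-open
    curve: ScatteringCurve | None
    guinier: guinier_mod.GuinierResult | None
    kratky: tuple[np.ndarray, np.ndarray] | None
    invariants: invariants_mod.InvariantsResult | None
    pddf: bift_mod.PDDF | None
    status: dict = field(default_factory=dict)


def assemble_chromatogram(partial_files: Sequence[PartialChromatogram],
                          n_frames: int | None = None) -> Chromatogram:
    """Concatenate partial chromatograms into one full-length matrix.

    Rows are placed by global frame id; frames of missing blocks are
    masked (not dropped), so the chromatogram keeps the nominal run
    length and elution times stay aligned.
    """
    if len(partial_files) == 0:
        raise ValueError("need at least one partial file")
    q = partial_files[0].q
    for p in partial_files[1:]:
        if p.q.shape != q.shape or not np.array_equal(p.q, q):
            raise ValueError("partial files have inconsistent q grids")
    top = max(int(p.frame_ids.max()) for p in partial_files) + 1
    n = top if n_frames is None else max(n_frames, top)
    M = np.zeros((n, q.size))
    S = np.zeros((n, q.size))
    mask = np.zeros(n, dtype=bool)
    for p in partial_files:
        M[p.frame_ids] = p.I
        S[p.frame_ids] = p.sigma
        mask[p.frame_ids] = True
    return Chromatogram(M, S, q.copy(), mask)


def _omega(beta: float) -> float:
    """Gavish–Donoho omega(beta) coefficient (rational approximation)."""
    return 0.56 * beta**3 - 0.95 * beta**2 + 1.82 * beta + 1.43


def svd_rank(chromatogram: Chromatogram) -> DecompositionResult:
    """SVD of the unmasked rows with the optimal-threshold rank estimate.

    Singular values above tau = omega(beta) * median(singular values)
    are retained, beta being the matrix aspect ratio (<= 1).  The first
    right singular vector — dominated by buffer scattering — is returned
    with its sign fixed so its mean is positive.
    """
    rows = chromatogram.unmasked_indices()
    if rows.size < 2:
        raise ValueError("need at least 2 unmasked frames")
    X = chromatogram.M[rows]
    if not np.any(X):
        raise ValueError("chromatogram matrix is all zero")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    beta = min(X.shape) / max(X.shape)
    tau = _omega(beta) * float(np.median(s))
    k = int(np.sum(s > tau))
    v1 = Vt[0]
    if v1.mean() < 0:
        v1 = -v1
    return DecompositionResult(
        rank=k, singular_values=s, first_singular_vector=v1, threshold=tau,
    )


def _refine_factorization(W: np.ndarray, H: np.ndarray, X: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the rotational ambiguity of W @ H toward pure spectra.

    A dense background (buffer scatters in every frame) lets NMF trade
    arbitrary amounts of background — and even differences of components
    — between rows without changing the fit.  Two chromatography-
    standard constraints pin the factorization down: (i) each eluting
    component occupies one contiguous elution interval, so every
    non-background column of W is clipped to the contiguous support
    around its maximum and H is refit by per-channel NNLS; (ii) the
    maximal multiple of the background spectrum is subtracted from each
    component spectrum (compensated in W, so W @ H is unchanged).  The
    background row is identified as the one with the flattest elution
    profile.
    """
    k = H.shape[0]
    if k < 2:
        return W, H
    cv = W.std(axis=0) / (W.mean(axis=0) + 1e-300)
    bg = int(np.argmin(cv))
    for i in range(k):
        if i == bg:
            continue
        col = W[:, i]
        pk = int(np.argmax(col))
        thr = 0.02 * col[pk]
        lo = pk
        while lo > 0 and col[lo - 1] > thr:
            lo -= 1
        hi = pk
        while hi < len(col) - 1 and col[hi + 1] > thr:
            hi += 1
        keep = np.zeros_like(col)
        keep[lo:hi + 1] = col[lo:hi + 1]
        W[:, i] = keep
    H_new = np.zeros_like(H)
    for j in range(X.shape[1]):
        H_new[:, j], _ = nnls(W, X[:, j])
    H = H_new
    for i in range(k):
        if i == bg or not np.any(H[bg] > 0):
            continue
        ratio = H[i] / np.where(H[bg] > 0, H[bg], np.inf)
        c = float(max(ratio.min(), 0.0))
        H[i] -= c * H[bg]
        W[:, bg] += c * W[:, i]
    return W, H


def nmf_components(chromatogram: Chromatogram, k: int,
                   max_iter: int = 10000) -> DecompositionResult:
    """Non-negative factorization of the chromatogram into k components.

    Deterministic by construction: non-negative double SVD (nndsvd)
    initialization and a fixed iteration cap.  Negative matrix entries
    (possible after subtraction) are clipped at zero and counted.  The
    raw factorization is refined by :func:`_refine_factorization` so the
    extracted spectra approximate pure components rather than arbitrary
    admixtures; each spectrum (row of H) is finally normalized to unit
    maximum with the scale absorbed into the elution profiles W.
    """
    rows = chromatogram.unmasked_indices()
    X = chromatogram.M[rows]
    if not (1 <= k <= min(X.shape)):
        raise ValueError("k must satisfy 1 <= k <= min(n_frames, n_q)")
    n_clipped = int(np.sum(X < 0))
    X = np.clip(X, 0.0, None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = NMF(n_components=k, init="nndsvda", solver="cd", tol=1e-9,
                    max_iter=max_iter, random_state=0)
        W_rows = model.fit_transform(X)
    H = model.components_.copy()
    W_rows, H = _refine_factorization(W_rows, H, X)
    scale = H.max(axis=1)
    scale[scale == 0] = 1.0
    H = H / scale[:, None]
    W_rows = W_rows * scale[None, :]
    W = np.zeros((chromatogram.n_frames, k))
    W[rows] = W_rows
    svd = svd_rank(chromatogram)
    return DecompositionResult(
        rank=k, singular_values=svd.singular_values,
        first_singular_vector=svd.first_singular_vector,
        nmf_chromatograms=W, nmf_spectra=H,
        threshold=svd.threshold, n_clipped=n_clipped,
    )


def _rank_against(chromatogram: Chromatogram, rows: np.ndarray,
                  v: np.ndarray, n_sel: int) -> np.ndarray:
    """Top n_sel frames ranked by CorMap similarity to the scaled vector v
    (p-value descending, ties by smaller longest run C, then frame id)."""
    vv = float(v @ v)
    records = []
    for i in rows:
        row = chromatogram.M[i]
        scale = float(row @ v) / vv
        try:
            n, C = longest_run(row, scale * v)
            p = prob_longest_run_ge(n, C)
        except ValueError:      # exactly identical: maximally buffer-like
            p, C = 1.0, 0
        records.append((-p, C, int(i)))
    records.sort()
    return np.array(sorted(r[2] for r in records[:n_sel]), dtype=int)


def select_buffer(chromatogram: Chromatogram,
                  first_singular_vector: np.ndarray,
                  fraction: float = 0.30,
                  n_iter: int = 3) -> tuple[ScatteringCurve, np.ndarray]:
    """Select and average the frames most similar to the background.

    Each unmasked frame is compared, via the CorMap statistic, against a
    background template scaled to it by least squares; frames are ranked
    from most to least buffer-like (p-value descending, ties by smaller
    longest run C, then by frame id) and the top floor(fraction * n) are
    averaged with inverse-variance weights propagated from the
    azimuthal-integration uncertainties.

    The template starts as the first singular vector, which carries a
    residue of the eluting components; re-ranking against the average of
    the previously selected frames (``n_iter`` fixed passes, so the
    result stays deterministic) purges that residue and keeps frames
    under the elution peaks out of the selection.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    rows = chromatogram.unmasked_indices()
    n_sel = int(np.floor(fraction * rows.size))
    if n_sel < 2:
        raise ValueError("fewer than 2 selectable frames")
    v = np.asarray(first_singular_vector, dtype=float)
    selected = _rank_against(chromatogram, rows, v, n_sel)
    for _ in range(max(n_iter - 1, 0)):
        template = sigma_weighted_average_curves(
            [chromatogram.frame_curve(i) for i in selected])
        refined = _rank_against(chromatogram, rows, template.I, n_sel)
        if np.array_equal(refined, selected):
            break
        selected = refined
    curves = [chromatogram.frame_curve(i) for i in selected]
    return sigma_weighted_average_curves(curves), selected


def find_fractions(chromatogram_subtracted: Chromatogram,
                   widths: tuple[int, int] = (5, 50),
                   boundary_fraction: float = 0.10,
                   min_snr: float = 1.0,
                   significance: float = 5.0) -> list[tuple[int, int]]:
    """Locate elution peaks on the subtracted total-scattering trace.

    The per-frame total scattering (sum over q) is smoothed by a
    5-frame median filter and searched with continuous-wavelet-transform
    peak detection over the given width range.  The CWT stage is run
    permissively (its internal SNR heuristic is unreliable for tall
    smooth peaks) and only localizes candidates; peaks must then exceed
    the robust (median/MAD) noise level of the smoothed trace by
    ``significance`` sigma to count.  Each surviving peak is
    expanded to the surrounding region where the smoothed signal stays
    above ``boundary_fraction`` of the peak height, and overlapping
    regions are split at the minimum between peaks.  An empty list is a
    valid outcome (no eluting species).
    """
    total = np.where(chromatogram_subtracted.frame_mask,
                     chromatogram_subtracted.M.sum(axis=1), 0.0)
    smoothed = medfilt(total, kernel_size=5)
    peak_idx = find_peaks_cwt(smoothed, np.arange(widths[0], widths[1] + 1),
                              min_snr=min_snr)
    if len(peak_idx) == 0:
        return []
    baseline = float(np.median(smoothed))
    noise = 1.4826 * float(np.median(np.abs(smoothed - baseline))) or 1e-300
    peaks = [int(p) for p in peak_idx
             if smoothed[p] - baseline > significance * noise]
    if not peaks:
        return []
    peaks.sort()
    regions = []
    n = len(smoothed)
    for p in peaks:
        height = smoothed[p]
        floor = baseline + boundary_fraction * (height - baseline)
        lo = p
        while lo > 0 and smoothed[lo - 1] > floor:
            lo -= 1
        hi = p
        while hi < n - 1 and smoothed[hi + 1] > floor:
            hi += 1
        regions.append([lo, hi + 1, p])
    # split overlapping regions at the minimum between their peaks
    merged: list[list[int]] = []
    for reg in regions:
        if merged and reg[0] < merged[-1][1]:
            prev = merged[-1]
            cut = prev[2] + int(np.argmin(smoothed[prev[2]:reg[2] + 1]))
            if cut <= prev[2] or cut >= reg[2]:
                # no interior minimum: same peak detected twice, keep first
                prev[1] = max(prev[1], reg[1])
                continue
            prev[1] = cut
            reg[0] = cut
        merged.append(reg)
    return [(int(lo), int(hi)) for lo, hi, _ in merged]


def analyze_fraction(chromatogram: Chromatogram,
                     frame_range: tuple[int, int],
                     buffer_average: ScatteringCurve) -> FractionResult:
    """Average and analyse one elution fraction.

    Buffer-subtracted curves in the range are averaged with inverse-
    variance weights, then passed through the fast GPA Guinier estimator
    (with the exhaustive search as fallback), the dimensionless Kratky
    plot, the invariants and BIFT.  A Guinier failure yields a partial
    result with an explicit status and no crash.
    """
    lo, hi = int(frame_range[0]), int(frame_range[1])
    if not (0 <= lo < hi <= chromatogram.n_frames):
        raise ValueError("frame range out of bounds")
    rows = [i for i in range(lo, hi) if chromatogram.frame_mask[i]]
    status: dict = {}
    if not rows:
        return FractionResult((lo, hi), None, None, None, None, None,
                              {"error": "all frames in range are masked"})
    subtracted = []
    for i in rows:
        I = chromatogram.M[i] - buffer_average.I
        s = np.sqrt(chromatogram.sigma[i] ** 2 + buffer_average.sigma**2)
        subtracted.append(ScatteringCurve(chromatogram.q, I, s))
    curve = sigma_weighted_average_curves(subtracted)

    try:
        try:
            fit = guinier_mod.auto_gpa(curve)
            status["guinier_method"] = "gpa"
        except guinier_mod.GuinierError:
            fit = guinier_mod.auto_guinier(curve)
            status["guinier_method"] = "auto"
    except guinier_mod.GuinierError as exc:
        status["error"] = f"Guinier analysis failed: {exc}"
        return FractionResult((lo, hi), curve, None, None, None, None, status)

    kratky = invariants_mod.kratky_dimensionless(curve, fit)
    try:
        inv = invariants_mod.compute_invariants(curve, fit)
    except ValueError as exc:
        inv = None
        status["invariants_error"] = str(exc)
    try:
        pddf = bift_mod.bift_auto(curve)
    except bift_mod.BiftError as exc:
        pddf = None
        status["bift_error"] = str(exc)
    return FractionResult((lo, hi), curve, fit, kratky, inv, pddf, status)
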