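"""Correlation-map (CorMap) equivalence test between scattering curves.

Two statistically equivalent noisy curves differ by noise alone, so the
signs of their channel-wise differences behave like fair coin flips.  The
test statistic is C, the length of the longest run of same-sign
differences over n channels; its exact null distribution (longest run of
identical outcomes in n fair Bernoulli trials) yields
p = Pr(longest run >= C), computed here with exact integer arithmetic.

The pipelines use this test to detect radiation damage between successive
frames and to rank SEC-SAXS frames by similarity to the buffer.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .sas_model import ScatteringCurve

__all__ = [
    "CormapOutcome",
    "longest_run",
    "prob_longest_run_ge",
    "prob_longest_run_ge_exact",
    "cormap_test",
    "pairwise_equivalence",
    "DEFAULT_THRESHOLD_ADJACENT",
    "DEFAULT_THRESHOLD_ANY",
]

DEFAULT_THRESHOLD_ADJACENT = 0.01
DEFAULT_THRESHOLD_ANY = 0.001


@dataclass(frozen=True)
class CormapOutcome:
    n: int                 # number of compared channels (ties dropped)
    C: int                 # longest run of same-sign differences
    p_value: float         # Pr(longest run >= C) under the fair-coin null
    equivalent: bool       # p_value >= threshold used for the call

    def __post_init__(self) -> None:
        if not (1 <= self.C <= self.n):
            raise ValueError("C must lie in [1, n]")
        if not (0 < self.p_value <= 1 or self.p_value == 0.0):
            raise ValueError("p_value must lie in (0, 1]")


def longest_run(values_a: np.ndarray, values_b: np.ndarray) -> tuple[int, int]:
    """Longest contiguous block of constant sign of (a - b).

    Channels where a == b exactly are dropped before computing runs (a
    zero-probability event under continuous noise, but it must be handled
    deterministically for integer-valued synthetic data).
    Returns (n_usable_channels, C).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1D arrays")
    signs = np.sign(a - b)
    signs = signs[signs != 0]
    n = signs.size
    if n == 0:
        raise ValueError("no usable channels: the curves are exactly identical")
    # run-length encode
    change = np.flatnonzero(np.diff(signs) != 0)
    bounds = np.concatenate(([0], change + 1, [n]))
    C = int(np.max(np.diff(bounds)))
    return n, C


def _count_max_run_lt(n: int, c: int) -> int:
    """Number of length-n binary sequences whose longest run is < c.

    Counted as 2 * (compositions of n into parts <= c-1): runs alternate
    between the two symbols, and the first symbol is free.  Prefix sums
    make the recursion O(n) big-integer additions.
    """
    m = c - 1
    if m <= 0:
        return 0
    # comp[k] = number of compositions of k into parts of size 1..m
    comp = [0] * (n + 1)
    comp[0] = 1
    running = 1  # sum of comp[max(0, k-m) .. k-1]
    for k in range(1, n + 1):
        comp[k] = running
        running += comp[k]
        if k - m >= 0:
            running -= comp[k - m]
    return 2 * comp[n]


def prob_longest_run_ge_exact(n: int, c: int) -> Fraction:
    """Exact Pr(longest run >= c) for n fair Bernoulli trials."""
    if not (1 <= c <= n):
        raise ValueError("require 1 <= c <= n")
    return 1 - Fraction(_count_max_run_lt(n, c), 2**n)


def prob_longest_run_ge(n: int, c: int) -> float:
    """Pr(longest run of identical outcomes >= c | n fair coin flips).

    Computed by exact integer recursion and converted to float at the end,
    so there is no overflow or cancellation for n up to 10^4 and the
    result underflows gracefully for extreme C.
    """
    frac = prob_longest_run_ge_exact(n, c)
    # int/int division is correctly rounded at arbitrary precision and
    # underflows gracefully to 0.0 for extreme run lengths.
    return frac.numerator / frac.denominator


def cormap_test(curve_a: ScatteringCurve, curve_b: ScatteringCurve,
                q_range: tuple[float, float] | None = None,
                threshold: float = DEFAULT_THRESHOLD_ADJACENT) -> CormapOutcome:
    """CorMap equivalence test between two curves on a common q grid.

    The q grids must match exactly — no interpolation is attempted, since
    resampling would correlate neighbouring channels and break the
    fair-coin null.
    """
    if curve_a.q.shape != curve_b.q.shape or not np.array_equal(curve_a.q, curve_b.q):
        raise ValueError("curves must share an identical q grid (no interpolation)")
    Ia, Ib, q = curve_a.I, curve_b.I, curve_a.q
    if q_range is not None:
        m = (q >= q_range[0]) & (q <= q_range[1])
        if not np.any(m):
            raise ValueError("q_range excludes all points")
        Ia, Ib = Ia[m], Ib[m]
    n, C = longest_run(Ia, Ib)
    p = prob_longest_run_ge(n, C)
    return CormapOutcome(n=n, C=C, p_value=p, equivalent=bool(p >= threshold))


def pairwise_equivalence(curves: Sequence[ScatteringCurve],
                         threshold_adjacent: float = DEFAULT_THRESHOLD_ADJACENT,
                         threshold_any: float = DEFAULT_THRESHOLD_ANY,
                         q_range: tuple[float, float] | None = None,
                         ) -> tuple[list[int], np.ndarray]:
    """Select the frames equivalent to the first one in an acquisition.

    Radiation damage accumulates with dose, so acceptance is a contiguous
    prefix in time: frames are accepted while the adjacent-pair p-value
    stays above ``threshold_adjacent`` AND the p-value against the first
    accepted frame stays above ``threshold_any``.  The thresholds are
    familywise significance levels: they are Bonferroni-corrected by the
    number of sequential comparisons (n - 1), so the chance of falsely
    discarding good frames does not grow with the stack length.  Returns
    the accepted frame indices and the full pairwise p-value matrix for
    reporting.
    """
    n = len(curves)
    if n == 0:
        raise ValueError("need at least one curve")
    pmat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                p = cormap_test(curves[i], curves[j], q_range=q_range).p_value
            except ValueError:
                p = 1.0   # exactly identical curves are trivially equivalent
            pmat[i, j] = pmat[j, i] = p
    thr_adj = threshold_adjacent / max(n - 1, 1)
    thr_any = threshold_any / max(n - 1, 1)
    accepted = [0]
    for k in range(1, n):
        if pmat[k - 1, k] >= thr_adj and pmat[0, k] >= thr_any:
            accepted.append(k)
        else:
            break
    return accepted, pmat
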