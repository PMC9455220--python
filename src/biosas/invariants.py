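"""Kratky representation and size/mass invariants.

From a background-subtracted curve and its Guinier fit this module
computes:

* the dimensionless Kratky plot (q Rg)^2 I/I0 vs q Rg, which separates
  globular particles (peak at (sqrt(3), 3/e)) from flexible chains
  (plateau at 2);
* the Porod invariant Q_p = int q^2 I dq and Porod volume
  V_p = 2 pi^2 I0 / Q_p;
* the volume of correlation V_c = I0 / int q I dq (Rambo & Tainer), the
  derived ratio Q_R = V_c^2 / Rg and the empirical molecular-mass
  estimate (Q_R / c)^k with class-specific constants.

Integrals use trapezoid quadrature with an analytic Guinier closed form
for the unmeasured [0, q_min] head and, for Q_p, a fitted q^-4 Porod tail
extended to infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .guinier import GuinierResult
from .sas_model import ScatteringCurve

__all__ = [
    "InvariantsResult",
    "kratky_dimensionless",
    "porod",
    "rambo_tainer",
    "compute_invariants",
    "MASS_CONSTANTS",
]

#: Empirical (c, k) constants of the Q_R -> mass power law, per molecule
#: class, as published by Rambo & Tainer (2013).  Mass in kDa when I and q
#: are on an absolute-calibrated scale with q in A^-1; on arbitrary
#: synthetic scales the estimate is only meaningful for comparisons.
MASS_CONSTANTS = {
    "version": "2013.1",
    "protein": {"c": 0.1231, "k": 1.0},
    "rna": {"c": 0.00934, "k": 0.808},
}


@dataclass(frozen=True)
class InvariantsResult:
    porod_invariant: float        # Q_p, intensity * nm^-3
    porod_volume: float           # V_p, nm^3
    volume_of_correlation: float  # V_c
    qr_ratio: float               # Q_R = V_c^2 / Rg
    mass_estimate: float          # kDa (meaningful on calibrated scales)
    mass_method: str
    kratky_x: np.ndarray = field(repr=False, default=None)
    kratky_y: np.ndarray = field(repr=False, default=None)
    flags: tuple[str, ...] = ()


def kratky_dimensionless(curve: ScatteringCurve, guinier: GuinierResult
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Dimensionless Kratky arrays x = q Rg, y = (q Rg)^2 I / I0."""
    if guinier.I0 <= 0:
        raise ValueError("I0 must be positive for a dimensionless Kratky plot")
    x = curve.q * guinier.Rg
    y = x**2 * curve.I / guinier.I0
    return x, y


def _guinier_head_q2(qmin: float, Rg: float, I0: float) -> float:
    """int_0^qmin q^2 I0 exp(-a q^2) dq with a = Rg^2/3 (closed form)."""
    a = Rg**2 / 3.0
    if a <= 0:
        return I0 * qmin**3 / 3.0
    return I0 * (np.sqrt(np.pi) / (4.0 * a**1.5) * erf(np.sqrt(a) * qmin)
                 - qmin * np.exp(-a * qmin**2) / (2.0 * a))


def _guinier_head_q1(qmin: float, Rg: float, I0: float) -> float:
    """int_0^qmin q I0 exp(-a q^2) dq with a = Rg^2/3 (closed form)."""
    a = Rg**2 / 3.0
    if a <= 0:
        return I0 * qmin**2 / 2.0
    return I0 * (1.0 - np.exp(-a * qmin**2)) / (2.0 * a)


def porod(curve: ScatteringCurve, guinier: GuinierResult,
          tail_decades: float = 1.0) -> tuple[float, float, tuple[str, ...]]:
    """Porod invariant Q_p and Porod volume V_p = 2 pi^2 I0 / Q_p.

    Q_p = int_0^inf q^2 I dq, assembled from an analytic Guinier head on
    [0, q_min], trapezoid quadrature over the measured range, and a
    Porod tail A/q^4 fitted over the last ``tail_decades`` decades of q
    and integrated beyond q_max (contributing A/q_max).
    """
    q, I = curve.q, curve.I
    head = _guinier_head_q2(q[0], guinier.Rg, guinier.I0)
    body = float(np.trapezoid(q**2 * I, q))
    flags: tuple[str, ...] = ()
    tail_sel = q >= q[-1] / 10.0**tail_decades
    A = float(np.mean(I[tail_sel] * q[tail_sel] ** 4))
    if A <= 0:
        flags = ("negative_porod_tail",)
        tail = 0.0
    else:
        tail = A / q[-1]
    Q_p = head + body + tail
    V_p = 2.0 * np.pi**2 * guinier.I0 / Q_p
    return float(Q_p), float(V_p), flags


def rambo_tainer(curve: ScatteringCurve, guinier: GuinierResult,
                 molecule_class: str = "protein",
                 q_cut: float | None = None) -> tuple[float, float, float, tuple[str, ...]]:
    """Volume of correlation V_c, Q_R = V_c^2/Rg and the mass estimate.

    V_c = I0 / int_0^q_cut q I dq with q_cut defaulting to 8/Rg (capped
    at the measured maximum); the integral head below q_min uses the
    Guinier closed form.  Mass = (Q_R / c)^k with class constants from
    the versioned table :data:`MASS_CONSTANTS`.
    """
    if molecule_class not in ("protein", "rna"):
        raise ValueError(f"unknown molecule class {molecule_class!r}")
    q, I = curve.q, curve.I
    flags: tuple[str, ...] = ()
    cut = 8.0 / guinier.Rg if q_cut is None else q_cut
    if cut > q[-1]:
        cut = q[-1]
        flags = ("q_cut_beyond_data",)
    sel = q <= cut
    head = _guinier_head_q1(q[sel][0], guinier.Rg, guinier.I0)
    body = float(np.trapezoid(q[sel] * I[sel], q[sel]))
    integral = head + body
    if integral <= 0:
        raise ValueError("non-positive int q I dq; curve not background-free?")
    V_c = guinier.I0 / integral
    Q_R = V_c**2 / guinier.Rg
    consts = MASS_CONSTANTS[molecule_class]
    mass = (Q_R / consts["c"]) ** consts["k"]
    return float(V_c), float(Q_R), float(mass), flags


def compute_invariants(curve: ScatteringCurve, guinier: GuinierResult,
                       molecule_class: str = "protein") -> InvariantsResult:
    """All invariants plus the dimensionless Kratky arrays in one bundle."""
    kx, ky = kratky_dimensionless(curve, guinier)
    Q_p, V_p, flags_p = porod(curve, guinier)
    V_c, Q_R, mass, flags_rt = rambo_tainer(curve, guinier, molecule_class)
    return InvariantsResult(
        porod_invariant=Q_p, porod_volume=V_p,
        volume_of_correlation=V_c, qr_ratio=Q_R,
        mass_estimate=mass,
        mass_method=f"rambo_tainer:{molecule_class}:{MASS_CONSTANTS['version']}",
        kratky_x=kx, kratky_y=ky,
        flags=flags_p + flags_rt,
    )
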