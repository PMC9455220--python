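# Methods

This note records the models implemented in `biosas`, the defaults that
matter, and the choices made where the design was genuinely open. Units
throughout: q in inverse nanometres, distances in nm, detector geometry
in mm and pixels.

## Data model and I/O

A reduced datum is a `ScatteringCurve` (strictly increasing q ≥ 0,
intensities, optional 1σ uncertainties). q is handled internally in
nm⁻¹ only; readers accept a declared `angstrom^-1` unit and convert on
load, because mixing the two conventions silently produces 10× errors
in every derived size. Three-column ASCII files are written with 17
significant digits so read/write round-trips are lossless at double
precision. HDF5 result files use NeXus-flavoured group names
(`NXentry`/`NXprocess`), one group per pipeline stage, each carrying a
JSON copy of the parameters that produced it — any stage can be re-run
from the stored file alone. Raw inputs are recorded as path strings
rather than HDF5 external links so result files stay portable. All
datasets are written with `track_times=False`, which is what makes
repeated writes byte-identical and pipeline replay verifiable by hash.

## Guinier estimators

`ln I = ln I₀ − (qRg)²/3` is fitted by weighted least squares with
delta-method weights `(I/σ)²`. Window admissibility: at least 10
points, all I > 0, a significantly negative slope (−slope ≥ 2σ_slope,
applied only when uncertainties exist), and with the window's own
self-consistent Rg: `qmax·Rg ≤ 1.3` (the validity bound of the Guinier
approximation), `qmin·Rg < 1.0` (guards against beam-stop shadow and
aggregation upturns at the very lowest q), and `qmax·Rg ≥ 0.5` (the
window must span a measurable decay; without this bound a flat curve
yields a numerically-tiny negative slope and a spurious "region").

* `auto_guinier` scans every admissible window (prefix-sum algebra
  makes the exhaustive scan O(n²) with small constants) and scores
  each with fixed weights 0.6·R² + 0.3·(relative length) +
  0.1·(1 − qmin·Rg): fit quality dominates, longer windows are
  preferred, and reaching low q earns a small bonus.
* `auto_rg_consensus` keeps all admissible fits and returns the
  inverse-variance-weighted mean of the densest band of relative
  half-width 2% (mode seeking). Plain single-linkage clustering was
  tried first and rejected: on curves with a low-q contamination the
  window estimates form a continuum and single linkage chains ~100% of
  windows into one cluster.
* `auto_gpa` (Guinier-peak analysis) fits `q·I₀·exp(−q²Rg²/3)` to
  `q·I` on the window `qRg ∈ [0.2, 2.0]` around the empirical peak
  (the analytic peak sits at `qRg = √(3/2)`); fits with
  `σ_Rg > Rg/2` are rejected as not significant. GPA is the fast path
  used per-fraction in chromatography mode.

On data of exactly Guinier form all three return identical Rg to
solver tolerance; on sphere data they carry the expected small
window-truncation bias (≈1–2%). No byte-equality with any external
AUTORG-style implementation is claimed.

## CorMap

Two statistically equivalent curves differ by noise alone, so the signs
of channel-wise differences are i.i.d. fair coins. The statistic is the
longest run C of constant sign over n channels; exact ties are dropped
(deterministic for integer-valued synthetic data, measure-zero
otherwise). `Pr(longest run ≥ c)` is computed exactly:
`#(sequences with max run < c) = 2·C_m(n)` where `C_m` counts
compositions of n into parts ≤ c−1, accumulated with a prefix-sum
recursion in O(n) big-integer additions — exact for any n, no overflow,
with graceful float underflow for extreme C.

Frame screening accepts a contiguous prefix in acquisition order
(radiation damage accumulates with dose): frames are accepted while the
adjacent-pair p-value and the p-value against the first frame stay
above the thresholds (defaults 0.01 and 0.001). The thresholds are
familywise levels, Bonferroni-corrected by the number of sequential
comparisons; without the correction a 10-frame stack of good frames is
falsely truncated in roughly 9% of realizations.

The p-value distribution under the null is discrete (the modal atom of
the longest-run distribution carries ~0.25 of the mass at any n), so
calibration is checked against the exact discrete null CDF at the
attainable atoms, not against a continuous uniform.

## BIFT

Forward model: `I = T·p` with
`T[i,j] = 4π·Δr·sinc(q_i r_j)` and trapezoid end-weights; p lives on a
uniform r grid on [0, Dmax] with clamped zero endpoints. At fixed
(Dmax, α) the solution minimizes `½χ² + α∫(p″)² dr` subject to p ≥ 0,
solved as one non-negative least-squares problem on the stacked system.
The second-difference operator is scaled by `Δr^(−3/2)` so the penalty
is the continuum integral of (p″)² — this makes α a physical constant
and the evidence comparable across different Dmax grids.

Hyperparameters are selected by the Laplace-approximated log evidence
`−χ²/2 − αS + ½log det(2αK) − ½log det(H)` with `K = D′D` and
`H = T_σ′T_σ + 2αK`, evaluated over **all** interior coordinates. The
common alternative — evaluating on the active set only — was measured
to remove the Occam penalty for r bins the data constrain to zero: the
evidence then stays flat for oversized Dmax and the optimum overshoots
by 5–20%. With the full-set Hessian the evidence peaks at the true
Dmax (recovered within ~1.5% on the default noisy sphere).

Search: Dmax grid of 20 points on [2·Rg, 5·Rg] (Rg from the Guinier
fit; the sphere is the most compact shape at Dmax = 2.58·Rg, flexible
chains reach ~4–5·Rg) crossed with a log-α grid of 15 points/decade
over 6 decades centred where the misfit and smoothness terms of a
lightly regularized probe solution balance; the coarse optimum is then
locally refined (11 × 11). The maximum-evidence point is returned, not
a posterior mean — determinism is worth more to a pipeline than the
marginal accuracy gain. Real-space outputs follow from the moments:
`Rg² = ∫r²p / 2∫p`, `I₀ = 4π∫p`. Results flagged `converged=False`
when the optimum sits on the search boundary.

## Invariants

Q_p and ∫qI use trapezoid quadrature plus an analytic Guinier closed
form (erf-based) for the unmeasured [0, q_min] head; Q_p additionally
fits a Porod `A/q⁴` tail over the last decade of q (A = mean of `I·q⁴`
there, averaging over the sphere's oscillations) and integrates it to
infinity (contributing A/q_max). The Rambo–Tainer cutoff is
`q_cut = 8/Rg`, capped at the measured range with a flag. The mass
power-law constants (protein c = 0.1231, k = 1.0; RNA c = 0.00934,
k = 0.808) live in a versioned table recorded in every output; the
estimate is physically meaningful only on absolute-calibrated
intensity scales.

## Reduction and the averaging identity

Averaging over frames weighted by the beam-stop diode is the ratio of
sums `ΣF_k/Σd_k` with Poisson variance `ΣF_k/(Σd_k)²` — never the mean
of per-frame ratios. Azimuthal integration uses equal-width q bins to
the corner q, the arithmetic mean of normalized pixel values per bin,
`σ = √(Σvar)/N`, empty bins dropped (downstream CorMap requires exact
grid matches; NaN-filling would break them), and a +1 variance floor on
zero-count bins. Because both routes are linear in the same pixel sums,
the monitor-weighted 1D average `Σd_k I_k/Σd_k` reproduces the
2D average-then-integrate route to machine precision, while the plain
mean of normalized curves differs whenever monitors are unequal — both
facts are asserted numerically in the tests. No solid-angle,
polarization or flat-field corrections are applied: the synthetic
geometry is ideal, and real-geometry corrections belong to a dedicated
integration library.

## SEC-SAXS pipeline

1. Partial chromatograms are placed by global frame id; missing blocks
   are masked, never dropped, so elution times stay aligned.
2. Rank: SVD of the unmasked rows; singular values above
   `ω(β)·median(σ)` are kept, with the Gavish–Donoho coefficient
   `ω(β) ≈ 0.56β³ − 0.95β² + 1.82β + 1.43` and β the aspect ratio.
3. NMF (scikit-learn, `nndsvda` init, coordinate descent, fixed caps —
   deterministic) factors the chromatogram into elution profiles W and
   spectra H. Raw NMF is rotationally ambiguous when a dense background
   is present: admixtures of the buffer spectrum (and even differences
   of components) move between rows at identical reconstruction error.
   Two chromatography-standard constraints pin it down: each component's
   elution profile is clipped to its contiguous support (elution peaks
   are single intervals) with H refit by per-channel NNLS, and the
   maximal multiple of the background spectrum is subtracted from each
   component row with exact compensation in W. Spectra are reported
   normalized to unit maximum.
4. Buffer extraction: frames are ranked by the CorMap statistic against
   a least-squares-scaled background template (p descending, ties by
   smaller C, then frame id) and the top 30% are averaged with
   inverse-variance weights. The template starts as the first singular
   vector but is refined over 3 fixed re-ranking passes against the
   average of the previous selection: the first singular vector carries
   an elution-weighted residue of the components, and a single pass
   measurably prefers frames whose contamination matches that residue.
   This 1D σ-weighted averaging is an approximation of the exact 2D
   route; the exact monitor-weighted variant exists in the reduction
   module for workflows that keep the raw frames.
5. Fractions: the total scattering per frame is median-filtered
   (window 5) and searched with CWT peak detection (widths 5–50
   frames). The CWT stage only localizes candidates — its internal SNR
   heuristic misses tall smooth peaks — and significance is decided by
   a 5σ median/MAD filter on the smoothed trace. Peaks extend to where
   the smoothed signal falls to 10% of peak height; overlaps split at
   the inter-peak minimum. An empty list is a valid outcome.
6. Each fraction: buffer-subtracted curves averaged (σ-weighted), then
   GPA-first Guinier with the exhaustive search as fallback, Kratky,
   invariants, BIFT; failures degrade to a partial result with an
   explicit status.

## Synthetic data: what it emulates and what it does not

Form factors are the homogeneous sphere and the Debye Gaussian chain;
noise is Poisson counting at a configurable exposure (counts =
exposure·I); detector frames use a flat-field normal-incidence
small-angle geometry `q = (4π/λ)·sin(½·atan(r/D))`; SEC runs are
elution profiles × spectra + flat buffer, grouped 100 frames per file
with optional missing blocks. Defaults are chosen to resemble a
realistic BioSAXS measurement: sphere R = 3 nm (Rg ≈ 2.324 nm), I₀ =
100 on a buffer of 50 (signal-to-background 2:1 at q→0), a 1000-point
q grid to 5 nm⁻¹ so the Guinier region spans >100 points, and for SEC
runs an exposure of 10 photons per intensity unit (~500 counts/channel
on buffer, peak-channel component SNR ≈ 25) — per-frame statistics at
which template-similarity ranking is informative, as it is for 1 s
exposures in practice. The default SEC run has two sphere components
(R = 3 and 1.5 nm) eluting at 35% and 65% of the run with width 3% of
the run length.

Not emulated: detector gaps, flat-field error, parallax, polarization
and solid-angle effects, inter-particle structure factors,
concentration series, capillary fouling, and non-Poisson detector
pathologies. Passing tests therefore demonstrate the correctness of
the estimators and pipeline logic under ideal counting statistics, not
robustness to instrument systematics.

## Numerical choices and degenerate inputs

Sphere and Debye form factors switch to series expansions below
x = 10⁻⁴ (10⁻⁶ for the Debye argument). Exactly identical curves have
no usable CorMap channels and are treated as trivially equivalent where
a pipeline needs a decision, as an error where the statistic itself is
requested. A subtracted curve consistent with zero fails the Guinier
stage gracefully (flagged, downstream stages skipped). Job replay
validates `schema_version` and reports unknown pipelines by name.

## Known limitations

* The BIFT evidence is a Laplace approximation around a constrained
  optimum; its absolute value is only meaningful for comparisons within
  one curve.
* The Porod tail window ("last decade of q") is a convention; for
  curves truncated near qR ≈ 4 the residual volume bias is ~6%.
* The mass estimate inherits the intensity scale; without absolute
  calibration it is relative.
* The NMF refinement assumes unimodal, well-separated elution peaks —
  heavily overlapping species would need an explicitly regularized
  decomposition, which is out of scope.
* Acceptance of frames is prefix-contiguous by design; transient
  single-frame glitches mid-acquisition terminate the accepted prefix
  rather than being excised.
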