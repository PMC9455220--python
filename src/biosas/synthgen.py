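"""Synthetic scattering data with known ground truth.

Every analysis stage in this package is exercised against data generated
here: analytic form factors (homogeneous sphere, Gaussian chain), Poisson
counting noise at a configurable exposure, small detector images with a
known beam geometry, and SEC-SAXS elution runs built as elution profiles
times component spectra on top of a buffer background.

All generators are deterministic under a fixed seed and return the ground
truth (Rg, Dmax, I0, spectra, elution profiles) alongside the data, so
parameter recovery can be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sas_model import FrameStack, Geometry, ScatteringCurve

__all__ = [
    "GroundTruth",
    "PartialChromatogram",
    "sphere_intensity",
    "gaussian_chain_intensity",
    "sphere_pddf",
    "guinier_intensity",
    "add_noise",
    "default_geometry",
    "make_frames",
    "make_sec_run",
    "default_sec_run",
    "write_partial_h5",
    "read_partial_h5",
    "gaussian_profile",
    "DEFAULT_SPHERE_R",
    "DEFAULT_I0",
    "DEFAULT_BUFFER_LEVEL",
]

#: Default synthetic protein: sphere of radius 3 nm (Rg = sqrt(3/5)*3 ~ 2.324 nm)
DEFAULT_SPHERE_R = 3.0
DEFAULT_I0 = 100.0
DEFAULT_BUFFER_LEVEL = 50.0


@dataclass(frozen=True)
class GroundTruth:
    """Known parameters of a synthetic sample."""

    model: str                      # sphere | gaussian_chain | guinier
    Rg: float                       # nm
    I0: float
    Dmax: float                     # nm (sphere: 2R)
    buffer_level: float = 0.0
    exposure: float = np.inf
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.Rg <= 0 or self.Dmax <= 0:
            raise ValueError("sizes must be positive")


def sphere_intensity(q: np.ndarray, R: float, I0: float = 1.0) -> np.ndarray:
    """Form factor of a homogeneous sphere of radius R (nm).

    I(q) = I0 * [3 (sin(qR) - qR cos(qR)) / (qR)^3]^2, with the q -> 0
    limit I(0) = I0 taken by series expansion.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    q = np.asarray(q, dtype=float)
    x = q * R
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    small = x < 1e-4
    if np.any(small):
        xs = x[small]
        # 3(sin x - x cos x)/x^3 = 1 - x^2/10 + O(x^4)
        amp = np.asarray(amp)
        amp[small] = 1.0 - xs**2 / 10.0
    return I0 * amp**2


def gaussian_chain_intensity(q: np.ndarray, Rg: float, I0: float = 1.0) -> np.ndarray:
    """Debye form factor of a Gaussian chain: I = I0 * 2(e^-x - 1 + x)/x^2, x = (q Rg)^2."""
    if Rg <= 0:
        raise ValueError("Rg must be positive")
    q = np.asarray(q, dtype=float)
    x = (q * Rg) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 2.0 * (np.expm1(-x) + x) / x**2
    small = x < 1e-6
    if np.any(small):
        out = np.asarray(out)
        out[small] = 1.0 - x[small] / 3.0
    return I0 * out


def guinier_intensity(q: np.ndarray, Rg: float, I0: float = 1.0) -> np.ndarray:
    """Pure Guinier law I = I0 exp(-(q Rg)^2 / 3) over the whole q range."""
    if Rg <= 0:
        raise ValueError("Rg must be positive")
    return I0 * np.exp(-(np.asarray(q, dtype=float) * Rg) ** 2 / 3.0)


def sphere_pddf(r: np.ndarray, R: float, I0: float = 1.0) -> np.ndarray:
    """Analytic pair-distance distribution of a homogeneous sphere.

    p(r) ∝ r^2 (1 - 3r/(4R) + r^3/(16 R^3)) on [0, 2R], normalized so that
    4*pi*∫p dr = I0, matching the forward-transform convention used by the
    BIFT module.
    """
    r = np.asarray(r, dtype=float)
    shape = np.where(
        (r >= 0) & (r <= 2 * R),
        r**2 * (1.0 - 3.0 * r / (4.0 * R) + r**3 / (16.0 * R**3)),
        0.0,
    )
    # ∫0^2R shape dr = (8/3 - 3 + 4/10? ) R^3 ... integrate analytically:
    # ∫ r^2 dr = 8R^3/3 ; ∫ 3r^3/(4R) dr = 3*(2R)^4/(16R) = 3R^3
    # ∫ r^5/(16R^3) dr = (2R)^6/(96 R^3) = (2/3) R^3  -> total = R^3/3
    norm = R**3 / 3.0
    return I0 / (4.0 * np.pi) * shape / norm


def add_noise(curve: ScatteringCurve, exposure: float, seed: int) -> ScatteringCurve:
    """Apply Poisson counting noise at the given exposure (photons per
    intensity unit).

    Counts are drawn as Poisson(exposure * I) and scaled back; sigma is
    sqrt(counts)/exposure with a floor of 1/exposure on zero-count bins.
    """
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    rng = np.random.default_rng(seed)
    lam = np.clip(curve.I, 0, None) * exposure
    counts = rng.poisson(lam).astype(float)
    I = counts / exposure
    sigma = np.sqrt(np.maximum(counts, 1.0)) / exposure
    return ScatteringCurve(curve.q, I, sigma, dict(curve.metadata))


def default_geometry(shape: tuple[int, int] = (128, 128),
                     wavelength: float = 0.1,
                     distance: float = 2000.0,
                     pixel_size: float = 0.5,
                     mask: np.ndarray | None = None) -> Geometry:
    """A small, fast detector geometry with the beam in the image centre.

    Defaults give a corner q of roughly 4.5 nm^-1 at 0.1 nm wavelength
    (12.4 keV), comparable to a BioSAXS setup scaled down for testing.
    """
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    return Geometry(wavelength, distance, center, pixel_size, shape, mask)


def make_frames(truth: GroundTruth, geometry: Geometry, n_frames: int,
                monitor_values: Sequence[float], seed: int | None = 0,
                model_intensity=None, noise: bool = True) -> FrameStack:
    """Simulate a stack of detector frames for one sample.

    Pixel counts are Poisson-distributed around ``monitor_k * I(q(pixel))``
    where q(pixel) follows from the geometry; masked pixels are zero.
    With ``noise=False`` the expected (float) counts are returned, which
    the commutation tests rely on.
    """
    monitor = np.asarray(monitor_values, dtype=float)
    if monitor.shape != (n_frames,):
        raise ValueError("monitor_values must have length n_frames")
    if np.any(monitor <= 0):
        raise ValueError("monitor values must be positive")
    qmap = geometry.q_map()
    if model_intensity is None:
        def model_intensity(q):
            return truth.buffer_level + sphere_intensity(q, truth.Dmax / 2.0, truth.I0)
    expected = model_intensity(qmap.ravel()).reshape(qmap.shape)
    if geometry.mask is not None:
        expected = np.where(geometry.mask, 0.0, expected)
    frames = np.empty((n_frames,) + tuple(geometry.shape), dtype=float)
    rng = np.random.default_rng(seed)
    for k in range(n_frames):
        lam = monitor[k] * expected
        frames[k] = rng.poisson(lam) if noise else lam
    if noise:
        frames = frames.astype(np.int64)
    return FrameStack(frames, monitor, geometry)


# ---------------------------------------------------------------------------
# SEC-SAXS run simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartialChromatogram:
    """One acquisition file of a SEC-SAXS run: a block of integrated curves."""

    frame_ids: np.ndarray     # global frame indices of the rows
    q: np.ndarray
    I: np.ndarray             # (n_frames_in_file, n_q)
    sigma: np.ndarray         # same shape

    def __post_init__(self) -> None:
        if self.I.shape != (len(self.frame_ids), len(self.q)):
            raise ValueError("intensity block shape mismatch")
        if self.sigma.shape != self.I.shape:
            raise ValueError("sigma block shape mismatch")


def write_partial_h5(partial: PartialChromatogram, path) -> None:
    """Write one partial-chromatogram acquisition file."""
    import h5py

    with h5py.File(path, "w") as h5:
        g = h5.create_group("entry/chromatogram")
        g.attrs["NX_class"] = "NXdata"
        g.create_dataset("frame_ids", data=partial.frame_ids, track_times=False)
        g.create_dataset("q", data=partial.q, track_times=False)
        g.create_dataset("I", data=partial.I, track_times=False)
        g.create_dataset("sigma", data=partial.sigma, track_times=False)


def read_partial_h5(path) -> PartialChromatogram:
    import h5py

    with h5py.File(path, "r") as h5:
        g = h5["entry/chromatogram"]
        return PartialChromatogram(
            frame_ids=g["frame_ids"][()], q=g["q"][()],
            I=g["I"][()], sigma=g["sigma"][()],
        )


def gaussian_profile(n_frames: int, center: float, width: float,
                     amplitude: float = 1.0) -> np.ndarray:
    t = np.arange(n_frames)
    return amplitude * np.exp(-0.5 * ((t - center) / width) ** 2)


def make_sec_run(components: Sequence[ScatteringCurve],
                 elution_profiles: np.ndarray,
                 buffer_curve: ScatteringCurve,
                 n_frames: int = 1000,
                 exposure: float = 10.0,
                 missing_blocks: Sequence[int] = (),
                 seed: int = 7,
                 frames_per_file: int = 100) -> tuple[list[PartialChromatogram], GroundTruth]:
    """Simulate a SEC-SAXS acquisition as partial chromatogram files.

    Frame i carries ``buffer + sum_c profile_c(i) * spectrum_c`` with
    Poisson noise at the given exposure.  Frames are grouped into files of
    ``frames_per_file`` (matching typical beamline acquisitions of 1000
    frames in ten files); block indices in ``missing_blocks`` are omitted,
    emulating lost acquisition files.
    """
    profiles = np.atleast_2d(np.asarray(elution_profiles, dtype=float))
    if profiles.shape != (len(components), n_frames):
        raise ValueError("need one elution profile of length n_frames per component")
    if np.any(profiles < 0):
        raise ValueError("elution profiles must be non-negative")
    q = buffer_curve.q
    for c in components:
        if c.q.shape != q.shape or not np.array_equal(c.q, q):
            raise ValueError("components and buffer must share one q grid")
    spectra = np.vstack([c.I for c in components]) if components else np.zeros((0, q.size))
    clean = buffer_curve.I[None, :] + profiles.T @ spectra   # (n_frames, n_q)

    rng = np.random.default_rng(seed)
    counts = rng.poisson(np.clip(clean, 0, None) * exposure).astype(float)
    I = counts / exposure
    sigma = np.sqrt(np.maximum(counts, 1.0)) / exposure

    missing = set(int(b) for b in missing_blocks)
    partials: list[PartialChromatogram] = []
    for block, start in enumerate(range(0, n_frames, frames_per_file)):
        if block in missing:
            continue
        stop = min(start + frames_per_file, n_frames)
        ids = np.arange(start, stop)
        partials.append(PartialChromatogram(ids, q, I[start:stop], sigma[start:stop]))

    truth = GroundTruth(
        model="sec_run", Rg=1.0, I0=1.0, Dmax=1.0,
        buffer_level=float(np.mean(buffer_curve.I)), exposure=exposure, seed=seed,
        extras={
            "n_frames": n_frames,
            "profiles": profiles,
            "spectra": spectra,
            "buffer_I": buffer_curve.I.copy(),
            "missing_blocks": sorted(missing),
        },
    )
    return partials, truth


def default_sec_run(seed: int = 7, n_frames: int = 1000,
                    missing_blocks: Sequence[int] = ()) -> tuple[list[PartialChromatogram], GroundTruth, dict]:
    """The default two-component SEC-SAXS simulation.

    Two globular components (spheres of radius 3 nm and 1.5 nm) elute as
    Gaussian peaks at 35% and 65% of the run with a width of 3% of the
    run length (frames 350 and 650, width 30, for the default 1000-frame
    acquisition), over a flat buffer background; the exposure gives a
    peak-channel signal-to-noise of ~25.  Returns the partial files, the ground truth and a dict of
    per-component truths (Rg, Dmax, elution center).
    """
    q = np.linspace(0.05, 4.0, 200)
    R1, R2 = 3.0, 1.5
    comp1 = ScatteringCurve(q, sphere_intensity(q, R1, DEFAULT_I0))
    comp2 = ScatteringCurve(q, sphere_intensity(q, R2, DEFAULT_I0 * 0.6))
    buffer_curve = ScatteringCurve(q, np.full_like(q, DEFAULT_BUFFER_LEVEL))
    centers = (0.35 * n_frames, 0.65 * n_frames)
    width = 0.03 * n_frames
    profiles = np.vstack([
        gaussian_profile(n_frames, centers[0], width, 1.0),
        gaussian_profile(n_frames, centers[1], width, 1.0),
    ])
    partials, truth = make_sec_run(
        [comp1, comp2], profiles, buffer_curve,
        n_frames=n_frames, exposure=10.0, missing_blocks=missing_blocks, seed=seed,
    )
    info = {
        "components": [
            {"R": R1, "Rg": np.sqrt(3.0 / 5.0) * R1, "Dmax": 2 * R1, "center": centers[0]},
            {"R": R2, "Rg": np.sqrt(3.0 / 5.0) * R2, "Dmax": 2 * R2, "center": centers[1]},
        ],
        "width": width,
        "buffer_level": DEFAULT_BUFFER_LEVEL,
    }
    return partials, truth, info
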