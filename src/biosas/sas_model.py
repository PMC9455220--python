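"""Core domain types and I/O for small-angle scattering data.

The types defined here are shared by every analysis module:

* :class:`ScatteringCurve` — a reduced 1D datum ``(q, I, sigma)``.
* :class:`Geometry` — detector geometry for azimuthal integration.
* :class:`FrameStack` — a stack of 2D detector frames with per-frame
  beam-stop diode (monitor) readings.
* :class:`JobDescription` — a JSON-serializable processing job.

All q values are handled internally in inverse nanometres.  Readers accept
a declared unit (``nm^-1`` or ``angstrom^-1``) and convert on load, which
avoids silent factor-of-ten confusion between conventions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import h5py
import numpy as np
from pydantic import BaseModel, Field, field_validator

__all__ = [
    "ScatteringCurve",
    "Geometry",
    "FrameStack",
    "JobDescription",
    "SCHEMA_VERSION",
    "read_dat",
    "write_dat",
    "write_result_h5",
    "read_curve_h5",
]

#: Version of the JSON job schema understood by this package.
SCHEMA_VERSION = "1.0"

_UNIT_FACTORS = {"nm^-1": 1.0, "angstrom^-1": 10.0, "a^-1": 10.0, "1/nm": 1.0, "1/angstrom": 10.0}


@dataclass(frozen=True)
class ScatteringCurve:
    """A reduced scattering curve I(q) with optional 1-sigma uncertainties.

    Parameters
    ----------
    q:
        Scattering-vector magnitudes in inverse nanometres, strictly
        increasing, non-negative.  ``q = 4*pi*sin(theta)/lambda`` with
        ``2*theta`` the scattering angle.
    I:
        Intensities in arbitrary (normalized) units.
    sigma:
        1-sigma uncertainties on ``I``.  May be ``None`` only for
        synthetic noiseless curves.
    metadata:
        Free-text key/value metadata (sample name, concentration, ...).
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        I = np.asarray(self.I, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "I", I)
        if q.ndim != 1 or I.shape != q.shape:
            raise ValueError("q and I must be 1D arrays of equal length")
        if np.any(np.isnan(q)):
            raise ValueError("NaN forbidden in q")
        if q.size and (np.any(q < 0) or np.any(np.diff(q) <= 0)):
            raise ValueError("q must be non-negative and strictly increasing")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(s[~np.isnan(s)] < 0):
                raise ValueError("sigma must be non-negative")

    def __len__(self) -> int:
        return int(self.q.size)

    def restrict(self, qmin: float = -np.inf, qmax: float = np.inf) -> "ScatteringCurve":
        """Return the sub-curve with qmin <= q <= qmax."""
        m = (self.q >= qmin) & (self.q <= qmax)
        return ScatteringCurve(
            self.q[m], self.I[m], None if self.sigma is None else self.sigma[m],
            dict(self.metadata),
        )

    def scaled(self, factor: float) -> "ScatteringCurve":
        """Return the curve with I (and sigma) multiplied by ``factor``."""
        return ScatteringCurve(
            self.q, self.I * factor,
            None if self.sigma is None else self.sigma * factor,
            dict(self.metadata),
        )


@dataclass(frozen=True)
class Geometry:
    """Normal-incidence detector geometry.

    wavelength is in nm, sample_detector_distance and pixel_size in mm,
    beam_center in (row, col) pixel coordinates.  ``mask`` marks invalid
    pixels with True.
    """

    wavelength: float
    sample_detector_distance: float
    beam_center: tuple[float, float]
    pixel_size: float
    shape: tuple[int, int]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.wavelength <= 0 or self.sample_detector_distance <= 0 or self.pixel_size <= 0:
            raise ValueError("wavelength, distance and pixel size must be positive")
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            object.__setattr__(self, "mask", m)
            if m.shape != tuple(self.shape):
                raise ValueError("mask shape must equal frame shape")

    def q_map(self) -> np.ndarray:
        """Per-pixel q magnitude (nm^-1) in the small-angle flat-detector
        approximation q = (4*pi/lambda) * sin(atan(r/D)/2)."""
        rows = np.arange(self.shape[0])[:, None] - self.beam_center[0]
        cols = np.arange(self.shape[1])[None, :] - self.beam_center[1]
        r_mm = np.hypot(rows, cols) * self.pixel_size
        theta2 = np.arctan2(r_mm, self.sample_detector_distance)
        return (4.0 * np.pi / self.wavelength) * np.sin(0.5 * theta2)


@dataclass(frozen=True)
class FrameStack:
    """A stack of detector frames plus per-frame monitor readings.

    ``frames`` holds non-negative counts with axes (frame, row, col);
    ``monitor`` holds one positive beam-stop diode intensity per frame,
    used as the statistical weight when frames are averaged.
    """

    frames: np.ndarray
    monitor: np.ndarray
    geometry: Geometry
    frame_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        monitor = np.asarray(self.monitor, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "monitor", monitor)
        if frames.ndim != 3:
            raise ValueError("frames must be 3D (frame, row, col)")
        if monitor.shape != (frames.shape[0],):
            raise ValueError("need one monitor value per frame")
        if np.any(monitor <= 0):
            raise ValueError("monitor must be positive for every frame")
        if np.any(frames < 0):
            raise ValueError("counts must be non-negative")
        if frames.shape[1:] != tuple(self.geometry.shape):
            raise ValueError("frame shape differs from geometry shape")
        if self.frame_ids is None:
            object.__setattr__(self, "frame_ids", np.arange(frames.shape[0]))
        else:
            ids = np.asarray(self.frame_ids, dtype=int)
            object.__setattr__(self, "frame_ids", ids)
            if ids.shape != (frames.shape[0],):
                raise ValueError("frame_ids must match the number of frames")

    def __len__(self) -> int:
        return int(self.frames.shape[0])


class JobDescription(BaseModel):
    """A serializable description of one processing job.

    Replaying the same description on the same inputs is bit-reproducible;
    the JSON form is stored alongside every result for provenance.
    """

    schema_version: str = SCHEMA_VERSION
    pipeline: str
    input_paths: list[str] = Field(default_factory=list)
    sample_name: str = ""
    concentration_mg_ml: float | None = None
    buffer_description: str = ""
    parameters: dict[str, Any] = Field(default_factory=dict)
    output_path: str = ""

    @field_validator("pipeline")
    @classmethod
    def _known_pipeline(cls, v: str) -> str:
        if not v:
            raise ValueError("pipeline name must be non-empty")
        return v

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    @classmethod
    def from_json(cls, text: str) -> "JobDescription":
        obj = json.loads(text)
        version = obj.get("schema_version", "<missing>")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"job schema_version {version!r} not supported "
                f"(this package understands {SCHEMA_VERSION!r})"
            )
        return cls.model_validate(obj)


# ---------------------------------------------------------------------------
# Three-column ASCII I/O
# ---------------------------------------------------------------------------

def read_dat(path: str | Path, unit: str | None = None) -> ScatteringCurve:
    """Read a three-column ASCII scattering file (q, I, sigma).

    Lines starting with ``#`` are kept as free-text header metadata.
    Two-column files yield a curve without uncertainties.  A declared
    q unit in the header (``# q_unit: angstrom^-1``) or via ``unit``
    converts q to the internal nm^-1 convention.
    """
    path = Path(path)
    header_lines: list[str] = []
    rows: list[list[float]] = []
    ncols: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                header_lines.append(line.lstrip("#").strip())
                continue
            parts = line.split()
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric data") from exc
            if len(values) not in (2, 3):
                raise ValueError(f"{path}: line {lineno}: expected 2 or 3 columns")
            if ncols is None:
                ncols = len(values)
            elif len(values) != ncols:
                raise ValueError(f"{path}: line {lineno}: inconsistent column count")
            if ncols == 3 and values[2] < 0:
                raise ValueError(f"{path}: line {lineno}: negative sigma")
            rows.append(values)

    meta: dict[str, Any] = {"header": header_lines}
    declared = unit
    for h in header_lines:
        if ":" in h:
            key, _, val = h.partition(":")
            if key.strip().lower() in ("q_unit", "unit"):
                declared = val.strip()
    factor = 1.0
    if declared is not None:
        try:
            factor = _UNIT_FACTORS[declared.lower()]
        except KeyError:
            raise ValueError(f"unknown q unit {declared!r}") from None
        meta["q_unit_declared"] = declared

    if not rows:
        return ScatteringCurve(np.empty(0), np.empty(0), np.empty(0), meta)
    arr = np.asarray(rows, dtype=float)
    q = arr[:, 0] * factor
    if np.any(np.diff(q) <= 0):
        raise ValueError(f"{path}: q values are not strictly increasing")
    sigma = arr[:, 2] if arr.shape[1] == 3 else None
    return ScatteringCurve(q, arr[:, 1], sigma, meta)


def write_dat(curve: ScatteringCurve, path: str | Path) -> None:
    """Write a curve as three-column ASCII with a ``#`` comment header.

    Values are written in scientific notation with 17 significant digits,
    so a read/write roundtrip is lossless at double precision.
    """
    path = Path(path)
    lines = ["# biosas scattering curve", "# q_unit: nm^-1"]
    for key, val in curve.metadata.items():
        if key in ("header", "q_unit_declared"):
            continue
        lines.append(f"# {key}: {val}")
    cols = "q  I  sigma" if curve.sigma is not None else "q  I"
    lines.append(f"# columns: {cols}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for i in range(len(curve)):
            if curve.sigma is not None:
                fh.write(f"{curve.q[i]:.16e} {curve.I[i]:.16e} {curve.sigma[i]:.16e}\n")
            else:
                fh.write(f"{curve.q[i]:.16e} {curve.I[i]:.16e}\n")


# ---------------------------------------------------------------------------
# HDF5 result container
# ---------------------------------------------------------------------------

def _store(group: h5py.Group, key: str, value: Any) -> None:
    """Store one result entry under ``group``, recursing into mappings."""
    if value is None:
        return
    if isinstance(value, ScatteringCurve):
        sub = group.create_group(key)
        sub.attrs["NX_class"] = "NXdata"
        sub.attrs["signal"] = "I"
        sub.attrs["axes"] = "q"
        sub.create_dataset("q", data=curve_array(value.q), track_times=False)
        sub.create_dataset("I", data=curve_array(value.I), track_times=False)
        if value.sigma is not None:
            sub.create_dataset("errors", data=curve_array(value.sigma), track_times=False)
        return
    if isinstance(value, Mapping):
        sub = group.create_group(key)
        for k, v in value.items():
            _store(sub, str(k), v)
        return
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        _store(group, key, _dataclass_dict(value))
        return
    if isinstance(value, np.ndarray):
        group.create_dataset(key, data=value, track_times=False)
        return
    if isinstance(value, (bool, np.bool_)):
        group.attrs[key] = bool(value)
        return
    if isinstance(value, (int, float, np.integer, np.floating)):
        group.attrs[key] = value
        return
    if isinstance(value, str):
        group.attrs[key] = value
        return
    if isinstance(value, (list, tuple)):
        try:
            group.create_dataset(key, data=np.asarray(value), track_times=False)
        except (TypeError, ValueError):
            group.attrs[key] = json.dumps([str(v) for v in value])
        return
    group.attrs[key] = str(value)


def _dataclass_dict(obj: Any) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        out[f.name] = getattr(obj, f.name)
    return out


def curve_array(a: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(a, dtype=np.float64)


def write_result_h5(result_bundle: Mapping[str, Any], path: str | Path,
                    job: JobDescription | None = None,
                    input_paths: Iterable[str] = (),
                    default_plot: str | None = None) -> None:
    """Write a pipeline result bundle to an HDF5 file.

    The bundle maps stage names to dictionaries of outputs; each stage
    becomes one NXprocess-like group holding a machine-readable copy of
    its configuration (under ``configuration``) plus its outputs, so any
    result can be reprocessed from the stored parameters alone.  A stage
    that failed carries an ``error`` attribute instead of outputs.  Raw
    inputs are recorded as stored path strings rather than external
    links, which keeps result files portable.
    """
    path = Path(path)
    with h5py.File(path, "w", track_order=False) as h5:
        h5.attrs["NX_class"] = "NXroot"
        h5.attrs["creator"] = "biosas"
        entry = h5.create_group("entry")
        entry.attrs["NX_class"] = "NXentry"
        prov = entry.create_group("provenance")
        prov.attrs["NX_class"] = "NXnote"
        paths = list(input_paths)
        if paths:
            prov.create_dataset(
                "input_paths", data=np.array(paths, dtype=h5py.string_dtype()),
                track_times=False,
            )
        if job is not None:
            prov.create_dataset(
                "job_json", data=job.to_json(), track_times=False,
            )
        if default_plot is not None:
            entry.attrs["default"] = default_plot
        for i, (stage, payload) in enumerate(result_bundle.items()):
            g = entry.create_group(stage)
            g.attrs["NX_class"] = "NXprocess"
            g.attrs["sequence_index"] = i
            if not isinstance(payload, Mapping):
                payload = {"value": payload}
            config = payload.get("configuration", {})
            cfg = g.create_group("configuration")
            cfg.attrs["NX_class"] = "NXcollection"
            cfg.attrs["json"] = json.dumps(config, default=str, sort_keys=True)
            if "error" in payload:
                g.attrs["error"] = str(payload["error"])
            for key, value in payload.items():
                if key in ("configuration", "error"):
                    continue
                _store(g, key, value)


def write_frames_h5(stack: FrameStack, path: str | Path) -> None:
    """Write a frame stack with its geometry and monitor values to HDF5,
    emulating a multi-frame acquisition file."""
    geo = stack.geometry
    with h5py.File(path, "w") as h5:
        entry = h5.create_group("entry")
        entry.attrs["NX_class"] = "NXentry"
        data = entry.create_group("data")
        data.attrs["NX_class"] = "NXdata"
        data.create_dataset("frames", data=stack.frames, track_times=False)
        data.create_dataset("monitor", data=stack.monitor, track_times=False)
        data.create_dataset("frame_ids", data=stack.frame_ids, track_times=False)
        g = entry.create_group("geometry")
        g.attrs["wavelength_nm"] = geo.wavelength
        g.attrs["distance_mm"] = geo.sample_detector_distance
        g.attrs["beam_center"] = geo.beam_center
        g.attrs["pixel_size_mm"] = geo.pixel_size
        g.attrs["shape"] = geo.shape
        if geo.mask is not None:
            g.create_dataset("mask", data=geo.mask, track_times=False)


def read_frames_h5(path: str | Path) -> FrameStack:
    """Read back a frame stack written by :func:`write_frames_h5`."""
    with h5py.File(path, "r") as h5:
        g = h5["entry/geometry"]
        mask = g["mask"][()] if "mask" in g else None
        geo = Geometry(
            wavelength=float(g.attrs["wavelength_nm"]),
            sample_detector_distance=float(g.attrs["distance_mm"]),
            beam_center=tuple(g.attrs["beam_center"]),
            pixel_size=float(g.attrs["pixel_size_mm"]),
            shape=tuple(int(v) for v in g.attrs["shape"]),
            mask=mask,
        )
        data = h5["entry/data"]
        return FrameStack(
            frames=data["frames"][()],
            monitor=data["monitor"][()],
            geometry=geo,
            frame_ids=data["frame_ids"][()],
        )


def read_curve_h5(path: str | Path, dataset: str) -> ScatteringCurve:
    """Read back a curve stored by :func:`write_result_h5` (NXdata group)."""
    with h5py.File(path, "r") as h5:
        g = h5[dataset]
        sigma = g["errors"][()] if "errors" in g else None
        return ScatteringCurve(g["q"][()], g["I"][()], sigma)
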