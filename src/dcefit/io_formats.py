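"""Image and tabular I/O, ROI masks, preferences file, batch runner, reports.

Formats supported:

* NIfTI-1 (``.nii``/``.nii.gz``) and Analyze 7.5 (``.hdr``/``.img``) via
  nibabel — read and write;
* DICOM series directories via pydicom — read-only, frames ordered by
  acquisition time (never by filename);
* ImageJ ``.roi`` files (rectangle, oval, polygon, freehand subtypes) and
  label images as ROI masks;
* a ``key = value`` preferences text file for fit bounds and tolerances;
* CSV (canonical) and XLSX (convenience) results tables.

Every pipeline stage writes one plain-text RunReport naming inputs, the
configuration digest and the seed, so that two runs with identical
inputs + config + seed are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import struct
import time as _time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "DynamicSeries",
    "ROIMask",
    "PreferencesConfig",
    "RunReport",
    "read_dynamic_series",
    "write_parameter_map",
    "read_roi_mask",
    "read_imagej_roi",
    "load_preferences",
    "run_batch",
    "export_results_table",
]


@dataclass
class DynamicSeries:
    """4-D dynamic acquisition: voxels (x, y, z, t) plus timing metadata."""

    voxels: np.ndarray
    frame_times: np.ndarray  # seconds from acquisition start
    tr_ms: float | None = None
    te_ms: float | None = None
    flip_angle_deg: float | None = None
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    source_format: str = "nifti"

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be 4-D (x, y, z, t)")
        if len(self.frame_times) != self.voxels.shape[-1]:
            raise ValueError("frame_times length must equal the t dimension")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame times must be strictly increasing")

    def require_kinetic_metadata(self):
        missing = [
            n
            for n, v in (("tr_ms", self.tr_ms), ("flip_angle_deg", self.flip_angle_deg))
            if v is None
        ]
        if missing:
            raise ValueError(f"metadata required for kinetic fitting missing: {missing}")


@dataclass
class ROIMask:
    """Integer label volume (0 = background) with optional label names."""

    labels: np.ndarray
    label_names: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if np.any(self.labels < 0):
            raise ValueError("labels must be >= 0")
        for lab in np.unique(self.labels):
            if lab != 0 and int(lab) not in self.label_names:
                self.label_names[int(lab)] = f"roi_{int(lab)}"


@dataclass
class PreferencesConfig:
    """Fit bounds, multistart values, tolerances and execution settings."""

    bounds: dict = field(default_factory=dict)  # param -> (lower, upper)
    ktrans_starts: tuple = (0.005, 0.05, 0.5, 2.0)
    func_tol: float = 1e-8
    param_tol: float = 1e-8
    max_iterations: int = 500
    n_jobs: int = 1
    seed: int = 0

    def __post_init__(self):
        from .fitting_selection import DEFAULT_BOUNDS

        merged = dict(DEFAULT_BOUNDS)
        merged.update(self.bounds)
        for name, (lo, hi) in merged.items():
            if lo > hi:
                raise ValueError(f"bound for {name}: lower {lo} > upper {hi}")
        self.bounds = merged
        if len(self.ktrans_starts) == 0:
            raise ValueError("multistart list must be non-empty")

    def digest(self):
        text = repr(sorted(dataclasses.asdict(self).items()))
        return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    module: str
    input_paths: list = field(default_factory=list)
    output_paths: list = field(default_factory=list)
    config_digest: str = ""
    seed: int | None = None
    messages: list = field(default_factory=list)
    started: float = field(default_factory=_time.time)

    def log(self, msg):
        self.messages.append(msg)

    def write(self, path):
        lines = [
            f"module: {self.module}",
            f"started: {_time.strftime('%Y-%m-%dT%H:%M:%S', _time.localtime(self.started))}",
            f"finished: {_time.strftime('%Y-%m-%dT%H:%M:%S')}",
            f"config_digest: {self.config_digest}",
            f"seed: {self.seed}",
            "inputs:",
            *[f"  - {p}" for p in self.input_paths],
            "outputs:",
            *[f"  - {p}" for p in self.output_paths],
            "messages:",
            *[f"  - {m}" for m in self.messages],
        ]
        Path(path).write_text("\n".join(lines) + "\n")
        return path


# ---------------------------------------------------------------------------
# image I/O


def _read_dicom_series(path):
    import pydicom

    files = sorted(p for p in Path(path).iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # non-DICOM files in the directory are skipped
        if not hasattr(ds, "pixel_array"):
            continue
        slices.append(ds)
    if not slices:
        raise OSError(f"no readable DICOM files in {path}")
    shapes = {s.pixel_array.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent DICOM series: mixed dimensions {shapes}")

    def acq_time(ds):
        t = getattr(ds, "AcquisitionTime", None)
        if t is None:
            return None
        t = str(t)
        h, m = float(t[0:2]), float(t[2:4])
        s = float(t[4:]) if len(t) > 4 else 0.0
        return 3600 * h + 60 * m + s

    def z_pos(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        return float(ipp[2]) if ipp is not None else 0.0

    times = [acq_time(s) for s in slices]
    if any(t is None for t in times):
        raise ValueError("metadata error: DICOM series lacks AcquisitionTime tags")
    t_values = sorted(set(times))
    z_values = sorted({z_pos(s) for s in slices})
    ny, nx = slices[0].pixel_array.shape
    vol = np.full((nx, ny, len(z_values), len(t_values)), np.nan)
    for ds, t in zip(slices, times):
        it = t_values.index(t)
        iz = z_values.index(z_pos(ds))
        vol[:, :, iz, it] = ds.pixel_array.T.astype(float)
    if np.any(np.isnan(vol)):
        raise ValueError("inconsistent DICOM series: missing slice/time combinations")
    first = slices[0]
    spacing = getattr(first, "PixelSpacing", [1.0, 1.0])
    dz = float(getattr(first, "SliceThickness", 1.0))
    vox = (float(spacing[1]), float(spacing[0]), dz)
    affine = np.diag([*vox, 1.0])  # canonical axis-aligned RAS-like geometry
    return DynamicSeries(
        vol,
        np.asarray(t_values) - t_values[0],
        tr_ms=float(getattr(first, "RepetitionTime", None) or 0) or None,
        te_ms=float(getattr(first, "EchoTime", None) or 0) or None,
        flip_angle_deg=float(getattr(first, "FlipAngle", None) or 0) or None,
        voxel_size_mm=vox,
        affine=affine,
        source_format="dicom",
    )


def read_dynamic_series(path, format_hint=None, frame_interval_s=None, **metadata):
    """Read a 4-D dynamic series from NIfTI/Analyze file(s) or a DICOM directory.

    NIfTI/Analyze store no frame timing, so ``frame_interval_s`` must be
    supplied (uniform spacing assumed); DICOM frame times come from the
    AcquisitionTime tags, sorted ascending regardless of file order.
    Acquisition metadata (``tr_ms``, ``te_ms``, ``flip_angle_deg``) can be
    passed as keyword overrides.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such path: {path}")
    fmt = format_hint
    if fmt is None:
        if path.is_dir():
            fmt = "dicom"
        elif path.suffix in (".hdr", ".img"):
            fmt = "analyze"
        else:
            fmt = "nifti"
    if fmt == "dicom":
        series = _read_dicom_series(path)
    else:
        try:
            img = nib.load(str(path))
        except Exception as exc:
            raise OSError(f"unreadable image file {path}: {exc}") from None
        data = np.asanyarray(img.dataobj).astype(float)
        if data.ndim == 3:
            data = data[..., None]
        if data.ndim != 4:
            raise ValueError(f"expected 3-D or 4-D image, got {data.ndim}-D")
        if frame_interval_s is None:
            if data.shape[-1] > 1:
                raise ValueError(
                    "metadata error: no frame timing in NIfTI/Analyze; "
                    "supply frame_interval_s"
                )
            frame_interval_s = 1.0
        zooms = img.header.get_zooms()[:3]
        series = DynamicSeries(
            data,
            frame_interval_s * np.arange(data.shape[-1]),
            voxel_size_mm=tuple(float(z) for z in zooms),
            affine=np.asarray(img.affine) if img.affine is not None else np.eye(4),
            source_format=fmt,
        )
    for key in ("tr_ms", "te_ms", "flip_angle_deg"):
        if key in metadata and metadata[key] is not None:
            setattr(series, key, metadata[key])
    return series


def write_parameter_map(values, path, reference, name="", units=""):
    """Write a 3-D parameter map as NIfTI with the reference geometry.

    NaN marks unfitted voxels and survives the round trip.
    """
    values = np.asarray(values, dtype=np.float64)
    ref_shape = reference.voxels.shape[:3] if hasattr(reference, "voxels") else reference.shape
    if values.shape != tuple(ref_shape):
        raise ValueError(f"map shape {values.shape} does not match reference {ref_shape}")
    affine = reference.affine if hasattr(reference, "affine") else np.eye(4)
    img = nib.Nifti1Image(values, affine)
    img.header.set_zooms(getattr(reference, "voxel_size_mm", (1.0, 1.0, 1.0)))
    if name or units:
        img.header["descrip"] = f"{name} [{units}]".encode()[:79]
    nib.save(img, str(path))
    return Path(path)


# ---------------------------------------------------------------------------
# ImageJ .roi


_ROI_TYPES = {0: "polygon", 1: "rect", 2: "oval", 7: "freehand"}


def read_imagej_roi(path):
    """Parse an ImageJ .roi file (rectangle, oval, polygon, freehand only).

    Returns ``(subtype, bbox, coords)`` where bbox = (top, left, bottom,
    right) and coords is an (n, 2) array of absolute (x, y) vertices for
    polygon/freehand subtypes, else None.
    """
    raw = Path(path).read_bytes()
    if raw[:4] != b"Iout":
        raise ValueError(f"not an ImageJ .roi file: {path}")
    roi_type = raw[6]
    if roi_type not in _ROI_TYPES:
        raise ValueError(f"unsupported ImageJ roi subtype code {roi_type}")
    top, left, bottom, right, n_coords = struct.unpack(">5h", raw[8:18])
    coords = None
    if _ROI_TYPES[roi_type] in ("polygon", "freehand"):
        off = 64
        xs = np.frombuffer(raw[off : off + 2 * n_coords], dtype=">i2").astype(int) + left
        ys = np.frombuffer(
            raw[off + 2 * n_coords : off + 4 * n_coords], dtype=">i2"
        ).astype(int) + top
        coords = np.column_stack([xs, ys])
    return _ROI_TYPES[roi_type], (top, left, bottom, right), coords


def _rasterize_roi(subtype, bbox, coords, shape2d):
    """Pixel-center-inside rasterization onto an (nx, ny) grid."""
    top, left, bottom, right = bbox
    nx, ny = shape2d
    xs, ys = np.meshgrid(np.arange(nx) + 0.5, np.arange(ny) + 0.5, indexing="ij")
    if subtype == "rect":
        inside = (xs > left) & (xs < right) & (ys > top) & (ys < bottom)
    elif subtype == "oval":
        cx, cy = (left + right) / 2.0, (top + bottom) / 2.0
        rx, ry = (right - left) / 2.0, (bottom - top) / 2.0
        inside = ((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2 <= 1.0
    else:  # polygon / freehand
        from matplotlib.path import Path as MplPath

        poly = MplPath(coords)
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        inside = poly.contains_points(pts).reshape(nx, ny)
    return inside


def read_roi_mask(path, spatial_shape, label=1, slice_index=0):
    """Load an ROI mask from a label image or an ImageJ .roi file.

    Label images pass through (shape checked); a 2-D ImageJ ROI is
    rasterized onto slice ``slice_index`` of the voxel grid by the
    pixel-center containment rule.
    """
    path = Path(path)
    if path.suffix == ".roi":
        subtype, bbox, coords = read_imagej_roi(path)
        labels = np.zeros(spatial_shape, dtype=int)
        inside = _rasterize_roi(subtype, bbox, coords, spatial_shape[:2])
        labels[:, :, slice_index][inside] = label
        return ROIMask(labels, {label: path.stem})
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj)
    if labels.ndim == 4 and labels.shape[-1] == 1:
        labels = labels[..., 0]
    if labels.shape != tuple(spatial_shape):
        raise ValueError(f"ROI shape {labels.shape} does not match grid {spatial_shape}")
    labels = np.rint(labels).astype(int)
    if not np.any(labels > 0):
        warnings.warn("ROI mask is empty (all zero)")
    return ROIMask(labels)


# ---------------------------------------------------------------------------
# preferences file


_PREF_KEYS = {
    "tolerance.function": ("func_tol", float),
    "tolerance.param": ("param_tol", float),
    "max_iterations": ("max_iterations", int),
    "jobs": ("n_jobs", int),
    "seed": ("seed", int),
}


def load_preferences(path=None):
    """Parse a ``key = value`` preferences file into a PreferencesConfig.

    Recognised keys: ``<param>.lower`` / ``<param>.upper`` for the fit
    bounds, ``multistart.ktrans`` (comma-separated list), the tolerance and
    execution keys in ``_PREF_KEYS``.  Unknown keys warn but are not fatal;
    absent keys keep their defaults.
    """
    from .fitting_selection import DEFAULT_BOUNDS

    kwargs = {"bounds": {}}
    if path is not None:
        text = Path(path).read_text()
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                warnings.warn(f"line {lineno}: not a key = value pair, skipped")
                continue
            key, _, value = line.partition("=")
            key, value = key.strip().lower(), value.strip()
            try:
                if key in _PREF_KEYS:
                    attr, cast = _PREF_KEYS[key]
                    kwargs[attr] = cast(value)
                elif key == "multistart.ktrans":
                    kwargs["ktrans_starts"] = tuple(float(v) for v in value.split(","))
                elif key.endswith(".lower") or key.endswith(".upper"):
                    param, _, side = key.rpartition(".")
                    if param not in DEFAULT_BOUNDS:
                        warnings.warn(f"unknown parameter {param!r} in preferences")
                        continue
                    lo, hi = kwargs["bounds"].get(param, DEFAULT_BOUNDS[param])
                    val = float(value)
                    kwargs["bounds"][param] = (val, hi) if side == "lower" else (lo, val)
                else:
                    warnings.warn(f"unknown preferences key {key!r}")
            except ValueError as exc:
                raise ValueError(f"line {lineno}: cannot parse {key!r}: {exc}") from None
    return PreferencesConfig(**kwargs)


# ---------------------------------------------------------------------------
# batch execution and tables


def run_batch(jobs, output_dir, resume=False):
    """Execute fit jobs sequentially; one failure never aborts the rest.

    Each job is a mapping with ``name`` (unique), ``action`` (a callable
    executing the job; it should write the job's products) and optionally
    ``expected_outputs`` (paths; with ``resume`` the job is skipped when all
    already exist).  One RunReport per job is returned and written to
    ``output_dir``.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    reports = []
    for job in jobs:
        name = job["name"]
        report = RunReport(module=f"batch:{name}")
        expected = [Path(p) for p in job.get("expected_outputs", [])]
        if resume and expected and all(p.exists() for p in expected):
            report.log("skipped: outputs already exist (resume)")
            report.output_paths = [str(p) for p in expected]
        else:
            try:
                out = job["action"]()
                report.output_paths = [str(p) for p in (out or expected or [])]
                report.log("completed")
            except Exception as exc:
                report.log(f"FAILED: {type(exc).__name__}: {exc}")
        report.write(output_dir / f"report_{name}.txt")
        reports.append(report)
    return reports


def export_results_table(results, path, format="csv"):
    """Write per-ROI/per-voxel fit results as CSV (canonical) or XLSX.

    ``results`` is a DataFrame or list of records, one row per voxel/ROI x
    model.  NaN values render as empty cells in both formats.
    """
    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(list(results))
    if df.empty:
        raise ValueError("results table is empty")
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False, na_rep="")
    elif format == "xlsx":
        df.to_excel(path, index=False, na_rep="")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
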