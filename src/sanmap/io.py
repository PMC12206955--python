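"""Reading and writing of series, maps, label maps and histology.

Weighted series and parameter maps travel as NIfTI with a JSON sidecar
(frame timing lists are non-uniform, so they live in the sidecar rather than
the NIfTI time-axis spacing); histology is RGB TIFF; tables are CSV with
units embedded in the headers.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .phantom import (
    AcquisitionProtocol,
    Contrast,
    HistologySynth,
    LabelMap,
    WeightedSeries,
)
from .relaxometry import ParameterMap
from .tissues import Tissue

__all__ = [
    "save_series",
    "load_series",
    "save_map",
    "load_map",
    "save_labels",
    "load_labels",
    "save_histology",
    "load_histology",
    "sidecar_path",
]

_NIFTI_EXTS = (".nii", ".nii.gz")


def _check_ext(path: Path, exts: tuple[str, ...]) -> None:
    if not any(str(path).endswith(e) for e in exts):
        raise ValueError(f"unsupported extension for {path.name}; expected {exts}")


def sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for e in _NIFTI_EXTS:
        if name.endswith(e):
            return p.with_name(name[: -len(e)] + ".json")
    return p.with_suffix(".json")


def _affine(spacing_mm: float, slice_mm: float | None = None) -> np.ndarray:
    aff = np.diag([spacing_mm, spacing_mm, slice_mm or 1.0, 1.0])
    return aff


def save_series(path: str | Path, series: WeightedSeries) -> Path:
    """Write a WeightedSeries as 4D NIfTI (x, y[, z], frames) + JSON sidecar."""
    path = Path(path)
    _check_ext(path, _NIFTI_EXTS)
    data = np.moveaxis(series.images, 0, -1)  # frames last
    if data.ndim == 3:
        data = data[:, :, None, :]
    img = nib.Nifti1Image(data.astype(np.float64), _affine(series.spacing_mm))
    nib.save(img, str(path))
    proto = series.protocol
    meta = {
        "contrast": proto.contrast.value,
        "times_ms": list(proto.times_ms),
        "rf_amplitude_hz": proto.rf_amplitude_hz,
        "pulse_duration_ms": proto.pulse_duration_ms,
        "pulse_counts": list(proto.pulse_counts) if proto.pulse_counts else None,
        "sigma": series.sigma,
        "seed": series.seed,
        "spacing_mm": series.spacing_mm,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def load_series(path: str | Path) -> WeightedSeries:
    path = Path(path)
    _check_ext(path, _NIFTI_EXTS)
    sc = sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(
            f"series {path.name} is missing its protocol sidecar {sc.name}"
        )
    meta = json.loads(sc.read_text())
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if data.ndim == 4 and data.shape[2] == 1:
        data = data[:, :, 0, :]
    images = np.moveaxis(data, -1, 0)
    proto = AcquisitionProtocol(
        Contrast(meta["contrast"]),
        tuple(meta["times_ms"]),
        meta.get("rf_amplitude_hz"),
        meta.get("pulse_duration_ms"),
        tuple(meta["pulse_counts"]) if meta.get("pulse_counts") else None,
    )
    return WeightedSeries(
        images, proto, sigma=meta.get("sigma", 0.0), seed=meta.get("seed"),
        spacing_mm=meta.get("spacing_mm", 1.0),
    )


def save_map(path: str | Path, pmap: ParameterMap) -> Path:
    """Write a ParameterMap as 4D NIfTI stacking value/s0/R2/valid channels."""
    path = Path(path)
    _check_ext(path, _NIFTI_EXTS)
    grid = pmap.values.shape
    zeros = np.zeros(grid)
    chans = [
        pmap.values,
        pmap.s0 if pmap.s0 is not None else zeros,
        pmap.r_squared if pmap.r_squared is not None else zeros,
        pmap.valid.astype(float),
    ]
    data = np.stack(chans, axis=-1)
    if data.ndim == 3:
        data = data[:, :, None, :]
    img = nib.Nifti1Image(data.astype(np.float64), _affine(pmap.spacing_mm or 1.0))
    nib.save(img, str(path))
    meta = {
        "channels": ["value", "s0", "r_squared", "valid"],
        "units": pmap.units,
        "name": pmap.name,
        "spacing_mm": pmap.spacing_mm,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def load_map(path: str | Path) -> ParameterMap:
    path = Path(path)
    _check_ext(path, _NIFTI_EXTS)
    sc = sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"map {path.name} is missing its sidecar {sc.name}")
    meta = json.loads(sc.read_text())
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if data.ndim == 4 and data.shape[2] == 1:
        data = data[:, :, 0, :]
    return ParameterMap(
        values=data[..., 0],
        valid=data[..., 3] > 0.5,
        s0=data[..., 1],
        r_squared=data[..., 2],
        units=meta.get("units", ""),
        name=meta.get("name", ""),
        spacing_mm=meta.get("spacing_mm"),
    )


def save_labels(path: str | Path, labels: LabelMap) -> Path:
    path = Path(path)
    _check_ext(path, _NIFTI_EXTS)
    data = labels.labels.astype(np.int16)
    if data.ndim == 2:
        data = data[:, :, None]
    img = nib.Nifti1Image(
        data, _affine(labels.spacing_mm, labels.slice_thickness_mm)
    )
    nib.save(img, str(path))
    return path


def load_labels(path: str | Path) -> LabelMap:
    path = Path(path)
    _check_ext(path, _NIFTI_EXTS)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.int16)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    spacing = float(img.affine[0, 0])
    slice_mm = float(img.affine[2, 2]) if data.ndim == 3 else None
    return LabelMap(data, spacing, slice_mm)


def save_histology(path: str | Path, hist: HistologySynth) -> Path:
    path = Path(path)
    _check_ext(path, (".tif", ".tiff"))
    tifffile.imwrite(str(path), hist.rgb)
    meta = {
        "spacing_um": hist.spacing_um,
        "fractions": {Tissue(k).name: v for k, v in hist.fractions.items()},
        "seed": hist.seed,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def load_histology(path: str | Path) -> HistologySynth:
    path = Path(path)
    _check_ext(path, (".tif", ".tiff"))
    sc = sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(
            f"histology {path.name} is missing its sidecar {sc.name}"
        )
    meta = json.loads(sc.read_text())
    rgb = tifffile.imread(str(path))
    fractions = {Tissue[k]: v for k, v in meta["fractions"].items()}
    return HistologySynth(rgb, meta["spacing_um"], fractions, seed=meta.get("seed"))
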