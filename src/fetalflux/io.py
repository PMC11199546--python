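"""NIfTI and tidy-table I/O.

Image stacks are written as NIfTI (.nii.gz) in RAS orientation with the
pixel spacing in the header; acquisition metadata a NIfTI header cannot
carry (VENC, heart rate, preparation times, seed) goes in a JSON sidecar
next to the image with the same stem.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from .types import CineSeries, T2Series, ValidationError, VolumeSegmentation

__all__ = [
    "save_cine_series", "load_cine_series", "save_t2_series",
    "load_t2_series", "save_label_volume", "load_label_volume",
    "load_mask",
]


def _affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(spacing_mm) + [1.0])


def _to_nifti_axes(stack: np.ndarray) -> np.ndarray:
    # (frame, row, col) -> (x=col, y=row, z=frame): x fastest on disk
    return np.ascontiguousarray(np.transpose(stack, (2, 1, 0)))


def _from_nifti_axes(arr: np.ndarray) -> np.ndarray:
    return np.transpose(arr, (2, 1, 0))


def _sidecar_path(path: Path) -> Path:
    stem = path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return path.parent / (stem + ".json")


def save_cine_series(series: CineSeries, mag_path: Path, phase_path: Path,
                     seed: Optional[int] = None) -> None:
    mag_path, phase_path = Path(mag_path), Path(phase_path)
    sp = (series.pixel_spacing, series.pixel_spacing, series.slice_thickness)
    for stack, path in ((series.magnitude, mag_path), (series.phase, phase_path)):
        img = nib.Nifti1Image(_to_nifti_axes(stack), _affine(sp))
        img.header.set_zooms(sp)
        nib.save(img, str(path))
    meta = {"venc_cm_s": series.venc, "pixel_spacing_mm": series.pixel_spacing,
            "slice_thickness_mm": series.slice_thickness,
            "heart_rate_bpm": series.heart_rate, "n_phases": series.n_phases}
    if seed is not None:
        meta["seed"] = seed
    _sidecar_path(mag_path).write_text(json.dumps(meta, indent=2))


def load_cine_series(mag_path: Path, phase_path: Path,
                     venc: Optional[float] = None,
                     heart_rate: Optional[float] = None) -> CineSeries:
    mag_path, phase_path = Path(mag_path), Path(phase_path)
    sidecar = _sidecar_path(mag_path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    venc = venc if venc is not None else meta.get("venc_cm_s")
    if venc is None:
        raise ValidationError("VENC not given and no sidecar JSON found")
    heart_rate = heart_rate if heart_rate is not None \
        else meta.get("heart_rate_bpm", 140.0)

    mag_img = nib.load(str(mag_path))
    phase_img = nib.load(str(phase_path))
    spacing = float(mag_img.header.get_zooms()[0])
    thickness = float(mag_img.header.get_zooms()[2]) if mag_img.ndim >= 3 else 5.0
    return CineSeries(
        magnitude=_from_nifti_axes(np.asarray(mag_img.dataobj, dtype=float)),
        phase=_from_nifti_axes(np.asarray(phase_img.dataobj, dtype=float)),
        venc=float(venc), pixel_spacing=spacing, heart_rate=float(heart_rate),
        slice_thickness=thickness)


def save_t2_series(series: T2Series, path: Path,
                   spacing_mm: float = 1.3, seed: Optional[int] = None) -> None:
    path = Path(path)
    sp = (spacing_mm, spacing_mm, 6.0)
    img = nib.Nifti1Image(_to_nifti_axes(series.images), _affine(sp))
    img.header.set_zooms(sp)
    nib.save(img, str(path))
    meta = {"prep_times_ms": list(map(float, series.prep_times_ms))}
    if seed is not None:
        meta["seed"] = seed
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def load_t2_series(path: Path,
                   prep_times_ms: Optional[list[float]] = None) -> T2Series:
    path = Path(path)
    if prep_times_ms is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValidationError("prep times not given and no sidecar JSON")
        prep_times_ms = json.loads(sidecar.read_text())["prep_times_ms"]
    img = nib.load(str(path))
    return T2Series(images=_from_nifti_axes(np.asarray(img.dataobj, dtype=float)),
                    prep_times_ms=np.asarray(prep_times_ms, dtype=float))


def save_label_volume(seg: VolumeSegmentation, path: Path,
                      voxel_size_mm: tuple[float, float, float]) -> None:
    img = nib.Nifti1Image(np.asarray(seg.label_map, dtype=np.int16),
                          _affine(voxel_size_mm))
    img.header.set_zooms(voxel_size_mm)
    nib.save(img, str(Path(path)))


def load_label_volume(path: Path) -> VolumeSegmentation:
    img = nib.load(str(Path(path)))
    zooms = img.header.get_zooms()[:3]
    return VolumeSegmentation(label_map=np.asarray(img.dataobj, dtype=np.int16),
                              voxel_size_mm3=float(np.prod(zooms)))


def load_mask(path: Path) -> np.ndarray:
    """Load a 2-D boolean ROI mask from a NIfTI file (nonzero = inside)."""
    arr = np.asarray(nib.load(str(Path(path))).dataobj)
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ValidationError("expected a 2-D mask")
    return arr.T.astype(bool)   # x,y on disk -> row,col in memory
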