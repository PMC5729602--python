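"""Readers and writers for short-axis LV stacks.

Supported inputs: a DICOM series (one file per slice/frame), a NIfTI-1
volume (slices along the third axis, cine frames along the fourth), or a
directory of grayscale PNG/TIFF fixture images.  All readers return the
stack ordered base->apex with 0-based, row-major pixel indexing.  Results
are written as per-subject JSON (with provenance) or flat cohort CSV.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

MIN_SLICES = 3
MIN_DIM = 32

EdStrategy = Literal["first-frame", "max-pool-area"]


@dataclass
class SliceImage:
    """One end-diastolic short-axis slice.

    pixels are intensities in arbitrary units; pixel_spacing is (row, col)
    in mm; slice_index counts from the base (0 = most basal).
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_location: float | None = None
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError("slice pixels must be a 2-D array")
        if self.pixels.shape[0] < MIN_DIM or self.pixels.shape[1] < MIN_DIM:
            raise ValidationError(
                f"slice must be at least {MIN_DIM}x{MIN_DIM}, got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("slice intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValidationError("slice intensities must be non-negative")
        if not all(s > 0 for s in self.pixel_spacing):
            raise ValidationError("pixel spacing components must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class StackED:
    """End-diastolic stack of slices ordered base->apex."""

    slices: list[SliceImage]
    subject_id: str = "anonymous"
    ed_frame_index: int | list[int] = 0

    def __post_init__(self) -> None:
        if len(self.slices) < MIN_SLICES:
            raise ValidationError(
                f"a stack needs >= {MIN_SLICES} slices, got {len(self.slices)}"
            )
        idx = [s.slice_index for s in self.slices]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("slice_index must be strictly increasing base->apex")
        shapes = {s.shape for s in self.slices}
        if len(shapes) != 1:
            raise ValidationError(f"inconsistent in-plane dimensions: {shapes}")

    def __len__(self) -> int:
        return len(self.slices)


@dataclass
class CineSlice:
    """All cine frames of one slice position: array (n_frames, rows, cols)."""

    frames: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_location: float | None = None
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValidationError("cine frames must be a nonempty (f, r, c) array")


@dataclass
class CineStack:
    slices: list[CineSlice]
    subject_id: str = "anonymous"


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        logger.info("converting RGB fixture to grayscale via channel mean")
        arr = arr[..., :3].mean(axis=-1)
    return np.asarray(arr, dtype=float)


def _load_image_directory(path: Path) -> StackED:
    import imageio.v3 as iio

    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
    )
    if not files:
        raise InputError(f"no PNG/TIFF files found in {path}")
    slices = []
    for i, f in enumerate(files):
        try:
            arr = _to_grayscale(iio.imread(f))
        except Exception as exc:  # noqa: BLE001 - wrap reader faults uniformly
            raise InputError(f"could not read image {f}: {exc}") from exc
        slices.append(SliceImage(arr, slice_index=i))
    warnings.warn("image directory carries no pixel spacing; defaulting to 1.0 mm")
    return StackED(slices=slices, subject_id=path.name)


def _load_nifti(path: Path) -> StackED | CineStack:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001
        raise InputError(f"could not read NIfTI {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1])) if len(zooms) >= 2 else (1.0, 1.0)
    if spacing[0] <= 0 or spacing[1] <= 0:
        warnings.warn("NIfTI header lacks valid pixel spacing; defaulting to 1.0 mm")
        spacing = (1.0, 1.0)
    if data.ndim == 3:
        slices = [
            SliceImage(data[..., k], pixel_spacing=spacing, slice_index=k)
            for k in range(data.shape[2])
        ]
        return StackED(slices=slices, subject_id=path.stem)
    if data.ndim == 4:
        slices = [
            CineSlice(
                np.moveaxis(data[:, :, k, :], -1, 0),
                pixel_spacing=spacing,
                slice_index=k,
            )
            for k in range(data.shape[2])
        ]
        return CineStack(slices=slices, subject_id=path.stem)
    raise InputError(f"NIfTI volume must be 3-D or 4-D, got shape {data.shape}")


def _load_dicom_series(path: Path) -> StackED:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:  # noqa: BLE001 - skip non-DICOM files in the directory
            continue
        datasets.append(ds)
    if not datasets:
        raise InputError(f"no readable DICOM files in {path}")

    def sort_key(ds):
        if hasattr(ds, "SliceLocation"):
            return float(ds.SliceLocation)
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return int(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    slices = []
    for i, ds in enumerate(datasets):
        spacing = tuple(float(v) for v in getattr(ds, "PixelSpacing", (0, 0)))
        if not spacing or spacing[0] <= 0:
            warnings.warn("DICOM lacks PixelSpacing; defaulting to 1.0 mm")
            spacing = (1.0, 1.0)
        loc = float(ds.SliceLocation) if hasattr(ds, "SliceLocation") else None
        slices.append(
            SliceImage(
                ds.pixel_array.astype(float),
                pixel_spacing=spacing,
                slice_location=loc,
                slice_index=i,
            )
        )
    subject = str(getattr(datasets[0], "PatientID", path.name)) or path.name
    return StackED(slices=slices, subject_id=subject)


def load_stack(
    path: str | Path,
    format: Literal["dicom-series", "nifti", "image-directory"] | None = None,
    ed_strategy: EdStrategy = "first-frame",
) -> StackED:
    """Load a short-axis stack; cine inputs are reduced to end-diastole.

    When `format` is None it is inferred from the path (directory with
    images vs DICOM, or a .nii/.nii.gz file).  4-D NIfTI volumes are
    reduced to one frame per slice with `select_end_diastole(ed_strategy)`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"path does not exist: {path}")
    if format is None:
        if path.is_file() and path.name.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif path.is_dir():
            has_img = any(
                p.suffix.lower() in {".png", ".tif", ".tiff"} for p in path.iterdir()
            )
            format = "image-directory" if has_img else "dicom-series"
        else:
            raise InputError(f"cannot infer format for {path}")
    if format == "image-directory":
        return _load_image_directory(path)
    if format == "nifti":
        out = _load_nifti(path)
        if isinstance(out, CineStack):
            return select_end_diastole(out, strategy=ed_strategy)
        return out
    if format == "dicom-series":
        return _load_dicom_series(path)
    raise InputError(f"unknown format {format!r}")


def load_cine(path: str | Path) -> CineStack:
    """Load a 4-D NIfTI volume keeping the full cine frame axis."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"path does not exist: {path}")
    out = _load_nifti(path)
    if isinstance(out, StackED):
        # single-frame volume: wrap each slice as a one-frame cine
        return CineStack(
            slices=[
                CineSlice(
                    s.pixels[None],
                    pixel_spacing=s.pixel_spacing,
                    slice_location=s.slice_location,
                    slice_index=s.slice_index,
                )
                for s in out.slices
            ],
            subject_id=out.subject_id,
        )
    return out


def _pool_area(frame: np.ndarray) -> int:
    """Bright-pool pixel count: pixels above the midpoint intensity."""
    lo, hi = float(frame.min()), float(frame.max())
    if hi <= lo:
        return 0
    return int(np.count_nonzero(frame > (lo + hi) / 2.0))


def select_end_diastole(cine: CineStack, strategy: EdStrategy = "first-frame") -> StackED:
    """Keep one end-diastolic frame per slice.

    `first-frame` assumes ECG-triggered acquisition starting at end-diastole
    (the cine CMR convention); `max-pool-area` picks the frame with the
    largest thresholded blood-pool area, a proxy for maximal filling.
    """
    if not cine.slices or any(s.frames.shape[0] < 1 for s in cine.slices):
        raise ValidationError("every slice needs at least one cine frame")
    chosen: list[int] = []
    slices: list[SliceImage] = []
    for s in cine.slices:
        if strategy == "first-frame":
            k = 0
        elif strategy == "max-pool-area":
            k = int(np.argmax([_pool_area(f) for f in s.frames]))
        else:
            raise ValidationError(f"unknown ED strategy {strategy!r}")
        chosen.append(k)
        slices.append(
            SliceImage(
                s.frames[k],
                pixel_spacing=s.pixel_spacing,
                slice_location=s.slice_location,
                slice_index=s.slice_index,
            )
        )
    ed: int | list[int] = chosen if len(set(chosen)) > 1 else chosen[0]
    return StackED(slices=slices, subject_id=cine.subject_id, ed_frame_index=ed)


def write_stack_nifti(stack: StackED, path: str | Path) -> None:
    """Write a StackED as a 3-D NIfTI volume (slices on the third axis)."""
    import nibabel as nib

    data = np.stack([s.pixels for s in stack.slices], axis=2)
    sr, sc = stack.slices[0].pixel_spacing
    affine = np.diag([sr, sc, 1.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((sr, sc, 1.0))
    nib.save(img, str(path))


def write_subject_json(result, path: str | Path, params: dict | None = None,
                       seed: int | None = None) -> None:
    """Serialize a SubjectFD (see aggregate module) with provenance."""
    from . import __version__

    payload = {
        "subject_id": result.subject_id,
        "per_slice": [
            {"slice_index": i, "fd": fd} for i, fd in result.per_slice
        ],
        "global_fd": result.global_fd,
        "mean_apical_fd": result.mean_apical_fd,
        "max_apical_fd": result.max_apical_fd,
        "n_slices_analyzed": result.n_slices_analyzed,
        "excluded_indices": list(result.excluded_indices),
        "provenance": {
            "params": params or {},
            "seed": seed,
            "software_version": __version__,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_cohort_csv(results: Sequence, path: str | Path) -> None:
    """One row per subject: the three FD aggregates."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["subject_id", "global_fd", "mean_apical_fd", "max_apical_fd",
             "n_slices_analyzed"]
        )
        for r in results:
            w.writerow(
                [r.subject_id, f"{r.global_fd:.6f}", f"{r.mean_apical_fd:.6f}",
                 f"{r.max_apical_fd:.6f}", r.n_slices_analyzed]
            )
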