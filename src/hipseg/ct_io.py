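"""Reading and writing CT volumes and label volumes as NIfTI.

CT voxels are kept in their stored representation: unsigned 12-bit integers in
[0, 4095], converted to Hounsfield units through the usual linear rescale
``HU = slope * stored + intercept`` (default slope 1, intercept -1024, the
standard CT convention, so stored 0 is air at -1024 HU and stored 4095 is
3071 HU).  Per-axis voxel spacing is carried in millimetres; the third array
axis is the axial (slice) axis throughout the package.
"""

from __future__ import annotations

import dataclasses
import os

import nibabel as nib
import numpy as np

DEFAULT_SLOPE = 1.0
DEFAULT_INTERCEPT = -1024.0
STORED_MIN, STORED_MAX = 0, 4095

LABEL_BACKGROUND = 0
LABEL_FEMUR = 1
LABEL_OTHER_BONE = 2
DEFAULT_CLASS_MAP = {0: "background", 1: "femur", 2: "other_bone"}


class VolumeError(ValueError):
    """Raised for malformed volumes or files."""


@dataclasses.dataclass
class CtVolume:
    """A 3D CT volume in stored (12-bit) intensities with spacing metadata."""

    stored: np.ndarray
    spacing_mm: tuple
    rescale_slope: float = DEFAULT_SLOPE
    rescale_intercept: float = DEFAULT_INTERCEPT

    def __post_init__(self):
        self.stored = np.asarray(self.stored)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.stored.ndim != 3:
            raise VolumeError(f"CT volume must be 3D, got {self.stored.ndim}D")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise VolumeError(f"spacing must be three positive values, got {self.spacing_mm}")
        if self.stored.min() < STORED_MIN or self.stored.max() > STORED_MAX:
            raise VolumeError(
                f"stored intensities must lie in [{STORED_MIN}, {STORED_MAX}], "
                f"got [{self.stored.min()}, {self.stored.max()}]"
            )
        if self.rescale_slope <= 0:
            raise VolumeError("rescale slope must be positive (HU monotone in stored value)")

    @property
    def shape(self):
        return self.stored.shape

    def hu(self) -> np.ndarray:
        """Volume in Hounsfield units as float32."""
        return (self.rescale_slope * self.stored + self.rescale_intercept).astype(np.float32)


@dataclasses.dataclass
class LabelVolume:
    """Integer class volume aligned voxel-for-voxel with a CtVolume."""

    labels: np.ndarray
    spacing_mm: tuple
    class_map: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_CLASS_MAP))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.labels.ndim != 3:
            raise VolumeError(f"label volume must be 3D, got {self.labels.ndim}D")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise VolumeError(f"spacing must be three positive values, got {self.spacing_mm}")
        present = set(np.unique(self.labels).tolist())
        allowed = set(self.class_map)
        if not present <= allowed:
            raise VolumeError(
                f"labels contain classes {sorted(present - allowed)} outside class map "
                f"{sorted(allowed)}"
            )

    @property
    def shape(self):
        return self.labels.shape

    def mask(self, cls: int) -> np.ndarray:
        return self.labels == cls


def dequantize(stored, slope=DEFAULT_SLOPE, intercept=DEFAULT_INTERCEPT):
    """Stored integers -> Hounsfield units."""
    return slope * np.asarray(stored, dtype=np.float64) + intercept


def quantize_to_stored(hu, slope=DEFAULT_SLOPE, intercept=DEFAULT_INTERCEPT):
    """Hounsfield units -> stored 12-bit integers, rounded and clamped to [0, 4095].

    Exact inverse of :func:`dequantize` for values already on the integer grid
    inside the clamp-free range.
    """
    hu = np.asarray(hu, dtype=np.float64)
    if not np.all(np.isfinite(hu)):
        raise VolumeError("HU values must be finite")
    stored = np.rint((hu - intercept) / slope)
    return np.clip(stored, STORED_MIN, STORED_MAX).astype(np.uint16)


def _spacing_from(img) -> tuple:
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeError(f"file carries no valid 3-axis spacing: {zooms}")
    return tuple(float(z) for z in zooms)


def _load_3d(path):
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    # raw stored values; the scl_slope/scl_inter rescale is our HU conversion,
    # applied explicitly via CtVolume.hu(), never baked into the array
    data = img.dataobj.get_unscaled() if hasattr(img.dataobj, "get_unscaled") else np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeError(f"expected a 3D volume, got {data.ndim}D in {path}")
    return img, data


def read_volume(path) -> CtVolume:
    img, data = _load_3d(path)
    hdr = img.header
    slope = float(hdr["scl_slope"]) if np.isfinite(hdr["scl_slope"]) and hdr["scl_slope"] else DEFAULT_SLOPE
    inter = float(hdr["scl_inter"]) if np.isfinite(hdr["scl_inter"]) else DEFAULT_INTERCEPT
    return CtVolume(
        stored=np.asarray(data, dtype=np.uint16),
        spacing_mm=_spacing_from(img),
        rescale_slope=slope,
        rescale_intercept=inter,
    )


def write_volume(vol: CtVolume, path) -> None:
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    img = nib.Nifti1Image(vol.stored.astype(np.uint16), affine)
    img.header.set_zooms(vol.spacing_mm)
    img.header["scl_slope"] = vol.rescale_slope
    img.header["scl_inter"] = vol.rescale_intercept
    nib.save(img, str(path))


def read_labels(path, class_map=None) -> LabelVolume:
    img, data = _load_3d(path)
    return LabelVolume(
        labels=np.asarray(data, dtype=np.int16),
        spacing_mm=_spacing_from(img),
        class_map=dict(class_map) if class_map else dict(DEFAULT_CLASS_MAP),
    )


def write_labels(lab: LabelVolume, path) -> None:
    affine = np.diag(list(lab.spacing_mm) + [1.0])
    img = nib.Nifti1Image(lab.labels.astype(np.int16), affine)
    img.header.set_zooms(lab.spacing_mm)
    nib.save(img, str(path))
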