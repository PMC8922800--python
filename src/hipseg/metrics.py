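"""Segmentation evaluation metrics in physical units.

Given an automatically segmented voxel set AS and a ground-truth set GT:

* Dice overlap coefficient  DOC = 2|AS ∩ GT| / (|AS| + |GT|), on full voxel sets;
* directed Hausdorff distance  d_H(A, B) = max_{x∈A} min_{y∈B} d(x, y);
* Hausdorff distance  HD = max{d_H(A,B), d_H(B,A)};
* mean surface distance  MSD = (Σ_{x∈A} d(x,B) + Σ_{y∈B} d(y,A)) / (|A| + |B|),

where d is the Euclidean distance between voxel centres scaled by the per-axis
spacing in mm.  HD and MSD are computed on surface voxels (voxels of the class
with at least one 6-connected face neighbour outside the class), the standard
practice for surface-distance metrics; a pixel-unit variant is available by
passing unit spacing.  Nearest-neighbour queries use a k-d tree, which agrees
exactly with the brute-force double loop.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .ct_io import LabelVolume


class EmptySetError(ValueError):
    """A distance metric was asked for an empty voxel set."""


@dataclasses.dataclass
class VoxelSet:
    """A set of voxel coordinates with physical spacing (2D or 3D)."""

    coordinates: np.ndarray
    spacing_mm: tuple

    def __post_init__(self):
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates))
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.coordinates.size and self.coordinates.shape[1] != len(self.spacing_mm):
            raise ValueError(
                f"coordinates are {self.coordinates.shape[1]}-D but spacing has "
                f"{len(self.spacing_mm)} components"
            )

    def __len__(self):
        return 0 if self.coordinates.size == 0 else self.coordinates.shape[0]

    def physical(self) -> np.ndarray:
        return self.coordinates * np.asarray(self.spacing_mm)


@dataclasses.dataclass
class MetricReport:
    """Per-class evaluation results; distances in mm.

    ``hd_mm``/``msd_mm`` are ``None`` when undefined (one side empty)."""

    doc: float
    hd_mm: float | None
    directed_hd_mm: tuple | None
    msd_mm: float | None


def _as_voxelset(obj, spacing=None) -> VoxelSet:
    if isinstance(obj, VoxelSet):
        return obj
    arr = np.asarray(obj)
    if arr.dtype == bool or (arr.ndim in (2, 3) and spacing is not None and arr.ndim == len(spacing)):
        coords = np.argwhere(arr)
        return VoxelSet(coords, spacing if spacing is not None else (1.0,) * arr.ndim)
    return VoxelSet(arr, spacing if spacing is not None else (1.0,) * arr.shape[-1])


def doc(as_set, gt_set) -> float:
    """Dice overlap coefficient between two voxel sets (symmetric, in [0, 1])."""
    a = _as_voxelset(as_set)
    b = _as_voxelset(gt_set)
    if len(a) + len(b) == 0:
        raise EmptySetError("DOC undefined for two empty sets")
    if len(a) == 0 or len(b) == 0:
        return 0.0
    sa = set(map(tuple, a.coordinates.tolist()))
    sb = set(map(tuple, b.coordinates.tolist()))
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def dice_from_masks(pred_mask, gt_mask) -> float:
    """DOC straight from two boolean arrays (fast path for full volumes)."""
    pred_mask = np.asarray(pred_mask, dtype=bool)
    gt_mask = np.asarray(gt_mask, dtype=bool)
    total = pred_mask.sum() + gt_mask.sum()
    if total == 0:
        raise EmptySetError("DOC undefined for two empty masks")
    return 2.0 * np.logical_and(pred_mask, gt_mask).sum() / total


def point_to_set_distance(x, a: VoxelSet) -> float:
    """min_{y in A} of the spacing-scaled Euclidean distance from x to A, in mm."""
    a = _as_voxelset(a)
    if len(a) == 0:
        raise EmptySetError("distance to an empty set is undefined")
    xp = np.asarray(x, dtype=float) * np.asarray(a.spacing_mm)
    return float(np.sqrt(((a.physical() - xp) ** 2).sum(axis=1)).min())


def _nearest_distances(a: VoxelSet, b: VoxelSet) -> np.ndarray:
    """For each point of A, distance in mm to the nearest point of B."""
    tree = cKDTree(b.physical())
    d, _ = tree.query(a.physical(), k=1)
    return np.atleast_1d(d)


def directed_hausdorff(a, b, spacing=None) -> float:
    a = _as_voxelset(a, spacing)
    b = _as_voxelset(b, spacing)
    if len(a) == 0 or len(b) == 0:
        raise EmptySetError("directed Hausdorff undefined for an empty set")
    return float(_nearest_distances(a, b).max())


def hausdorff(a, b, spacing=None) -> float:
    return max(directed_hausdorff(a, b, spacing), directed_hausdorff(b, a, spacing))


def mean_surface_distance(a_surf, b_surf, spacing=None) -> float:
    """Symmetric average nearest-surface distance in mm."""
    a = _as_voxelset(a_surf, spacing)
    b = _as_voxelset(b_surf, spacing)
    if len(a) == 0 or len(b) == 0:
        raise EmptySetError("mean surface distance undefined for an empty set")
    dab = _nearest_distances(a, b)
    dba = _nearest_distances(b, a)
    return float((dab.sum() + dba.sum()) / (len(a) + len(b)))


def extract_surface(mask_or_labels, cls=None, spacing=None) -> VoxelSet:
    """Voxels of a class with at least one 6-connected (face) neighbour outside it.

    Accepts a boolean mask or a :class:`LabelVolume` plus class id.  A voxel on
    the array border counts as surface."""
    if isinstance(mask_or_labels, LabelVolume):
        if cls is None:
            raise ValueError("class id required with a LabelVolume")
        mask = mask_or_labels.labels == cls
        spacing = mask_or_labels.spacing_mm if spacing is None else spacing
    else:
        mask = np.asarray(mask_or_labels, dtype=bool)
    if not mask.any():
        raise EmptySetError(f"class {cls} absent; no surface to extract")
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure, border_value=0)
    surface = mask & ~interior
    return VoxelSet(np.argwhere(surface), spacing if spacing is not None else (1.0,) * mask.ndim)


def evaluate_case(pred: LabelVolume, gt: LabelVolume, classes=(1, 2)) -> dict:
    """Full per-class report: DOC on voxel sets; HD and MSD on surfaces, in mm.

    When the prediction (or truth) misses a class entirely, DOC is 0 and the
    distance metrics are reported as undefined (``None``) rather than infinite.
    """
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if not np.allclose(pred.spacing_mm, gt.spacing_mm):
        raise ValueError(f"spacing mismatch: {pred.spacing_mm} vs {gt.spacing_mm}")
    report = {}
    for cls in classes:
        pm, gm = pred.mask(cls), gt.mask(cls)
        if not pm.any() and not gm.any():
            continue
        d = dice_from_masks(pm, gm)
        if pm.any() and gm.any():
            ps = extract_surface(pm, spacing=pred.spacing_mm)
            gs = extract_surface(gm, spacing=gt.spacing_mm)
            fwd = directed_hausdorff(ps, gs)
            bwd = directed_hausdorff(gs, ps)
            report[cls] = MetricReport(
                doc=d,
                hd_mm=max(fwd, bwd),
                directed_hd_mm=(fwd, bwd),
                msd_mm=mean_surface_distance(ps, gs),
            )
        else:
            report[cls] = MetricReport(doc=d, hd_mm=None, directed_hd_mm=None, msd_mm=None)
    return report
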