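"""Procedural hip-like CT phantoms with voxel-accurate ground-truth labels.

Each phantom emulates the intensity regime of clinical hip CT — a soft-tissue
body on an air background, bone with a bright cortical shell over darker
trabecular interior, Gaussian acquisition noise, 12-bit stored intensities —
around a parametric-primitive hip geometry:

* femur (label 1): spherical head, oblique cylindrical neck, vertical shaft;
* pelvis (label 2): hemispherical acetabular cup shell plus an iliac slab.

The superior slices contain pelvis but no femur, so the slice classifier
always has genuine negatives to learn from.  Four disease-like variants
deform the labels before rendering: osteoarthritis (OA) grows osteophyte-like
rim protrusions on head and cup; osteonecrosis of the femoral head (ONFH)
craters the superior head; femoral neck fracture (FNF) opens a gap through
the neck; developmental dysplasia of the hip (DDH) shallows the lateral cup
and displaces the head superolaterally.  Severities are free phantom
parameters, not calibrated to clinical staging systems.

Geometry is expressed in millimetres and scales with the volume extent, so the
same spec works at the default desk scale (64 x 64 x 60 at 3 mm) and at
clinical resolution (512 x 512 at sub-millimetre spacing).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .ct_io import (
    CtVolume,
    LabelVolume,
    LABEL_FEMUR,
    LABEL_OTHER_BONE,
    quantize_to_stored,
)

CONDITIONS = ("normal", "OA", "DDH", "FNF", "ONFH")

_6CONN = ndimage.generate_binary_structure(3, 1)


class PhantomSpecError(ValueError):
    """A phantom spec violated one of its invariants."""


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one synthetic hip CT case.

    ``femur_head_radius_mm=None`` derives the radius as 12.5% of the smaller
    in-plane physical extent, which keeps the default geometry valid at any
    resolution.
    """

    shape: tuple = (64, 64, 60)
    spacing_mm: tuple = (3.0, 3.0, 3.0)
    condition: str = "normal"
    femur_head_radius_mm: float | None = None
    joint_gap_mm: float = 4.0
    cortical_hu: float = 1200.0
    trabecular_hu: float = 300.0
    soft_tissue_hu: float = 40.0
    air_hu: float = -1000.0
    noise_sd_hu: float = 30.0
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.shape) != 3 or any(s < 16 for s in self.shape):
            raise PhantomSpecError(f"all shape components must be >= 16, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise PhantomSpecError(f"spacing must be positive, got {self.spacing_mm}")
        if self.condition not in CONDITIONS:
            raise PhantomSpecError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.joint_gap_mm <= 0:
            raise PhantomSpecError("joint_gap_mm must be positive (femur and pelvis disjoint)")
        if not (self.cortical_hu > 200.0 > self.soft_tissue_hu):
            raise PhantomSpecError(
                "need cortical_hu > 200 HU > soft_tissue_hu so the bone threshold "
                f"separates them, got {self.cortical_hu} and {self.soft_tissue_hu}"
            )
        if self.noise_sd_hu < 0:
            raise PhantomSpecError("noise_sd_hu must be nonnegative")
        if self.femur_head_radius_mm is not None and self.femur_head_radius_mm <= 0:
            raise PhantomSpecError("femur_head_radius_mm must be positive")

    @property
    def extent_mm(self):
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))

    def head_radius(self) -> float:
        if self.femur_head_radius_mm is not None:
            return float(self.femur_head_radius_mm)
        return 0.125 * min(self.extent_mm[0], self.extent_mm[1])


def _grids(spec: PhantomSpec):
    """Physical (mm) coordinates of voxel centres along each axis."""
    ax = [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing_mm)]
    return np.meshgrid(*ax, indexing="ij", sparse=True)


def _build_normal_labels(spec: PhantomSpec) -> np.ndarray:
    x, y, z = _grids(spec)
    ex, ey, ez = spec.extent_mm
    cx, cy = ex / 2.0, ey / 2.0
    r = spec.head_radius()
    gap = spec.joint_gap_mm
    cup_thick = max(0.25 * r, 2.0 * min(spec.spacing_mm))
    z_head = 0.30 * ez + r
    hc = np.array([cx, cy, z_head])

    labels = np.zeros(spec.shape, dtype=np.int16)

    # pelvis: iliac slab (elliptical column, superior) + acetabular cup shell
    slab_top = 0.08 * ez
    slab_bottom = z_head - r - gap - cup_thick + 2.0
    slab = (
        ((x - cx) / (1.1 * r)) ** 2 + ((y - cy) / (0.8 * r)) ** 2 <= 1.0
    ) & (z >= slab_top) & (z <= slab_bottom)
    d_head = np.sqrt((x - hc[0]) ** 2 + (y - hc[1]) ** 2 + (z - hc[2]) ** 2)
    cup = (d_head >= r + gap) & (d_head <= r + gap + cup_thick) & (z <= z_head)
    labels[slab | cup] = LABEL_OTHER_BONE

    # femur: head sphere + oblique neck + vertical shaft
    head = d_head <= r
    n_dir = np.array([0.45, 0.0, 1.0])
    n_dir /= np.linalg.norm(n_dir)
    neck_len = 1.2 * r
    # distance of each voxel to the neck axis segment, via projection
    vx, vy, vz = x - hc[0], y - hc[1], z - hc[2]
    t = vx * n_dir[0] + vy * n_dir[1] + vz * n_dir[2]
    t_clip = np.clip(t, 0.6 * r, r + neck_len)
    d_axis = np.sqrt(
        (vx - t_clip * n_dir[0]) ** 2
        + (vy - t_clip * n_dir[1]) ** 2
        + (vz - t_clip * n_dir[2]) ** 2
    )
    neck = (d_axis <= 0.42 * r) & (t >= 0.6 * r) & (t <= r + neck_len)
    shaft_c = hc + (r + neck_len) * n_dir
    shaft = (
        np.sqrt((x - shaft_c[0]) ** 2 + (y - shaft_c[1]) ** 2) <= 0.5 * r
    ) & (z >= shaft_c[2]) & (z <= ez - 2.0 * spec.spacing_mm[2])
    labels[head | neck | shaft] = LABEL_FEMUR
    return labels


def _find_head(labels: np.ndarray, spacing) -> tuple:
    """Locate the femoral head as the largest inscribed sphere of the femur.

    Returns (centre_index, centre_mm, radius_mm)."""
    femur = labels == LABEL_FEMUR
    if not femur.any():
        raise PhantomSpecError("labels contain no femur component")
    edt = ndimage.distance_transform_edt(femur, sampling=spacing)
    idx = np.unravel_index(np.argmax(edt), edt.shape)
    centre_mm = np.array(idx, dtype=float) * np.asarray(spacing)
    return idx, centre_mm, float(edt[idx])


def _mm_coords(shape, spacing):
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*ax, indexing="ij", sparse=True)


def _sphere_mask(shape, spacing, centre_mm, radius_mm):
    x, y, z = _mm_coords(shape, spacing)
    return (
        (x - centre_mm[0]) ** 2 + (y - centre_mm[1]) ** 2 + (z - centre_mm[2]) ** 2
        <= radius_mm ** 2
    )


def _separate_classes(labels: np.ndarray) -> np.ndarray:
    """Remove femur voxels face-adjacent to pelvis so the two stay disjoint
    with at least a background voxel between them."""
    pelvis_halo = ndimage.binary_dilation(labels == LABEL_OTHER_BONE, _6CONN)
    labels[(labels == LABEL_FEMUR) & pelvis_halo] = 0
    return labels


def apply_disease_deformation(labels: LabelVolume, condition: str, seed: int) -> LabelVolume:
    """Deform a labelled hip into one of the disease-like variants.

    Works on labels alone: the femoral head is located as the largest sphere
    inscribed in the femur (Euclidean distance transform), so the operation
    applies to any labelling with a femur component, not just fresh phantoms.
    ``condition='normal'`` is the identity.
    """
    if condition not in CONDITIONS:
        raise PhantomSpecError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if condition == "normal":
        return LabelVolume(labels.labels.copy(), labels.spacing_mm, dict(labels.class_map))

    lab = labels.labels.copy()
    spacing = np.asarray(labels.spacing_mm)
    rng = np.random.default_rng(seed)
    _, hc, r = _find_head(lab, spacing)

    if condition == "ONFH":
        # crater the superior head: subtract a sphere centred above the head centre
        crater_c = hc - np.array([0.0, 0.0, 0.85 * r])
        crater = _sphere_mask(lab.shape, spacing, crater_c, 0.55 * r)
        lab[crater & (lab == LABEL_FEMUR)] = 0

    elif condition == "FNF":
        # open a background gap through the neck, just distal to the head
        z = np.arange(lab.shape[2]) * spacing[2]
        z_lo = hc[2] + 1.05 * r
        in_gap = (z >= z_lo) & (z <= z_lo + 2.0 * spacing[2])
        lab[:, :, in_gap] = np.where(
            lab[:, :, in_gap] == LABEL_FEMUR, 0, lab[:, :, in_gap]
        )

    elif condition == "DDH":
        # shallow the lateral cup, then displace the head superolaterally
        x = np.arange(lab.shape[0])[:, None, None] * spacing[0]
        near_head = _sphere_mask(lab.shape, spacing, hc, 2.2 * r)
        lateral_cup = (lab == LABEL_OTHER_BONE) & near_head & (x > hc[0] + 0.3 * r)
        lab[lateral_cup] = 0
        shift_mm = np.array([0.7 * r, 0.0, -0.2 * r]) * (1.0 + 0.2 * rng.random())
        shift_vox = np.rint(shift_mm / spacing).astype(int)
        head = _sphere_mask(lab.shape, spacing, hc, 1.05 * r) & (lab == LABEL_FEMUR)
        lab[head] = 0
        moved = np.roll(head, shift_vox, axis=(0, 1, 2))
        # roll wraps; zero the wrapped margins
        for ax, s in enumerate(shift_vox):
            sl = [slice(None)] * 3
            if s > 0:
                sl[ax] = slice(0, s)
            elif s < 0:
                sl[ax] = slice(s, None)
            else:
                continue
            moved[tuple(sl)] = False
        lab[moved & (lab == 0)] = LABEL_FEMUR
        lab = _separate_classes(lab)

    elif condition == "OA":
        # osteophyte-like rim protrusions on the head equator and the cup rim
        x, y, z = _mm_coords(lab.shape, spacing)
        d_head = np.sqrt((x - hc[0]) ** 2 + (y - hc[1]) ** 2 + (z - hc[2]) ** 2)
        for target, band in (
            (LABEL_FEMUR, (lab == LABEL_FEMUR) & (d_head >= 0.85 * r)
             & (np.abs(np.broadcast_to(z, lab.shape) - hc[2]) < 0.35 * r)),
            (LABEL_OTHER_BONE, (lab == LABEL_OTHER_BONE)
             & (d_head <= 1.45 * r)
             & (np.abs(np.broadcast_to(z, lab.shape) - hc[2]) < 0.25 * r)),
        ):
            sites = np.argwhere(band)
            if len(sites) == 0:
                continue
            picks = sites[rng.choice(len(sites), size=min(4, len(sites)), replace=False)]
            bump = np.zeros(lab.shape, dtype=bool)
            for p in picks:
                bump |= _sphere_mask(lab.shape, spacing, p * spacing, 0.16 * r)
            other = LABEL_OTHER_BONE if target == LABEL_FEMUR else LABEL_FEMUR
            halo = ndimage.binary_dilation(lab == other, _6CONN)
            lab[bump & (lab == 0) & ~halo] = target

    return LabelVolume(lab, labels.spacing_mm, dict(labels.class_map))


def _render(spec: PhantomSpec, labels: np.ndarray) -> CtVolume:
    """Labels -> noisy, quantised stored-intensity volume."""
    x, y, _ = _grids(spec)
    ex, ey, _ = spec.extent_mm
    body = ((x - ex / 2) / (0.46 * ex)) ** 2 + ((y - ey / 2) / (0.42 * ey)) ** 2 <= 1.0
    hu = np.full(spec.shape, spec.air_hu, dtype=np.float64)
    hu[np.broadcast_to(body, spec.shape)] = spec.soft_tissue_hu

    bone = labels > 0
    hu[bone] = spec.trabecular_hu
    for cls in (LABEL_FEMUR, LABEL_OTHER_BONE):
        mask = labels == cls
        if mask.any():
            shell = mask & ~ndimage.binary_erosion(mask, _6CONN)
            hu[shell] = spec.cortical_hu

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_hu > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd_hu, size=spec.shape)
    return CtVolume(stored=quantize_to_stored(hu), spacing_mm=spec.spacing_mm)


def generate_phantom(spec: PhantomSpec):
    """Generate one labelled hip phantom.

    Returns ``(CtVolume, LabelVolume)`` sharing shape and spacing.  Identical
    spec and seed give bitwise-identical output.
    """
    labels = _build_normal_labels(spec)
    lab_vol = LabelVolume(labels, spec.spacing_mm)
    if spec.condition != "normal":
        lab_vol = apply_disease_deformation(lab_vol, spec.condition, spec.seed)
    ct = _render(spec, lab_vol.labels)
    return ct, lab_vol


def generate_cases(n, conditions, base_seed=0, **spec_kwargs):
    """Yield ``(case_id, spec, ct, labels)`` for ``n`` cases.

    ``conditions`` may be a single condition name or a sequence cycled over the
    cases; each case gets a distinct seed derived from ``base_seed``.
    """
    if isinstance(conditions, str):
        conditions = [conditions]
    for i in range(n):
        spec = PhantomSpec(
            condition=conditions[i % len(conditions)],
            seed=(int(base_seed) * 100003 + i) % (2**31 - 1),
            **spec_kwargs,
        )
        ct, lab = generate_phantom(spec)
        yield i, spec, ct, lab
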