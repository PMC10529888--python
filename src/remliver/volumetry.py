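"""Liver volumetry from 3-D segmentation label volumes.

Volumes are voxel counts times the voxel volume from the grid spacing.
The functional liver volume (LV) is the union of the remnant and resected
labels; lesion and vessel labels mark tissue excluded from functional
parenchyma and are never counted toward LV.  The future remnant volume is
rLV = LV - resected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "DEFAULT_LABEL_MAP",
    "SegmentationMask",
    "VolumeSet",
    "mask_volume",
    "volume_set",
    "read_mask",
    "write_mask",
]

DEFAULT_LABEL_MAP: dict[str, int] = {
    "background": 0,
    "remnant": 1,
    "resected": 2,
    "lesion": 3,
    "vessel": 4,
}

# roles that count toward functional liver volume
_LIVER_ROLES = ("remnant", "resected")


@dataclass
class SegmentationMask:
    """A labelled 3-D voxel grid with physical spacing.

    Parameters
    ----------
    labels
        3-D integer array of role labels.
    spacing
        Voxel edge lengths in mm per axis (three positive values).
    label_map
        Mapping role name -> integer label.  Defaults to
        ``DEFAULT_LABEL_MAP``.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    label_map: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("spacing must be three positive values (mm)")
        self.spacing = sp
        declared = set(self.label_map.values())
        present = set(np.unique(self.labels).tolist())
        if not present <= declared:
            raise ValueError(
                f"labels contain undeclared values {sorted(present - declared)}"
            )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class VolumeSet:
    """Functional liver (lv), resected and remnant (rlv) volumes in mL."""

    lv: float
    resected: float
    rlv: float

    def __post_init__(self):
        if not (0 <= self.resected <= self.lv + 1e-9):
            raise ValueError("resected volume must lie in [0, lv]")
        if abs(self.rlv - (self.lv - self.resected)) > 1e-6 * max(1.0, self.lv):
            raise ValueError("rlv must equal lv - resected")


def mask_volume(mask: SegmentationMask, roles: Iterable[str]) -> float:
    """Volume in mL of all voxels whose label role is in ``roles``.

    Raises
    ------
    ValueError
        If a requested role is not declared in the mask's label map.
    """
    roles = set(roles)
    unknown = roles - set(mask.label_map)
    if unknown:
        raise ValueError(f"unknown roles requested: {sorted(unknown)}")
    values = [mask.label_map[r] for r in roles]
    count = int(np.isin(mask.labels, values).sum())
    return count * mask.voxel_volume_mm3 / 1000.0


def volume_set(mask: SegmentationMask) -> VolumeSet:
    """Liver, resected and remnant volumes of a mask.

    LV counts only the remnant and resected roles; lesion and vessel
    voxels are excluded from functional liver by construction.
    """
    lv = mask_volume(mask, _LIVER_ROLES)
    resected = mask_volume(mask, ("resected",))
    return VolumeSet(lv=lv, resected=resected, rlv=lv - resected)


def read_mask(path, label_map: Mapping[str, int] | None = None) -> SegmentationMask:
    """Read a segmentation label volume from a NIfTI file.

    Axis spacing is taken from the header zooms.
    """
    import nibabel as nib

    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SegmentationMask(labels=labels, spacing=spacing,
                            label_map=dict(label_map or DEFAULT_LABEL_MAP))


def write_mask(mask: SegmentationMask, path) -> None:
    """Write a segmentation mask as an integer NIfTI volume."""
    import nibabel as nib

    affine = np.diag(list(mask.spacing) + [1.0])
    img = nib.Nifti1Image(mask.labels.astype(np.int16), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
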