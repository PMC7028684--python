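"""Lesion burden, brain atrophy and cross-subject lesion possibility maps.

This module consumes binary masks (segmentation itself is upstream); all
volumes are reported in millilitres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import VolumeGeometry

__all__ = ["LesionSet", "mask_volume_ml", "relative_brain_volume",
           "possibility_map"]


@dataclass
class LesionSet:
    """Per-subject lesion and reference masks sharing one geometry."""

    wmh_mask: np.ndarray
    lacune_masks: np.ndarray
    brain_mask: np.ndarray
    icv_mask: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        dims = tuple(self.geometry.dims)
        for name in ("wmh_mask", "lacune_masks", "brain_mask", "icv_mask"):
            m = getattr(self, name)
            if m is not None and m.shape[:3] != dims:
                raise ValueError(f"{name} shape {m.shape} does not match "
                                 f"geometry dims {dims}")


def _check_binary(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool:
        vals = np.unique(mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"{name} is not binary (values {vals[:5]}...)")
        mask = mask.astype(bool)
    return mask


def mask_volume_ml(mask: np.ndarray, geometry: VolumeGeometry) -> float:
    """Set-voxel count times voxel volume, in ml."""
    mask = _check_binary(mask)
    return float(mask.sum()) * geometry.voxel_volume_mm3 / 1000.0


def relative_brain_volume(brain_mask: np.ndarray, icv_mask: np.ndarray,
                          geometry: VolumeGeometry) -> float:
    """Absolute brain volume divided by intracranial volume."""
    brain = _check_binary(brain_mask, "brain_mask")
    icv = _check_binary(icv_mask, "icv_mask")
    outside = int(np.sum(brain & ~icv))
    if outside:
        raise ValueError(f"brain mask extends outside the intracranial "
                         f"mask by {outside} voxels")
    icv_ml = mask_volume_ml(icv, geometry)
    if icv_ml <= 0:
        raise ValueError("intracranial volume is zero")
    return mask_volume_ml(brain, geometry) / icv_ml


def possibility_map(masks: list[np.ndarray]) -> np.ndarray:
    """Voxelwise fraction of subjects carrying a lesion at that location."""
    if len(masks) == 0:
        raise ValueError("need at least one subject mask")
    shape = np.asarray(masks[0]).shape
    stack = []
    for i, m in enumerate(masks):
        m = _check_binary(m, f"mask {i}")
        if m.shape != shape:
            raise ValueError(f"mask {i} shape {m.shape} differs from "
                             f"{shape}: geometry mismatch")
        stack.append(m)
    return np.mean(stack, axis=0)
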