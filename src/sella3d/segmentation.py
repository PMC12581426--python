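"""Bone segmentation: window thresholding, ROI cropping, component selection.

Clinical CT/CBCT bone is segmented with a fixed grayscale window applied
uniformly to every dataset; micro-CT-like scans, which lack a stable
intensity calibration, instead use a per-scan adaptive threshold placed at
the midpoint between a sampled bone intensity and a sampled soft-tissue
intensity. Both produce a :class:`~sella3d.types.BinaryMask` in the frame of
the source volume.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi

from .types import BinaryMask, SeedPointError, ThresholdWindow, VoxelVolume

__all__ = [
    "threshold_bone",
    "adaptive_microct_threshold",
    "crop_roi_cube",
    "keep_component_containing",
]

#: Fixed clinical bone window (GU) applied uniformly to patient scans.
DEFAULT_CLINICAL_WINDOW = ThresholdWindow(lower=-728.0, upper=2047.0)


def threshold_bone(vol: VoxelVolume, window: ThresholdWindow) -> BinaryMask:
    """Voxels with intensity in the closed interval [lower, upper] become bone.

    Closed bounds keep the operation idempotent on integer grayscale data and
    monotone: widening the window can only add voxels.
    """
    values = (vol.values >= window.lower) & (vol.values <= window.upper)
    return BinaryMask.like(vol, values)


def adaptive_microct_threshold(
    vol: VoxelVolume,
    bone_sample: np.ndarray | BinaryMask,
    soft_sample: np.ndarray | BinaryMask,
) -> ThresholdWindow:
    """Per-scan threshold for uncalibrated micro-CT-like data.

    The lower bound is the arithmetic midpoint between the mean intensity of
    a bone sample region and that of a surrounding soft-tissue sample region;
    the upper bound is the maximum intensity of the volume.
    """
    lower_means = []
    for name, region in (("bone_sample", bone_sample), ("soft_sample", soft_sample)):
        values = region.values if isinstance(region, BinaryMask) else np.asarray(region)
        if values.dtype == bool:
            if values.shape != vol.shape:
                raise ValueError(f"{name} mask must match the volume shape")
            if not values.any():
                raise ValueError(f"{name} region is empty")
            sample = vol.values[values]
        else:
            if values.size == 0:
                raise ValueError(f"{name} region is empty")
            sample = values
        lower_means.append(float(np.mean(sample)))
    bone_mean, soft_mean = lower_means
    if np.isclose(bone_mean, soft_mean):
        warnings.warn(
            "bone and soft-tissue sample means coincide; adaptive threshold is degenerate",
            stacklevel=2,
        )
    lower = 0.5 * (bone_mean + soft_mean)
    upper = float(vol.values.max())
    if upper <= lower:  # degenerate scan darker than the midpoint
        upper = lower + 1.0
    return ThresholdWindow(lower=lower, upper=upper)


def crop_roi_cube(vol: VoxelVolume, center, edge: float) -> VoxelVolume:
    """Crop the axis-aligned cube of side ``edge`` (mm) centred at ``center``.

    The returned subvolume keeps the physical frame: its origin is updated so
    every retained voxel centre has the same physical coordinate as before.
    """
    if edge <= 0:
        raise ValueError("edge must be positive")
    center = np.asarray(center, dtype=float).reshape(3)
    origin = np.asarray(vol.origin)
    spacing = np.asarray(vol.spacing)
    lo = center - edge / 2.0
    hi = center + edge / 2.0
    i0 = np.ceil((lo - origin) / spacing - 1e-9).astype(int)
    i1 = np.floor((hi - origin) / spacing + 1e-9).astype(int)
    i0 = np.maximum(i0, 0)
    i1 = np.minimum(i1, np.asarray(vol.shape) - 1)
    if np.any(i1 < i0):
        raise ValueError("ROI cube does not intersect the volume extent")
    sub = vol.values[i0[0]:i1[0] + 1, i0[1]:i1[1] + 1, i0[2]:i1[2] + 1]
    new_origin = origin + i0 * spacing
    cls = type(vol)
    return cls(values=sub.copy(), spacing=vol.spacing, origin=tuple(new_origin))


def keep_component_containing(mask: BinaryMask, point) -> BinaryMask:
    """Retain only the 26-connected component containing ``point``.

    26-connectivity is the permissive standard for bone continuity, so thin
    diagonal bridges do not artificially split the cranial base. Raises
    :class:`SeedPointError` (naming the distance to the nearest foreground
    voxel) when the point falls on background.
    """
    idx = mask.nearest_index(point)
    if not mask.values[idx]:
        if mask.values.any():
            dist = ndi.distance_transform_edt(~mask.values, sampling=mask.spacing)
            near = float(dist[idx])
        else:
            near = float("inf")
        raise SeedPointError(
            f"point {tuple(np.asarray(point, float))} falls on a background voxel; "
            f"nearest foreground voxel is {near:.3f} mm away"
        )
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-neighbourhood
    labels, _ = ndi.label(mask.values, structure=structure)
    return BinaryMask.like(mask, labels == labels[idx])
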