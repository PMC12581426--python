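"""Volume I/O through SimpleITK (NIfTI and MetaImage) plus landmark JSON.

SimpleITK stores arrays in (z, y, x) order; this module transposes so that
the in-memory :class:`~sella3d.types.VoxelVolume` keeps (x, y, z) indexing
with voxel centres at ``origin + index * spacing``. Only axis-aligned
volumes with an identity direction matrix are supported.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .types import BinaryMask, VoxelVolume

_SUPPORTED = {".nii", ".gz", ".mha", ".mhd"}


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) scalar volume."""
    path = Path(path)
    img = sitk.ReadImage(str(path))
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(
            f"{path}: only axis-aligned volumes (identity direction) are supported"
        )
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VoxelVolume(values=values, spacing=img.GetSpacing(), origin=img.GetOrigin())


def write_volume(vol: VoxelVolume, path: str | Path) -> None:
    """Write a volume; format chosen by extension."""
    values = vol.values
    if values.dtype == bool:  # masks as 0/1 bytes
        values = values.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(vol.origin))
    sitk.WriteImage(img, str(Path(path)))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    write_volume(mask, path)


def read_mask(path: str | Path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(values=vol.values != 0, spacing=vol.spacing, origin=vol.origin)
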