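"""Cavity closure, extraction and volumetry.

The sella turcica is open cranially and laterally where its borders are not
ossified. Those gaps are sealed with planes defined by landmark triplets,
the enclosed cavity is recovered by a flood fill bounded by bone and by the
planes, and volumes are voxel counts times the physical voxel volume.

Geometric conventions
---------------------
* A voxel belongs to the side of a plane its *centre* is on; no
  partial-volume weighting. Accuracy is then a pure resolution question and
  is covered by the convergence experiments.
* Each cutting plane has a kerf (cut thickness, default 0.1 mm in the
  pipeline): voxel centres strictly within ``kerf/2`` of the plane are
  removed, a symmetric, orientation-neutral reading of the trim the
  modelling workflow applies.
* The anterior/posterior split uses kerf 0 and assigns boundary voxels
  (signed distance exactly 0) to the anterior side, so
  ``vol_t == vol_a + vol_p`` holds exactly, matching the definition of the
  anterior volume as total minus posterior.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .types import (
    BinaryMask,
    ClosurePlaneSet,
    CuttingPlane,
    DegeneratePlaneError,
    LeakError,
    SeedPointError,
    VolumeTriple,
)

__all__ = [
    "plane_from_points",
    "closure_planes_from_landmarks",
    "clip_cavity",
    "extract_cavity",
    "split_anterior_posterior",
    "compute_volume",
]

_MIN_TRIANGLE_AREA_MM2 = 1e-6

_FACE_NAMES = (
    ("x_min", "x_max"),
    ("y_min", "y_max"),
    ("z_min", "z_max"),
)


def plane_from_points(p1, p2, p3, orient_toward, kerf: float = 0.0) -> CuttingPlane:
    """Plane through three landmarks, oriented so ``orient_toward`` is on the keep side."""
    p1, p2, p3, ref = (np.asarray(p, dtype=float).reshape(3) for p in (p1, p2, p3, orient_toward))
    normal = np.cross(p2 - p1, p3 - p1)
    area = 0.5 * float(np.linalg.norm(normal))
    if area <= _MIN_TRIANGLE_AREA_MM2:
        raise DegeneratePlaneError(
            f"landmarks are collinear (triangle area {area:.3g} mm^2); cannot define a plane"
        )
    normal = normal / np.linalg.norm(normal)
    side = float(np.dot(normal, ref - p1))
    if abs(side) < 1e-9:
        raise DegeneratePlaneError("orientation point lies on the plane; keep side undefined")
    if side < 0:
        normal = -normal
    return CuttingPlane(point=tuple(p1), unit_normal=tuple(normal), kerf=kerf)


def closure_planes_from_landmarks(lm, kerf: float = 0.1) -> ClosurePlaneSet:
    """Build the cranial and both lateral closure planes from their landmark triplets.

    Each plane passes through its three named landmarks (``cranial_1..3``,
    ``lat_left_1..3``, ``lat_right_1..3``) and is oriented so the sella
    midpoint lies on the keep side.
    """
    sella_mid = lm["sella_mid"]

    def plane(prefix: str) -> CuttingPlane:
        p1, p2, p3 = lm.require(f"{prefix}_1", f"{prefix}_2", f"{prefix}_3")
        return plane_from_points(p1, p2, p3, orient_toward=sella_mid, kerf=kerf)

    return ClosurePlaneSet(
        cranial=plane("cranial"),
        lateral_left=plane("lat_left"),
        lateral_right=plane("lat_right"),
    )


def _keep_region(mask_like, planes) -> np.ndarray:
    """Boolean grid of voxel centres on the keep side (beyond the kerf) of all planes."""
    if isinstance(planes, CuttingPlane):
        planes = (planes,)
    keep = np.ones(mask_like.shape, dtype=bool)
    for plane in planes:
        sd = plane.signed_distance_grid(mask_like)
        keep &= sd > plane.kerf / 2.0
    return keep


def clip_cavity(mask: BinaryMask, planes: ClosurePlaneSet | CuttingPlane) -> BinaryMask:
    """Remove voxels on the discard side of, or within the kerf of, each plane."""
    return BinaryMask.like(mask, mask.values & _keep_region(mask, planes))


def extract_cavity(bone: BinaryMask, planes: ClosurePlaneSet | CuttingPlane, seed_point) -> BinaryMask:
    """Flood-fill the cavity ("positive model") bounded by bone and closure planes.

    The fill is 6-connected (face neighbours only) so it cannot slip
    diagonally through a one-voxel bone wall. If the filled region reaches
    any face of the volume the closure is incomplete and a :class:`LeakError`
    naming that face is raised.
    """
    idx = bone.nearest_index(seed_point)
    if bone.values[idx]:
        raise SeedPointError(
            f"seed point {tuple(np.asarray(seed_point, float))} lies inside bone"
        )
    fillable = ~bone.values & _keep_region(bone, planes)
    if not fillable[idx]:
        raise SeedPointError(
            "seed point is outside the keep side of the closure planes"
        )
    structure = ndi.generate_binary_structure(3, 1)  # 6-connectivity
    labels, _ = ndi.label(fillable, structure=structure)
    cavity = labels == labels[idx]
    for axis in range(3):
        faces = (cavity.take(0, axis=axis), cavity.take(-1, axis=axis))
        for face_values, face_name in zip(faces, _FACE_NAMES[axis]):
            if face_values.any():
                raise LeakError(face_name)
    return BinaryMask.like(bone, cavity)


def split_anterior_posterior(
    cavity: BinaryMask, pcp, dorsum, floor_caudal, anterior_point
) -> VolumeTriple:
    """Split the cavity along the plane through the posterior clinoid process,
    the dorsum sellae and the caudal extension of the sella floor.

    ``anterior_point`` (the tuberculum in the standard pipeline) identifies
    the anterior side. The split uses kerf 0 and the posterior volume is the
    strict-negative side, so the three volumes satisfy
    ``vol_t == vol_a + vol_p`` exactly.
    """
    if cavity.voxel_count == 0:
        raise ValueError("cavity mask is empty")
    plane = plane_from_points(pcp, dorsum, floor_caudal, orient_toward=anterior_point, kerf=0.0)
    sd = plane.signed_distance_grid(cavity)
    vv = cavity.voxel_volume_mm3
    n_total = cavity.voxel_count
    n_posterior = int(np.count_nonzero(cavity.values & (sd < 0)))
    vol_p = n_posterior * vv
    vol_a = (n_total - n_posterior) * vv
    # summing the two sides keeps vol_t == vol_a + vol_p exact in floating point
    return VolumeTriple(vol_t=vol_a + vol_p, vol_a=vol_a, vol_p=vol_p)


def compute_volume(mask: BinaryMask) -> float:
    """Volume in mm³: foreground voxel count times the voxel volume."""
    return mask.volume_mm3
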