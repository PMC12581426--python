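"""Core spatial containers shared by every pipeline stage.

All geometry lives in a single physical frame: millimetres, axis-aligned
grids, voxel centre of index ``(i, j, k)`` at ``origin + index * spacing``.
Arrays are indexed ``values[i, j, k]`` with axis order (x, y, z). Image
intensities are uncalibrated grayscale units (GU), not Hounsfield units.
"""
from __future__ import annotations

import json
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "VoxelVolume",
    "BinaryMask",
    "ThresholdWindow",
    "CuttingPlane",
    "ClosurePlaneSet",
    "LandmarkSet",
    "STMeasurements",
    "VolumeTriple",
    "SizingError",
    "MissingLandmarkError",
    "DegeneratePlaneError",
    "LeakError",
    "SeedPointError",
]


class SizingError(ValueError):
    """A requested grid cannot contain the phantom geometry."""


class MissingLandmarkError(KeyError):
    """A named landmark required by an operation is absent."""

    def __init__(self, name: str):
        self.name = name
        super().__init__(f"missing landmark: {name!r}")

    def __str__(self) -> str:  # KeyError would quote the message
        return self.args[0]


class DegeneratePlaneError(ValueError):
    """Three landmarks are (near-)collinear or the orientation point lies on the plane."""


class LeakError(RuntimeError):
    """A cavity flood fill escaped the region of interest."""

    def __init__(self, face: str):
        self.face = face
        super().__init__(
            f"cavity flood fill leaked out of the volume through face {face!r}; "
            "the osseous boundary or a closure plane is missing"
        )


class SeedPointError(ValueError):
    """A seed/anchor point does not fall where the operation requires."""


def _as_point(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"point has non-finite coordinates: {p!r}")
    return arr


@dataclass
class VoxelVolume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    values : (nx, ny, nz) ndarray of GU intensities.
    spacing : per-axis voxel size in mm (all > 0).
    origin : physical coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("values must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in np.asarray(self.spacing, float).reshape(3))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in np.asarray(self.origin, float).reshape(3))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centres along each axis."""
        return tuple(
            self.origin[ax] + self.spacing[ax] * np.arange(self.shape[ax])
            for ax in range(3)
        )  # type: ignore[return-value]

    def index_to_physical(self, index) -> np.ndarray:
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_index(self, point) -> np.ndarray:
        """Continuous (fractional) index of a physical point."""
        p = _as_point(point)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def nearest_index(self, point) -> tuple[int, int, int]:
        """Index of the voxel whose centre is closest to ``point`` (clipped to the grid)."""
        idx = np.rint(self.physical_to_index(point)).astype(int)
        idx = np.clip(idx, 0, np.asarray(self.shape) - 1)
        return tuple(int(i) for i in idx)

    def same_frame_as(self, other: "VoxelVolume | BinaryMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class BinaryMask(VoxelVolume):
    """A boolean voxel grid sharing the frame of its source volume."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.values.dtype != bool:
            self.values = self.values.astype(bool)

    @classmethod
    def like(cls, vol: VoxelVolume, values: np.ndarray) -> "BinaryMask":
        if values.shape != vol.shape:
            raise ValueError("mask shape must match its source volume")
        return cls(values=values, spacing=vol.spacing, origin=vol.origin)

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.values))

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3


@dataclass(frozen=True)
class ThresholdWindow:
    """Closed grayscale interval [lower, upper] treated as bone."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"require lower < upper, got [{self.lower}, {self.upper}]")


@dataclass(frozen=True)
class CuttingPlane:
    """An oriented plane with a finite cut thickness (kerf).

    ``unit_normal`` points toward the *keep* side. Material strictly within
    ``kerf / 2`` of the plane is removed when clipping, mimicking the trim
    the modelling software applies along reconstruction planes.
    """

    point: tuple[float, float, float]
    unit_normal: tuple[float, float, float]
    kerf: float = 0.0

    def __post_init__(self) -> None:
        p = _as_point(self.point)
        n = np.asarray(self.unit_normal, dtype=float).reshape(3)
        norm = float(np.linalg.norm(n))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"unit_normal must have norm 1 (got {norm:.3g})")
        if self.kerf < 0:
            raise ValueError("kerf must be >= 0")
        object.__setattr__(self, "point", tuple(p))
        object.__setattr__(self, "unit_normal", tuple(n))
        object.__setattr__(self, "kerf", float(self.kerf))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance (mm); positive on the keep side."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.point)) @ np.asarray(self.unit_normal)

    def signed_distance_grid(self, vol: VoxelVolume) -> np.ndarray:
        """Signed distance of every voxel centre, computed separably."""
        xs, ys, zs = vol.axis_coordinates()
        nx, ny, nz = self.unit_normal
        off = float(np.dot(self.point, self.unit_normal))
        return (
            nx * xs[:, None, None]
            + ny * ys[None, :, None]
            + nz * zs[None, None, :]
            - off
        )


@dataclass(frozen=True)
class ClosurePlaneSet:
    """The three planes that seal the non-ossified sella borders.

    The cranial plane caps the open top of the fossa; the two lateral planes
    close the non-ossified gaps toward the carotid sulci. Each is oriented so
    the sella midpoint lies strictly on its keep side.
    """

    cranial: CuttingPlane
    lateral_left: CuttingPlane
    lateral_right: CuttingPlane

    def __iter__(self) -> Iterator[CuttingPlane]:
        return iter((self.cranial, self.lateral_left, self.lateral_right))


class LandmarkSet(Mapping):
    """Named anatomical points in physical mm coordinates.

    A thin mapping ``name -> (3,) ndarray`` with JSON round-tripping and a
    ``require`` accessor that raises :class:`MissingLandmarkError` naming the
    first absent landmark.
    """

    def __init__(self, points: Mapping[str, object]):
        self._points: dict[str, np.ndarray] = {
            str(name): _as_point(p) for name, p in points.items()
        }

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self._points[name]
        except KeyError:
            raise MissingLandmarkError(name) from None

    def __iter__(self):
        return iter(self._points)

    def __len__(self) -> int:
        return len(self._points)

    def __repr__(self) -> str:
        return f"LandmarkSet({sorted(self._points)})"

    def require(self, *names: str) -> tuple[np.ndarray, ...]:
        return tuple(self[name] for name in names)

    def transformed(self, rotation: np.ndarray | None = None, translation=None) -> "LandmarkSet":
        """Rigidly transformed copy (used to test motion invariance)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else _as_point(translation)
        return LandmarkSet({k: R @ v + t for k, v in self._points.items()})

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        with open(path) as fh:
            return cls(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({k: [float(x) for x in v] for k, v in self._points.items()},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")


#: Landmark names the full pipeline understands. The first block defines the
#: linear measurements, the second the closure and split planes.
LANDMARK_VOCABULARY: tuple[str, ...] = (
    "sella_mid", "tuberculum", "dorsum_posterior_cranial",
    "interclinoid_left", "interclinoid_right", "nasofrontal_suture",
    "length_ant", "length_post", "height_sup", "height_inf",
    "pcp", "dorsum", "floor_caudal",
    "cranial_1", "cranial_2", "cranial_3",
    "lat_left_1", "lat_left_2", "lat_left_3",
    "lat_right_1", "lat_right_2", "lat_right_3",
)


@dataclass
class VolumeTriple:
    """Total/anterior/posterior cavity volumes (mm³); vol_t == vol_a + vol_p by construction."""

    vol_t: float
    vol_a: float
    vol_p: float

    def __post_init__(self) -> None:
        for name in ("vol_t", "vol_a", "vol_p"):
            v = float(getattr(self, name))
            if v < 0:
                raise ValueError(f"{name} must be >= 0 (got {v})")
            setattr(self, name, v)


@dataclass
class STMeasurements:
    """The eight sella turcica outcome variables.

    Linear measures in mm, volumes in mm³. Volumes default to NaN so the
    morphometric (landmark-only) stage can run without volumetry.
    """

    st_length: float
    st_width: float
    st_height: float
    st_diameter: float
    cb: float
    vol_t: float = float("nan")
    vol_a: float = float("nan")
    vol_p: float = float("nan")

    def with_volumes(self, volumes: VolumeTriple) -> "STMeasurements":
        return STMeasurements(
            st_length=self.st_length, st_width=self.st_width,
            st_height=self.st_height, st_diameter=self.st_diameter, cb=self.cb,
            vol_t=volumes.vol_t, vol_a=volumes.vol_a, vol_p=volumes.vol_p,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "st_length": self.st_length, "st_width": self.st_width,
            "st_height": self.st_height, "st_diameter": self.st_diameter,
            "cb": self.cb, "vol_t": self.vol_t, "vol_a": self.vol_a,
            "vol_p": self.vol_p,
        }
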