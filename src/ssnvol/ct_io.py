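"""Volume and mask data model, standard-format I/O, and coordinate conversions.

The package-wide conventions live here:

* arrays are indexed ``[x, y, z]`` and voxel index axes coincide with world
  axes (readers transpose from file order);
* voxel indices are 0-based and a voxel's world position is its *center*;
* all user-facing points and strokes are world millimetres;
* Hounsfield values are clamped to the 12-bit CT range [-1024, 3071] on load
  so that noise or synthesis outliers cannot corrupt density integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

logger = logging.getLogger(__name__)

HU_MIN = -1024.0
HU_MAX = 3071.0

#: file suffixes accepted by :func:`read_volume` / :func:`write_volume`
SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd", ".nrrd")


class VolumeIOError(IOError):
    """Unreadable / unwritable volume file or unsupported format."""


class OutOfBoundsError(ValueError):
    """A world point or voxel index falls outside the volume grid."""


def clamp_hu(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Clamp attenuation values to [-1024, 3071] HU.

    Returns the clamped array and the number of voxels that were clamped.
    """
    n_out = int(np.count_nonzero((values < HU_MIN) | (values > HU_MAX)))
    if n_out:
        values = np.clip(values, HU_MIN, HU_MAX)
    return values, n_out


@dataclass
class CTVolume:
    """A 3-D scalar grid of CT attenuation in Hounsfield units.

    Parameters
    ----------
    values
        3-D array of HU, indexed ``[x, y, z]``.
    spacing
        Voxel edge lengths ``(sx, sy, sz)`` in mm; all strictly positive.
    origin
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(
            not np.isfinite(s) or s <= 0 for s in self.spacing
        ):
            raise ValueError(f"spacing must be three positive finite mm, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite HU values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class NoduleMask:
    """Binary voxel set congruent with a parent :class:`CTVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.values))

    def congruent_with(self, vol: CTVolume) -> bool:
        return (
            self.shape == vol.shape
            and np.allclose(self.spacing, vol.spacing)
            and np.allclose(self.origin, vol.origin)
        )


# ---------------------------------------------------------------------------
# file I/O


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in SUPPORTED_SUFFIXES):
        raise VolumeIOError(
            f"unsupported volume format {path.name!r}; supported: "
            + ", ".join(SUPPORTED_SUFFIXES)
        )


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    # Reorient non-identity direction cosines to the axis-aligned frame so
    # index axes always coincide with world axes.
    if not np.allclose(np.reshape(img.GetDirection(), (3, 3)), np.eye(3)):
        img = sitk.DICOMOrient(img, "LPS")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    values = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return values, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def _to_sitk(values: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def read_volume(path: str | Path) -> CTVolume:
    """Read a CT volume from NIfTI (.nii/.nii.gz), MetaImage (.mha/.mhd) or NRRD.

    Spacing and origin are taken from the file header; HU values are clamped
    to [-1024, 3071] with a logged warning if any voxel falls outside.
    """
    path = Path(path)
    _check_suffix(path)
    if not path.exists():
        raise VolumeIOError(f"volume file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # sitk raises RuntimeError on malformed files
        raise VolumeIOError(f"could not read {path.name} as {path.suffix}: {exc}") from exc
    values, spacing, origin = _from_sitk(img)
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise VolumeIOError(f"invalid spacing metadata {spacing} in {path.name}")
    values = values.astype(np.float64)
    values, n_clamped = clamp_hu(values)
    if n_clamped:
        logger.warning(
            "%d voxel(s) outside [%d, %d] HU clamped on load of %s",
            n_clamped, int(HU_MIN), int(HU_MAX), path.name,
        )
    return CTVolume(values=values, spacing=spacing, origin=origin)


def write_volume(vol: CTVolume, path: str | Path) -> None:
    """Write a volume; the file round-trips through :func:`read_volume`."""
    path = Path(path)
    _check_suffix(path)
    if not path.parent.is_dir():
        raise VolumeIOError(f"output directory does not exist: {path.parent}")
    img = _to_sitk(np.asarray(vol.values, dtype=np.float64), vol.spacing, vol.origin)
    try:
        sitk.WriteImage(img, str(path))
    except Exception as exc:
        raise VolumeIOError(f"could not write {path}: {exc}") from exc


def read_mask(path: str | Path) -> NoduleMask:
    """Read a binary mask (any nonzero voxel counts as foreground)."""
    vol = read_volume(path)
    return NoduleMask(values=vol.values > 0, spacing=vol.spacing, origin=vol.origin)


def write_mask(mask: NoduleMask, path: str | Path) -> None:
    """Write a mask as an 8-bit {0,1} volume."""
    path = Path(path)
    _check_suffix(path)
    if not path.parent.is_dir():
        raise VolumeIOError(f"output directory does not exist: {path.parent}")
    img = _to_sitk(mask.values.astype(np.uint8), mask.spacing, mask.origin)
    try:
        sitk.WriteImage(img, str(path))
    except Exception as exc:
        raise VolumeIOError(f"could not write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# coordinate conversions

_AXES = "xyz"


def world_to_voxel(vol: CTVolume | NoduleMask, point) -> tuple[int, int, int]:
    """Map a world-mm point to the nearest voxel index.

    ``i = round((p - origin) / spacing)`` per axis; raises
    :class:`OutOfBoundsError` naming the offending axis if the index falls
    outside the grid.
    """
    point = np.asarray(point, dtype=float)
    if point.shape != (3,):
        raise ValueError(f"point must be a world-mm triple, got {point!r}")
    idx = np.rint((point - np.asarray(vol.origin)) / np.asarray(vol.spacing)).astype(int)
    for ax in range(3):
        if idx[ax] < 0 or idx[ax] >= vol.shape[ax]:
            raise OutOfBoundsError(
                f"point {tuple(point)} outside volume on axis {_AXES[ax]} "
                f"(index {idx[ax]} not in [0, {vol.shape[ax] - 1}])"
            )
    return int(idx[0]), int(idx[1]), int(idx[2])


def voxel_to_world(vol: CTVolume | NoduleMask, index) -> tuple[float, float, float]:
    """World-mm position of a voxel's center."""
    idx = np.asarray(index)
    for ax in range(3):
        if idx[ax] < 0 or idx[ax] >= vol.shape[ax]:
            raise OutOfBoundsError(
                f"index {tuple(int(i) for i in idx)} outside volume on axis {_AXES[ax]}"
            )
    pos = np.asarray(vol.origin) + idx * np.asarray(vol.spacing)
    return float(pos[0]), float(pos[1]), float(pos[2])
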