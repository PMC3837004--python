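"""Semi-automatic subsolid nodule segmentation.

Pipeline, mirroring the interactive workflow of SSN volumetry software:

1. the user clicks a center point or draws a stroke across the nodule's
   largest diameter (world mm);
2. a cubic volume of interest (VOI) is defined around the derived seed,
   scaled from the stroke length (or a default expected diameter);
3. dual-threshold region growing (default band [-750, -150] HU, the range
   of ground-glass attenuation) yields an initial 6-connected segmentation;
4. morphological operators remove the chest wall (above-band structures
   entering the VOI from outside) and attached vessels (thin structures
   culled by opening, with a depth-limited conditional dilation restoring
   the nodule's own irregular margin);
5. enclosed cavities are filled so the solid core of a part-solid nodule,
   whose attenuation lies above the growing band, is counted in the mask.

Everything is deterministic: identical volume, input and parameters give
identical masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .ct_io import CTVolume, NoduleMask, world_to_voxel

#: 6-connectivity (faces only) — the strictest standard choice; prevents
#: diagonal leakage through noise.
CONN6 = ndimage.generate_binary_structure(3, 1)

VoiBox = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


class SegmentationError(RuntimeError):
    """Base class for segmentation failures."""


class SeedOutOfRangeError(SegmentationError):
    """Seed voxel attenuation outside the growing band."""


class NoSubsolidTissueError(SegmentationError):
    """No in-band voxel within the snap radius of the seed."""


class NoduleLostError(SegmentationError):
    """Chest-wall removal erased the whole mask (seed in pleural shell)."""


class RoundnessTooAggressiveError(SegmentationError):
    """Morphological opening erased the seed component even after fallback."""


class SegmentationFailedError(SegmentationError):
    """Empty final mask."""


@dataclass
class SeedInput:
    """User input: a click point or a stroke across the largest diameter.

    ``seed`` is the point itself or the stroke midpoint; ``scale`` is the
    stroke length or, for a point, a default expected diameter.
    """

    point: Optional[tuple[float, float, float]] = None
    stroke: Optional[tuple[tuple[float, float, float], tuple[float, float, float]]] = None
    default_diameter_mm: float = 10.0

    def __post_init__(self) -> None:
        if (self.point is None) == (self.stroke is None):
            raise ValueError("provide exactly one of point or stroke")
        if self.stroke is not None:
            p0, p1 = (np.asarray(p, dtype=float) for p in self.stroke)
            if float(np.linalg.norm(p1 - p0)) < 1.0:
                raise ValueError("stroke endpoints must be at least 1 mm apart")

    @property
    def seed_world(self) -> tuple[float, float, float]:
        if self.point is not None:
            return tuple(float(c) for c in self.point)
        p0, p1 = (np.asarray(p, dtype=float) for p in self.stroke)
        return tuple((p0 + p1) / 2.0)

    @property
    def scale_mm(self) -> float:
        """Expected nodule diameter: stroke length, or the configured default."""
        if self.stroke is None:
            return float(self.default_diameter_mm)
        p0, p1 = (np.asarray(p, dtype=float) for p in self.stroke)
        return float(np.linalg.norm(p1 - p0))


@dataclass
class SegmentationParams:
    """Tunables of the pipeline (HU thresholds are the user-adjustable pair)."""

    t_low: float = -750.0       # lower growing threshold (HU)
    t_high: float = -150.0      # upper growing threshold (HU)
    roundness: float = 0.5      # 0 = keep all irregularity, 1 = maximally round
    wall_margin_mm: float = 1.4  # exclusion margin around detected chest wall
    voi_scale: float = 3.0      # VOI side length = voi_scale x expected diameter
    snap_radius_mm: float = 2.0  # how far a seed may be moved into the band

    def __post_init__(self) -> None:
        if not self.t_low < self.t_high:
            raise ValueError("t_low must be below t_high")
        if not 0.0 <= self.roundness <= 1.0:
            raise ValueError("roundness must be in [0, 1]")
        if self.wall_margin_mm < 0:
            raise ValueError("wall margin must be >= 0")
        if self.voi_scale < 1.5:
            raise ValueError("VOI scale factor must be >= 1.5")


@dataclass
class SegmentationResult:
    """Final mask plus the audit trail of the pipeline."""

    mask: NoduleMask
    voi: VoiBox
    seed_index: tuple[int, int, int]
    params: SegmentationParams
    intermediates: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------


def define_voi(vol: CTVolume, seed_input: SeedInput, params: SegmentationParams) -> VoiBox:
    """Cubic voxel box centered on the seed, world side = voi_scale x scale.

    Clipped to the volume; always contains the seed voxel.
    """
    seed = world_to_voxel(vol, seed_input.seed_world)
    side = params.voi_scale * seed_input.scale_mm
    box = []
    for ax in range(3):
        half = max(1, int(round(side / (2.0 * vol.spacing[ax]))))
        lo = max(0, seed[ax] - half)
        hi = min(vol.shape[ax], seed[ax] + half)
        hi = max(hi, seed[ax] + 1)  # keep the seed inside after clipping
        box.append((lo, hi))
    return tuple(box)  # type: ignore[return-value]


def _voi_slices(voi: VoiBox) -> tuple[slice, slice, slice]:
    return tuple(slice(lo, hi) for lo, hi in voi)  # type: ignore[return-value]


def region_grow(
    vol: CTVolume, voi: VoiBox, seed: tuple[int, int, int],
    t_low: float, t_high: float,
) -> NoduleMask:
    """Maximal 6-connected in-band component containing the seed, within the VOI.

    The band is closed on both ends: a voxel belongs iff
    ``t_low <= HU <= t_high``.
    """
    sl = _voi_slices(voi)
    sub = vol.values[sl]
    local_seed = tuple(seed[ax] - voi[ax][0] for ax in range(3))
    for ax in range(3):
        if not 0 <= local_seed[ax] < sub.shape[ax]:
            raise ValueError(f"seed {seed} outside VOI {voi}")
    hu = float(vol.values[seed])
    if not t_low <= hu <= t_high:
        raise SeedOutOfRangeError(
            f"seed outside density range: {hu:.1f} HU not in [{t_low:g}, {t_high:g}]"
        )
    in_band = (sub >= t_low) & (sub <= t_high)
    labels, _ = ndimage.label(in_band, structure=CONN6)
    component = labels == labels[local_seed]
    out = np.zeros(vol.shape, dtype=bool)
    out[sl] = component
    return NoduleMask(values=out, spacing=vol.spacing, origin=vol.origin)


def remove_wall(
    vol: CTVolume, voi: VoiBox, grown: NoduleMask,
    t_high: float, wall_margin_mm: float,
) -> NoduleMask:
    """Subtract the chest wall's partial-volume shell from the grown mask.

    The wall is identified as any 6-connected component of above-band voxels
    (HU > t_high) that touches a VOI face — the only way a dense structure of
    that size enters the VOI from outside.  The grown mask is cleared within
    ``wall_margin_mm`` (anisotropy-aware Euclidean distance) of the wall, which
    removes the lung/wall transition shell the region growing leaks into.
    """
    if grown.voxel_count == 0:
        raise ValueError("grown mask is empty")
    sl = _voi_slices(voi)
    sub = vol.values[sl]
    above = sub > t_high
    if not above.any():
        return grown
    labels, n = ndimage.label(above, structure=CONN6)
    face_labels: set[int] = set()
    for ax in range(3):
        for face in (0, -1):
            idx = [slice(None)] * 3
            idx[ax] = face
            face_labels.update(np.unique(labels[tuple(idx)]))
    face_labels.discard(0)
    if not face_labels:
        return grown
    wall = np.isin(labels, sorted(face_labels))
    dist = ndimage.distance_transform_edt(~wall, sampling=vol.spacing)
    exclusion = dist <= wall_margin_mm
    out = grown.values.copy()
    out_sub = out[sl]
    out_sub &= ~exclusion
    out[sl] = out_sub
    if not out.any():
        raise NoduleLostError(
            "nodule lost to wall removal (seed likely in pleural partial-volume shell)"
        )
    return NoduleMask(values=out, spacing=grown.spacing, origin=grown.origin)


def _ball_structure(radius_mm: float, spacing) -> np.ndarray | None:
    """Anisotropic Euclidean ball structuring element; None if sub-voxel."""
    r = [int(math.floor(radius_mm / s)) for s in spacing]
    if max(r) == 0:
        return None
    grids = np.ogrid[tuple(slice(-ri, ri + 1) for ri in r)]
    dist2 = sum((g * s) ** 2 for g, s in zip(grids, spacing))
    return dist2 <= radius_mm**2


def remove_vessels(
    grown: NoduleMask, seed: tuple[int, int, int],
    roundness: float, scale_mm: float, spacing,
) -> NoduleMask:
    """Cull thin attached structures (vessels) by opening with limited regrowth.

    The roundness knob maps to an opening radius rho = roundness x scale / 4
    (roundness 0 keeps maximal irregularity: identity).  After opening, the
    component containing the seed is regrown by conditional dilation into the
    pre-opening mask, but only to a geodesic depth of rho: the nodule's own
    margin (removed by the erosion) is restored, while an attached vessel —
    which the opening erased well beyond that depth — stays out apart from a
    stump of at most rho at the attachment site.
    """
    if not grown.values[seed]:
        raise ValueError("grown mask does not contain the seed")
    if roundness <= 0.0:
        return grown
    rho = roundness * scale_mm / 4.0
    selem = _ball_structure(rho, spacing)
    if selem is None:
        return grown

    def _open_and_regrow(r_mm: float):
        se = _ball_structure(r_mm, spacing)
        if se is None:
            return grown.values
        opened = ndimage.binary_opening(grown.values, structure=se)
        if not opened.any():
            return None
        if opened[seed]:
            labels, _ = ndimage.label(opened, structure=CONN6)
            marker = labels == labels[seed]
        else:
            # seed eroded away: start from the opened component nearest to it
            labels, _ = ndimage.label(opened, structure=CONN6)
            idx = ndimage.distance_transform_edt(
                labels == 0, sampling=spacing, return_distances=False,
                return_indices=True,
            )
            nearest = tuple(idx[ax][seed] for ax in range(3))
            marker = labels == labels[nearest]
        n_iter = max(1, int(math.ceil(r_mm / min(spacing))))
        regrown = ndimage.binary_dilation(
            marker, structure=CONN6, iterations=n_iter, mask=grown.values
        )
        return regrown

    result = _open_and_regrow(rho)
    if result is None:
        result = _open_and_regrow(rho / 2.0)  # one fallback at half radius
        if result is None:
            raise RoundnessTooAggressiveError(
                f"roundness too aggressive for nodule size (opening radius {rho:.2f} mm)"
            )
    return NoduleMask(values=result, spacing=grown.spacing, origin=grown.origin)


def fill_holes(mask: NoduleMask) -> NoduleMask:
    """Add enclosed cavities to the mask, in 3-D and per axial slice.

    This is what folds a part-solid nodule's dense core — excluded by the
    growing band — back into the measured lesion.
    """
    filled = ndimage.binary_fill_holes(mask.values, structure=CONN6)
    for z in range(filled.shape[2]):
        filled[:, :, z] = ndimage.binary_fill_holes(filled[:, :, z])
    return NoduleMask(values=filled, spacing=mask.spacing, origin=mask.origin)


def _snap_seed(
    vol: CTVolume, seed: tuple[int, int, int], voi: VoiBox,
    params: SegmentationParams,
) -> tuple[tuple[int, int, int], bool]:
    """Move an out-of-band seed to the nearest in-band voxel within the snap radius."""
    hu = float(vol.values[seed])
    if params.t_low <= hu <= params.t_high:
        return seed, False
    r = [int(math.floor(params.snap_radius_mm / s)) for s in vol.spacing]
    grids = np.ogrid[tuple(slice(-ri, ri + 1) for ri in r)]
    dist2 = sum((g * s) ** 2 for g, s in zip(grids, vol.spacing))
    offsets = np.argwhere(dist2 <= params.snap_radius_mm**2) - np.array(r)
    # deterministic order: by distance, then lexicographic offset
    d2 = np.array([
        sum((o * s) ** 2 for o, s in zip(off, vol.spacing)) for off in offsets
    ])
    order = np.lexsort((offsets[:, 2], offsets[:, 1], offsets[:, 0], d2))
    for off in offsets[order]:
        cand = tuple(int(seed[ax] + off[ax]) for ax in range(3))
        if any(not voi[ax][0] <= cand[ax] < voi[ax][1] for ax in range(3)):
            continue
        if params.t_low <= float(vol.values[cand]) <= params.t_high:
            return cand, True
    raise NoSubsolidTissueError(
        f"no subsolid tissue at seed: no voxel in [{params.t_low:g}, "
        f"{params.t_high:g}] HU within {params.snap_radius_mm:g} mm"
    )


def _nearest_mask_voxel(mask: np.ndarray, seed, spacing) -> tuple[int, int, int]:
    idx = ndimage.distance_transform_edt(
        ~mask, sampling=spacing, return_distances=False, return_indices=True
    )
    return tuple(int(idx[ax][seed]) for ax in range(3))


def segment_nodule(
    vol: CTVolume, seed_input: SeedInput,
    params: SegmentationParams | None = None,
    keep_intermediates: bool = True,
) -> SegmentationResult:
    """Run the full pipeline: VOI, seed snap, growing, wall/vessel removal, fill.

    Pure function of its inputs; raises a :class:`SegmentationError` subclass
    on the failure modes (seed in air, mask lost to wall removal, empty result).
    """
    params = params or SegmentationParams()
    voi = define_voi(vol, seed_input, params)
    seed = world_to_voxel(vol, seed_input.seed_world)
    seed, snapped = _snap_seed(vol, seed, voi, params)

    grown = region_grow(vol, voi, seed, params.t_low, params.t_high)
    wallless = remove_wall(vol, voi, grown, params.t_high, params.wall_margin_mm)
    eff_seed = seed
    if not wallless.values[eff_seed]:
        eff_seed = _nearest_mask_voxel(wallless.values, seed, vol.spacing)
    vesselless = remove_vessels(
        wallless, eff_seed, params.roundness, seed_input.scale_mm, vol.spacing
    )
    final = fill_holes(vesselless)
    if final.voxel_count == 0:
        raise SegmentationFailedError("segmentation failed: empty final mask")

    sl = _voi_slices(voi)
    touches = _touches_box_face(final.values[sl])
    flags = {
        "seed_snapped": bool(snapped),
        "wall_removed": bool(wallless.voxel_count != grown.voxel_count),
        "vessels_removed": bool(vesselless.voxel_count != wallless.voxel_count),
        "holes_filled": bool(final.voxel_count != vesselless.voxel_count),
        "touches_voi_boundary": bool(touches),
    }
    intermediates = (
        {"grown": grown, "wall_removed": wallless, "vessel_removed": vesselless}
        if keep_intermediates
        else {}
    )
    return SegmentationResult(
        mask=final, voi=voi, seed_index=seed, params=params,
        intermediates=intermediates, flags=flags,
    )


def _touches_box_face(sub: np.ndarray) -> bool:
    for ax in range(3):
        for face in (0, -1):
            idx = [slice(None)] * 3
            idx[ax] = face
            if sub[tuple(idx)].any():
                return True
    return False
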