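"""Digital CT phantoms with analytically known nodule volume, mass and density.

The generator emulates the acquisition regime of a low-dose lung screening
protocol (0.7 mm isotropic reconstruction grid, Gaussian noise of order
20 HU) and places a spherical subsolid nodule — optionally with a denser
solid core, an attached vessel and a nearby chest-wall slab — in uniform
lung parenchyma.  Partial-volume blur at structure boundaries is synthesized
by supersampled averaging: each voxel value is the mean HU of ``factor**3``
subvoxel label assignments.  Ground truth (volume, mass, mean density,
effective diameter) is computed from closed-form geometry, never from the
noisy voxel data, so it is exact and noise-independent.

Overlapping structures are resolved by priority: core > vessel > nodule >
wall > background.  The vessel cylinder starts one vessel-radius inside the
nodule surface so attachment is guaranteed; the small sphere–cylinder
overlap it carves out of the nodule has a closed form and is subtracted
from the nodule-labelled truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .ct_io import CTVolume, NoduleMask, clamp_hu

SOLID_FLOOR_HU = -150.0  # upper region-growing threshold: anything denser is "solid"


@dataclass
class PhantomSpec:
    """Geometry, attenuation and noise parameters of one synthetic phantom.

    All lengths are world mm; all attenuations are HU.  ``center=None``
    places the nodule at the volume center.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (0.7, 0.7, 0.7)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_hu: float = -850.0
    center: tuple[float, float, float] | None = None
    diameter_mm: float = 10.0
    ggo_hu: float = -600.0
    core_diameter_mm: float | None = None
    core_hu: float = 50.0
    vessel_radius_mm: float | None = None
    vessel_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    vessel_hu: float = -50.0
    wall_thickness_mm: float | None = None
    wall_hu: float = 40.0
    wall_gap_mm: float = 0.0
    noise_sd_hu: float = 20.0
    supersample: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.center is None:
            # volume center (world)
            self.center = tuple(
                o + (n - 1) / 2.0 * s
                for o, n, s in zip(self.origin, self.shape, self.spacing)
            )
        self.center = tuple(float(c) for c in self.center)
        if self.diameter_mm <= 0:
            raise ValueError("nodule diameter must be positive")
        if self.core_diameter_mm is not None:
            if not 0 < self.core_diameter_mm < self.diameter_mm:
                raise ValueError("core diameter must be in (0, nodule diameter)")
            if self.core_hu <= SOLID_FLOOR_HU:
                raise ValueError(
                    f"core must be solid-range (HU > {SOLID_FLOOR_HU:g}), got {self.core_hu:g}"
                )
        if not self.background_hu < self.ggo_hu < SOLID_FLOOR_HU:
            raise ValueError(
                "ground-glass HU must lie strictly between background "
                f"({self.background_hu:g}) and {SOLID_FLOOR_HU:g}"
            )
        if self.supersample < 1:
            raise ValueError("supersampling factor must be >= 1")
        if self.vessel_radius_mm is not None:
            if self.vessel_radius_mm <= 0:
                raise ValueError("vessel radius must be positive")
            if self.vessel_radius_mm >= self.radius:
                raise ValueError("vessel radius must be smaller than the nodule radius")
            if (
                self.core_diameter_mm is not None
                and self.core_diameter_mm / 2.0 >= self.radius - self.vessel_radius_mm
            ):
                raise ValueError("core would intersect the attached vessel")
        if self.wall_thickness_mm is not None and self.wall_thickness_mm <= 0:
            raise ValueError("wall thickness must be positive")
        # nodule must fit strictly inside the sampled extent
        for ax in range(3):
            lo = self.origin[ax] - 0.5 * self.spacing[ax]
            hi = self.origin[ax] + (self.shape[ax] - 0.5) * self.spacing[ax]
            if self.center[ax] - self.radius < lo or self.center[ax] + self.radius > hi:
                raise ValueError(
                    f"nodule (center {self.center}, d={self.diameter_mm} mm) "
                    f"intersects the volume boundary on axis {'xyz'[ax]}"
                )

    @property
    def radius(self) -> float:
        return self.diameter_mm / 2.0

    # -- config round-trip -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "PhantomSpec":
        """Load a spec from a YAML or JSON config file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"phantom config {path} must be a mapping")
        return cls.from_dict(data)


@dataclass
class PhantomTruth:
    """Closed-form ground truth for one phantom (noise-independent)."""

    volume_mm3: float
    mass_mg: float
    mean_density_mg_ml: float
    effective_diameter_mm: float
    mask: NoduleMask

    def to_dict(self) -> dict:
        return {
            "volume_mm3": self.volume_mm3,
            "mass_mg": self.mass_mg,
            "mean_density_mg_ml": self.mean_density_mg_ml,
            "effective_diameter_mm": self.effective_diameter_mm,
            "mask_voxels": self.mask.voxel_count,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# geometry helpers


def _sphere_volume(d: float) -> float:
    return math.pi / 6.0 * d**3


def _cyl_sphere_overlap(R: float, r: float) -> float:
    """Volume of {cylinder of radius r starting R-r from the center} ∩ sphere R.

    The cylinder axis passes through the sphere center; its base plane sits at
    axial distance R - r, so it penetrates the sphere by one cylinder radius.
    Splitting at u* = sqrt(R^2 - r^2) (where the sphere's cross-section radius
    equals r) gives a full-disk part and a spherical-cap part, both elementary.
    """
    if r >= R:
        raise ValueError("vessel radius must be smaller than nodule radius")
    u0 = math.sqrt(R * R - r * r)
    s_star = u0 - (R - r)  # axial extent over which the full disk is inside
    full_disk = math.pi * r * r * s_star
    cap = math.pi * ((R * R * R - R**3 / 3.0) - (R * R * u0 - u0**3 / 3.0))
    return full_disk + cap


def _vessel_frame(spec: PhantomSpec):
    """Unit axis, start point and length of the vessel cylinder."""
    u = np.asarray(spec.vessel_axis, dtype=float)
    n = np.linalg.norm(u)
    if n == 0:
        raise ValueError("vessel axis must be nonzero")
    u = u / n
    c0 = np.asarray(spec.center) + (spec.radius - spec.vessel_radius_mm) * u
    # long enough to leave the volume on any axis
    length = float(
        sum(n_ * s_ for n_, s_ in zip(spec.shape, spec.spacing))
    )
    return u, c0, length


class _Component:
    """A labelled geometric region: an inside-test plus a world bbox."""

    def __init__(self, name: str, hu: float, inside, bbox_world):
        self.name = name
        self.hu = hu
        self.inside = inside  # inside(X, Y, Z) -> bool array (broadcasting)
        self.bbox_world = bbox_world  # ((xlo,xhi),(ylo,yhi),(zlo,zhi))


def _components(spec: PhantomSpec) -> list[_Component]:
    """Components in priority order (highest first), wall excluded."""
    c = np.asarray(spec.center)
    comps: list[_Component] = []
    if spec.core_diameter_mm is not None:
        rc = spec.core_diameter_mm / 2.0

        def in_core(X, Y, Z, c=c, rc=rc):
            return (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= rc * rc

        comps.append(
            _Component("core", spec.core_hu, in_core,
                       tuple((c[a] - rc, c[a] + rc) for a in range(3)))
        )
    if spec.vessel_radius_mm is not None:
        u, c0, length = _vessel_frame(spec)
        rv = spec.vessel_radius_mm

        def in_vessel(X, Y, Z, u=u, c0=c0, rv=rv, length=length):
            dx, dy, dz = X - c0[0], Y - c0[1], Z - c0[2]
            s = dx * u[0] + dy * u[1] + dz * u[2]
            rad2 = (dx - s * u[0]) ** 2 + (dy - s * u[1]) ** 2 + (dz - s * u[2]) ** 2
            return (s >= 0) & (s <= length) & (rad2 <= rv * rv)

        p1 = c0 + length * u
        bbox = tuple(
            (min(c0[a], p1[a]) - rv, max(c0[a], p1[a]) + rv) for a in range(3)
        )
        comps.append(_Component("vessel", spec.vessel_hu, in_vessel, bbox))

    R = spec.radius

    def in_nodule(X, Y, Z, c=c, R=R):
        return (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= R * R

    comps.append(
        _Component("nodule", spec.ggo_hu, in_nodule,
                   tuple((c[a] - R, c[a] + R) for a in range(3)))
    )
    return comps


def _bbox_to_index(spec: PhantomSpec, bbox_world, pad: int = 1):
    """Voxel index ranges [lo, hi) covering a world bbox, clipped to the grid."""
    rng = []
    for ax in range(3):
        a, b = bbox_world[ax]
        lo = math.ceil((a - spec.origin[ax]) / spec.spacing[ax] - 0.5) - pad
        hi = math.floor((b - spec.origin[ax]) / spec.spacing[ax] + 0.5) + pad + 1
        rng.append((max(lo, 0), min(hi, spec.shape[ax])))
    return tuple(rng)


def _fine_axes(spec: PhantomSpec, idx_rng, factor: int):
    """Per-axis subvoxel-center world coordinates over an index box."""
    axes = []
    for ax in range(3):
        lo, hi = idx_rng[ax]
        i = np.arange(lo, hi)
        j = (np.arange(factor) + 0.5) / factor - 0.5  # offsets within a voxel
        coords = spec.origin[ax] + (i[:, None] + j[None, :]) * spec.spacing[ax]
        axes.append(coords.reshape(-1))
    return axes


def _block_mean(fine: np.ndarray, factor: int) -> np.ndarray:
    nx, ny, nz = (n // factor for n in fine.shape)
    return (
        fine.reshape(nx, factor, ny, factor, nz, factor)
        .mean(axis=(1, 3, 5))
    )


def _occupancy(spec: PhantomSpec, comp: _Component, higher: list[_Component],
               factor: int) -> tuple[tuple, np.ndarray]:
    """Per-voxel occupancy of ``comp`` minus higher-priority components."""
    idx_rng = _bbox_to_index(spec, comp.bbox_world)
    if any(hi <= lo for lo, hi in idx_rng):
        empty = tuple((0, 0) for _ in range(3))
        return empty, np.zeros((0, 0, 0))
    xs, ys, zs = _fine_axes(spec, idx_rng, factor)
    X, Y, Z = xs[:, None, None], ys[None, :, None], zs[None, None, :]
    inside = comp.inside(X, Y, Z)
    for h in higher:
        inside &= ~h.inside(X, Y, Z)
    return idx_rng, _block_mean(inside.astype(np.float64), factor)


def _wall_interval(spec: PhantomSpec) -> tuple[float, float]:
    """World x-extent of the chest-wall slab (placed on the +x side)."""
    x0 = spec.center[0] + spec.radius + spec.wall_gap_mm
    return x0, x0 + spec.wall_thickness_mm


def _wall_fraction_1d(spec: PhantomSpec) -> np.ndarray:
    """Exact per-voxel overlap fraction of the slab along x (axis-aligned)."""
    a, b = _wall_interval(spec)
    i = np.arange(spec.shape[0])
    lo = spec.origin[0] + (i - 0.5) * spec.spacing[0]
    hi = lo + spec.spacing[0]
    return np.clip(
        (np.minimum(hi, b) - np.maximum(lo, a)) / spec.spacing[0], 0.0, 1.0
    )


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Synthesize the phantom volume and its closed-form ground truth.

    Voxel values are supersampled partial-volume averages of the component
    HU assignments plus seeded Gaussian noise; the returned truth (and its
    ground-truth mask, voxels with nodule occupancy >= 0.5) depends only on
    the geometry.
    """
    f = spec.supersample
    comps = _components(spec)
    bg = spec.background_hu

    hu = np.full(spec.shape, bg, dtype=np.float64)
    nodule_frac = np.zeros(spec.shape)  # occupancy of the nodule region (core + GGO)

    for k, comp in enumerate(comps):
        idx_rng, frac = _occupancy(spec, comp, comps[:k], f)
        sl = tuple(slice(lo, hi) for lo, hi in idx_rng)
        hu[sl] += frac * (comp.hu - bg)
        if comp.name in ("core", "nodule"):
            nodule_frac[sl] += frac

    if spec.wall_thickness_mm is not None:
        frac_w = _wall_fraction_1d(spec)
        hu += frac_w[:, None, None] * (spec.wall_hu - bg)
        # The slab fraction above ignores higher-priority components; where the
        # slab overlaps one, subtract the double count.  The correction is the
        # same quantity whichever component's bbox evaluates it, so assignment
        # into a canvas is safe even where bboxes overlap (core inside nodule).
        a, b = _wall_interval(spec)
        corr = np.zeros(spec.shape)
        for comp in comps:
            idx_rng = _bbox_to_index(spec, comp.bbox_world)
            if any(hi <= lo for lo, hi in idx_rng):
                continue
            xs, ys, zs = _fine_axes(spec, idx_rng, f)
            X, Y, Z = xs[:, None, None], ys[None, :, None], zs[None, None, :]
            in_any = np.zeros((len(xs), len(ys), len(zs)), dtype=bool)
            for other in comps:
                in_any |= other.inside(X, Y, Z)
            in_any &= (X >= a) & (X <= b)
            sl = tuple(slice(lo, hi) for lo, hi in idx_rng)
            corr[sl] = _block_mean(in_any.astype(np.float64), f)
        hu -= corr * (spec.wall_hu - bg)

    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd_hu, size=spec.shape)
    hu, _ = clamp_hu(hu)

    vol = CTVolume(values=hu, spacing=spec.spacing, origin=spec.origin)
    truth = _analytic_truth(spec, nodule_frac)
    return vol, truth


def _analytic_truth(spec: PhantomSpec, nodule_frac: np.ndarray) -> PhantomTruth:
    V_sphere = _sphere_volume(spec.diameter_mm)
    V_core = _sphere_volume(spec.core_diameter_mm) if spec.core_diameter_mm else 0.0
    V_ov = (
        _cyl_sphere_overlap(spec.radius, spec.vessel_radius_mm)
        if spec.vessel_radius_mm
        else 0.0
    )
    volume = V_sphere - V_ov
    ggo_vol = V_sphere - V_core - V_ov
    mass = (
        ggo_vol * (spec.ggo_hu + 1000.0) / 1000.0
        + V_core * (spec.core_hu + 1000.0) / 1000.0
    )
    density = 1000.0 * mass / volume
    d_eff = (6.0 * volume / math.pi) ** (1.0 / 3.0)
    mask = NoduleMask(
        values=nodule_frac >= 0.5, spacing=spec.spacing, origin=spec.origin
    )
    return PhantomTruth(
        volume_mm3=volume,
        mass_mg=mass,
        mean_density_mg_ml=density,
        effective_diameter_mm=d_eff,
        mask=mask,
    )


def occupancy_oracle(spec: PhantomSpec, factor: int) -> float:
    """Brute-force nodule volume estimate (mm^3) by subvoxel counting.

    Counts supersampled subvoxels inside the nodule region (sphere minus any
    vessel carve-out) and multiplies by the subvoxel volume; converges to the
    analytic truth as ``factor`` grows.  Independent of the partial-volume
    synthesis path in :func:`generate_phantom`.
    """
    if factor < 1:
        raise ValueError("supersampling factor must be >= 1")
    comps = _components(spec)
    nodule = next(c for c in comps if c.name == "nodule")
    higher = [c for c in comps if c.name == "vessel"]
    idx_rng = _bbox_to_index(spec, nodule.bbox_world)
    xs, ys, zs = _fine_axes(spec, idx_rng, factor)
    X, Y, Z = xs[:, None, None], ys[None, :, None], zs[None, None, :]
    inside = nodule.inside(X, Y, Z)
    for h in higher:
        inside &= ~h.inside(X, Y, Z)
    sub_vol = spec.spacing[0] * spec.spacing[1] * spec.spacing[2] / factor**3
    return float(np.count_nonzero(inside)) * sub_vol
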