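import numpy as np
import pytest

from ssnvol.ct_io import CTVolume, NoduleMask
from ssnvol.phantom import PhantomSpec, generate_phantom
from ssnvol.quantify import quantify
from ssnvol.segmentation import (
    NoSubsolidTissueError,
    SeedInput,
    SeedOutOfRangeError,
    SegmentationParams,
    define_voi,
    fill_holes,
    region_grow,
    remove_vessels,
    remove_wall,
    segment_nodule,
)

from conftest import offset_spec, rel_err_pct, run_pipeline, sphere_volume

SP7 = (0.7, 0.7, 0.7)


def flood_fill_oracle(values, seed, t_low, t_high):
    """Independent brute-force 6-connected flood fill (pure-python BFS)."""
    shape = values.shape
    in_band = lambda p: t_low <= values[p] <= t_high
    assert in_band(seed)
    seen = {seed}
    stack = [seed]
    while stack:
        x, y, z = stack.pop()
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            q = (x + dx, y + dy, z + dz)
            if any(not 0 <= q[a] < shape[a] for a in range(3)):
                continue
            if q not in seen and in_band(q):
                seen.add(q)
                stack.append(q)
    out = np.zeros(shape, bool)
    for p in seen:
        out[p] = True
    return out


def full_box(shape):
    return tuple((0, n) for n in shape)


# ---------------------------------------------------------------------------
# define_voi


def test_voi_side_from_stroke():
    vol = CTVolume(values=np.zeros((100, 100, 100)), spacing=(1, 1, 1))
    si = SeedInput(stroke=((50.0, 45.0, 50.0), (50.0, 55.0, 50.0)))
    voi = define_voi(vol, si, SegmentationParams(voi_scale=3.0))
    assert voi == ((35, 65), (35, 65), (35, 65))  # 30 voxels per side around seed


def test_voi_clipped_at_face_still_contains_seed():
    vol = CTVolume(values=np.zeros((100, 100, 100)), spacing=(1, 1, 1))
    si = SeedInput(point=(5.0, 50.0, 50.0))
    voi = define_voi(vol, si, SegmentationParams())
    assert voi[0][0] == 0 and voi[0][1] == 20
    assert voi[0][0] <= 5 < voi[0][1]


def test_voi_default_scale_for_point_input():
    vol = CTVolume(values=np.zeros((100, 100, 100)), spacing=(1, 1, 1))
    si = SeedInput(point=(50.0, 50.0, 50.0))  # default expected diameter 10 mm
    voi = define_voi(vol, si, SegmentationParams())
    assert all(hi - lo == 30 for lo, hi in voi)


def test_seed_input_validation():
    with pytest.raises(ValueError, match="exactly one"):
        SeedInput()
    with pytest.raises(ValueError, match="1 mm"):
        SeedInput(stroke=((0.0, 0.0, 0.0), (0.5, 0.0, 0.0)))


# ---------------------------------------------------------------------------
# region_grow


def test_region_grow_isolated_voxel():
    values = np.full((5, 5, 5), -1000.0)
    values[2, 2, 2] = -400.0
    vol = CTVolume(values=values, spacing=(1, 1, 1))
    mask = region_grow(vol, full_box(vol.shape), (2, 2, 2), -750, -150)
    assert mask.voxel_count == 1 and mask.values[2, 2, 2]


def test_region_grow_uniform_volume_fills_voi():
    vol = CTVolume(values=np.full((6, 6, 6), -400.0), spacing=(1, 1, 1))
    voi = ((1, 5), (1, 5), (1, 5))
    mask = region_grow(vol, voi, (2, 2, 2), -750, -150)
    assert mask.voxel_count == 4**3
    assert not mask.values[0, :, :].any()


def test_region_grow_excludes_edge_neighbors():
    """Two in-range voxels sharing only an edge are separate under 6-connectivity."""
    values = np.full((5, 5, 5), -1000.0)
    values[2, 2, 2] = -400.0
    values[3, 3, 2] = -400.0  # diagonal in the xy-plane: edge contact only
    vol = CTVolume(values=values, spacing=(1, 1, 1))
    mask = region_grow(vol, full_box(vol.shape), (2, 2, 2), -750, -150)
    oracle = flood_fill_oracle(values, (2, 2, 2), -750, -150)
    assert not mask.values[3, 3, 2]
    np.testing.assert_array_equal(mask.values, oracle)


def test_region_grow_seed_out_of_band_raises():
    vol = CTVolume(values=np.full((4, 4, 4), -900.0), spacing=(1, 1, 1))
    with pytest.raises(SeedOutOfRangeError, match="-900.0 HU"):
        region_grow(vol, full_box(vol.shape), (1, 1, 1), -750, -150)


def test_region_grow_matches_flood_fill_oracle_randomized():
    """Exact set equality with a brute-force flood fill on random small volumes."""
    rng = np.random.default_rng(17)
    for _ in range(25):
        shape = tuple(rng.integers(4, 13, 3))
        values = rng.uniform(-1000, 0, shape)
        t_low, t_high = sorted(rng.uniform(-1000, 0, 2))
        in_band = np.argwhere((values >= t_low) & (values <= t_high))
        if len(in_band) == 0:
            continue
        seed = tuple(in_band[rng.integers(len(in_band))])
        vol = CTVolume(values=values, spacing=(1, 1, 1))
        mask = region_grow(vol, full_box(shape), seed, t_low, t_high)
        np.testing.assert_array_equal(
            mask.values, flood_fill_oracle(values, seed, t_low, t_high)
        )


def test_region_grow_band_widening_monotonicity():
    """Widening the threshold band never shrinks the grown region."""
    rng = np.random.default_rng(23)
    values = rng.uniform(-1000, 0, (12, 12, 12))
    vol = CTVolume(values=values, spacing=(1, 1, 1))
    seed = tuple(np.unravel_index(np.argmax(values > -500), values.shape))
    values[seed] = -400.0
    narrow = region_grow(vol, full_box(vol.shape), seed, -600, -300)
    wide = region_grow(vol, full_box(vol.shape), seed, -750, -150)
    assert np.all(wide.values[narrow.values])


# ---------------------------------------------------------------------------
# remove_wall


def test_remove_wall_no_wall_is_identity():
    values = np.full((10, 10, 10), -400.0)
    vol = CTVolume(values=values, spacing=(1, 1, 1))
    voi = full_box(vol.shape)
    grown = region_grow(vol, voi, (5, 5, 5), -750, -150)
    out = remove_wall(vol, voi, grown, -150, 1.4)
    np.testing.assert_array_equal(out.values, grown.values)


def test_remove_wall_interior_dense_blob_is_not_wall():
    """A dense blob not touching any VOI face must be left alone."""
    values = np.full((12, 12, 12), -400.0)
    values[5:7, 5:7, 5:7] = 100.0  # dense but interior
    vol = CTVolume(values=values, spacing=(1, 1, 1))
    voi = full_box(vol.shape)
    grown = region_grow(vol, voi, (1, 1, 1), -750, -150)
    out = remove_wall(vol, voi, grown, -150, 1.4)
    np.testing.assert_array_equal(out.values, grown.values)


def test_remove_wall_strips_pleural_shell_on_phantom():
    """With a chest-wall slab in contact, recovery stays within 10% of truth."""
    rng = np.random.default_rng(31)
    spec = offset_spec(10.0, rng, noise_sd_hu=0.0, wall_thickness_mm=20.0,
                       wall_gap_mm=0.0)
    truth, metrics, result = run_pipeline(spec)
    assert result.flags["wall_removed"]
    assert abs(rel_err_pct(metrics.volume_mm3, truth.volume_mm3)) < 10.0
    # the leaked shell is gone: the mask stays clear of the above-band slab
    vol, _ = generate_phantom(spec)
    assert not (result.mask.values & (vol.values > -150.0)).any()


# ---------------------------------------------------------------------------
# remove_vessels


def test_remove_vessels_zero_roundness_is_identity():
    rng = np.random.default_rng(5)
    mask = NoduleMask(values=rng.random((15, 15, 15)) > 0.6, spacing=SP7)
    seed = tuple(np.argwhere(mask.values)[0])
    out = remove_vessels(mask, seed, 0.0, 10.0, SP7)
    np.testing.assert_array_equal(out.values, mask.values)


def test_remove_vessels_ball_without_attachments_is_identity():
    g = np.ogrid[0:40, 0:40, 0:40]
    dist2 = sum(((a - 20) * s) ** 2 for a, s in zip(g, SP7))
    ball = dist2 <= 5.0**2
    mask = NoduleMask(values=ball, spacing=SP7)
    out = remove_vessels(mask, (20, 20, 20), 0.5, 10.0, SP7)
    np.testing.assert_array_equal(out.values, ball)


def test_remove_vessels_culls_attached_cylinder_on_phantom():
    """Attached 1 mm vessel removed: volume within 5% of sphere-only truth."""
    rng = np.random.default_rng(37)
    spec = offset_spec(10.0, rng, noise_sd_hu=0.0, vessel_radius_mm=1.0)
    truth, metrics, result = run_pipeline(spec)
    assert abs(rel_err_pct(metrics.volume_mm3, sphere_volume(10.0))) < 5.0


# ---------------------------------------------------------------------------
# fill_holes


def test_fill_holes_shell_becomes_solid_and_is_idempotent():
    g = np.ogrid[0:30, 0:30, 0:30]
    dist2 = sum((a - 15.0) ** 2 for a in g)
    shell = (dist2 <= 100) & (dist2 >= 36)
    mask = NoduleMask(values=shell, spacing=(1, 1, 1))
    filled = fill_holes(mask)
    np.testing.assert_array_equal(filled.values, dist2 <= 100)
    again = fill_holes(filled)
    np.testing.assert_array_equal(again.values, filled.values)


def test_fill_holes_recovers_part_solid_core_mass():
    """Without filling, the solid core (above-band) is missed and mass falls far
    short; with filling the measured mass is within 10% of truth."""
    rng = np.random.default_rng(41)
    spec = offset_spec(10.0, rng, noise_sd_hu=0.0, core_diameter_mm=5.0, core_hu=50.0)
    vol, truth = generate_phantom(spec)
    c = spec.center
    # click on the ground-glass rim (a center click would land on the solid
    # core, beyond the 2 mm snap radius for a 5 mm core)
    si = SeedInput(point=(c[0], c[1] + 3.2, c[2]))
    result = segment_nodule(vol, si)
    assert result.flags["holes_filled"]
    unfilled = result.intermediates["vessel_removed"]
    m_unfilled = quantify(vol, unfilled)
    m_filled = quantify(vol, result.mask)
    assert rel_err_pct(m_unfilled.mass_mg, truth.mass_mg) < -20.0
    assert abs(rel_err_pct(m_filled.mass_mg, truth.mass_mg)) < 10.0


# ---------------------------------------------------------------------------
# segment_nodule pipeline


def test_pipeline_recovers_pure_ggo_sphere():
    rng = np.random.default_rng(43)
    spec = offset_spec(10.0, rng, noise_sd_hu=0.0)
    truth, metrics, _ = run_pipeline(spec)
    assert abs(rel_err_pct(metrics.volume_mm3, sphere_volume(10.0))) < 5.0


def test_pipeline_seed_position_invariance_within_component():
    """Any in-mask, in-band seed yields the identical final mask (noise-free)."""
    rng = np.random.default_rng(47)
    spec = offset_spec(10.0, rng, noise_sd_hu=0.0)
    vol, _ = generate_phantom(spec)
    c = spec.center
    masks = []
    for shift in ((0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (0.0, -2.0, 1.0)):
        pt = tuple(ci + si for ci, si in zip(c, shift))
        res = segment_nodule(vol, SeedInput(point=pt))
        masks.append(res.mask.values)
    np.testing.assert_array_equal(masks[0], masks[1])
    np.testing.assert_array_equal(masks[0], masks[2])


def test_pipeline_is_deterministic():
    spec = PhantomSpec(diameter_mm=10.0, noise_sd_hu=20.0, seed=7)
    vol, _ = generate_phantom(spec)
    si = SeedInput(point=spec.center)
    m1 = segment_nodule(vol, si).mask.values
    m2 = segment_nodule(vol, si).mask.values
    np.testing.assert_array_equal(m1, m2)


def test_pipeline_seed_in_air_raises():
    spec = PhantomSpec(diameter_mm=10.0, noise_sd_hu=0.0)
    vol, _ = generate_phantom(spec)
    far = tuple(c + 20.0 for c in spec.center)
    with pytest.raises(NoSubsolidTissueError, match="no subsolid tissue"):
        segment_nodule(vol, SeedInput(point=far))


def test_pipeline_snaps_seed_on_solid_core():
    """A click on the dense core (above-band) is snapped into the GGO band."""
    rng = np.random.default_rng(53)
    spec = offset_spec(10.0, rng, noise_sd_hu=0.0, core_diameter_mm=4.0)
    vol, _ = generate_phantom(spec)
    res = segment_nodule(vol, SeedInput(point=spec.center))
    assert res.flags["seed_snapped"]
    assert res.mask.voxel_count > 0


def test_pipeline_prefill_mask_is_within_band_and_voi():
    rng = np.random.default_rng(59)
    spec = offset_spec(10.0, rng, noise_sd_hu=20.0, seed=2)
    vol, _ = generate_phantom(spec)
    res = segment_nodule(vol, SeedInput(point=spec.center))
    pre = res.intermediates["vessel_removed"].values
    in_band = (vol.values >= -750) & (vol.values <= -150)
    assert np.all(in_band[pre])
    outside_voi = np.ones(vol.shape, bool)
    sl = tuple(slice(lo, hi) for lo, hi in res.voi)
    outside_voi[sl] = False
    assert not (res.mask.values & outside_voi).any()
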