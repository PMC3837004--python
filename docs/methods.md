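# Methods

## The measurement model

Subsolid nodules (SSNs) are lung lesions of hazy, ground-glass attenuation,
optionally containing a solid component. On CT they occupy an attenuation
band between aerated parenchyma (≈ −850 HU) and soft tissue (> −150 HU).
For soft tissue, attenuation maps linearly to physical density:
`density [mg/ml] ≈ HU + 1000` (water = 0 HU = 1000 mg/ml, air = −1000 HU =
0 mg/ml), provided the lesion contains no calcium and no contrast material
was injected. `ssnvol` therefore measures, over a segmented voxel set:

- volume `V = N · sx·sy·sz`,
- mean density `ρ̄ = mean(HU) + 1000` with the per-voxel density floored at
  0 mg/ml (noise can push clamped values slightly below −1000 HU; physical
  density is nonnegative),
- mass `M = Σ_voxels max(HU+1000, 0) · v_voxel / 1000`, integrated in one
  pass; this is analytically identical to `V·ρ̄/1000` and asserted equal to
  1e-9 relative in the tests,
- effective diameter `d_eff = (6V/π)^{1/3}`, the sphere-equivalent
  diameter. A caliper-like maximal 3-D extent is available separately
  (`quantify.max_extent`) because manual diameter measurements differ
  systematically from sphere-equivalent ones.

## Segmentation pipeline

All user-facing coordinates are world millimetres; voxel indices are
0-based with the voxel center as its world position; arrays are indexed
(x, y, z) with index axes parallel to world axes.

1. **Seed and scale.** A click gives the seed directly with a configurable
   expected diameter (default 10 mm); a stroke across the largest diameter
   gives the midpoint as seed and its length as the scale.
2. **VOI.** A cube of world side `k × scale` (default k = 3) centered on
   the seed, clipped to the volume. k = 3 leaves room for wall and vessel
   context without pulling in unrelated structures.
3. **Seed snap.** If the seed voxel is outside the growing band (an
   observer may click on a core or vessel), it moves to the nearest
   in-band voxel within 2 mm (anisotropy-aware; deterministic tie-break by
   distance then lexicographic offset). No candidate → "no subsolid tissue
   at seed".
4. **Region growing.** The maximal 6-connected component of voxels with
   `t_low ≤ HU ≤ t_high` containing the seed, inside the VOI. The band is
   closed on both ends for determinism; 6-connectivity is the strictest
   standard choice and prevents diagonal leakage through noise. Defaults
   −750 / −150 HU; both thresholds are exposed since density cut-off
   adjustment is part of the interactive workflow.
5. **Chest-wall removal.** Above-band (HU > t_high) 6-connected components
   touching any VOI face are declared wall — the wall is the only
   above-band structure that enters the VOI from outside. The grown mask
   is cleared within a Euclidean margin w (default 1.4 mm ≈ two in-plane
   voxels) of the wall, which strips the pleural partial-volume shell the
   growing leaks into. Interior dense blobs (cores, vessels in cross
   section) never touch a face and are untouched. An emptied mask raises
   "nodule lost to wall removal".
6. **Vessel removal.** Morphological opening with an anisotropy-aware ball
   of radius `ρ = roundness × scale/4` (roundness 0 → identity), then
   conditional dilation of the opened component containing the seed into
   the pre-opening mask, **limited to a geodesic depth of ρ** (voxel-wise
   6-connected steps, `ceil(ρ/min spacing)` iterations). The depth limit is
   deliberate: an attached vessel remains 6-connected to the nodule inside
   the pre-opening mask, so an unlimited reconstruction would regrow
   everything the opening removed; limiting the regrowth to the erosion
   depth restores exactly the nodule margin the erosion ate while leaving
   the vessel out apart from a ≤ ρ stump at the attachment. If the opening
   erases the seed component the radius is halved once, then the operation
   fails ("roundness too aggressive").
7. **Hole filling**, in 3-D and per axial slice. The growing band excludes
   solid tissue, yet part-solid nodules are measured as one lesion; a solid
   core enclosed by ground glass becomes a cavity in the grown mask and is
   restored here. Cores that breach the ground-glass shell are only
   partially recovered — visible as a mass underestimate.

The pipeline is a pure function of (volume, input, parameters): no
randomness anywhere.

## Digital phantom

With no public SSN screening CTs to test on, validation uses digital
phantoms in the spirit of anthropomorphic-phantom studies of volumetry
software. The generator emulates a low-dose screening acquisition: 0.7 mm
isotropic grid (the reconstruction increment of a 1.0 mm / 0.7 mm overlapping
protocol; the effective z-sampling of such software is not standardised, so
isotropic 0.7 mm is the documented default rather than a claim), lung
background −850 HU, ground-glass −600 HU (mid-band), optional solid core
(+50 HU), attached vessel (−50 HU cylinder entering the sphere by one
vessel radius, guaranteeing attachment), chest-wall slab (+40 HU), Gaussian
noise SD 20 HU (a plausible low-dose value), all configurable.

Partial volume is synthesized by supersampled averaging: each voxel value
is the mean HU over `factor³` subvoxels (default 4³), with overlaps
resolved by priority core > vessel > nodule > wall > background. Ground
truth is closed-form — sphere and cylinder volumes, the sphere∩cylinder
carve-out via an elementary cap integral — and never touches the noisy
voxel data. The ground-truth mask is the majority voxelization (nodule
occupancy ≥ 0.5). An independent brute-force occupancy oracle (subvoxel
counting) cross-checks the analytic truth to < 1% at factor 8.

**Lattice alignment.** Phantom evaluations place the nodule center at a
seeded random sub-voxel offset. Exact alignment of the sphere center with
a voxel corner or center is a measure-zero configuration that produces
voxelization resonance (boundary voxels crossing the inclusion threshold
coherently); random offsets are the standard way to sample generic
alignment, and the noise-robustness protocol prescribes them anyway.

**What the phantom does not emulate:** lung texture, airways and fissures,
scanner noise power spectra and reconstruction-kernel correlation, motion,
juxtapleural geometry beyond a flat slab, multiple or non-spherical
lesions. Passing the phantom suite therefore demonstrates correctness of
the operators and of the measurement chain under controlled conditions,
not clinical accuracy on patient data.

## Known systematic effects

- The fixed lower threshold (−750 HU) lies below the 50% partial-volume
  level between −850 HU background and −600 HU ground glass, so boundary
  voxels with ≥ 40% occupancy are included: volumes are overestimated by
  ≈ +2–5% (larger for smaller nodules, surface/volume scaling). Mass is
  much less affected because the added rim voxels carry near-background
  density (errors ≈ ±2%).
- Wall removal clips a ≤ w spherical cap from a nodule in pleural contact
  (volume ≈ −4% at 10 mm); this is the price of removing the pleural shell
  without a full lung segmentation.
- Vessel removal leaves a ≤ ρ stump and removes the vessel-occupied sliver
  inside the sphere (< 1% at default geometry).

## Agreement statistics

`bland_altman` reports mean difference, sample SD (n−1), limits of
agreement mean ± 1.96·SD (the fixed multiplier, not a small-sample
t-correction), and per-pair relative differences with the pair mean as
denominator (switchable to the first column). `paired_t` is the exact
closed form with degenerate cases defined (equal vectors → t = 0, p = 1;
zero-variance nonzero differences → t = ±∞, p = 0). `icc` defaults to
ICC(2,1) — two-way random effects, absolute agreement, single measure,
computed from the two-way ANOVA mean squares — the appropriate form for
absolute measurements by interchangeable observers; ICC(1,1) and ICC(3,1)
are available as options. Tests cross-check the ICC against an independent
sums-of-squares computation and against `pingouin`, and the t-test against
`scipy.stats.ttest_rel`.

## Problem sizes and defaults

Phantom volumes default to 96³ voxels at 0.7 mm (a 67 mm cube — ample for
a 15 mm nodule plus a 45 mm VOI); generation takes ~50 ms and a full
segment-and-measure cycle ~150 ms, so the validation suites (tens of
phantom draws) run in seconds. The synthetic observer cohort uses 33
nodules with lognormal diameters around 11 mm, 5% proportional reading
noise per observer, and a 20% manual undersegmentation factor — the scale
and direction of effects typical for manual vs semi-automatic SSN
measurement; the agreement numbers computed from it demonstrate the
statistics machinery, not any clinical finding.

## Limitations

- No DICOM series input (convert to NIfTI/NRRD first); header direction
  cosines are reoriented to the axis-aligned frame, patient-frame
  orientation is otherwise ignored.
- No automatic detection, no lobe/airway segmentation, no longitudinal
  registration or growth-rate estimation.
- The wall/vessel operators are a reconstruction in spirit of interactive
  SSN volumetry prototypes, not a clone of any commercial implementation;
  their parameters (w = 1.4 mm, ρ = roundness × scale/4, k = 3) are
  documented defaults, all exposed.
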