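# ssnvol

Semi-automatic segmentation and quantification of **subsolid pulmonary
nodules (SSNs)** on thoracic CT, for researchers who need reproducible
volume and *mass* measurements of ground-glass and part-solid lesions —
the nodule type where generic solid-nodule volumetry software fails and
manual contouring takes ~10 minutes per lesion.

## What it computes

Given a CT volume in Hounsfield units (HU) and a single user click or a
stroke across the nodule's largest diameter, `ssnvol`:

1. defines a cubic **volume of interest** (VOI) around the seed, scaled
   from the stroke length;
2. runs **dual-threshold region growing** — the maximal 6-connected set of
   voxels with HU in `[t_low, t_high]` containing the seed (defaults
   −750 HU and −150 HU, the attenuation band of ground-glass opacity);
3. applies **morphological post-processing**: above-band structures that
   enter the VOI from a face are treated as chest wall and removed together
   with a 1.4 mm exclusion margin; thin attached vessels are culled by
   opening with a ball of radius ρ = roundness × diameter/4, followed by a
   depth-limited conditional dilation that restores the nodule's own
   irregular margin; enclosed cavities (the solid core of a part-solid
   nodule, which lies above the growing band) are filled back in;
4. reports for the final mask

   - volume `V = N · sx·sy·sz` (mm³, voxel counting),
   - mean density `ρ̄ = mean HU + 1000` (mg/ml; valid for soft tissue with
     no calcium and no contrast),
   - **mass** `M = V · ρ̄ / 1000` (mg), integrated per voxel with density
     floored at 0,
   - effective diameter `d_eff = (6V/π)^{1/3}` (mm, sphere-equivalent).

Because mass combines size and attenuation, it is the more sensitive
quantity for detecting growth of slowly evolving SSNs.

The package also ships a **digital phantom generator** (spheres with
optional solid core, attached vessel and chest-wall slab, supersampled
partial-volume synthesis, seeded Gaussian noise, closed-form ground truth)
and an **agreement module** implementing the standard method-comparison
protocol: Bland–Altman limits of agreement, paired t-tests, and the
intraclass correlation coefficient ICC(2,1).

## Worked example

Simulate a 10 mm part-solid nodule (ground-glass −600 HU with a 4 mm,
+50 HU core) on a 0.7 mm isotropic grid with 20 HU noise, segment it and
compare against the analytic truth:

```yaml
# nodule.yaml
shape: [96, 96, 96]
spacing: [0.7, 0.7, 0.7]
diameter_mm: 10.0
core_diameter_mm: 4.0
noise_sd_hu: 20.0
```

```bash
ssnvol end2end --spec nodule.yaml --seed 7
```

prints (abridged):

```json
{
  "truth":    {"volume_mm3": 523.599, "mass_mg": 231.221, "effective_diameter_mm": 10.0},
  "measured": {"volume_mm3": 537.824, "mass_mg": 228.594, "effective_diameter_mm": 10.090},
  "volume_error_pct": 2.72,
  "mass_error_pct": -1.14,
  "flags": {"seed_snapped": true, "holes_filled": true}
}
```

Truth volume is the closed-form sphere volume π/6·10³ = 523.60 mm³; truth
mass adds the denser core, 231.22 mg. The measured volume overshoots by
2.7% (partial-volume voxels at the faint ground-glass rim fall inside the
growing band), mass is accurate to ~1%, and the flags record that the seed
(which landed on the solid core, outside the growing band) was snapped into
ground glass and that the core was recovered by hole filling.

The same steps are available piecewise (`ssnvol phantom`, `ssnvol segment`,
`ssnvol quantify`) and as library calls:

```python
from ssnvol import PhantomSpec, SeedInput, generate_phantom, segment_nodule, quantify

spec = PhantomSpec(diameter_mm=10.0, seed=7)
vol, truth = generate_phantom(spec)
res = segment_nodule(vol, SeedInput(point=spec.center))
print(quantify(vol, res.mask).to_dict())
```

Observer tables (CSV, one row per nodule, one column per reading) are
compared with

```bash
ssnvol compare --table measurements.csv --pairs manual:semi1,semi1:semi2 \
               --out report.json --plot ba.png
```

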