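# spectharm

Quantitative SPECT/CT phantom analysis: recovery-coefficient (RC) curves,
calibration factors, and robust inter-system variability statistics for
NEMA IEC body-phantom studies — with a synthetic reconstructed-image
simulator so the full multi-center study design can be exercised without
scanner data.

## Who this is for

Medical physicists and imaging scientists who harmonize absolute SPECT
quantification across scanners: determining calibration factors from
uniform phantom fills, measuring how much of a small sphere's activity an
imaging system recovers, and quantifying how repeatable and how
vendor-dependent those recovery measurements are.

## The model in brief

A fillable torso phantom holds six spheres (10–37 mm) at a 10:1
sphere-to-background activity-concentration ratio.  For each system the
package:

1. **Calibrates** — CF [(cps/ml)/(kBq/ml)] = (μ/(t·n·ν))/A, with μ the mean
   voxel value in a uniform ROI, t the time per projection, n the number of
   projections, ν the voxel volume, A the true concentration.
2. **Segments** each sphere by region growing from the hottest voxel near
   the known center down to the background-corrected half-maximum threshold
   VV_thresh = 0.5·(VV_max + VV_mean,bg), where VV_mean,bg pools six
   cylindrical background VOIs (⌀ 4.5 cm).
3. **Computes recovery** — RC = a/A for the mean and maximum VOI voxel
   value.  RC falls with sphere diameter (partial-volume effect).
4. **Summarizes dispersion** with the median absolute deviation
   MAD = median(|RCᵢ − median RC|): per-system repeatability across
   replicates, and per-sphere inter-system variability across the
   per-system median RCs.

The simulator emulates a reconstructed image as the true activity map
blurred by the system's effective Gaussian PSF, scaled to expected counts
via CF·t·n·ν, with optional Poisson noise.  Bundled profile fixtures model
a five-system, three-vendor comparison in two modes: a heterogeneous
("vendor-specific") set with per-system filters, voxel sizes and
calibration biases, and a homogenized ("vendor-neutral") set emulating one
shared third-party reconstruction.  See `docs/methods.md` for assumptions
and limitations.

## Worked example

```python
from spectharm import (AcquisitionSettings, CalibrationResult, compute_background_rc,
                       compute_rc, counts_to_concentration, place_background_vois,
                       segment_sphere, simulate_recon, voxelize)
from spectharm.data import load_phantom, load_profiles

spec = load_phantom("small")                      # 9.70 l NEMA phantom, 6 spheres
profile = next(p for p in load_profiles("vendor-specific")
               if p.name == "symbia-t16-2")
truth = voxelize(spec, profile.voxel_size_mm)     # kBq/ml activity map

settings = AcquisitionSettings(n_projections=profile.n_projections,
                               time_per_projection_s=20.0, seed=7)
image = simulate_recon(truth, profile, settings)  # noisy counts image

cal = CalibrationResult.from_factor(profile.calibration_factor,
                                    settings.time_per_projection_s,
                                    settings.n_projections, image.voxel_volume_ml)
conc = counts_to_concentration(image, cal)
vois, vv_bg = place_background_vois(conc, spec)
print(f"background RC = {compute_background_rc(conc, vois, spec.background_kbq_per_ml):.3f}")
for sphere in spec.spheres[:4]:
    mask = segment_sphere(conc, sphere, vv_bg)
    rec = compute_rc(mask, conc, sphere.activity_kbq_per_ml,
                     sphere_diameter_mm=sphere.inner_diameter_mm)
    print(f"{sphere.inner_diameter_mm:4.0f} mm: RC_mean={rec.rc_mean:.2f} "
          f"RC_max={rec.rc_max:.2f}  VOI={rec.voi_volume_ml:.1f} ml")
```

Output:

```
background RC = 1.038
  37 mm: RC_mean=0.89 RC_max=1.08  VOI=23.7 ml
  28 mm: RC_mean=0.83 RC_max=1.05  VOI=10.4 ml
  22 mm: RC_mean=0.80 RC_max=1.04  VOI=4.4 ml
  17 mm: RC_mean=0.69 RC_max=0.92  VOI=2.2 ml
```

The background RC of 1.038 reflects this profile's simulated calibration
bias (1.04) plus noise — on a perfectly cross-calibrated system it would be
1.0.  RC_mean falls from 0.89 to 0.69 as the sphere shrinks from 37 to
17 mm: with a ~6.7 mm effective resolution, an increasing fraction of each
sphere's signal blurs into the surroundings.  RC_max exceeds RC_mean and is
noise-inflated for large spheres.

## Command line

```sh
spectharm phantoms list
spectharm simulate --phantom small --profile all --replicates 5 --seed 7 --out imgs/
spectharm quantify --images imgs/ --phantom small --out rc.csv
spectharm report --rc rc.csv --out report/        # Table5.csv, Table6.csv, rc_curves.csv
spectharm run --config experiment.json --seed 7 --out results/
```

Images are NIfTI/MetaImage with JSON sidecars (unit, settings, seed,
profile); phantoms/profiles/configs are JSON with bundled schemas
(`spectharm.data.load_schema`).

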