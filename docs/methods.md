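# Methods

`spectharm` implements the quantification chain used in multi-center
quantitative SPECT/CT phantom comparisons — calibration factors, recovery
coefficients (RC) from threshold-based sphere segmentation, and robust
(MAD-based) repeatability and inter-system variability statistics — together
with a synthetic-image simulator so that the whole study design can be
exercised without scanner acquisitions.

## Phantom model

The standard object is the NEMA IEC body phantom without lung insert: a
torso-shaped fillable shell holding six hollow spheres with inner diameters
37, 28, 22, 17, 13 and 10 mm (nominal volumes (π/6)·d³ ≈ 26.5 … 0.5 ml).
The interior cross-section is modelled as a "stadium": two lateral
semicircles of radius `height/2` joined by straight top/bottom segments,
extruded axially.  The small phantom uses the NEMA interior dimensions
(300 × 230 mm) with the axial length chosen so the outline volume is exactly
9.70 l.  Two enlarged variants emulate obese patients (BMI 28 and
47 kg/m²): the cross-section is scaled isotropically so that its perimeter
equals the stated waist circumference (100 and 130 cm), and the axial length
is set to match the stated volume (14.73 and 25.96 l).  Only volume and
circumference of the enlarged shells are published; the scaling rule is this
package's documented assumption, not a measured geometry.

Sphere centers are not published either; the package adopts the standard
NEMA convention: all six centers in one transaxial plane on a 57.2 mm-radius
ring about the phantom axis, 60° apart, ordered by decreasing diameter.
Default fill is 100 kBq/ml in the spheres and 10 kBq/ml in the background —
the 10:1 sphere-to-background ratio used by harmonization programmes.

### Rasterization

`voxelize` renders a phantom onto a voxel grid as an activity-concentration
map (kBq/ml).  Voxels whose centers lie farther than half the voxel
diagonal from every material interface are classified analytically and
carry the exact compartment concentration.  Interface voxels get
volume-weighted concentrations from regular sub-voxel sampling: 5 samples
per axis at the body wall (default), and at least ten samples per smallest
sphere radius at sphere surfaces, so that even 4.8 mm grids integrate the
0.5 ml sphere's activity to better than 1%.  `subsamples_per_axis=1`
requests hard-edged center classification (useful for exactness tests).
Grids are centred on the phantom centroid with coordinates computed
symmetrically, so mirrored phantoms rasterize to voxel-exact mirrored maps.

## Image simulator

The simulator emulates the *reconstructed image domain* directly; no
projection-space physics or tomographic reconstruction is modelled.  For a
system profile with calibration factor CF ((cps/ml)/(kBq/ml)), calibration
bias b, and acquisition settings (n projections, t s per projection, voxel
volume ν ml), the expected counts per voxel are

    E[counts] = (truth ⊛ Gaussian(FWHM_eff)) · CF · b · t · n · ν

and a noisy realization draws every voxel independently from a Poisson law
with that mean, using a named, seedable generator whose seed is recorded in
the image metadata.  The effective resolution is the quadrature sum of the
system's SPECT resolution and its post-reconstruction Gaussian filter; this
single isotropic Gaussian is the simplest model that reproduces
resolution-driven recovery curves.  Poisson noise applied post-blur in the
image domain preserves the count-statistics dependence on t, n and CF that
the quantification chain manipulates, though it does not reproduce the
spatially correlated noise texture of iterative reconstruction.

### System profiles

Ten profile fixtures are bundled, five per reconstruction mode, emulating a
five-system, three-vendor comparison (two general-purpose cameras at
6.4/4.4 mm SPECT resolution, three at 4.4 mm with 5–8.4 mm post-filters;
sensitivities 66–91 cps/MBq; voxel sizes 2.21–4.8 mm; calibration factors
0.075–1.0).  The *vendor-specific* (heterogeneous) set carries per-system
post-filters, voxel sizes and calibration biases {1.01, 0.93, 1.07, 0.98,
1.04}; the bias values are synthetic, chosen once to span the 0.93–1.07
background-recovery range reported for such comparisons, since no published
quantitative link exists between system characteristics and calibration
error.  The *vendor-neutral* (homogenized) set keeps each system's physical
resolution but shares one 5 mm post-filter, one 4.8 mm voxel size, and an
unbiased calibration, emulating a common third-party quantitative
reconstruction.  One system whose published data is already calibrated in
kBq is represented with CF = 1.0 in the count-domain model.

### High-BMI degradation

Enlarged phantoms degrade the image through a count-scaling factor (default
0.6 medium, 0.25 large) and an additive FWHM term (+1 mm, +2 mm).  These
magnitudes are tunable configuration values, not measurements.  The count
scale is applied to the simulated counts — degrading Poisson statistics —
and compensated in the conversion stage of the pipeline, which is the role
CT-based attenuation correction plays on real systems: bulk attenuation
costs signal-to-noise, not calibration accuracy.  Consequently the
large-phantom study shows near-unity background recovery with markedly
noisier, lower small-sphere RCs, rather than a uniform scale error.

## Quantification

**Calibration factor.**  CF = (μ/(t·n·ν))/A with μ the mean voxel value in
a uniform-region ROI.  The CLI and tests use a central cylindrical ROI
(radius 40 mm, height 80 mm) placed at least 4σ of the widest bundled PSF
from every wall, so noiseless round-trips recover the profile CF to
floating-point accuracy.

**Background VOIs.**  Six cylinders (diameter 4.5 cm, height 4 cm) on a
45 mm ring about the phantom axis, three on each side of the sphere plane,
keeping ≥ 15 mm from every sphere surface and ≥ 10 mm from the wall.  The
background mean is the unweighted mean over all voxels of all cylinders
(the cylinders are congruent by construction).  The 4 cm height is an
assumption; only the 4–5 cm diameter is standard.

**Sphere segmentation.**  Region growing with the background-corrected
half-maximum threshold VV_thresh = 0.5·(VV_max + VV_mean,bg).  The
published definition is circular (the maximum is taken over a VOI that does
not yet exist); this is resolved by taking VV_max over a search ball around
the nominal sphere center (radius = sphere radius + one voxel — the centers
are known in a phantom setting), then growing once, with no iteration: the
mask is the 26-connected component of `value ≥ VV_thresh` containing the
maximum voxel.  Ties at the maximum break to the lowest linear index, making
the mask deterministic.  When no voxel in the search ball exceeds the
background mean, a `NoContrastError` is raised; the pipeline records the
sphere as missing (the standard fate of the 10 mm sphere at 10:1 contrast)
and downstream statistics skip missing values.  The background mean is
re-estimated per replicate.

**Recovery coefficients.**  RC = a/A per sphere, for both the mean
(RC_mean) and maximum (RC_max) voxel value of the VOI, from the image
converted to kBq/ml.  RC is invariant under joint rescaling of image and A,
and with zero background the threshold reduces to a plain 50%-of-max rule.

## Variability statistics

Dispersion uses the unscaled median absolute deviation
MAD = median(|RCᵢ − median(RC)|); even-length medians take the midpoint of
the central order statistics.  *Repeatability* is the per-sphere MAD across
replicate acquisitions on one system, summarized per system as the median
and range over sphere diameters.  *Inter-system variability* reduces each
system's replicates to a median first, then takes the per-sphere MAD across
systems.  Relative MADs (100·MAD/median RC) are reported as a clearly
labelled derived convenience; the absolute MAD is the primary output, since
the percentage normalization used in published abstracts is not defined
precisely.  Report tables round to 2 decimals, half away from zero.

## Experiment orchestration and determinism

`run_experiment` executes phantoms × profiles × replicates, with child
seeds derived via `numpy.random.SeedSequence` from one base seed (all seeds
stay below 2³¹), and emits tidy CSV tables (RC records, background RC,
repeatability, inter-system, RC curves) in which every row carries
(system, phantom, replicate, sphere) provenance.  Reruns with the same base
seed are byte-identical.  Rasterized truth maps are cached and reusable
across runs because they are independent of seed and profile mode.

## Problem sizes

Default study conditions mirror the emulated design: 128 projections (120
for the 6.4 mm-resolution system) × 20 s, five replicates, five systems,
5³ sub-voxel samples.  The statistical test suites use reduced Monte-Carlo
sizes chosen as a deliberate compromise: the harmonization comparison runs
10 base seeds × 2 modes with 3 replicates per system, and the
repeatability-pattern check runs 12 seeds with 5 replicates on one system.

## Known limitations

- No projection-space modelling: attenuation, scatter, collimator septal
  penetration, detector-orbit effects and Gibbs/ringing artifacts are absent.
  Passing tests therefore demonstrate the correctness of the quantification
  and statistics chain under a resolution+Poisson image model, not the
  quantitative accuracy of any real scanner.
- Noise is voxel-independent Poisson; iterative reconstruction produces
  spatially correlated noise, so RC_max repeatability on real data is worse
  than the simulator suggests.
- Partial-volume correction is deliberately absent, as in the emulated
  analysis protocol.
- Lung/air/bone inserts and mesh-based geometries are out of scope; results
  reflect soft-tissue-like conditions.
- The enlarged-phantom degradation magnitudes and the heterogeneous
  calibration biases are synthetic calibrations, not measurements; the
  inter-system spread they produce is structurally, not numerically,
  comparable to published multi-center tables.
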