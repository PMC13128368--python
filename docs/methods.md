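# Methods

This note documents the models, numerical conventions and design choices
behind `cpmap`, and what the synthetic validation does and does not show.

## Coordinate frame and rasters

All computation happens in bregma-relative millimetre coordinates on the
fixed axis order (AP, ML, DV): AP increasing anterior, ML increasing lateral
from the midsagittal plane, DV increasing ventral. A `CoordinateFrame` maps
integer raster indices to mm by an axis-aligned affine `mm = origin + sign ·
index · spacing`; the per-axis signs accommodate reference-space storage
conventions (the common atlas storage order runs anterior→posterior, so its
AP sign is −1; `DEFAULT_CCF_FRAME` encodes bregma at +5.40 mm from the
stored AP origin and the midline at 5.70 mm from the stored ML origin, both
configurable). Voxel ownership is half-open everywhere — a point exactly on
a shared face belongs to the higher-index voxel — which makes binning
deterministic and count-conserving.

Label volumes (region mask, ventricle mask, parcellation) are integer 3D
rasters with isotropic spacing, read from NRRD (a minimal reader/writer for
raw- and gzip-encoded files, pynrrd-compatible layout) or NIfTI-1 via
nibabel.

## Analysis grid

The analysis lattice consists of cubic voxels (default edge 150 μm, so
voxel volume 3.375 × 10⁻³ mm³) spanning the region's bounding box, with the
grid origin anchored at the bounding-box minimum corner; anchoring is
deterministic so voxel counts are reproducible. A voxel is a candidate iff
it contains at least one region-labeled raster voxel centre. Candidates are
then excluded when the Chebyshev (L∞) distance from the voxel centre to the
nearest region-exterior raster voxel centre is < 50 μm, or to the nearest
ventricle-labeled raster voxel centre is < 175 μm. Distances are evaluated
centre-to-centre at the label raster's native resolution: the thresholds
are physical (μm) but sub-voxel surface geometry is not defined by a label
raster, and centre-to-centre is reproducible at any raster spacing. Both
thresholds and the distance definition are configuration, and the ventricle
volume is optional (exclusion is skipped with a logged warning so reduced
fixtures still run). The implementation restricts the exterior search to a
dilated boundary shell before a KD-tree query; the shell provably contains
every exterior voxel that can decide an exclusion, and the test suite
checks equivalence against a full brute-force scan.

The raster spacing should divide the grid edge (50 μm into 150 μm in all
defaults). With non-divisible spacings the grid still bins correctly, but
the raster-based slab volume and centroid estimates used by the axis
profiles become coarse.

## Densities and the hemisphere bootstrap

The independent sampling unit is the hemisphere: all cells of one subtype
in one hemisphere of one animal. Left-hemisphere cells are mirrored across
the midline (`ml ← 2·midline − ml`) before any density estimation, keeping
the side label so lateralization questions remain askable; mirroring is an
involution and cells exactly on the midline are fixed points.

A bootstrap replicate draws n hemispheres with replacement from the n
available and computes per-voxel density as summed counts divided by
(n × voxel volume); with 1,000 replicates (default) the map's value is the
replicate mean and its standard error the replicate standard deviation
(ddof 1). Replicates are drawn as multinomial hemisphere weights, which is
distributionally identical to listing draws and considerably faster. The
resampling unit is switchable to cells-within-hemispheres
(`bootstrap_unit: cell`) since "hemisphere-level resampling" admits both
readings; hemisphere is the default because it matches the mixed models'
independence unit.

Smoothing uses a truncated Gaussian (σ = 0.5 voxel ≈ 75 μm, radius 3σ)
renormalized within the inclusion mask: each output voxel is the
kernel-weighted mean over included voxels only. This preserves constants,
maps non-negative inputs to non-negative outputs, and never bleeds
masked-out values inward; on a fully included grid it reduces to ordinary
discrete Gaussian convolution. Smoothing is applied to the bootstrap mean
(and SE) after aggregation.

Quantile display bins pool the included-voxel densities of all subtype
maps and cut them at the k/15 empirical quantiles (linear interpolation,
k = 1..15). Binning is half-open upward — a voxel's bin is one plus the
number of interior thresholds ≤ its density — so each map's maximum always
falls in the top bin and an all-constant map is "densest" rather than
"sparsest". Predominance maps take the per-voxel argmax of the subtype
means; exact ties go to the fixed priority order (SST, PV, TH) and are
counted and logged.

## Axis profiles and gradient models

Profiles collapse densities into the grid's 150 μm voxel layers along one
axis. Per hemisphere and plane, density = cells in the plane's included
voxels / included volume of the plane; planes with no included voxels are
dropped. Two refinements matter numerically because the 50 μm boundary
margin is smaller than half the voxel edge, so surviving voxels can
straddle the region surface:

- the plane's volume is measured as the region-mask volume inside its
  included voxels (at raster resolution), not the number of voxels times
  the cube volume — otherwise partial voxels dilute boundary planes and
  attenuate fitted slopes by tens of percent;
- the plane's coordinate is the volume-weighted centroid of that included
  region volume along the axis (`plane_coord: volume`, switchable to the
  geometric slab centre): for an intensity linear along the axis the
  expected slab density equals the intensity at that centroid exactly, so
  the regression is correctly specified at the region's end caps.

The gradient model is a Gaussian random-intercept model on the
per-hemisphere per-plane raw densities, `density ~ coordinate +
(1 | hemisphere)`. Plane-level observations are the default
(`lme_unit: plane`); per-voxel observations are available
(`lme_unit: voxel`), but the plane-level unit is what the profile
bookkeeping (hemispheres × retained planes) naturally produces. Estimation
is maximum likelihood (REML available) through statsmodels' MixedLM behind
the package's own `fit_random_intercept` surface; fixed effects use Wald z
tests, adequate at the hundreds of observations these fits see. The
coordinate is not centred, so the intercept is the extrapolated density at
coordinate zero; slopes are unaffected. Sex is treatment-coded with female
as reference, so the interaction coefficient is directly the
male-minus-female slope difference and the per-sex simple slopes are
β_female = β₁, β_male = β₁ + β₃. Singular or failed optimizations fall back
to the ordinary-least-squares limit (σ_u² = 0) flagged `converged=False`.
Degenerate fits with exactly zero residual variance are reported as clean
nulls in Wald tests rather than 0/0 noise.

These slopes summarize global directional bias only; non-monotonic
structure and spatial autocorrelation are deliberately out of scope.

## Subregion composition

A parcellation volume (four territories: DMCP, LCP, TCP, aVMCP) is
intersected with the region mask; parcel volumes are measured on the
intersected raster. Cells landing on unlabeled region voxels are counted
and excluded from densities. Composition is tested in two pivots of the
same hemisphere × subregion density table: `density ~ subtype +
(1 | hemisphere)` within each subregion, and `density ~ subregion +
(1 | hemisphere)` within each subtype. The omnibus test is a joint Wald
chi-square on the factor's dummy coefficients; pairwise level contrasts are
Wald tests on coefficient differences, each Šidák-corrected with m = number
of pairs (3 for subtypes, 6 for subregions). In the within-subregion pivot
each hemisphere carries a single subtype, so the random intercept is
partially confounded with the factor; it is retained for consistency with
the gradient models, and a fixed-effects-only fallback is available. Sex
follow-ups add sex and factor × sex fixed effects and report the
interaction's omnibus p.

## Synthetic generator

The generator emulates the structure of the real inputs, not their
biology: an ellipsoidal region (default semi-axes 2.0 / 1.6 / 1.7 mm — AP,
ML, DV — chosen so the 150 μm grid yields 27 / ~20 / 23 retained planes, the
plane counts the axis fits operate on) on a 50 μm raster, a 100 μm
ventricle sheet pressed against the medial face, and four parcels that
partition the region (posterior third = TCP, lateral half = LCP, medial
remainder split dorsal/ventral = DMCP/aVMCP).

Cells are drawn from per-hemisphere inhomogeneous Poisson intensities,
linear along the axes about the region centroid and truncated at zero:

    λ_h(x) = max(0, β0 + u_h + Σ_a slope_a (x_a − c_a) + male·(sex terms) + ε)

with Gaussian hemisphere intercepts u_h (default SD 300 cells/mm³) and an
optional piecewise-constant Gaussian perturbation ε per hemisphere and
150 μm slab along a chosen axis (default SD 400 cells/mm³). The ε component
exists because a pure Poisson process at realistic intensities produces
plane-level residual scatter of only ~50 cells/mm³, far tighter than real
profiles; the slab noise realizes the residual variance the plane-level
mixed model assumes, and its slabs are anchored to the region bounding-box
corner so they coincide with the analysis planes — misaligned slabs leak
shared noise into adjacent planes, which deflates interaction standard
errors measurably. Default gradient magnitudes follow the axis analyses on
real data (e.g. TH: +240 AP, +520 DV; PV: −350 DV cells/mm³ per mm), the
default design is 3 animals per sex × 2 hemispheres = 12 hemispheres per
subtype, and the default male TH AP slope offset is +60 cells/mm³·mm⁻¹.
Left hemispheres are generated pre-mirrored so the mirroring stage is
exercised. A seed fully determines every output.

The truncation at zero means strongly sloped, low-baseline configurations
are *not* linear-in-expectation; the recovery experiments use baseline
3,000 cells/mm³ so truncation is negligible. The generator does not emulate
detection errors, registration error, non-monotonic density structure, or
labeling artifacts — passing recovery therefore validates the pipeline's
estimators under a correctly specified model, not robustness to those
upstream effects.

## Validation targets and problem sizes

`recovery_experiment` replicates the full pipeline (simulate → mirror →
filter → grid/exclusions → profiles → mixed model). At the default scale
(12 hemispheres, ~0.8M cells per replicate, 100 replicates — the size the
bundled scripts and tests use) the measured performance is ~1% slope bias,
95% CI coverage 0.92–0.98, type-I error 0.04–0.07 at α = 0.05, and the
60-unit sex slope offset within 2 SE in ≥ 95/100 replicates; the
acceptance script recomputes these from scratch at each run. The
single-axis recovery configurations zero the off-axis slopes so the
plane-level model is exactly specified; with all axes sloped
simultaneously, ellipsoid symmetry still makes the off-axis terms an
intercept shift, and the fitted slopes track the generator (the worked
example in the README shows both).

## Known limitations

- Chebyshev distances are centre-to-centre on the label raster; a
  surface-based definition would differ by up to half a raster voxel.
- Whether the upstream quantile thresholds should be computed on smoothed
  or unsmoothed maps is a convention; the default is smoothed
  (configurable order of operations would require recomputing maps).
- Wald (normal) inference is used throughout; with very few hemispheres
  and strata (the subregion pivots) small-sample t/F corrections would be
  more conservative.
- The within-subregion random intercept is confounded with subtype when
  each hemisphere carries one subtype; see above.
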