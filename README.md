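# cpmap — voxel-wise interneuron density mapping of the mouse caudoputamen

`cpmap` builds a three-dimensional density atlas of genetically labeled
GABAergic interneuron subtypes — somatostatin (SST), parvalbumin (PV) and
tyrosine hydroxylase (TH) positive cells — across the mouse caudoputamen
(dorsal striatum), and quantifies their large-scale spatial organization.
It is written for anatomists and quantitative neuroscientists who have
CCF-registered per-cell coordinate tables (one row per detected soma, with
anteroposterior/mediolateral/dorsoventral positions plus subtype, animal,
hemisphere and sex labels) and want reproducible density maps and gradient
statistics; a bundled synthetic generator with known ground truth makes the
whole pipeline runnable and testable without any data download.

## What it computes

**Density atlas.** Left-hemisphere detections are reflected across the
midline, filtered to the caudoputamen mask, and binned into cubic voxels
(150 × 150 × 150 μm). Voxels are dropped when their Chebyshev (L∞) distance
is < 50 μm from the region boundary or < 175 μm from the ventricle (which
excludes PV⁺ ependymal contamination). Hemisphere-level observations are
resampled with replacement (1,000 bootstrap replicates); each voxel's
density (cells/mm³) is the replicate mean, its uncertainty the replicate
standard deviation. Maps are smoothed with a mask-renormalized Gaussian
(σ = 0.5 voxel), pooled across subtypes into 15 quantile bins, and
summarized by a per-voxel predominance label (the densest subtype).

**Axis gradients.** Densities are collapsed into 150 μm planes along each
anatomical axis, per hemisphere, and the global directional bias is the
fixed slope β₁ of a random-intercept linear mixed model

    density_hp = β0 + β1·coordinate_p + u_h + ε_hp ,  u_h ~ N(0, σ_u²)

fit by maximum likelihood on the per-hemisphere per-plane raw densities
(slopes in cells/mm³ per mm; Wald z inference). Sex follow-ups add sex
(female reference) and its coordinate interaction, so β₃ is the
male-minus-female slope difference.

**Subregion composition.** Cells are assigned to four cortical-input-defined
territories (DMCP, LCP, TCP, aVMCP), per-hemisphere densities are computed
against parcel volumes, and composition is tested with the same
random-intercept machinery in two pivots — subtype differences within each
subregion and subregion differences within each subtype — with all pairwise
contrasts Šidák-corrected (p_adj = 1 − (1 − p)^m).

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
(12 hemispheres per subtype, axis gradients of a few hundred cells/mm³ per
mm, hemisphere SD 300 cells/mm³):

```sh
python analysis/01_simulate.py       # toy atlas + ~1.9M synthetic cells
python analysis/02_density_atlas.py  # bootstrap maps, quantiles, predominance
python analysis/03_axis_gradients.py # mixed-model slopes vs generator truth
python analysis/04_subregions.py     # composition tests with Sidak contrasts
python analysis/05_recovery.py       # bias / coverage / type-I calibration
```

`03_axis_gradients.py` prints the fitted slope, its standard error and the
generating value for every subtype × axis, e.g. (seed 1):

```
fit           beta1     se    true
PV_DV    -333.5    5.9  -350.0
SST_DV    265.0    6.3   255.0
TH_DV     526.1    4.4   520.0
TH AP sex offset: beta_male - beta_female = 67.13 (p = 2.33e-20; generator: 60.0)
```

i.e. the dorsoventral gradients are recovered within a few standard errors,
and the simulated male–female slope difference of 60 cells/mm³·mm⁻¹ is
detected. (The pooled TH AP slope exceeds its per-sex truth by half the sex
offset, as it should.) `02_density_atlas.py` reports the analysis lattice:
6,716 included 150 μm voxels ≈ 22.7 mm³ for the default two-hemisphere-sized
toy region.

The same stages are exposed as a CLI over one YAML configuration
(`cpmap simulate|atlas|gradients|subregions|report --config ... --seed ...`)
whose defaults are the study's analysis constants.

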