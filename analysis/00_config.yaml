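# Shared configuration for the numbered analysis scripts.
# The synthetic block defines the study conditions the generator emulates:
# an ellipsoidal caudoputamen-like region (semi-axes 2.0/1.6/1.7 mm) on a
# 50 um label raster, 12 hemispheres per subtype (3 animals/sex x 2 sides),
# per-axis density gradients at the magnitudes the axis analyses report on
# real data, hemisphere SD 300 cells/mm^3, and a male-female AP slope offset
# for TH. Analysis constants are the study defaults: 150 um voxels, 50 um
# boundary / 175 um ventricle Chebyshev exclusions, 1,000 bootstraps,
# sigma = 0.5 voxel smoothing, 15 quantile bins.
paths:
  out_dir: results/run
  region: results/run/region.nrrd
  ventricle: results/run/ventricle.nrrd
  parcellation: results/run/parcellation.nrrd
  parcellation_labels: results/run/parcellation_labels.json
  cells_csv: results/run/cells.csv
frame:
  origin_mm: [0.025, 0.025, 0.025]
  axis_signs: [1, 1, 1]
  midline_ml_mm: 0.25
grid:
  edge_um: 150.0
  d_boundary_um: 50.0
  d_ventricle_um: 175.0
density:
  n_boot: 1000
  sigma_voxel: 0.5
  n_bins: 15
  bootstrap_unit: hemisphere
models:
  lme_unit: plane
  method: ML
  sex: true
synthetic:
  atlas:
    semi_axes_mm: [2.0, 1.6, 1.7]
    spacing_um: 50.0
    margin_mm: 0.25
  cells:
    baseline: {SST: 2500.0, PV: 3000.0, TH: 1500.0}
    slopes:
      SST: [5.0, -30.0, 255.0]
      PV: [-145.0, 5.0, -350.0]
      TH: [240.0, -45.0, 520.0]
    hemisphere_sd: 300.0
    residual_sd: 0.0
    sex_slope_offset: {TH: [60.0, 0.0, 0.0]}
    n_animals_per_sex: 3
seed: 1
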