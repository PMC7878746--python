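# Example configuration for the nltvfdk command-line interface.
#
#   nltvfdk simulate    --config pipeline_config.yaml --out-dir out/
#   nltvfdk reconstruct --config pipeline_config.yaml \
#       --input out/projections_noisy.tif --output out/recon.tif \
#       --denoise nltv --interp bspline
#   nltvfdk evaluate    --config pipeline_config.yaml \
#       --input out/recon.tif --reference out/ground_truth.tif \
#       --report out/report.tsv
#   nltvfdk pipeline    --config pipeline_config.yaml --out-dir out/

geometry:
  sad_mm: 1000.0          # source-to-axis distance
  sdd_mm: 1536.0          # source-to-detector distance
  n_u: 64
  n_v: 64
  pitch_u_mm: 2.4
  pitch_v_mm: 2.4
  n_projections: 90
  angle_start_deg: 0.0
  angle_range_deg: 360.0

phantom: catphan_like     # or a list of ellipsoid records:
# phantom:
#   - {center_mm: [0, 0, 0], semi_axes_mm: [45, 45, 45], rot_z_deg: 0.0, dmu_per_mm: 0.02}

noise:
  i0: 100.0               # unattenuated photons per pixel (the dose knob)
  seed: 1

grid:
  shape_zyx: [32, 32, 32]
  voxel_size_mm_zyx: [4.0, 4.0, 4.0]

nltv: {}                  # published defaults; any NLTVParams field overrides
atv: {}

filter:
  beta: 0.5               # raised-cosine window parameter (1 = pure Shepp-Logan)

evaluate:
  mu_water: 0.02
  mu_air: 0.0
  mask_radius_mm: 38.0
  mask_half_height_mm: 30.0
  rois:
    background: {center_x: 0.0, center_y: 0.0, slice_index: 16, radius: 6.0, label: water}
    inserts:
      - {center_x: 18.7, center_y: 23.4, slice_index: 16, radius: 4.0, label: teflon}
      - {center_x: -6.7, center_y: 29.2, slice_index: 16, radius: 4.0, label: air}
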