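# Demonstration pipeline configuration: a small synthetic cohort on the
# packaged 84/58/16/6/4 gray-matter hierarchy with a focal patient effect
# at four medial-temporal/limbic parcels.
#
#   netpyramid run-all --config examples/demo_config.yaml --out demo_run
seed: 42
hierarchy: packaged
cohort:
  n_patients: 10
  n_controls: 10
  n_timepoints: 240
  tr_seconds: 2.0
  voxels_per_parcel: 3
  effect_nodes: [46, 74, 76, 69]   # PHG_R, Amyg_R, Hippo_R, PCC_L
  coupling_reduction: 0.5
  alff_reduction: 0.5
  noise_sd: 1.0
band: [0.01, 0.1]
threshold_p: 0.5
alpha: 0.05
k_folds: 10
svm:
  kernel: linear
  C: 1.0
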