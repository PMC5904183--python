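# Study-parameter pipeline: stepwise stiffness gene calling with the
# published filter settings (floor 5, |log2FC| > 0.5, >= 3 probes),
# knockdown dependence, a second-stimulus comparison, and the Hertz AFM
# branch (nu = 0.5, face half-angle 25 deg) at the two reported region
# moduli (3.6 and 0.27 kPa).
seed: 1
out_dir: stiffscape_out
stages:
  - stage: simulate_array
    as: array
    design: stiffness_4arm
    config:
      n_genes: 500
      n_reps_ctrl: 6
      n_reps_kd: 2
  - stage: call_genes
    matrix: array
    cond_a: ctrl-stiff
    cond_b: ctrl-soft
    floor: 5.0
    threshold: 0.5
    min_probes: 3
  - stage: dependence
    matrix: array
    cond_a: ctrl-soft
    cond_b: kd-soft
  - stage: simulate_array
    as: oss
    design: oss_2arm
    config:
      n_genes: 500
      n_reps_ctrl: 2
  - stage: flat_filter
    matrix: oss
    cond_a: static
    cond_b: OSS
  - stage: compare
    a: array
    b: oss
  - stage: simulate_curves
    regions:
      CV: 3.6
      outside: 0.27
    n_per_region: 10
  - stage: afm_fit
    fit_params:
      poisson_ratio: 0.5
      edge_angle_deg: 25.0
  - stage: afm_aggregate
  - stage: simulate_images
  - stage: quantify
    measures: [ctcf, circularity, nuccyt]
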