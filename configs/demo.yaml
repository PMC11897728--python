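# Demonstration run: small enough to finish end-to-end on one CPU in a
# few minutes. Start it with
#
#   emopac run --config configs/demo.yaml --out runs/demo --seed 7
#
# Every block below overrides the corresponding stage defaults; delete a
# block to accept the defaults documented in docs/methods.md.

seed: 7
out_dir: runs/demo

# stages to execute, in dependency order
stages: [simulate, preprocess, tf, permtest, pac, behavior, correlate, report]

simulate:
  # study_defaults: true (implied) injects the default condition effects:
  # happy gamma burst + LF->LP theta/low-gamma coupling, sad slow-power
  # increase + LF->RP coupling, shared RF->LP alpha/low-gamma path
  n_participants: 4
  n_trials_per_condition: 10
  # sampling_rate: 512.0
  # epoch_window: [-8.0, 18.0]
  # noise_exponent: 1.0        # pink-noise 1/f^beta slope
  # noise_scale: 10.0          # broadband uV SD per channel

preprocess:
  target_rate: 256.0
  # bad_channels: [T7]         # spherical-spline reconstruction
  # order: [rereference, resample, filter, interpolate]
  # filter:
  #   notch_band: [47.0, 53.0]
  #   bandpass: [0.1, 100.0]

tf:
  decim: 16            # TF maps sampled at 256/16 = 16 Hz
  freq_step: 2.0       # analysis grid 1..70 Hz in 2-Hz steps
  # activation_window: [0.0, 10.0]
  # reference_window: [-6.0, -1.0]

permutation:
  n_permutations: 500
  # alpha: 0.001
  # cluster_k: 100
  # smoothing_halfwidth: 2
  # connectivity: 4

pac:
  n_surrogates: 100
  # smooth_halfwidth: 2
  # permutation: {cluster_k: 12}

report:
  heatmaps: true
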