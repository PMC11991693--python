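# Demo run: 6 synthetic individuals carrying the first six cohort CSI values.
seed: 7
run_dir: runs/demo
stages: [simulate, score, fit, decode, report]
simulate:
  n_individuals: 6
  steps_per_individual: 168
  missing_dive_prob: 0.25
hmm:
  n_restarts: 2
  ftol: 1.0e-7
  compute_hessian: true
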