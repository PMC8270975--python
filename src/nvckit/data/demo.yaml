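# Demo configuration: two simulated vascular arbors, anesthetized-like
# 5 Hz / 5 s whisker-stimulation protocol, 9.5 s z-score baseline.
seed: 1
outdir: nvc_demo
n_arbors: 2
n_trials: 6
stim_rate_hz: 5.0
stim_duration_s: 5.0
stim_onset_s: 10.0
trace_rate_hz: 10.0
duration_s: 35.0
baseline_s: 9.5
baseline_diameter_um: 10.0
tf_runs_round1: 10
tf_runs_round2: 10
tf_n_iter: 60
truth:
  tf_params: [2.0, 1.0, 0.3, 8.0]
  vasomotion_amplitude: 2.0
  noise_sd: 0.3
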