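# Three-state riboswitch aptamer simulation (2 mM Mg2+ kinetics).
# Rates in 1/s; rows of rate_matrix sum to zero. Lifetimes: 0.69/0.11/0.40 s.
states:
  - {label: unfolded,   efret_mean: 0.2, efret_sd: 0.05}
  - {label: pre-folded, efret_mean: 0.5, efret_sd: 0.05}
  - {label: folded,     efret_mean: 0.8, efret_sd: 0.05}
rate_matrix:
  - [-1.4493,  1.4493,  0.0]
  - [ 4.5455, -9.0909,  4.5455]
  - [ 0.0,     2.5,    -2.5]
emission:
  total_intensity: 1000.0
  intensity_noise_sd: 50.0
  frame_interval: 0.1
  donor_bleach_rate: 0.0
  acceptor_bleach_rate: 0.005
n_traces: 20
trace_length: 600
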