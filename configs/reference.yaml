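# Reference setup: symmetric rates, shared Hill parameters, reduced diffusion.
grid:
  L: 2.0
  N: 250
mhb:
  alpha: [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
  beta: [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
  k: 0.1
  n: 2.0
  d_fgf8: 0.001
  d_wnt1: 0.001
integration:
  t_final: 50.0
steady:
  n_samples: 24
  seed: 1
ic:
  kind: unimodal
  xstar: 0.0
  widths: 0.18
  amplitudes: 0.7
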