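# Intra-slab phase-scheduling study: reports the peak-RF reduction of the
# (0, 0, 0, pi, 0) schedule relative to the all-zero-phase composition.
slab:
  n_p: 5
  slice_thickness: 0.86
noise:
  snr: 20.0
seed: 0
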