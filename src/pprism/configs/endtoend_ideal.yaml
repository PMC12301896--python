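# Inverse-consistency preset: noiseless, zero shot phases, ideal
# partition-encoding mixing, vanishing final ridge -> the phantom is
# recovered to numerical precision.
noise:
  snr: 0.0
  phase_amplitude: 0.0
recon:
  self_navigate: false
  lambda_final_scale: 1.0e-12
seed: 0
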