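# pprism

Pseudo partition-encoded simultaneous multislab (pPRISM) diffusion MRI:
RF pulse design, 3D Fourier encoding, forward simulation and
reconstruction, exercisable end to end on synthetic phantoms.

Submillimeter diffusion MRI is limited by SNR, acquisition time and
slab-boundary artifacts. The pPRISM approach addresses these with two
ideas:

* **PRISM encoding** — simultaneous inter-slab and intra-slab Fourier
  encoding using the slice gradient only. With `M` simultaneous slabs,
  `n_p` partitions per slab and a k_z comb of `M·n_p` points spaced
  `q/FOV_z`, the encoding bases are mutually orthogonal exactly when
  `gcd(M, q) = 1`; the simultaneously excited slabs then fold into a
  pseudo FOV of `FOV_z/q` and concatenate without overlap.
* **Pseudo slabs** — each "slab" is `n_p` thin slices spaced twice the
  slice thickness. The gaps suppress inter-slab signal leakage and Gibbs
  artifacts, and they admit a per-slice phase schedule `φ_j ∈ {0, π}`
  that cuts the peak RF of the summed excitation while keeping every
  partition-encoded shot's signal high enough for navigator-free phase
  estimation.

The package implements the full chain: Shinnar–Le Roux pulse design and a
spinor-domain Bloch simulator (`bloch_rf`); pseudo-slab composition,
schedule search and refocusing-polarity selection (`pseudo_slab_rf`);
PRISM pattern generation and validation (`prism_encoding`); the
slice-crosstalk resolution matrix `R = F⁻¹·E·A` and a steady-state
crosstalk model (`psf_model`); synthetic phantoms/coils/shot-phases and
the forward acquisition operator (`synth`); and the two-step
reconstruction — CG-SENSE slab unaliasing, structured low-rank
(block-Hankel nuclear norm, `λ₁ = 0.01‖x‖²/‖H(s_ini)‖_*`,
`λ₂ = 0.1‖x‖²/‖s_ini‖²`) self-navigated phase estimation on 4×
down-sampled images, and the final slice solve
`argmin_s ‖x − P Φ s‖² + λ‖s‖²`, `λ = 0.1/N_shot` — plus analytic SENSE
g-factor maps (`recon`). See `docs/methods.md` for the models and their
assumptions.

## Worked example

```python
>>> import json, pprism
>>> report = pprism.run_experiment({"seed": 1})
>>> print(json.dumps(report, indent=1, sort_keys=True))
{
 "mean_nrmse": 0.041563487866650234,
 "peak_rf_reduction_percent": 40.02898790583548,
 "phase_schedule": [
  0.0,
  0.0,
  0.0,
  3.141592653589793,
  0.0
 ],
 "psf_max_off_diagonal_percent": 7.682537670056852,
 "seed": 1,
 "slabs": [
  {
   "lambda1": 0.03242318401776279,
   "lambda2": 0.4999999999999999,
   "nrmse": 0.04515720530448818,
   "phase_iterations": 4
  },
  {
   "lambda1": 0.036230899509741114,
   "lambda2": 0.5000000000000001,
   "nrmse": 0.037969770428812284,
   "phase_iterations": 4
  }
 ]
}
```

This designs the
default pulses (5-slice pseudo slab, 0.86 mm slices, 8 ms TB-5.4
excitation, 9.6 ms TB-3.4 Hamming refocusing), simulates a 2-slab ×
5-shot acquisition of a synthetic phantom with smooth per-shot motion
phases at SNR 20, and reconstructs it with self-navigation. The report
says: the (0,0,0,π,0) intra-slab schedule reduces the peak RF of the
summed excitation by 40 %; the worst inter-slice leakage of the
Bloch-simulated point-spread function is 7.7 % of the main lobe; the
data-driven regularization weights λ₁/λ₂ used for the phase estimate; and
the reconstructed slices differ from the ground-truth phantom by ~4 %
magnitude NRMSE per slab.

A thin CLI exposes the same drivers (`pprism design-rf`,
`pprism make-pattern`, `pprism run --config ... --seed ... --out ...`);
two study presets ship in `src/pprism/configs/`.

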