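# Methods

This note describes the models implemented in `pprism`, the assumptions
behind them, and the numerical choices that were genuinely open.

## RF design and Bloch simulation (`bloch_rf`)

Slice-selective pulses are designed with the Shinnar–Le Roux (SLR)
transform. The beta filter is either a Hamming-windowed sinc (the
refocusing default, matching the common "windowed sinc, spin-echo" design)
or a Parks–McClellan equiripple filter with passband/stopband
magnetization ripples of 1 %/1 % (the excitation default). The standard
ripple conversions are used (excitation: `d1b = sqrt(d1/2)`,
`d2b = d2/sqrt(2)`; spin echo: `d1b = d1/4`, `d2b = sqrt(d2)`). Because the
empirical transition-width estimate underlying the band-edge placement is
approximate, the design widens the transition iteratively until the
achieved beta ripple meets the request. The beta polynomial is calibrated
so the DC (centre-of-slice) response is exactly `sin(flip/2)`; for
refocusing pulses, where ripple overshoot would push `|b|` past 1, the
peak is pinned just below 1 instead. The alpha polynomial is the
minimum-phase counterpart obtained by the cepstral method, and the RF
waveform follows from inverting the hard-pulse recursion.

Profiles come from a spinor-domain (Cayley–Klein) hard-pulse simulator,
exact for piecewise-constant B1 and gradient. Excitation profiles are
`2 conj(a) b` with the gradient rephasing lobe (half the pulse area)
rewound; refocusing profiles are the crushed-spin-echo response `b^2`,
already echo-referenced in this convention. Relaxation during the pulse is
ignored by default (a magnetization-domain engine with per-sample
relaxation exists for excitation profiles). Gradients are constant during
RF — no VERSE — which is what makes the design robust to off-resonance.

With these defaults the SLR excitation/refocusing pair integrates 77 % of
the ideal-slice signal (the phase-flat comparison in the source material
reports 75 % for the same pair) and shows a large in-slice real-part
fluctuation (~52 % here; the printed ~37.5 % depends on ripple
specifications that are not stated anywhere, so tests bound this loosely).

## Pseudo-slab composition and scheduling (`pseudo_slab_rf`)

A pseudo slab is `n_p = 5` slices of thickness 0.86 mm spaced
centre-to-centre at twice the slice thickness ("separated by a distance
equivalent to double the slice thickness" is read as centre-to-centre;
the edge-to-edge reading would put a full slice width between neighbours
and make the inter-slab crosstalk negligible, contradicting the observed
few-percent signal loss). The slab pulse is the sum of frequency-shifted
copies of the base pulse, with time referenced to the pulse centre so the
all-zero-phase schedule sums coherently at the envelope peak.

The intra-slab phase schedule is found by exhaustive search over the
`2^n_p` vectors with entries in {0, pi}, keeping the intersection of the
lowest-5 % peak-RF set and the highest-5 % minimum-shot-signal set
(relaxed in +5-point steps when empty) and choosing the highest minimum
signal, ties broken lexicographically. For the default geometry the search
returns (0, 0, 0, pi, 0): a 40 % peak-RF reduction (ideal-envelope
closed form: 1 − 3/5) and a four-orders-of-magnitude increase of the
minimum partition-encoded shot signal for ideal symmetric profiles
(the realistic-profile gain reported in the source is ~18-fold; the exact
factor is profile-dependent because the unscheduled minimum is a
near-cancellation).

Refocusing polarities are scored by gap oscillation — the maximum
refocused-signal magnitude in each inter-slice gap over the mean in-slice
magnitude. Two numerical choices matter: the gap region is the central
half of each gap (any realizable profile has transition shoulders just
outside the slice edges that would otherwise dominate the metric
identically for every candidate), and the threshold separating
"oscillating" from quiet gaps defaults to 0.10, consistent with the 10 %
PSF threshold used throughout. With realistic composed pulses the
alternating polarity (+,−,+,−,+) shows the least gap oscillation and the
highest peak RF of the candidate set, reproducing the qualitative
trade-off that motivates the compromise choice (−,+,+,−,+); the exact
per-gap counts are envelope-dependent and are not asserted.

## PRISM encoding (`prism_encoding`)

The k_z comb is the convolution of a partition comb (`n_p` points spaced
`M q / FOV_z`) with an SMS comb (`M` points spaced `q / FOV_z`): `M n_p`
points spaced `q / FOV_z`, centred so a zero-encoding shot exists. The
geometry this implies — intra-slab slice pitch `FOV_z / (M q n_p)`, slab
span `FOV_z / (M q)`, slab centres spaced `FOV_z / M` — is validated
numerically: for every `gcd(M, q) = 1` with `M, n_p ≤ 6` the encoding
Gram matrix equals `M n_p · I` to 1e−10, and every violating combination
is rank-deficient or overlaps after folding into the pseudo FOV
(`FOV_z / q`). Blipped-CAIPI blips cycle `(ky mod M)/FOV_z`, giving
adjacent slabs the standard `FOV/M` shift; the table is phase-referenced
to the slab centre.

## Resolution matrix and steady state (`psf_model`)

Crosstalk is summarized by `R = F^{-1} E A`: `A` holds the refocused
profile of each pseudo-slice restricted to its own block on a fine grid
ten times denser than the output (100×5 for the default geometry, avoiding
the inverse crime), `E` is the 5-frequency partition encoding and `F^{-1}`
the 5-point inverse DFT at the slice centres. Columns normalized by their
diagonal give the normalized PSF. Two properties deserve emphasis:

* delta objects at the slice centres decode exactly to the identity (the
  brute-force oracle the tests use), but a *block-wide boxcar* does not —
  block-limited signals are not bandlimited to 5 Fourier coefficients, so
  even ideal profiles carry ~8 % Dirichlet leakage. That leakage is the
  baseline of the measured PSF; the Bloch profiles with polarities
  (−,+,+,−,+) give a maximum off-diagonal of 7.7 %, below the 10 % design
  threshold.
* a uniform off-resonance displaces the whole slice stack by
  `−df/(γG)` (0.064 mm for the excitation and 0.121 mm for the refocusing
  pulse at 50 Hz). A reconstruction that uses the measured profiles sees
  this as a common coordinate offset, not crosstalk, so the off-resonance
  analysis references its decode blocks to the displaced pattern (mean of
  the two displacements). The off-diagonals then stay at the on-resonance
  baseline, reproducing the constant-gradient robustness claim; treating
  the displacement as leakage would instead report 13 %.

The steady-state model tracks only T1 saturation/recovery of longitudinal
magnetization (transverse magnetization is assumed fully crushed between
repetitions, so T2 does not enter). Each TR applies the slab's own
excitation and refocusing (`Mz ← Mz (|a|² − |b|²)` per pulse), and, for
the crosstalk arm, the interleaved group's pulses shifted by half the
slice spacing. Timing follows packed slice acquisition, the norm in
diffusion spin-echo EPI: the groups are acquired pass-by-pass, so the
other group's RF lands `slabs_per_group × slab_acq_time` (default
8 × 125 ms = 1.0 s) before the own excitation, late in the recovery
period. With TR 3.5 s and T1 1200 ms this yields a 6.0 % mean in-slice
amplitude loss (reported value: 5.7 %) with a nearly unchanged normalized
PSF. The loss is *lead-limited*: it saturates rather than vanishing as TR
grows, and it is sensitive to the packing assumption (uniformly spread
acquisitions would give ~2.9 %) — the acquisition timing is the least
constrained part of this model.

## Synthetic data and forward model (`synth`)

Phantoms are piecewise-smooth random ellipsoid composites (or the classic
3D head phantom); the default study fixture replicates one in-plane
pattern through the slab with a mild ramp, reflecting how strongly
adjacent 1.7-mm slices of real anatomy correlate. Coil maps are Gaussian
lobes on a ring with smooth complex phase, root-sum-of-squares normalized.
Shot phase maps are dominated by random polynomials up to second order
(rigid-motion-like) plus a small smooth random field, projected exactly
onto the central quarter of k-space so the slowly-varying-phase contract
holds by construction; shot 1 is the zero-phase reference.

The forward model weights phantom slices by the shot-domain mixing matrix
`T` (partition-encoding phases × schedule; optionally `T = F·R` to include
the Bloch crosstalk), applies the per-shot phase maps, sums the `M`
simultaneous slabs with CAIPI phases per ky line, multiplies by slab-level
coil maps, takes a unitary 2D FFT and subsamples (in-plane acceleration +
partial Fourier as a ky mask). Only acquired lines are stored. Noise is
circular Gaussian with complex per-sample variance `sigma²`; the default
fixture sets `sigma` = (mean in-support object intensity)/SNR with
SNR = 20. The operator is linear with an exact adjoint (dot-product test
to 1e−10). Diffusion contrast is not simulated mechanistically.

## Reconstruction (`recon`)

Step 1 unaliases the simultaneous slabs per shot by conjugate-gradient
SENSE on the normal equations (tolerance 1e−6, 200 iterations by
default); a dense least-squares oracle provides an independent check on
small instances.

Step 2 estimates the per-shot motion phase from 4×-downsampled slab
images. The per-shot problem is 1-equation-in-`n_p`-unknowns per pixel;
the coupling across shots comes from a structured low-rank penalty: a
block-Hankel matrix of centred-k-space patches (3×3 windows by default)
with shots stacked as column blocks and slices as row blocks, so the
smooth annihilating filters relating shots are shared across slices. The
objective — data term + `lambda1`·nuclear norm + `lambda2`·Tikhonov, with
the data-driven weights `lambda1 = 0.01‖x‖²/‖H(s_ini)‖_*` and
`lambda2 = 0.1‖x‖²/‖s_ini‖²` — is solved by ADMM: singular-value
thresholding for the Hankel variable, CG for the quadratic subproblem
(the Hankel Gram is diagonal in k-space; the data Gram is per-pixel
rank-one). The estimated slice images are averaged within the pseudo slab
(the phase of the mean image is the magnitude-weighted circular mean of
the slice phases), the mean image is up-sampled by zero-padded k-space
interpolation, and its phase is taken as the unit-magnitude estimate.
Upsampling the mean *image* rather than a unit-magnitude phasor matters:
the phasor's arbitrary phase outside the object rings into the support and
triples the error. On the default fixture the estimate reaches ~0.04 rad
circular RMSE in support at SNR 20; the floor is set by the 4×
downsampling of the phase maps, not by the solver.

Step 3 solves `argmin_s ‖x − P Φ s‖² + λ‖s‖²` with `λ = 0.1/N_shot` per
slab. Because `|Φ| = 1`, the per-pixel normal matrix is `T^H T + λI`
everywhere, so the normal equations are solved exactly in closed form —
the fixed point a conjugate-gradient solver would converge to. Matching
the Bloch resolution matrix in `P` removes the inter-slice striping that
an ideal-DFT `P` leaves behind (0.2 % vs 8 % scaled magnitude error on
the noiseless fixture). The analytic SENSE g-factor treats the CAIPI kz
modulation as the standard relative in-plane shift `m·N/M` between slabs
and reports `sqrt(diag(N^{-1})·diag(N))` per aliased set.

## Default study conditions

5 slices/slab of 0.86 mm (spacing 1.72 mm), SMS factor 2, q = 1, 5 shots,
schedule (0,0,0,pi,0), polarities (−,+,+,−,+), 48×48 in-plane matrix,
6 coils, shot-phase amplitude pi/2, SNR 20, TR 3.5 s, T1 1200 ms. Matrix
size and coil count are desk-scale choices; every quantitative claim above
is computed at these sizes by the test suite and `scripts/acceptance.py`.

## Limitations

* DIST excitation, VERSE, ESPIRiT calibration, NORDIC denoising, GRAPPA,
  BUDA and gSlider sequence modelling are out of scope (hooks accept
  user-supplied pulses/profiles/volumes where relevant).
* The synthetic fixture has no EPI distortion, eddy currents, or motion
  beyond per-shot smooth phase; passing tests show method-level
  correctness, not in vivo image quality.
* The steady-state crosstalk number depends on acquisition packing
  assumptions that real sequences only approximately satisfy.
* The phase-recovery accuracy claim relies on through-slab correlation of
  the object; fully independent slices leave a per-shot bias that no
  slab-collapsed self-navigation can remove.
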