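# Methods

## Physical model

A swept-source OCT interferometer detects, for each A-scan, the spectral
intensity

    I_D(k) = I1 + I2 + I3 + N_G,

where the depth-encoding cross term between the reference mirror
(path length d_r, reflectivity r_r) and the sample scatterers
(path lengths d_Si, reflectivities r_Si) is

    I2(k) = S(k) (ρ/2) Σ_i sqrt(r_r r_Si) cos(k (d_r − d_Si)),

with S(k) the source spectral envelope and ρ the detector responsivity.
I1 is the depth-independent DC pedestal and I3 the mutual interference
between scatterers; both are small when the reference dominates and are
off by default in the simulator, but remain as toggles so the size of the
approximation is measurable. N_G is additive white Gaussian noise.

Depths here are micrometres of optical path difference in air — the
conjugate variable of the wavenumber k = 2π/λ in the cosine above.  Under
this convention the inverse-DFT depth axis has pitch 2π/(N·δk) per pixel
for a k-linear grid with per-sample step δk, the unambiguous range is N/2
pixels, and a Gaussian source of centre λ0 and FWHM bandwidth Δλ has an
axial point-spread FWHM of

    (4 ln2 / π) · λ0² / Δλ  ≈ 15.1 µm  for λ0 = 1310 nm, Δλ = 100 nm,

matching the 15 µm axial resolution of a 1310/100 nm swept laser.  When
the point-spread function is measured numerically, the sweep must span
more than the source FWHM: sampling exactly one FWHM truncates the
envelope at half maximum and inflates the measured width by ~50%, so the
PSF checks sweep 2.5× the FWHM (λ0 ± 125 nm), where the closed form is
recovered to ~1%.

Three sweep models map wavelength to sample index: `k_linear` (ideal,
wavenumber affine in the index), `lambda_linear` (wavelength affine in
time, the plain swept source), and `fdml_sinusoidal`
(λ(t) = λ0 + (Δλ/2)·sin(2π f_t t), sampled over the monotonic up-sweep
between turning points, as in Fourier-domain mode-locked lasers).
Non-k-linear sampling chirps the fringe and blurs the depth profile,
increasingly with depth — the core problem the package addresses.

## Speckle and ground truth

Speckle is generated physically, not injected: each phantom layer is
filled with Poisson-distributed sub-resolution scatterers (default ~2 per
depth pixel per A-scan) at uniform random depths, so the coherent sum in
a resolution cell has fully random phase.  The reconstructed within-layer
magnitude is then Rayleigh-distributed with contrast std/mean ≈
√(4/π − 1) ≈ 0.52; the simulator reproduces 0.55–0.57 including envelope
and discretization effects.

Ground truth emulates consecutive-B-scan averaging of a static sample:
for each phantom geometry, `n_avg = 7` independent speckle realizations
are reconstructed on the ideal k-linear sweep and averaged pixelwise,
shrinking within-layer speckle std by ≈ 1/√7 ≈ 0.38 while preserving the
morphology.  The degraded input is the first realization simulated with
the non-linear sweep and reconstructed without resampling.

What the synthetic data does *not* emulate: dispersion, polarization,
detector shot/RIN noise spectra, galvo distortion, sample motion between
the averaged scans, and the textural richness of biological tissue.
Passing tests therefore demonstrate that the pipeline learns to undo
sweep non-linearity and suppress speckle under the stated statistical
model, not that it reaches any particular quality on real acquisitions.

## Processing chain

Raw frame → optional background subtraction (default estimator: the mean
A-scan across the frame) → Hann spectral shaping → per-column inverse DFT
(unnormalized forward / 1/N inverse, depth axis only — used consistently
everywhere) → magnitude of the first N/2 bins (the mirror half of a real
spectrum is redundant).  A wavenumber layer — the non-uniform k(s) of
Eqs. k = 2π/(λ_min + s(λ_max−λ_min)/(N−1)) computed at the image depth
(the 2304-point grid decimated to 1152 rows preserves the non-linearity
profile), shifted/scaled to zero mean and unit variance, replicated
across A-scans — is stacked as a second channel.  The two-channel tensor
is split into four equal depth patches (288×256 at full scale),
standardized with the training-split mean/std (degraded and ground-truth
pixels pooled), and fed to the spatial network.

## Networks

Both networks share one backbone: four encoder blocks
(BN → PReLU → conv ×2 with the block input concatenated to its output),
stride-2 convolutions between stages with channel doubling (base 32;
"tiny" preset 8), one bottleneck block, and four decoder stages (stride-2
transpose conv + BN + PReLU, additive attention gate on the encoder skip,
3-tap merge conv).  Attention coefficients are
sigmoid(ψ(relu(θ(skip) + φ(gate)))) — a single-channel map in [0,1]
multiplying the skip.  Kernel size 3 throughout; weights use fan-in
Gaussian init from a recorded seed.  The SD-CNN is the 2D instance
(2 channels in, 1 out, linear head); the FD-CNN is the 1D instance
operating on each A-scan's full two-sided DFT amplitude column
independently (batch = lateral index).

The FD-CNN output head is a zero-initialized residual: the network
predicts a correction added to the input amplitude and clamped at zero
(ReLU), so the untrained model is exactly the identity and training can
only move away from the spatial-domain solution when the loss supports
it.  A free softplus head is available as a config option; in desk-scale
pilots it had to re-learn the whole amplitude and degraded the fused
reconstruction.

Because every layer had to be differentiable without a deep-learning
framework dependency, the package carries a small reverse-mode autodiff
engine (`autodiff.py`) with im2col convolutions, transpose convolutions,
batch norm, PReLU and Adam; all gradients are validated against central
finite differences in the test suite.

## Training and inference

Training is sequential.  The SD-CNN minimizes the L1 loss against
standardized ground truth (Adam, full-scale defaults lr 1e-4, 200
epochs).  The FD-CNN is then trained with the SD-CNN frozen (verified by
hashing its weights): inputs are per-A-scan DFT amplitudes of SD outputs,
targets are amplitudes of the ground truth, and the loss is the focal
frequency loss restricted to amplitudes,

    FFL = (1/MN) Σ w|F_k − F_λ|²,   w = |F_k − F_λ|^α,  α = 1,

i.e. the mean cubed amplitude error (full-scale default 400 epochs).
Amplitudes are divided by the training-split mean ground-truth amplitude
so optimization runs at unit scale.  Checkpoint selection differs per
stage: the SD-CNN keeps the epoch with the lowest validation L1; the
FD-CNN keeps the epoch whose amplitude/phase-fused output scores the best
validation PSNR, with the identity initialization as the epoch-0
candidate.  This task-metric selection is deliberate: amplitude-only FFL
can decrease while the fused pixel error grows (the phase is fixed), and
at desk scale the validated best refinement may be the identity itself —
an honest outcome the evaluation reports as SD+FD equal to SD-only.

Inference chains: preprocess → k-layer → patchify → SD-CNN → unpatchify →
destandardize to a non-negative magnitude image → per-A-scan DFT → FD-CNN
on amplitude → recombine with the SD output's phase → inverse DFT →
magnitude.  Running the Fourier stage as the identity reproduces the SD
output bit-for-bit (the amplitude/phase round trip is exact for a
non-negative image), which is tested.

## Classical baseline

The comparator is conventional k-linearization: each spectrum is
re-interpolated from its non-uniform wavenumbers onto a uniform grid with
the same endpoints and length (linear or natural cubic spline;
no extrapolation), then inverse-DFT'd.  Splines restore the
point-spread width to within a few percent of the k-linear reference at
moderate depth; a single resampled frame retains full speckle, which is
what the 7-average ground truth and the learned reconstruction improve
on (quantified by the β_s structural-correlation score and CNR).

## Evaluation

MSE, PSNR (dynamic range = ground-truth maximum over the evaluation set),
SSIM (canonical Gaussian 11×11 window, σ 1.5, clamped to the largest odd
window that fits small images), CNR per rectangular foreground ROI
against one background ROI in dB, and β_s — the normalized correlation of
mean-subtracted images, 1 for perfect structural agreement.  PSNR of
identical images reports +inf rather than raising; CNR reports ±inf
sentinels for degenerate ROIs.

## Desk-scale study conditions

The demonstration scale (presets.py) uses 200 phantoms of 128 spectral
samples × 64 A-scans (64×64 images), wavelength-linear sweeps over
1260–1360 nm, ~2 scatterers per depth pixel, additive noise σ = 0.02,
7-average ground truth, a 70/20/10 random split with disjoint phantom
seeds, tiny-preset networks and 12 (SD) / 8 (FD) epochs at lr 1e-3 —
sized so the whole two-stage training completes in minutes on one CPU
core.  A separate held-out phantom family (a fixed two-layer geometry the
random training generator never draws) probes generalization to unseen
morphology.  Full-scale settings (2304×256 frames, base-32 channels,
200/400 epochs, lr 1e-4) remain the config defaults.

## Known limitations

* The simulator omits dispersion and system-specific calibration, so the
  λ→k mapping is exactly known — real systems need the mapping estimated.
* FD-CNN refinement reuses the SD phase; at desk scale, where the SD
  output is already close to ground truth, the validated refinement is
  often the identity.  The stage demonstrably helps only when the
  amplitude spectrum carries errors the spatial stage cannot fix.
* Fully developed speckle plus layered geometry is a stylized tissue
  model; quantitative gains do not transfer 1:1 to real samples.
* All computation is float64 on CPU; paper-scale training is possible but
  slow without a GPU framework.
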