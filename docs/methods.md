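# Methods

This note documents the models, numerical choices and limitations of
`ktfmri`. It is the design record; the README shows how to run things.

## Data model and conventions

All containers hold complex single-slice 2D+t arrays of shape
(N_RO, N_PE, T). One Fourier convention is shared package-wide
(`ktfmri.fourier`): unitary DFTs (`norm="ortho"`, so Parseval holds
exactly and noise standard deviations are identical in image and k-space),
with signed frequency indices running −(N/2−1)..N/2 and the DC sample at
0-based array row N/2−1. For N_PE = 192 this puts k_y in −95..96 — the
index range the mask densities are defined on. Every mask generator, the
simulator and the reconstruction operators use this one mapping.

## Synthetic data generator

The generator exists because the study design needs phase-cycled bSSFP and
GRE block-design runs with known ground truth, and no public data of this
kind exists. It emulates, deliberately at desk scale:

* **Geometry.** A 4:3 matrix (default 64 × 48, the ratio of the 256 × 192
  acquisition; 48 is divisible by 12 as the mixture patterns require). An
  elliptical "parenchyma" with a cortical band; relaxation values are
  high-field rat-brain-like (cortex T1/T2 ≈ 1900/50 ms, deeper tissue
  1700/40 ms). Proton density defaults to 1000 a.u. — raw scanner data are
  large compared to 1 in arbitrary units, and this matters because the
  reconstruction's regularization factor λ is dimensional (it competes
  with transform-coefficient magnitudes); at O(1000) image units the
  standard λ values sit in the weak-regularization regime where the
  reconstruction error is insensitive to λ, which is the regime the method
  is meant to operate in. A seeded ±5% smooth texture prevents piecewise-
  constant frames.
* **Activation.** Two cortical disk foci with fractional BOLD amplitudes
  6% and 5% — the few-percent range of high-field somatosensory responses
  in pass-band bSSFP/GRE. The response enters as a multiplicative
  amplitude change on the steady-state signal, not a T2/T2* change: a
  simplification sufficient for detection statistics, stated as such. The
  default response is rectangular (the block-contrast t-test does not use
  response shape); `ramp=True` gives a 1-frame linear onset/offset.
* **Off-resonance heterogeneity.** A gentle ±15 Hz left-right background
  gradient plus a +60 Hz local bump under the second focus. At
  TR = 10 ms, 60 Hz is more than half a banding period (1/(2·TR) = 50 Hz),
  so the two foci sit in different parts of the bSSFP profile at any given
  phase-cycling angle, and the dominant activation focus shifts with the
  angle — the heterogeneity signature the reconstruction must preserve.
* **Signal models.** bSSFP: the Freeman–Hill steady state evaluated at the
  per-TR precession phase β = 2π·Δf·TR + Δφ_PC, echoed at TE = TR/2 with
  T2 decay and off-resonance phase. GRE: the Ernst spoiled steady state
  with the T2 magnitude factor standing in for T2* (no static-dephasing
  model). Defaults: TR/TE = 10/5 ms, flip 16° (bSSFP); 20/10 ms, 8° (GRE);
  paradigm 16/8/24 frames (bSSFP) and 8/4/12 (GRE, halved to mirror its
  halved frame count).
* **Noise.** Additive complex Gaussian in k-space, per-channel SD set via
  `noise_sd_for_snr` (SNR = mean baseline magnitude over the support /
  per-channel SD; 20 in the default experiment). Real fMRI repetitions are
  typically averaged 15–25×, so a single run at SNR 20 stands between a
  raw single acquisition and a fully averaged one; neither is privileged —
  the noise level is an explicit input.

Not emulated (and therefore outside what passing tests demonstrate about
real data): physiological noise and drift, motion, multi-coil reception,
3D slabs, T2*-mediated BOLD, eddy-current artifacts themselves (the paired
pattern reproduces the sampling scheme, not the artifact physics).

## Sampling patterns

All generators keep exactly N_PE/D lines per frame (D = 4 throughout the
study design) and draw each frame independently. Weighted
without-replacement draws use **randomized systematic PPS sampling**
(random line order, unit-spaced comb over cumulative weights k·P(k_y),
with saturated lines peeled off first): per-line inclusion probabilities
are then exactly min(k·P, 1), so empirical line frequencies converge to
the target density — the property the evaluation checks. A sequential
renormalized-draw scheme was measured to distort inclusion probabilities
by up to 0.15 at the study's σ = N_PE/9 and was rejected for that reason;
which scheme the original masks used is unknowable from the sources.
Specifics:

* mixture split 2:1 (N_PE/6 Gaussian + N_PE/12 uniform at D = 4); for odd
  remainders (GRC1's N_PE/D − 1 lines) the Gaussian share rounds up;
* the Gaussian density is evaluated on the discrete k_y grid and
  renormalized to sum to 1;
* GRC1 forces k_y = 0 every frame and excludes it from both mixture draws;
* the paired pattern works on (2m, 2m+1) row couples, always includes the
  couple containing DC, and weights the others by the mixture line density
  summed within each couple;
* the center-only control is deterministic: the contiguous central N_PE/D
  block, k_y ∈ [−(N_PE/2D − 1), N_PE/2D].

## Reconstruction

`forward_model` is A = M·F_PE·Φᴴ. The fully sampled readout axis is
inverse-transformed once up front, after which every readout position is
an independent (k_PE × t) problem — mathematically identical to the 2D
formulation, linear-memory.

The inner problem (W AᴴA W + λI) q = W Aᴴ y is solved by plain conjugate
gradients **from zero**, N_CG = 30 iterations (early exit at relative
gradient norm 10⁻¹²). Three deliberate choices here:

* **Zero start.** The zero-filled adjoint is always data-consistent
  (AAᴴy = y on sampled lines), so warm-starting at the previous iterate is
  a near-stationary point of the weakly regularized objective; CG-30
  cannot leave it and aliasing freezes in (measured: 3× worse NMSE for the
  KLT variant), and the residual trace loses its monotone decrease. The
  zero-start truncated solve approximates the minimum-norm weighted
  solution — the FOCUSS mapping proper.
* **No preconditioning.** A Jacobi-preconditioned variant (preconditioner
  W² + λ) converges to the exact regularized solution fast enough that the
  truncation regularization disappears and the reconstruction error
  becomes strongly λ-dependent (3.4× spread over λ ∈ [10⁻³, 1] versus
  < 2% with plain CG). The λ-insensitivity of the method in practice
  *is* the truncated-CG behavior, so plain CG is kept.
* **Exact diagonal solve at full sampling.** When the mask is all-ones,
  AᴴA = I and the normal matrix is exactly diagonal; it is solved in
  closed form, making the full-sampling reconstruction exact to machine
  precision rather than CG-accurate.

Outer loop: W = |x⁽ᵏ⁻¹⁾|^p with p = 0.5 (implicit ℓ₁ penalty), weights
floored at 10⁻¹²·max|x| so zero-locked coefficients stay recoverable;
x⁽⁰⁾ is the adjoint reconstruction in the sparse domain. λ defaults:
0.1 (temporal FT), 0.01 (KLT). N_FOC is either fixed or `"auto"`: stop at
the first k with ‖Û⁽ᵏ⁾−Û⁽ᵏ⁻¹⁾‖_F/‖Û⁽ᵏ⁾‖_F < 0.1, hard-capped at 20
(`converged=False` if the cap is hit, never an exception). The
sampled-k-space residual ‖y−ŷ‖² is recorded after every CG iteration as
the convergence diagnostic. An optional `mean_subtract` flag removes the
per-location temporal-mean k-space before solving and adds its image back
after; it is off by default — with DC sampled every frame (GRC1) the plain
formulation is well posed.

KLT variant: a preliminary temporal-FT run with N_FOC = 2 builds
C = ÛᴴÛ (T × T, i.e. the covariance over time — Φ acts along the frame
axis); its eigenvectors, sorted by descending eigenvalue, form Φ, updated
N_KLT = 1 time. The KLT stage then runs the same FOCUSS loop from its own
adjoint initialization, so its auto-stopped N_FOC counts its own
iterations (and is never below the FT value in the seeded experiments, the
expected qualitative relation).

Cross-validated N_FOC: each dataset's first stopping-criterion iteration
is computed; for each held-out dataset the consensus over the training
datasets is the mode with ties broken toward the smaller value; the
returned value is the consensus of the per-holdout values, with all
per-fold numbers reported.

Convergence caveat: p = 0.5 FOCUSS is an IRLS-ℓ₁ scheme with linear-rate
tail contraction (measured per-iteration factors 0.45–0.8 on 1D toys).
Support recovery is fast, but coefficient agreement with the exact ℓ₁
solution to 10⁻³ typically needs ~15 outer iterations, not 10 — relevant
when fixing N_FOC a priori instead of using the stopping criterion.

## Statistics

Welch's unequal-variance t statistic per pixel on magnitude data
(baseline = prestimulus frames; activation = stimulation frames, optional
hemodynamic delay in frames, default 0), with Welch–Satterthwaite degrees
of freedom. Pixels with zero variance in both blocks return 0 when the
means agree and a signed sentinel (10⁶) otherwise, flagged — this makes
noiseless simulations usable. Thresholding is two-sided at α (default
0.05) with the per-pixel df; supra-threshold clusters below 6 pixels
(4-connectivity) are rejected; the operation is idempotent. The ROI is the
active mask of each dataset's own full-sampled map — never shared across
datasets. ROC curves sweep the |T| threshold over pooled score quantiles
(200 by default) with (0,0)/(1,1) anchors and trapezoidal AUC; AUC is
invariant under monotone score transforms and cross-checked against an
independent implementation in the tests. Fidelity metrics are the
frame-wise normalized MSE and the average MSE over all T·N pixels; they
satisfy the exact identity
avgMSE = Σ_t NMSE_t·‖u_t‖²/(T·N), which the tests assert.

The "ground truth" for both metrics is the *noisy full-sampled* data, as
in a retrospective study — a perfect denoiser would not reach NMSE 0.

## Experiment orchestration

`run_experiment` expands (subjects × contrasts × patterns × transforms),
derives every seed from one master seed via SHA-256 (all below 2³¹),
tags failures with their stage, and writes CSV/JSON outputs plus a
SHA-256 manifest when an output directory is set. GRE contrasts
automatically use the halved paradigm. The default headline analysis uses
bSSFP at 180° phase cycling — the conventional pass-band contrast.
`compare_patterns` ranks patterns per metric and checks the expected
orderings (center-weighted ≥ uniform random on AUC; Gaussian-weighted
< center-only on NMSE), reporting violations instead of hiding them:
near-tied pairs (e.g. G vs GR on AUC) legitimately swap order from seed
to seed.

Problem sizes used throughout the package's own experiments: 64 × 48
matrix, 48 frames, 3 subjects — chosen so that a full pattern-comparison
study, including cross-validation, completes in minutes on a single CPU
while keeping N_PE divisible by 12 and the 4:3 aspect of the original
matrix.

## Known limitations

* Single-coil, single-slice, Cartesian only; no motion or physiological
  noise; no prospective-acquisition effects.
* The BOLD model is amplitude-multiplicative; contrast mechanisms that
  differ between bSSFP pass-band and GRE BOLD are not modeled beyond the
  steady-state signal levels.
* The uniform-random pattern at desk scale (12 lines/frame) is harsher
  than at full scale (48 lines/frame); its KLT reconstructions can be
  poor because the preliminary-pass covariance inherits aliasing. This is
  reported as-is by the pipeline.
* Reported AUC/NMSE values are properties of the synthetic conditions;
  they support qualitative pattern orderings, not quantitative claims
  about any particular scanner or subject.
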