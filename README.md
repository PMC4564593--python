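# ktfmri

Compressed-sensing reconstruction and evaluation for **non-EPI fMRI**:
k-t undersampling mask design, **k-t FOCUSS** reconstruction with temporal
Fourier and Karhunen-Loève sparsifying transforms, and the statistics used
to judge whether an accelerated acquisition still detects the same
activation as the fully sampled one.

Non-EPI steady-state sequences — spoiled gradient echo (GRE) and balanced
SSFP — avoid the distortion that plagues EPI at high field (9.4 T), but
acquire one phase-encode line per TR and are therefore slow. Undersampling
k-space over time (k-t space) by a factor *D* = 4 and reconstructing with a
sparsity-promoting algorithm can buy that speed back. This package lets you
study, end to end and fully synthetically, how the choice of sampling
pattern and sparsifying transform affects baseline image fidelity and BOLD
activation detection. It is aimed at MR-physics and fMRI-methods
researchers prototyping CS sampling schemes before committing them to a
scanner.

## The method

Dynamic images $U = [\,u_1 \dots u_T\,]$ are modeled as sparse in a unitary
temporal transform $\Phi$ (temporal FT, or the KLT built from the
eigenvectors of the time covariance $C = \hat U^H \hat U$). With
$x = \Phi U$ the measurements are $y = M F_{PE} \Phi^H x$, where $F_{PE}$
is the spatial DFT along the phase-encode axis and $M$ the binary k-t mask.
FOCUSS recovers a sparse $x$ by iterative reweighting: with
$W = \mathrm{diag}(|x^{(k-1)}|^{p})$, each outer iteration solves

$$\min_q \; \|y - A W q\|_2^2 + \lambda \|q\|_2^2, \qquad x^{(k)} = W q,$$

by conjugate gradients on $(W A^H A W + \lambda I)\,q = W A^H y$; the
exponent $p = 0.5$ makes the implicit penalty $\sum_i |x_i|$, i.e. the
$\ell_1$ solution. The outer loop stops when
$\|\hat U^{(k)} - \hat U^{(k-1)}\|_F / \|\hat U^{(k)}\|_F < 0.1$.

Sampling patterns (all with exactly $N_{PE}/D$ lines per frame): uniform
random (**R**); Gaussian variable density
$P(k_y) = A e^{-k_y^2/2\sigma^2}$, $\sigma = N_{PE}/9$ (**G**); a 2:1
Gaussian/uniform mixture (**GR**); the mixture plus the $k_y = 0$ line in
every frame (**GRC1**); a deterministic center-only control; and a paired
variant of GRC1 sampling adjacent line couples for eddy-current
suppression.

Evaluation against the fully sampled data: frame-by-frame normalized MSE
$\|u_t-\hat u_t\|_2^2/\|u_t\|_2^2$ and average MSE
$\sum_t \|u_t-\hat u_t\|_2^2 / (TN)$ for image fidelity; per-pixel Welch
*t* maps (two-sided $\alpha = 0.05$, clusters < 6 pixels rejected), ROI
time courses, and ROC/AUC of the reconstructed map against the
full-sampled map for detection fidelity.

Because no public dataset exists for this design, the package includes a
first-class synthetic generator: a brain-like phantom with cortical
activation foci that differ in off-resonance, imaged through the
Freeman–Hill bSSFP steady state (or the Ernst GRE steady state) so that
phase-cycling angles 0°/90°/180°/270° weight the foci differently — the
banding-driven spatial heterogeneity of high-field phase-cycled bSSFP
fMRI.

## Worked example

```python
import ktfmri as k

paradigm = k.Paradigm.bssfp_default()              # 16 pre / 8 stim / 24 post
phantom  = k.make_phantom((64, 48), seed=1)
series   = k.simulate_timeseries(phantom, paradigm, k.AcquisitionConfig.bssfp(180))
y_full   = k.to_kspace(series, noise_sd=k.noise_sd_for_snr(series, 20), seed=2)

mask   = k.gen_mixture_center1(48, paradigm.n_frames, d=4, seed=3)   # GRC1
y_down = k.apply_mask(y_full, mask)
recon  = k.reconstruct(y_down, k.ReconConfig.ft())

full = k.ImageSeries(k.kspace_to_image(y_full.data), paradigm=paradigm)
full_map = k.threshold_and_cluster(k.tscore_map(full))
print(k.frame_nmse(full, recon.series, t=20))              # 0.0076
print(k.roc_curve(k.tscore_map(recon.series), full_map.active_mask).auc)  # 0.9733
```

A frame NMSE of 0.0076 means the reconstruction from a quarter of the
k-space lines differs from the full-sampled frame by under 1% in energy
(zero-filling the same data gives ≈ 0.14); an AUC of 0.97 means its
activation map nearly reproduces the full-sampled reference map. The
scripts in `examples/` walk through each capability (phantom and banding
profile, mask design, reconstruction, activation statistics, and the full
pattern-comparison experiment) and print these numbers with commentary.

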