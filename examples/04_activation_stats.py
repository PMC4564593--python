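"""Activation mapping and detection fidelity of a CS reconstruction.

The full-sampled run defines the reference activation map (Welch t test,
two-sided alpha 0.05, clusters < 6 pixels rejected) and the ROI.  The
reconstruction's t-map is then swept over thresholds against that
reference to give the ROC curve and its AUC — the headline detection
metric (1 = the reconstruction finds exactly the reference activation).
"""

import numpy as np

import ktfmri as k

paradigm = k.Paradigm.bssfp_default()
phantom = k.make_phantom((64, 48), seed=1)
series = k.simulate_timeseries(phantom, paradigm, k.AcquisitionConfig.bssfp(180))
sd = k.noise_sd_for_snr(series, snr=20.0)
y_full = k.to_kspace(series, noise_sd=sd, seed=2)
full_images = k.ImageSeries(k.kspace_to_image(y_full.data), paradigm=paradigm)

full_map = k.threshold_and_cluster(k.tscore_map(full_images), alpha=0.05, min_cluster=6)
roi = k.select_roi(full_map)
print(f"full-sampled map: {int(full_map.active_mask.sum())} active pixels "
      f"(true activation: {int(phantom.activation_mask.sum())} pixels)")

mask = k.gen_mixture_center1(48, paradigm.n_frames, d=4, seed=3)
recon = k.reconstruct(k.apply_mask(y_full, mask), k.ReconConfig.ft()).series

roc = k.roc_curve(k.tscore_map(recon), full_map.active_mask)
print(f"GRC1 + temporal-FT reconstruction: ROC AUC = {roc.auc:.4f}")

course_full = k.roi_timecourse(full_images, roi)
course_rec = k.roi_timecourse(recon, roi)
stim = paradigm.stim_frames()
pct_full = 100 * (course_full[stim].mean() / course_full[: paradigm.n_pre].mean() - 1)
pct_rec = 100 * (course_rec[stim].mean() / course_rec[: paradigm.n_pre].mean() - 1)
print(f"ROI percent signal change: full-sampled {pct_full:.2f}%, "
      f"reconstruction {pct_rec:.2f}%")
print("\nAUC near 1 means the quarter-data reconstruction reproduces the")
print("reference activation map; the ROI time course keeps the block shape")
print("with a slightly reduced signal change.")
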