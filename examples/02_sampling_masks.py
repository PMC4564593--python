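"""Generate the five k-t undersampling patterns at acceleration factor 4.

Each mask samples exactly N_PE/4 phase-encode lines per time frame.  The
printout shows the per-frame budget, how often the DC (k_y = 0) line is
covered, and how strongly sampling concentrates in the k-space center —
the design trade-off between low-frequency contrast and high-frequency
detail that distinguishes the patterns.
"""

import numpy as np

import ktfmri as k
from ktfmri.fourier import dc_row

N_PE, T, D, SEED = 48, 48, 4, 0

masks = {
    "R (uniform)": k.gen_uniform(N_PE, T, D, SEED),
    "G (Gaussian)": k.gen_gaussian(N_PE, T, D, SEED),
    "GR (mixture)": k.gen_mixture(N_PE, T, D, SEED),
    "GRC1 (mixture + DC)": k.gen_mixture_center1(N_PE, T, D, SEED),
    "CENTER_ONLY (control)": k.gen_center_only(N_PE, T, D),
    "GRC1_PAIRED (eddy-current)": k.gen_pairwise(N_PE, T, D, SEED),
}

dc = dc_row(N_PE)
print(f"N_PE = {N_PE}, T = {T}, D = {D}  ->  {N_PE // D} lines per frame\n")
print(f"{'pattern':28s} {'lines/frame':>11s} {'DC coverage':>11s} {'center third':>12s}")
for name, mask in masks.items():
    budget = mask.lines.sum(axis=0)
    dc_cov = mask.lines[dc].mean()
    center = mask.lines[dc - N_PE // 6 : dc + N_PE // 6].sum() / mask.lines.sum()
    print(f"{name:28s} {int(budget[0]):11d} {dc_cov:10.0%} {center:11.0%}")
print("\n'DC coverage' = fraction of frames sampling k_y = 0; 'center third'")
print("= fraction of all samples falling in the central third of k-space.")
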