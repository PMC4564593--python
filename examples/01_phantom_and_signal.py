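"""Build the default phantom and inspect the bSSFP banding profile.

Generates the brain-like phantom with two cortical activation foci,
evaluates the balanced-SSFP steady state at the four phase-cycling angles,
and prints the signal magnitude at each focus.  Because the foci sit ~60 Hz
apart in off-resonance, each phase-cycling angle places them at different
points of the pass-band/stop-band profile — the focus with the stronger
baseline signal dominates the activation contrast at that angle.
"""

import numpy as np

import ktfmri as k

phantom = k.make_phantom((64, 48), seed=1)
(ay, ax), (by, bx) = phantom.focus_centers
print(f"focus A at {(ay, ax)}, off-resonance {phantom.off_resonance[ay, ax]:+.1f} Hz")
print(f"focus B at {(by, bx)}, off-resonance {phantom.off_resonance[by, bx]:+.1f} Hz")
print(f"activation amplitudes: {phantom.activation_amplitude[ay, ax]:.0%}, "
      f"{phantom.activation_amplitude[by, bx]:.0%}\n")

print("phase cycling | |S| focus A | |S| focus B  (a.u.)")
for pc in (0, 90, 180, 270):
    sig = np.abs(k.steady_state_signal(phantom, k.AcquisitionConfig.bssfp(pc)))
    print(f"    {pc:3d} deg   |   {sig[ay, ax]:7.2f}  |   {sig[by, bx]:7.2f}")
print("\nThe focus with the larger baseline signal carries the larger BOLD")
print("difference at that angle, so the apparent activation focus shifts")
print("with the phase-cycling angle.")
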