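"""Centered discrete Fourier transforms and the phase-encode index convention.

One convention is shared by the mask generators, the simulator and the
reconstruction engine: for an axis of even length N the signed frequency
indices run from -(N/2 - 1) to N/2, so the DC component sits at 0-based
array row N/2 - 1 (for N_PE = 192 the phase-encode index k_y spans -95..96
with DC at row 95).  All transforms are unitary (``norm="ortho"``), which
makes Parseval's identity exact up to floating-point rounding.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ky_index", "dc_row", "image_to_kspace", "kspace_to_image"]


def ky_index(n: int) -> np.ndarray:
    """Signed frequency index per array row: -(N/2-1)..N/2 for even N."""
    return np.arange(n) - (n // 2 - 1)


def dc_row(n: int) -> int:
    """0-based array row holding the DC (k = 0) line."""
    return n // 2 - 1


def _shift(n: int) -> int:
    # fft output has DC at index 0; roll it to dc_row(n)
    return n // 2 - 1


def image_to_kspace(img: np.ndarray, axes=(0, 1)) -> np.ndarray:
    """Unitary DFT along ``axes`` with DC rolled to the centered convention."""
    k = np.fft.fftn(img, axes=axes, norm="ortho")
    for ax in axes:
        k = np.roll(k, _shift(img.shape[ax]), axis=ax)
    return k


def kspace_to_image(ksp: np.ndarray, axes=(0, 1)) -> np.ndarray:
    """Inverse of :func:`image_to_kspace`."""
    for ax in axes:
        ksp = np.roll(ksp, -_shift(ksp.shape[ax]), axis=ax)
    return np.fft.ifftn(ksp, axes=axes, norm="ortho")
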