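"""Core in-memory containers for 2D+time fMRI data.

``ImageSeries`` holds the complex spatiotemporal stack U = [u_1 ... u_T]
(readout x phase-encode x time); ``KSpaceSeries`` holds the corresponding
k-space measurements y with an optional sampling mask; ``Paradigm`` encodes
the block design (pre / stimulation / post frame counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fourier import dc_row

__all__ = ["Paradigm", "ImageSeries", "KSpaceSeries"]


@dataclass(frozen=True)
class Paradigm:
    """Block-design stimulation paradigm.

    Frame counts of the prestimulus baseline, stimulation block and
    poststimulus period.  The defaults used throughout are (16, 8, 24) for
    bSSFP runs and the halved (8, 4, 12) for GRE runs.
    """

    n_pre: int
    n_stim: int
    n_post: int

    def __post_init__(self) -> None:
        for name in ("n_pre", "n_stim", "n_post"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")

    @property
    def n_frames(self) -> int:
        return self.n_pre + self.n_stim + self.n_post

    def baseline_frames(self) -> np.ndarray:
        """0-based indices of the prestimulus frames."""
        return np.arange(self.n_pre)

    def stim_frames(self, delay: int = 0) -> np.ndarray:
        """0-based indices of the stimulation frames, shifted by a
        hemodynamic delay (frames)."""
        idx = np.arange(self.n_pre, self.n_pre + self.n_stim) + delay
        if idx[-1] >= self.n_frames or idx[0] < 0:
            raise ValueError(
                f"delay {delay} pushes the stimulation block outside the run "
                f"(T = {self.n_frames})"
            )
        return idx

    @classmethod
    def bssfp_default(cls) -> "Paradigm":
        return cls(16, 8, 24)

    @classmethod
    def gre_default(cls) -> "Paradigm":
        return cls(8, 4, 12)


@dataclass
class ImageSeries:
    """Complex 2D+t image stack with paradigm and provenance metadata.

    frames : complex array, shape (n_ro, n_pe, T)
    paradigm : block design; when present T must match its frame total
    provenance : "ground_truth", "reconstruction" or "zero_filled"
    """

    frames: np.ndarray
    paradigm: Optional[Paradigm] = None
    provenance: str = "ground_truth"

    _PROVENANCES = ("ground_truth", "reconstruction", "zero_filled")

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3D (n_ro, n_pe, T) array")
        if not np.iscomplexobj(self.frames):
            self.frames = self.frames.astype(np.complex128)
        if self.provenance not in self._PROVENANCES:
            raise ValueError(f"provenance must be one of {self._PROVENANCES}")
        if self.paradigm is not None and self.paradigm.n_frames != self.n_frames:
            raise ValueError(
                f"paradigm total {self.paradigm.n_frames} != number of "
                f"frames {self.n_frames}"
            )

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def n_pixels(self) -> int:
        return self.frames.shape[0] * self.frames.shape[1]

    def magnitude(self) -> np.ndarray:
        return np.abs(self.frames)

    def copy(self, provenance: Optional[str] = None) -> "ImageSeries":
        return ImageSeries(
            self.frames.copy(),
            paradigm=self.paradigm,
            provenance=provenance or self.provenance,
        )


@dataclass
class KSpaceSeries:
    """Complex k-space time series y with an attached sampling mask.

    data : complex array, shape (n_ro, n_pe, T)
    mask : SamplingMask or None (None = fully sampled)
    paradigm : carried through from the source image series when known

    When a mask is attached, entries on unsampled phase-encode lines are
    exactly zero.
    """

    data: np.ndarray
    mask: Optional[object] = None  # SamplingMask; kept loose to avoid cycles
    paradigm: Optional[Paradigm] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be a 3D (n_ro, n_pe, T) array")
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)
        if self.mask is not None:
            lines = np.asarray(self.mask.lines, dtype=bool)
            if lines.shape != (self.data.shape[1], self.data.shape[2]):
                raise ValueError(
                    f"mask shape {lines.shape} does not match k-space "
                    f"(n_pe, T) = {self.data.shape[1:]}"
                )
            unsampled = self.data[:, ~lines]
            if unsampled.size and np.any(unsampled != 0):
                raise ValueError("unsampled k-space entries must be exactly zero")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def center_index(self) -> tuple:
        """(readout, phase-encode) array indices of the DC sample."""
        return (dc_row(self.data.shape[0]), dc_row(self.data.shape[1]))

    def is_fully_sampled(self) -> bool:
        return self.mask is None or bool(np.all(np.asarray(self.mask.lines, bool)))
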