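"""Synthetic phase-cycled bSSFP / spoiled-GRE fMRI phantom generator.

The generator builds a brain-like 2D phantom (elliptical parenchyma with a
cortical band), places two or more BOLD activation foci in the cortex, and
gives the foci different off-resonance offsets.  Because the bSSFP steady
state depends periodically on the off-resonance phase accrued per TR plus
the RF phase-cycling increment, the different foci sit at different points
of the pass-band/stop-band profile for each phase-cycling angle, so the
apparent activation focus shifts with the angle — the spatial heterogeneity
signature of phase-cycled bSSFP fMRI at high field that the downstream
reconstruction has to preserve.

Simplifications (deliberate): BOLD enters as a multiplicative fractional
amplitude change on the steady-state signal rather than a T2/T2* change;
no physiological noise, motion, or multi-coil sensitivities; noise is
additive complex Gaussian in k-space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .containers import ImageSeries, KSpaceSeries, Paradigm
from .fourier import image_to_kspace
from .sampling import full_mask

__all__ = [
    "Phantom",
    "AcquisitionConfig",
    "make_phantom",
    "steady_state_signal",
    "simulate_timeseries",
    "to_kspace",
    "noise_sd_for_snr",
]

MIN_SHAPE = (32, 32)

#: proton-density scale (a.u.).  Raw scanner data come in arbitrary units
#: that are large compared to 1; the regularization factor of the
#: reconstruction is dimensional (it competes with transform-coefficient
#: magnitudes), so emulating scanner-scale intensities keeps the standard
#: small lambda values in their intended weak-regularization regime.
DEFAULT_PD_SCALE = 1000.0

#: default fractional BOLD amplitudes of the two activation foci; forepaw
#: somatosensory responses in pass-band bSSFP/GRE at high field are a few
#: percent, so the foci are set to 6% and 5%.
DEFAULT_FOCUS_AMPLITUDES = (0.06, 0.05)


@dataclass
class Phantom:
    """Tissue-parameter maps of the numerical phantom.

    All maps share one shape.  T1/T2 in ms, off_resonance in Hz,
    activation_amplitude as a fractional signal change in [0, 0.5] that is
    zero outside ``activation_mask``.
    """

    proton_density: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    off_resonance: np.ndarray
    activation_mask: np.ndarray
    activation_amplitude: np.ndarray
    focus_centers: list = field(default_factory=list)

    def __post_init__(self) -> None:
        shape = self.proton_density.shape
        for name in ("t1", "t2", "off_resonance", "activation_mask", "activation_amplitude"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape differs from proton_density")
        self.activation_mask = self.activation_mask.astype(bool)
        support = self.proton_density > 0
        if np.any(self.t2[support] <= 0) or np.any(self.t1[support] <= 0):
            raise ValueError("T1 and T2 must be positive wherever proton_density > 0")
        if np.any(self.t1[support] < self.t2[support]):
            raise ValueError("T1 >= T2 must hold wherever proton_density > 0")
        if np.any(self.activation_amplitude[~self.activation_mask] != 0):
            raise ValueError("activation_amplitude must be 0 outside activation_mask")
        if np.any(self.activation_amplitude < 0) or np.any(self.activation_amplitude > 0.5):
            raise ValueError("activation_amplitude must lie in [0, 0.5]")

    @property
    def shape(self) -> tuple:
        return self.proton_density.shape

    @property
    def support(self) -> np.ndarray:
        return self.proton_density > 0


@dataclass(frozen=True)
class AcquisitionConfig:
    """Steady-state acquisition parameters.

    sequence : "bssfp" or "gre"
    tr, te : repetition / echo time (ms), TE <= TR
    flip_angle : degrees
    phase_cycling : RF phase increment per TR in degrees (bSSFP only)
    matrix : (N_RO, N_PE); informational, the phantom shape governs
    noise_sd : k-space complex-Gaussian noise SD per channel (a.u.)
    seed : noise seed
    """

    sequence: str
    tr: float
    te: float
    flip_angle: float
    phase_cycling: Optional[float] = None
    matrix: Optional[tuple] = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sequence not in ("bssfp", "gre"):
            raise ValueError("sequence must be 'bssfp' or 'gre'")
        if self.te > self.tr:
            raise ValueError(f"TE = {self.te} must not exceed TR = {self.tr}")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.sequence == "bssfp" and self.phase_cycling is None:
            object.__setattr__(self, "phase_cycling", 180.0)
        if self.matrix is not None and any(m <= 0 for m in self.matrix):
            raise ValueError("matrix dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @classmethod
    def bssfp(cls, phase_cycling: float = 180.0, **kw) -> "AcquisitionConfig":
        """bSSFP defaults: TR/TE = 10/5 ms, flip 16 degrees."""
        kw.setdefault("tr", 10.0)
        kw.setdefault("te", 5.0)
        kw.setdefault("flip_angle", 16.0)
        return cls(sequence="bssfp", phase_cycling=phase_cycling, **kw)

    @classmethod
    def gre(cls, **kw) -> "AcquisitionConfig":
        """Spoiled-GRE defaults: TR/TE = 20/10 ms, flip 8 degrees."""
        kw.setdefault("tr", 20.0)
        kw.setdefault("te", 10.0)
        kw.setdefault("flip_angle", 8.0)
        return cls(sequence="gre", **kw)


def _ellipse(shape, center, semi, yy, xx):
    return ((yy - center[0]) / semi[0]) ** 2 + ((xx - center[1]) / semi[1]) ** 2 <= 1.0


def make_phantom(shape, seed: int, focus_spec: Optional[Sequence[dict]] = None) -> Phantom:
    """Build the default brain-like phantom.

    An elliptical parenchyma with a cortical band; two (or ``focus_spec``-
    defined) activation foci inside the band whose local off-resonance
    values differ by >= 1/(2 TR) Hz at TR = 10 ms (i.e. >= 50 Hz), so that
    phase-cycled bSSFP contrasts weight them differently.  Deterministic for
    a fixed (shape, seed).

    focus_spec : optional list of dicts with keys ``center`` (row, col),
        ``radius`` (px), ``amplitude`` (fractional), ``df_offset`` (Hz).
    """
    shape = tuple(int(s) for s in shape)
    if shape[0] < MIN_SHAPE[0] or shape[1] < MIN_SHAPE[1]:
        raise ValueError(f"phantom shape {shape} too small; minimum is {MIN_SHAPE}")
    ny, nx = shape
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    semi = (0.45 * ny, 0.42 * nx)

    brain = _ellipse(shape, center, semi, yy, xx)
    r_norm = np.sqrt(((yy - center[0]) / semi[0]) ** 2 + ((xx - center[1]) / semi[1]) ** 2)
    cortex = brain & (r_norm >= 0.72)

    pd = np.zeros(shape)
    pd[brain] = DEFAULT_PD_SCALE
    # mild smooth proton-density texture so frames are not piecewise constant
    texture = rng.normal(0.0, 1.0, shape)
    kernel = np.outer(np.hanning(9), np.hanning(9))
    kernel /= kernel.sum()
    from scipy.signal import fftconvolve

    texture = fftconvolve(texture, kernel, mode="same")
    pd[brain] *= 1.0 + 0.05 * texture[brain]

    # rat-brain-like relaxation at high field (ms)
    t1 = np.where(cortex, 1900.0, 1700.0)
    t2 = np.where(cortex, 50.0, 40.0)
    t1[~brain] = 1.0
    t2[~brain] = 1.0

    # smooth background field: gentle left-right gradient, +-15 Hz
    off = 30.0 * ((xx - center[1]) / nx)

    if focus_spec is None:
        # two cortical foci on the dorsal band, opposite hemispheres;
        # focus B carries a +60 Hz local field offset (>= 1/(2 TR) at
        # TR = 10 ms) so the two foci see different bSSFP band positions
        ra = max(2.5, 0.045 * min(shape))
        focus_spec = [
            {
                "center": (int(center[0] - 0.80 * semi[0]), int(center[1] - 0.35 * semi[1])),
                "radius": ra,
                "amplitude": DEFAULT_FOCUS_AMPLITUDES[0],
                "df_offset": 0.0,
            },
            {
                "center": (int(center[0] - 0.80 * semi[0]), int(center[1] + 0.35 * semi[1])),
                "radius": ra,
                "amplitude": DEFAULT_FOCUS_AMPLITUDES[1],
                "df_offset": 60.0,
            },
        ]

    act_mask = np.zeros(shape, dtype=bool)
    act_amp = np.zeros(shape)
    centers = []
    for spec in focus_spec:
        cy, cx = spec["center"]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec["radius"] ** 2
        disk &= brain
        act_mask |= disk
        act_amp[disk] = spec["amplitude"]
        centers.append((int(cy), int(cx)))
        df_off = spec.get("df_offset", 0.0)
        if df_off:
            # smooth local field bump, ~2x focus radius footprint
            bump = df_off * np.exp(
                -(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * (1.6 * spec["radius"]) ** 2))
            )
            off = off + bump

    return Phantom(
        proton_density=pd,
        t1=t1,
        t2=t2,
        off_resonance=off,
        activation_mask=act_mask,
        activation_amplitude=act_amp,
        focus_centers=centers,
    )


def steady_state_signal(phantom: Phantom, acq: AcquisitionConfig) -> np.ndarray:
    """Complex steady-state signal map for the given acquisition.

    GRE: Ernst-law spoiled steady state with T2 decay folded in at TE and
    the off-resonance phase accrued over TE.

    bSSFP: Freeman-Hill balanced steady state evaluated at the per-TR
    precession phase beta = 2 pi df TR + phase-cycling increment, echoed at
    TE with T2 decay; as a function of (df, phase_cycling) this traces the
    characteristic pass-band/stop-band profile with period 2 pi in beta.
    """
    support = phantom.support
    if np.any(phantom.t1[support] <= 0) or np.any(phantom.t2[support] <= 0):
        raise ValueError("zero/negative T1 or T2 inside the phantom support")
    pd = phantom.proton_density
    alpha = np.deg2rad(acq.flip_angle)
    tr_s, te_s = acq.tr * 1e-3, acq.te * 1e-3
    e1 = np.exp(-acq.tr / phantom.t1)
    e2 = np.exp(-acq.te / phantom.t2)
    phi_te = np.exp(2j * np.pi * phantom.off_resonance * te_s)

    if acq.sequence == "gre":
        s = pd * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))
        out = s * e2 * phi_te
    else:
        e2tr = np.exp(-acq.tr / phantom.t2)
        beta = 2.0 * np.pi * phantom.off_resonance * tr_s + np.deg2rad(acq.phase_cycling)
        cb, ca = np.cos(beta), np.cos(alpha)
        denom = (1.0 - e1 * ca) * (1.0 - e2tr * cb) - e2tr * (e1 - ca) * (e2tr - cb)
        m = pd * (1.0 - e1) * np.sin(alpha) * (1.0 - e2tr * np.exp(1j * beta)) / denom
        out = m * e2 * phi_te
    out = np.asarray(out, dtype=np.complex128)
    out[~support] = 0.0
    return out


def simulate_timeseries(
    phantom: Phantom,
    paradigm: Paradigm,
    acq: AcquisitionConfig,
    ramp: bool = False,
) -> ImageSeries:
    """Noiseless block-design time series.

    Baseline frames carry the steady-state signal; during stimulation the
    signal inside the activation mask is scaled by (1 + activation
    amplitude).  With ``ramp=True`` the first stimulation frame and the
    first post frame carry half the amplitude (1-frame linear onset/offset);
    the default is a rectangular response, matching a block-contrast t-test.
    """
    base = steady_state_signal(phantom, acq)
    t_total = paradigm.n_frames
    frames = np.repeat(base[:, :, None], t_total, axis=2)
    amp = phantom.activation_amplitude
    stim = paradigm.stim_frames()
    weights = np.zeros(t_total)
    weights[stim] = 1.0
    if ramp:
        weights[stim[0]] = 0.5
        post0 = stim[-1] + 1
        if post0 < t_total:
            weights[post0] = 0.5
    for t in np.flatnonzero(weights):
        frames[:, :, t] = base * (1.0 + weights[t] * amp)
    return ImageSeries(frames, paradigm=paradigm, provenance="ground_truth")


def to_kspace(series: ImageSeries, noise_sd: float = 0.0, seed: int = 0) -> KSpaceSeries:
    """Per-frame unitary 2D DFT plus additive complex Gaussian k-space noise.

    ``noise_sd`` is the standard deviation per real/imaginary channel; with
    unitary transforms it equals the per-channel image-domain noise SD.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be nonnegative, got {noise_sd}")
    k = image_to_kspace(series.frames, axes=(0, 1))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        k = k + noise_sd * (
            rng.standard_normal(k.shape) + 1j * rng.standard_normal(k.shape)
        )
    n_pe, t = k.shape[1], k.shape[2]
    return KSpaceSeries(k, mask=full_mask(n_pe, t), paradigm=series.paradigm)


def noise_sd_for_snr(series: ImageSeries, snr: float) -> float:
    """k-space noise SD giving the requested baseline image SNR.

    SNR is defined as the mean first-frame magnitude over the object
    support divided by the per-channel noise SD (unitary transforms keep
    that SD identical in image and k-space).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    frame0 = np.abs(series.frames[:, :, 0])
    support = frame0 > 0
    if not support.any():
        raise ValueError("series has no nonzero support")
    return float(frame0[support].mean() / snr)
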