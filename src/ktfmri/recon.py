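"""k-t FOCUSS reconstruction for Cartesian k-t undersampled dynamic MRI.

The dynamic image stack U (n_ro x n_pe x T) is modeled as sparse in a
unitary temporal transform Phi (temporal Fourier or data-driven
Karhunen-Loeve) applied along the frame axis.  With x the transform-domain
coefficients, the measurement model is

    y = M F_pe Phi^H x

where F_pe is the unitary spatial DFT along the phase-encode axis and M
the binary k-t sampling mask.  The fully sampled readout axis is inverse-
transformed once up front, so every readout position decouples into an
independent (k_pe x t) problem; the implementation keeps the whole stack
together and lets numpy broadcast.

FOCUSS (FOCal Underdetermined System Solver) finds a sparse x by iterative
reweighting: with W = |x_prev|^p elementwise (p = 0.5 targets the l1
solution), each outer iteration solves the Tikhonov-regularized weighted
least-squares problem

    min_q || y - A W q ||_2^2 + lambda ||q||_2^2,   x = W q,

via conjugate gradients on the normal equations
(W A^H A W + lambda I) q = W A^H y.  The outer loop stops after N_FOC
iterations, or automatically when the relative Frobenius change of the
image iterate drops below ``stop_tol`` (0.1 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Union

import numpy as np

from .containers import ImageSeries, KSpaceSeries
from .fourier import image_to_kspace, kspace_to_image
from .sampling import SamplingMask

__all__ = [
    "ReconConfig",
    "TemporalTransform",
    "FocussState",
    "ReconResult",
    "forward_model",
    "adjoint_model",
    "cg_solve",
    "ktfocuss",
    "reconstruct",
    "build_klt",
    "stopping_criterion",
    "select_nfoc_cv",
    "residual_error",
]

#: multiplicative floor on FOCUSS weights, relative to max|x|; keeps the
#: CG system full-rank and lets zero-locked coefficients re-enter
WEIGHT_FLOOR = 1e-12

#: hard cap on the automatic outer-iteration count
MAX_FOC_DEFAULT = 20


@dataclass(frozen=True)
class ReconConfig:
    """k-t FOCUSS parameters.

    p : weighting power in (0, 1]; 0.5 targets the l1 solution
    lam : Tikhonov regularization (0.1 for temporal FT, 0.01 for KLT)
    n_cg : inner conjugate-gradient iterations (30 suffices in practice)
    n_foc : outer iteration count, or "auto" for the stopping criterion
    transform : "temporal_FT" or "KLT"
    n_klt : number of KLT basis updates (1 by default)
    prelim_n_foc : outer iterations of the temporal-FT preliminary pass
        from which the KLT covariance is built
    stop_tol : relative Frobenius change below which "auto" stops
    max_foc : hard cap for "auto"
    mean_subtract : subtract the temporal-mean k-space before solving and
        add its image back afterwards (off by default)
    """

    p: float = 0.5
    lam: float = 0.1
    n_cg: int = 30
    n_foc: Union[int, str] = "auto"
    transform: str = "temporal_FT"
    n_klt: int = 1
    prelim_n_foc: int = 2
    stop_tol: float = 0.1
    max_foc: int = MAX_FOC_DEFAULT
    mean_subtract: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.n_cg < 1:
            raise ValueError("n_cg must be >= 1")
        if self.stop_tol <= 0:
            raise ValueError("stop_tol must be positive")
        if self.transform not in ("temporal_FT", "KLT"):
            raise ValueError("transform must be 'temporal_FT' or 'KLT'")
        if self.n_foc != "auto" and (not isinstance(self.n_foc, int) or self.n_foc < 1):
            raise ValueError("n_foc must be a positive integer or 'auto'")

    @classmethod
    def ft(cls, **kw) -> "ReconConfig":
        kw.setdefault("lam", 0.1)
        return cls(transform="temporal_FT", **kw)

    @classmethod
    def klt(cls, **kw) -> "ReconConfig":
        kw.setdefault("lam", 0.01)
        return cls(transform="KLT", **kw)


class TemporalTransform:
    """Unitary T x T operator applied along the time axis.

    ``forward`` maps image time courses to transform coefficients
    (x = Phi u); ``inverse`` applies Phi^H.
    """

    def __init__(self, matrix: np.ndarray, kind: str, eigenvalues: Optional[np.ndarray] = None):
        matrix = np.asarray(matrix, dtype=np.complex128)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("transform matrix must be square")
        gram = matrix @ matrix.conj().T
        if not np.allclose(gram, np.eye(matrix.shape[0]), atol=1e-10):
            raise ValueError("temporal transform must be unitary (Phi Phi^H = I)")
        self.matrix = matrix
        self.kind = kind
        self.eigenvalues = eigenvalues

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    def forward(self, arr: np.ndarray) -> np.ndarray:
        """Apply Phi along the last axis."""
        return arr @ self.matrix.T

    def inverse(self, arr: np.ndarray) -> np.ndarray:
        """Apply Phi^H along the last axis."""
        return arr @ self.matrix.conj()

    @classmethod
    def fourier(cls, n_frames: int) -> "TemporalTransform":
        """Unitary temporal DFT."""
        phi = np.fft.fft(np.eye(n_frames), axis=1, norm="ortho")
        return cls(phi, kind="FT")


@dataclass
class FocussState:
    """Iterate state of the outer FOCUSS loop."""

    x: np.ndarray
    weights: np.ndarray
    q: Optional[np.ndarray]
    iteration: int


@dataclass
class ReconResult:
    """Reconstruction output.

    series : reconstructed image series (provenance "reconstruction")
    residual_trace : per outer iteration, the sampled-k-space residual
        ||y - y_hat||_2^2 after each CG iteration
    n_foc_used : outer iterations actually run
    transform : the temporal transform used
    converged : False only when "auto" hit the hard cap without firing
    """

    series: ImageSeries
    residual_trace: List[np.ndarray]
    n_foc_used: int
    transform: TemporalTransform
    converged: bool = True


def _lines(mask: SamplingMask) -> np.ndarray:
    return np.asarray(mask.lines, dtype=bool)


def forward_model(x: np.ndarray, mask: SamplingMask, phi: TemporalTransform) -> np.ndarray:
    """A x = M F_pe Phi^H x (readout axis already in image space)."""
    u = phi.inverse(x)
    k = image_to_kspace(u, axes=(1,))
    return np.where(_lines(mask)[None, :, :], k, 0.0 + 0.0j)


def adjoint_model(y: np.ndarray, mask: SamplingMask, phi: TemporalTransform) -> np.ndarray:
    """A^H y = Phi F_pe^H M y."""
    k = np.where(_lines(mask)[None, :, :], y, 0.0 + 0.0j)
    u = kspace_to_image(k, axes=(1,))
    return phi.forward(u)


def _vdot(a: np.ndarray, b: np.ndarray) -> complex:
    return np.vdot(a.reshape(-1), b.reshape(-1))


def cg_solve(
    mask: SamplingMask,
    phi: TemporalTransform,
    weights: np.ndarray,
    y: np.ndarray,
    lam: float,
    n_cg: int,
    q0: Optional[np.ndarray] = None,
    record_residual: Optional[np.ndarray] = None,
) -> tuple:
    """Conjugate gradients on (W A^H A W + lambda I) q = W A^H y.

    Starts from zero (or ``q0``) so the truncated solve approximates the
    minimum-norm weighted solution that drives FOCUSS sparsification; runs
    ``n_cg`` iterations, exiting early when the relative gradient norm
    drops below 1e-12.  When the mask is fully sampled A^H A = I, the
    normal matrix is exactly diagonal and the solve is done in closed form
    instead.  When ``record_residual`` (the sampled measurements) is given,
    the sampled-k-space residual ||y - A W q||_2^2 is recorded after every
    iteration and returned alongside q.
    """

    def apply_b(q):
        return weights * adjoint_model(forward_model(weights * q, mask, phi), mask, phi) + lam * q

    b = weights * adjoint_model(y, mask, phi)

    if np.all(_lines(mask)):
        # complete sampling: W A^H A W + lam I = W^2 + lam I, solve exactly
        q = b / (weights * weights + lam) if lam > 0 else np.where(
            weights > 0, b / np.where(weights > 0, weights**2, 1.0), 0.0
        )
        trace = []
        if record_residual is not None:
            diff = record_residual - forward_model(weights * q, mask, phi)
            trace.append(_vdot(diff, diff).real)
        return q, np.asarray(trace)
    q = np.zeros_like(b) if q0 is None else q0.astype(np.complex128, copy=True)
    r = b - apply_b(q)
    p = r.copy()
    rs = _vdot(r, r).real
    b_norm = np.sqrt(_vdot(b, b).real)
    trace = []

    def log_residual():
        if record_residual is not None:
            diff = record_residual - forward_model(weights * q, mask, phi)
            trace.append(_vdot(diff, diff).real)

    for _ in range(n_cg):
        if b_norm > 0 and np.sqrt(rs) / b_norm < 1e-12:
            break
        bp = apply_b(p)
        denom = _vdot(p, bp).real
        if denom <= 0:
            break
        alpha = rs / denom
        q = q + alpha * p
        log_residual()
        r = r - alpha * bp
        rs_new = _vdot(r, r).real
        p = r + (rs_new / rs) * p
        rs = rs_new
    return q, np.asarray(trace)


def _focuss_weights(x: np.ndarray, p: float) -> np.ndarray:
    mag = np.abs(x)
    floor = WEIGHT_FLOOR * mag.max()
    if floor == 0.0:
        return np.zeros_like(mag)
    return np.maximum(mag, floor) ** p


def ktfocuss(
    y: KSpaceSeries,
    config: ReconConfig,
    phi: Optional[TemporalTransform] = None,
    x0: Optional[np.ndarray] = None,
) -> ReconResult:
    """Run the FOCUSS outer loop with a fixed temporal transform.

    ``phi`` defaults to the temporal Fourier transform.  ``x0`` seeds the
    reweighting; by default it is the zero-filled adjoint reconstruction
    transformed into the sparse domain.  Use :func:`reconstruct` for the
    full KLT pipeline (preliminary FT pass + covariance eigenbasis).
    """
    if y.mask is None:
        raise ValueError("k-space series must carry a sampling mask")
    if phi is None:
        phi = TemporalTransform.fourier(y.n_frames)
    if phi.n_frames != y.n_frames:
        raise ValueError("temporal transform size does not match frame count")

    # decouple the fully sampled readout axis once
    yh = kspace_to_image(y.data, axes=(0,))
    mask = y.mask

    mean_img = None
    if config.mean_subtract:
        lines = _lines(mask)
        counts = lines.sum(axis=1, keepdims=True)  # (n_pe, 1)
        mean_k = np.where(
            counts[None, :, :] > 0,
            yh.sum(axis=2, keepdims=True) / np.maximum(counts[None, :, :], 1),
            0.0,
        )
        yh = np.where(lines[None, :, :], yh - mean_k, 0.0)
        mean_img = kspace_to_image(mean_k[:, :, 0], axes=(1,))

    x = adjoint_model(yh, mask, phi) if x0 is None else np.asarray(x0, dtype=np.complex128)
    if x.shape != yh.shape:
        raise ValueError("x0 shape does not match the data")

    auto = config.n_foc == "auto"
    n_outer = config.max_foc if auto else int(config.n_foc)
    u_prev = phi.inverse(x)
    residual_trace: List[np.ndarray] = []
    converged = not auto
    n_used = 0

    for k in range(1, n_outer + 1):
        w = _focuss_weights(x, config.p)
        if not np.any(w):
            # all-zero data: nothing to reconstruct
            n_used = k
            converged = True
            break
        q, trace = cg_solve(mask, phi, w, yh, config.lam, config.n_cg, record_residual=yh)
        x = w * q
        residual_trace.append(trace)
        n_used = k
        u_k = phi.inverse(x)
        if auto and stopping_criterion(u_k, u_prev, config.stop_tol):
            converged = True
            u_prev = u_k
            break
        u_prev = u_k

    u = u_prev
    if mean_img is not None:
        u = u + mean_img[:, :, None]
    series = ImageSeries(u, paradigm=y.paradigm, provenance="reconstruction")
    return ReconResult(
        series=series,
        residual_trace=residual_trace,
        n_foc_used=n_used,
        transform=phi,
        converged=converged,
    )


def build_klt(prelim: Union[ReconResult, ImageSeries]) -> TemporalTransform:
    """Karhunen-Loeve temporal basis from a preliminary reconstruction.

    The T x T covariance C = U^H U (frames stacked as columns of an N x T
    matrix) is eigendecomposed; eigenvectors sorted by descending
    eigenvalue form the unitary transform.
    """
    series = prelim.series if isinstance(prelim, ReconResult) else prelim
    frames = series.frames
    n_t = frames.shape[2]
    u_mat = frames.reshape(-1, n_t)
    if not np.any(u_mat):
        raise ValueError("preliminary reconstruction is all zero; cannot build a KLT")
    cov = u_mat.conj().T @ u_mat
    cov = 0.5 * (cov + cov.conj().T)  # enforce Hermitian symmetry numerically
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # Phi rows are the eigenvector conjugates: x = Phi u projects onto them
    return TemporalTransform(evecs.conj().T, kind="KLT", eigenvalues=evals)


def reconstruct(y: KSpaceSeries, config: ReconConfig) -> ReconResult:
    """Full reconstruction pipeline for either transform.

    temporal_FT: a single :func:`ktfocuss` run.  KLT: a preliminary
    temporal-FT pass (``prelim_n_foc`` outer iterations) builds the
    covariance eigenbasis, then the FOCUSS loop is re-run in that basis;
    repeated ``n_klt`` times.
    """
    if config.transform == "temporal_FT":
        return ktfocuss(y, config)
    prelim_cfg = replace(config, transform="temporal_FT", lam=0.1, n_foc=config.prelim_n_foc)
    result = ktfocuss(y, prelim_cfg)
    for _ in range(config.n_klt):
        phi = build_klt(result)
        result = ktfocuss(y, config, phi=phi)
    return result


def stopping_criterion(
    u_k: Union[ImageSeries, np.ndarray],
    u_km1: Union[ImageSeries, np.ndarray],
    stop_tol: float = 0.1,
) -> bool:
    """Relative Frobenius change ||U_k - U_{k-1}||_F / ||U_k||_F < stop_tol."""
    a = u_k.frames if isinstance(u_k, ImageSeries) else np.asarray(u_k)
    b = u_km1.frames if isinstance(u_km1, ImageSeries) else np.asarray(u_km1)
    if a.shape != b.shape:
        raise ValueError("iterates must share one shape")
    denom = np.linalg.norm(a.reshape(-1))
    if denom == 0:
        raise ValueError("current iterate has zero norm")
    return bool(np.linalg.norm((a - b).reshape(-1)) / denom < stop_tol)


@dataclass
class NFocSelection:
    """Leave-one-out cross-validated outer-iteration count."""

    value: int
    per_dataset: List[int]
    per_holdout: List[int]


def _mode_smallest(values: Sequence[int]) -> int:
    vals, counts = np.unique(np.asarray(values), return_counts=True)
    return int(vals[counts == counts.max()].min())


def _first_stopping_k(y: KSpaceSeries, config: ReconConfig) -> int:
    res = (
        reconstruct(y, replace(config, n_foc="auto"))
        if config.transform == "KLT"
        else ktfocuss(y, replace(config, n_foc="auto"))
    )
    return res.n_foc_used


def select_nfoc_cv(
    datasets: Sequence[KSpaceSeries],
    mask_pattern: Optional[str],
    config: ReconConfig,
    d: int = 4,
    base_seed: int = 0,
) -> NFocSelection:
    """Subject-based leave-one-out cross-validation of N_FOC.

    Each dataset's first outer iteration satisfying the stopping criterion
    is computed; for every held-out dataset the training consensus is the
    mode (ties broken toward the smaller value) over the remaining
    datasets.  Returns the overall consensus plus the per-fold values.

    ``mask_pattern`` (one of the generator pattern names) is applied to
    fully sampled inputs with per-dataset seeds; already-masked inputs are
    used as is.
    """
    if len(datasets) < 2:
        raise ValueError("cross-validation needs at least 2 datasets")
    from . import sampling as smp

    generators = {
        "R": smp.gen_uniform,
        "G": smp.gen_gaussian,
        "GR": smp.gen_mixture,
        "GRC1": smp.gen_mixture_center1,
        "GRC1_PAIRED": smp.gen_pairwise,
    }
    per_dataset = []
    for i, ds in enumerate(datasets):
        if ds.is_fully_sampled():
            if mask_pattern is None:
                raise ValueError("fully sampled dataset requires a mask_pattern")
            if mask_pattern == "CENTER_ONLY":
                mask = smp.gen_center_only(ds.shape[1], ds.n_frames, d)
            else:
                mask = generators[mask_pattern](
                    ds.shape[1], ds.n_frames, d, seed=base_seed + 7919 * i
                )
            ds = smp.apply_mask(ds, mask)
        per_dataset.append(_first_stopping_k(ds, config))
    per_holdout = [
        _mode_smallest([v for j, v in enumerate(per_dataset) if j != i])
        for i in range(len(datasets))
    ]
    return NFocSelection(
        value=_mode_smallest(per_holdout),
        per_dataset=per_dataset,
        per_holdout=per_holdout,
    )


def residual_error(y: KSpaceSeries, y_hat: KSpaceSeries) -> float:
    """Sum of squared moduli of (y - y_hat) over the sampled entries."""
    my, mh = y.mask, y_hat.mask
    ly = None if my is None else _lines(my)
    lh = None if mh is None else _lines(mh)
    if (ly is None) != (lh is None) or (ly is not None and not np.array_equal(ly, lh)):
        raise ValueError("residual_error requires both series to share one mask")
    diff = y.data - y_hat.data
    if ly is not None:
        diff = diff[:, ly]
    return float(np.sum(np.abs(diff) ** 2))
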