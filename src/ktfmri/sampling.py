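"""Cartesian k-t undersampling mask generators.

Masks are binary (N_PE x T) matrices: one column per time frame, one row
per phase-encode (PE) line.  Every generator samples exactly N_PE/D lines
per frame, where D is the downsampling (acceleration) factor.  Patterns:

=============  ===========================================================
R              uniform random lines, drawn independently per frame
G              Gaussian variable-density lines, P(k_y) ~ exp(-k_y^2/2s^2),
               s = N_PE/9 by default
GR             mixture: 2/3 of the lines Gaussian-weighted, 1/3 uniform
               from the remainder (N_PE/6 + N_PE/12 at D = 4)
GRC1           mixture plus the k_y = 0 center line in every frame
CENTER_ONLY    deterministic contiguous central N_PE/D block (control)
GRC1_PAIRED    GRC1-style center weighting applied at the level of
               adjacent-index line pairs (eddy-current suppression)
=============  ===========================================================

Weighted without-replacement draws use randomized systematic
probability-proportional-to-size (PPS) sampling: the lines are randomly
permuted, target weights k*P(k_y) are laid out cumulatively and hit with a
unit-spaced random comb.  Per-line inclusion probabilities are then exactly
min(k*P, 1), so empirical line frequencies converge to the target density;
uniform draws use plain without-replacement choice.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .containers import KSpaceSeries
from .fourier import dc_row, ky_index

__all__ = [
    "SamplingMask",
    "gen_uniform",
    "gen_gaussian",
    "gen_mixture",
    "gen_mixture_center1",
    "gen_center_only",
    "gen_pairwise",
    "full_mask",
    "apply_mask",
    "gaussian_density",
    "save_mask",
    "load_mask",
]

PATTERNS = ("R", "G", "GR", "GRC1", "CENTER_ONLY", "GRC1_PAIRED", "FULL", "CUSTOM")


@dataclass
class SamplingMask:
    """Binary phase-encode x time sampling matrix.

    lines : bool array (N_PE, T); True = line acquired in that frame
    pattern : one of R, G, GR, GRC1, CENTER_ONLY, GRC1_PAIRED, FULL
    d : downsampling factor (lines per frame = N_PE/D)
    sigma : Gaussian density width in PE-line units (None for R/CENTER_ONLY)
    seed : generator seed (None for deterministic patterns)
    """

    pattern: str
    lines: np.ndarray
    d: int
    sigma: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        self.lines = np.asarray(self.lines, dtype=bool)
        if self.lines.ndim != 2:
            raise ValueError("lines must be 2D (N_PE, T)")
        if self.pattern == "CUSTOM":
            return  # user-supplied mask; per-frame counts unconstrained
        counts = self.lines.sum(axis=0)
        expected = self.n_pe // self.d
        if not np.all(counts == expected):
            raise ValueError(
                f"per-frame line count must be N_PE/D = {expected} in every "
                f"frame; got counts {np.unique(counts)}"
            )

    @property
    def n_pe(self) -> int:
        return self.lines.shape[0]

    @property
    def n_frames(self) -> int:
        return self.lines.shape[1]

    @property
    def lines_per_frame(self) -> int:
        return self.n_pe // self.d


def _check_divisible(n_pe: int, d: int) -> int:
    if d < 1 or n_pe % d:
        raise ValueError(f"downsampling factor D = {d} must divide N_PE = {n_pe}")
    return n_pe // d


def gaussian_density(n_pe: int, sigma: Optional[float] = None) -> np.ndarray:
    """Discrete Gaussian PE-line density, renormalized to sum to 1.

    P(k_y) = A exp(-k_y^2 / 2 sigma^2) on the signed index grid
    -(N_PE/2 - 1)..N_PE/2, with sigma = N_PE/9 by default.
    """
    if sigma is None:
        sigma = n_pe / 9.0
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    ky = ky_index(n_pe).astype(float)
    p = np.exp(-(ky**2) / (2.0 * sigma**2))
    return p / p.sum()


def _pps_systematic(rng: np.random.Generator, p: np.ndarray, k: int) -> np.ndarray:
    """Draw k distinct indices with inclusion probability exactly min(k*p, 1).

    Randomized systematic PPS: indices with k*p >= 1 are always included and
    the residual weight is redistributed over the rest; the remainder is hit
    with a unit-spaced comb over the randomly permuted cumulative weights.
    """
    p = np.asarray(p, dtype=float)
    if k > np.count_nonzero(p):
        raise ValueError("fewer lines with nonzero probability than draws")
    certain = []
    active = p > 0
    w = np.zeros_like(p)
    # peel off inclusion probabilities saturated at 1
    while True:
        k_eff = k - len(certain)
        if k_eff == 0:
            break
        w[:] = 0.0
        w[active] = k_eff * p[active] / p[active].sum()
        sat = np.flatnonzero(w >= 1.0)
        if sat.size == 0:
            break
        certain.extend(sat.tolist())
        active[sat] = False
    k_eff = k - len(certain)
    if k_eff == 0:
        return np.array(sorted(certain), dtype=int)
    idx_active = np.flatnonzero(active)
    perm = rng.permutation(idx_active.size)
    wa = w[idx_active][perm]  # sums to k_eff
    c = np.cumsum(wa)
    c[-1] = k_eff  # guard rounding
    pts = rng.uniform(0.0, 1.0) + np.arange(k_eff)
    chosen = idx_active[perm[np.searchsorted(c, pts)]]
    out = np.concatenate([np.asarray(certain, dtype=int), chosen])
    if np.unique(out).size != k:  # defensive; cannot happen when k*p <= 1
        raise RuntimeError("systematic PPS produced duplicate lines")
    return out


def _empty(n_pe: int, t: int) -> np.ndarray:
    return np.zeros((n_pe, t), dtype=bool)


def gen_uniform(n_pe: int, t: int, d: int, seed: int) -> SamplingMask:
    """Pattern R: per frame, N_PE/D distinct lines uniformly at random."""
    k = _check_divisible(n_pe, d)
    rng = np.random.default_rng(seed)
    lines = _empty(n_pe, t)
    for f in range(t):
        lines[rng.choice(n_pe, size=k, replace=False), f] = True
    return SamplingMask("R", lines, d, seed=seed)


def gen_gaussian(
    n_pe: int, t: int, d: int, seed: int, sigma: Optional[float] = None
) -> SamplingMask:
    """Pattern G: per frame, N_PE/D distinct lines from the Gaussian density."""
    k = _check_divisible(n_pe, d)
    p = gaussian_density(n_pe, sigma)
    rng = np.random.default_rng(seed)
    lines = _empty(n_pe, t)
    for f in range(t):
        lines[_pps_systematic(rng, p, k), f] = True
    return SamplingMask("G", lines, d, sigma=sigma if sigma else n_pe / 9.0, seed=seed)


def _mixture_counts(k_total: int) -> tuple:
    # Gaussian : uniform = 2 : 1, Gaussian rounded up for odd remainders
    n_g = math.ceil(2 * k_total / 3)
    return n_g, k_total - n_g


def _draw_mixture_frame(
    rng: np.random.Generator, p_gauss: np.ndarray, n_g: int, n_u: int
) -> np.ndarray:
    gauss_idx = _pps_systematic(rng, p_gauss, n_g) if n_g else np.array([], int)
    # uniform stage draws from the not-yet-sampled admissible lines
    remaining = np.setdiff1d(np.flatnonzero(p_gauss > 0), gauss_idx)
    uni_idx = (
        rng.choice(remaining, size=n_u, replace=False) if n_u else np.array([], int)
    )
    return np.concatenate([gauss_idx, uni_idx])


def _check_mixture_pre(n_pe: int, d: int) -> int:
    if n_pe % 12:
        raise ValueError(f"mixture patterns require 12 | N_PE; got N_PE = {n_pe}")
    return _check_divisible(n_pe, d)


def gen_mixture(
    n_pe: int, t: int, d: int, seed: int, sigma: Optional[float] = None
) -> SamplingMask:
    """Pattern GR: 2/3 Gaussian-weighted lines then 1/3 uniform lines from
    the remainder (N_PE/6 + N_PE/12 at D = 4)."""
    k = _check_mixture_pre(n_pe, d)
    n_g, n_u = _mixture_counts(k)
    p = gaussian_density(n_pe, sigma)
    rng = np.random.default_rng(seed)
    lines = _empty(n_pe, t)
    for f in range(t):
        lines[_draw_mixture_frame(rng, p, n_g, n_u), f] = True
    return SamplingMask("GR", lines, d, sigma=sigma if sigma else n_pe / 9.0, seed=seed)


def gen_mixture_center1(
    n_pe: int, t: int, d: int, seed: int, sigma: Optional[float] = None
) -> SamplingMask:
    """Pattern GRC1: the k_y = 0 line in every frame plus a mixture draw of
    the remaining N_PE/D - 1 lines (Gaussian share rounded up)."""
    k = _check_mixture_pre(n_pe, d)
    dc = dc_row(n_pe)
    n_g, n_u = _mixture_counts(k - 1)
    p = gaussian_density(n_pe, sigma)
    p = p.copy()
    p[dc] = 0.0
    p /= p.sum()
    rng = np.random.default_rng(seed)
    lines = _empty(n_pe, t)
    for f in range(t):
        idx = _draw_mixture_frame(rng, p, n_g, n_u)
        lines[idx, f] = True
        lines[dc, f] = True
    return SamplingMask(
        "GRC1", lines, d, sigma=sigma if sigma else n_pe / 9.0, seed=seed
    )


def gen_center_only(n_pe: int, t: int, d: int) -> SamplingMask:
    """Control pattern: the contiguous central N_PE/D block (centered on
    k_y = 0) in every frame; deterministic."""
    k = _check_divisible(n_pe, d)
    dc = dc_row(n_pe)
    lo = dc - (k // 2 - 1) if k % 2 == 0 else dc - k // 2
    rows = np.arange(lo, lo + k)
    lines = _empty(n_pe, t)
    lines[rows, :] = True
    return SamplingMask("CENTER_ONLY", lines, d)


def gen_pairwise(
    n_pe: int, t: int, d: int, seed: int, sigma: Optional[float] = None
) -> SamplingMask:
    """Paired GRC1 variant: lines are taken in adjacent (2m, 2m+1) couples
    so consecutively played PE lines sit next to each other in k-space
    (suppressing eddy-current artifacts in bSSFP).  The pair containing
    k_y = 0 is sampled every frame; the other pairs are drawn with
    GRC1-style center weighting summed within each pair."""
    k = _check_mixture_pre(n_pe, d)
    if k % 2:
        raise ValueError(f"pairwise pattern needs an even line budget; got {k}")
    dc_pair = dc_row(n_pe) // 2
    # mixture-equivalent line density: 2/3 Gaussian + 1/3 uniform
    p_line = (2.0 / 3.0) * gaussian_density(n_pe, sigma) + (1.0 / 3.0) / n_pe
    p_pair = p_line.reshape(-1, 2).sum(axis=1)
    p_pair[dc_pair] = 0.0
    p_pair /= p_pair.sum()
    rng = np.random.default_rng(seed)
    lines = _empty(n_pe, t)
    for f in range(t):
        pairs = _pps_systematic(rng, p_pair, k // 2 - 1)
        pairs = np.concatenate([[dc_pair], pairs])
        lines[2 * pairs, f] = True
        lines[2 * pairs + 1, f] = True
    return SamplingMask(
        "GRC1_PAIRED", lines, d, sigma=sigma if sigma else n_pe / 9.0, seed=seed
    )


def full_mask(n_pe: int, t: int) -> SamplingMask:
    """All-ones mask (D = 1)."""
    return SamplingMask("FULL", np.ones((n_pe, t), dtype=bool), 1)


def apply_mask(full: KSpaceSeries, mask: SamplingMask) -> KSpaceSeries:
    """Retrospectively downsample a fully sampled k-space series.

    Entries on sampled lines are copied exactly; everything else is zeroed.
    """
    if not full.is_fully_sampled():
        raise ValueError("apply_mask expects a fully sampled input series")
    n_ro, n_pe, t = full.data.shape
    if mask.lines.shape != (n_pe, t):
        raise ValueError(
            f"mask shape {mask.lines.shape} does not match k-space "
            f"(n_pe, T) = {(n_pe, t)}"
        )
    data = np.where(mask.lines[None, :, :], full.data, 0.0 + 0.0j)
    return KSpaceSeries(data, mask=mask, paradigm=full.paradigm)


def save_mask(mask: SamplingMask, path) -> None:
    """Write the binary line matrix as integer text plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, mask.lines.astype(int), fmt="%d")
    sidecar = {
        "pattern": mask.pattern,
        "d": mask.d,
        "sigma": mask.sigma,
        "seed": mask.seed,
        "n_pe": mask.n_pe,
        "n_frames": mask.n_frames,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_mask(path) -> SamplingMask:
    path = Path(path)
    lines = np.loadtxt(path, dtype=int).astype(bool)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return SamplingMask(
        meta["pattern"], lines, meta["d"], sigma=meta["sigma"], seed=meta["seed"]
    )
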