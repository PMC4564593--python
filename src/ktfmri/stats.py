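"""Activation statistics and reconstruction-fidelity metrics.

Detection follows the classical block-contrast route: a per-pixel Welch
(unequal-variance) two-sample t statistic between baseline and stimulation
frames of the magnitude time course, a two-sided threshold at a chosen
significance level, and rejection of supra-threshold clusters smaller than
a minimum pixel count (6 by default, 4-connectivity).  Reconstruction
fidelity is measured against the full-sampled series by frame-by-frame
normalized MSE and by the average MSE over the whole run; detection
fidelity by an ROC sweep of the |T| threshold against the full-sampled
activation map, summarized as the area under the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .containers import ImageSeries, Paradigm

__all__ = [
    "ActivationMap",
    "ROCResult",
    "ROI",
    "tscore_map",
    "threshold_and_cluster",
    "select_roi",
    "roi_timecourse",
    "frame_nmse",
    "average_mse",
    "roc_curve",
    "T_SENTINEL",
]

#: signed sentinel returned for pixels whose pooled variance term is zero
#: but whose block means differ (|T| formally infinite)
T_SENTINEL = 1e6

#: 4-connectivity structuring element for cluster labeling
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class ActivationMap:
    """Per-pixel T scores with optional thresholded activation mask.

    t_scores : Welch statistic map
    df : Welch-Satterthwaite degrees of freedom per pixel
    zero_variance : pixels where both blocks had zero variance
    alpha, min_cluster, active_mask : filled by threshold_and_cluster
    """

    t_scores: np.ndarray
    df: np.ndarray
    zero_variance: np.ndarray
    alpha: Optional[float] = None
    min_cluster: Optional[int] = None
    active_mask: Optional[np.ndarray] = None
    source: str = ""


@dataclass
class ROI:
    """Region of interest: the pixels declared active on a reference map."""

    mask: np.ndarray
    source: str = ""

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ROCResult:
    """ROC sweep of the |T| threshold against a binary ground-truth map."""

    fpf: np.ndarray
    tpf: np.ndarray
    auc: float
    ground_truth: np.ndarray
    n_thresholds: int
    thresholds: np.ndarray = field(default_factory=lambda: np.array([]))


def tscore_map(
    series: ImageSeries,
    paradigm: Optional[Paradigm] = None,
    delay: int = 0,
) -> ActivationMap:
    """Per-pixel Welch t statistic between baseline and stimulation blocks.

    T = (xbar - ybar) / sqrt(s_x^2/n_x + s_y^2/n_y) with x the prestimulus
    baseline frames and y the stimulation frames (magnitude data), shifted
    by ``delay`` frames for the hemodynamic lag.  Pixels with zero variance
    in both blocks get T = 0 when the means agree and a signed sentinel of
    magnitude ``T_SENTINEL`` otherwise; their ``zero_variance`` flag is set.
    """
    paradigm = paradigm or series.paradigm
    if paradigm is None:
        raise ValueError("a paradigm is required to split baseline/stimulation")
    base_idx = paradigm.baseline_frames()
    stim_idx = paradigm.stim_frames(delay=delay)
    if base_idx.size < 2 or stim_idx.size < 2:
        raise ValueError("both baseline and stimulation blocks need >= 2 frames")
    mag = series.magnitude()
    x = mag[:, :, base_idx]
    y = mag[:, :, stim_idx]
    n_x, n_y = x.shape[2], y.shape[2]
    mx, my = x.mean(axis=2), y.mean(axis=2)
    vx, vy = x.var(axis=2, ddof=1), y.var(axis=2, ddof=1)
    pooled = vx / n_x + vy / n_y
    zero_var = pooled == 0
    # note sign convention: activation increase gives negative (xbar - ybar);
    # detection uses |T|, so only the magnitude matters downstream
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(pooled)
        df = pooled**2 / (
            (vx / n_x) ** 2 / (n_x - 1) + (vy / n_y) ** 2 / (n_y - 1)
        )
    diff = mx - my
    t = np.where(zero_var, np.where(diff == 0, 0.0, np.sign(diff) * T_SENTINEL), t)
    df = np.where(np.isfinite(df), df, n_x + n_y - 2)
    return ActivationMap(
        t_scores=t, df=df, zero_variance=zero_var, source=series.provenance
    )


def threshold_and_cluster(
    amap: ActivationMap, alpha: float = 0.05, min_cluster: int = 6
) -> ActivationMap:
    """Two-sided t threshold at ``alpha`` plus small-cluster rejection.

    Supra-threshold pixels (|T| above the two-sided t quantile at the
    pixel's degrees of freedom) are grouped by 4-connectivity; connected
    components smaller than ``min_cluster`` pixels are discarded.
    Idempotent: re-applying to the result changes nothing.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    thresh = sps.t.ppf(1.0 - alpha / 2.0, amap.df)
    supra = np.abs(amap.t_scores) > thresh
    labels, n_lab = ndimage.label(supra, structure=_STRUCTURE_4)
    if n_lab:
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_cluster
        keep[0] = False
        supra = keep[labels]
    return ActivationMap(
        t_scores=amap.t_scores,
        df=amap.df,
        zero_variance=amap.zero_variance,
        alpha=alpha,
        min_cluster=min_cluster,
        active_mask=supra,
        source=amap.source,
    )


def select_roi(full_map: ActivationMap) -> ROI:
    """ROI = active pixels of the full-sampled activation map.

    Defined per dataset: each full-sampled run yields its own ROI.
    """
    if full_map.active_mask is None:
        raise ValueError("run threshold_and_cluster before selecting an ROI")
    if not full_map.active_mask.any():
        raise ValueError(
            "the full-sampled activation map has no active pixels; relax "
            "alpha/min_cluster or check the paradigm and noise level"
        )
    return ROI(mask=full_map.active_mask.copy(), source=full_map.source)


def roi_timecourse(series: ImageSeries, roi: ROI) -> np.ndarray:
    """Per-frame mean magnitude over the ROI pixels."""
    if not roi.mask.any():
        raise ValueError("ROI is empty")
    return series.magnitude()[roi.mask, :].mean(axis=0)


def frame_nmse(truth: ImageSeries, recon: ImageSeries, t: int) -> float:
    """Normalized MSE of frame t: ||u_t - u_hat_t||^2 / ||u_t||^2."""
    if truth.shape != recon.shape:
        raise ValueError("series shapes must match")
    u = truth.frames[:, :, t]
    uh = recon.frames[:, :, t]
    denom = np.sum(np.abs(u) ** 2)
    if denom == 0:
        raise ValueError(f"frame {t} of the reference series has zero norm")
    return float(np.sum(np.abs(u - uh) ** 2) / denom)


def average_mse(truth: ImageSeries, recon: ImageSeries) -> float:
    """Average MSE over the whole run: sum_t ||u_t - u_hat_t||^2 / (T N)."""
    if truth.shape != recon.shape:
        raise ValueError("series shapes must match")
    diff = truth.frames - recon.frames
    return float(np.sum(np.abs(diff) ** 2) / diff.size)


def roc_curve(
    t_map: ActivationMap, ground_truth: np.ndarray, n_thresholds: int = 200
) -> ROCResult:
    """ROC of |T| thresholding against a binary ground-truth map.

    The threshold sweeps the pooled |T| quantiles (equivalent to sweeping
    the significance level); at each threshold TPF is the detected fraction
    of truly active pixels and FPF the falsely detected fraction of truly
    inactive pixels.  Anchors (0,0) and (1,1) are appended and the AUC is
    the trapezoidal integral over (FPF, TPF).  The AUC is invariant under
    any strictly monotone transform of the score map.
    """
    gt = np.asarray(ground_truth, dtype=bool)
    if gt.shape != t_map.t_scores.shape:
        raise ValueError("ground-truth shape must match the score map")
    n_pos = int(gt.sum())
    n_neg = int((~gt).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ground truth must contain active and inactive pixels")
    scores = np.abs(t_map.t_scores)
    qs = np.linspace(0.0, 1.0, n_thresholds)
    thresholds = np.unique(np.quantile(scores, qs))[::-1]  # strict to loose
    tpf = np.empty(thresholds.size)
    fpf = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        pred = scores > thr
        tpf[i] = np.count_nonzero(pred & gt) / n_pos
        fpf[i] = np.count_nonzero(pred & ~gt) / n_neg
    fpf = np.concatenate([[0.0], fpf, [1.0]])
    tpf = np.concatenate([[0.0], tpf, [1.0]])
    auc = float(np.trapezoid(tpf, fpf))
    return ROCResult(
        fpf=fpf,
        tpf=tpf,
        auc=auc,
        ground_truth=gt,
        n_thresholds=n_thresholds,
        thresholds=thresholds,
    )
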