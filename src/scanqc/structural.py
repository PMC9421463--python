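"""Structural (T1w) image-quality features.

Twelve no-reference features per scan, spanning the five QC domains:

====== ============== =============================================
name   domain         definition
====== ============== =============================================
SNR    noise          mu_WM / sigma_WM
CNR    noise          |mu_GM - mu_WM| / sqrt(s_GM^2 + s_WM^2 + s_bg^2)
CJV    inhomogeneity  (s_WM + s_GM) / |mu_WM - mu_GM|
FBER   inhomogeneity  median(foreground^2) / median(background^2)
AI_perc asymmetry     100 * mean_brain |I - I_flip| / (midpoint + eps)
IQR    inhomogeneity  composite noise/bias rating (surrogate, see below)
CSF_k  descriptives   excess kurtosis of CSF intensities
WM2MAX inhomogeneity  mu_WM / P99.95(whole image)
GMfrac descriptives   GM fraction of brain volume
WMfrac descriptives   WM fraction of brain volume
CSFfrac descriptives  CSF fraction of brain volume
EFC    descriptives   entropy-focus criterion (Shannon entropy of the
                      normalized intensity distribution, scaled so a
                      uniform image scores 1)
====== ============== =============================================

Tissue means and SDs are probability-weighted by default (partial-volume
maps are the natural segmentation output); hard masks at
``prob_threshold`` are available via ``hard_masks=True``.

IQR is a surrogate for CAT12's proprietary Image Quality Rating: the
weighted RMS of two logistic-mapped sub-scores, a noise-to-contrast
ratio sigma_WM/|mu_WM - mu_GM| and a bias-amplitude estimate (the
coefficient of variation of a heavily smoothed WM intensity field).
Higher IQR = worse quality. It preserves the original feature's
noise/inhomogeneity sensitivity while being fully specified here.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage, stats

from .images import InputError, TissueMaps, VolumeImage
from .records import QCRecord

logger = logging.getLogger(__name__)

T1W_DOMAINS = {
    "SNR": "noise",
    "CNR": "noise",
    "CJV": "inhomogeneity",
    "FBER": "inhomogeneity",
    "AI_perc": "asymmetry",
    "IQR": "inhomogeneity",
    "CSF_k": "descriptives",
    "WM2MAX": "inhomogeneity",
    "GMfrac": "descriptives",
    "WMfrac": "descriptives",
    "CSFfrac": "descriptives",
    "EFC": "descriptives",
}

#: |mu_WM - mu_GM| below this fraction of mu_WM counts as degenerate contrast.
CONTRAST_TOL = 1e-9

# Logistic mapping constants for the two IQR sub-scores (midpoint, width).
_IQR_NOISE_MID, _IQR_NOISE_WIDTH = 0.3, 0.1
_IQR_BIAS_MID, _IQR_BIAS_WIDTH = 0.10, 0.05
_IQR_SMOOTH_SIGMA = 6.0  # voxels


def weighted_mean_sd(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Probability-weighted mean and SD.

    The SD uses the reliability-weights correction
    ``sum(w (x-m)^2) / (V1 - V2/V1)`` with V1 = sum(w), V2 = sum(w^2),
    which reduces to the ordinary ddof=1 sample SD for 0/1 weights.
    """
    values = np.asarray(values, dtype=float).ravel()
    weights = np.asarray(weights, dtype=float).ravel()
    v1 = weights.sum()
    if v1 <= 0:
        raise InputError("empty (zero-weight) tissue mask")
    mean = float(np.dot(weights, values) / v1)
    v2 = float(np.dot(weights, weights))
    denom = v1 - v2 / v1
    if denom <= 0:
        return mean, 0.0
    var = float(np.dot(weights, (values - mean) ** 2) / denom)
    return mean, float(np.sqrt(var))


def entropy_focus_criterion(data: np.ndarray) -> float:
    """Shannon entropy of voxel intensities normalized by the image's
    total energy, scaled to [0, 1] so a maximally uniform (blurred /
    motion-degraded) image scores 1 and a concentrated one scores low."""
    x = np.abs(np.asarray(data, dtype=float)).ravel()
    e_total = np.sqrt(np.dot(x, x))
    if e_total == 0:
        return 0.0
    r = x / e_total
    nz = r > 0
    entropy = -float(np.dot(r[nz], np.log(r[nz])))
    n = x.size
    max_entropy = np.sqrt(n) * np.log(np.sqrt(n))  # uniform image
    return entropy / max_entropy


def asymmetry_index(img: VolumeImage, brain_mask: np.ndarray) -> float:
    """Mean relative left-right intensity difference (percent) after
    mirroring across the L/R axis; eps = 1e-6 * P99 of brain intensities
    guards the midpoint denominator."""
    flipped = np.flip(img.data, axis=img.lr_axis)
    brain_vals = img.data[brain_mask]
    if brain_vals.size == 0:
        raise InputError("empty brain mask")
    eps = 1e-6 * np.percentile(brain_vals, 99)
    num = np.abs(img.data - flipped)[brain_mask]
    den = 0.5 * (img.data + flipped)[brain_mask] + eps
    return float(100.0 * np.mean(num / den))


def _logistic(x: float, mid: float, width: float) -> float:
    return float(1.0 / (1.0 + np.exp(-(x - mid) / width)))


def image_quality_rating(img: VolumeImage, tissues: TissueMaps,
                         mu_gm: float, mu_wm: float, sigma_wm: float) -> float:
    """Composite noise/inhomogeneity rating in (0, 1); higher = worse."""
    noise_score = sigma_wm / max(abs(mu_wm - mu_gm), CONTRAST_TOL * max(abs(mu_wm), 1.0))
    # Bias amplitude: CV of a heavily smoothed WM intensity field. Smoothing
    # the product and the weights separately gives a low-frequency estimate
    # of the WM intensity surface that ignores mask geometry.
    wm_prob = tissues.wm
    smooth_num = ndimage.gaussian_filter(img.data * wm_prob, _IQR_SMOOTH_SIGMA)
    smooth_den = ndimage.gaussian_filter(wm_prob, _IQR_SMOOTH_SIGMA)
    wm_hard = tissues.binary("wm")
    if not wm_hard.any():
        raise InputError("empty wm mask")
    field = smooth_num[wm_hard] / np.maximum(smooth_den[wm_hard], 1e-12)
    bias_score = float(np.std(field) / max(abs(np.mean(field)), 1e-12))
    l_noise = _logistic(noise_score, _IQR_NOISE_MID, _IQR_NOISE_WIDTH)
    l_bias = _logistic(bias_score, _IQR_BIAS_MID, _IQR_BIAS_WIDTH)
    return float(np.sqrt(0.5 * l_noise**2 + 0.5 * l_bias**2))


def compute_structural_features(img: VolumeImage, tissues: TissueMaps,
                                scan_id: str = "", hard_masks: bool = False) -> QCRecord:
    """Compute the 12 T1w QC features for one scan.

    Parameters
    ----------
    img, tissues
        The intensity volume and its aligned GM/WM/CSF probability maps.
    hard_masks
        Use binary masks at ``tissues.prob_threshold`` instead of
        probability weights for tissue means/SDs.

    Returns
    -------
    QCRecord with exactly the 12 features listed in the module docstring.
    CJV is NaN (with a logged warning) when the GM/WM contrast is
    degenerate; everything else is finite or the offending mask raises.
    """
    if img.data.shape != tissues.gm.shape:
        raise InputError("image and tissue maps are on different grids")

    weights = {}
    for tissue in ("gm", "wm", "csf"):
        prob = getattr(tissues, tissue)
        w = (prob > tissues.prob_threshold).astype(float) if hard_masks else prob
        if w.sum() <= 0:
            raise InputError(f"empty {tissue} mask")
        weights[tissue] = w

    mu_gm, sd_gm = weighted_mean_sd(img.data, weights["gm"])
    mu_wm, sd_wm = weighted_mean_sd(img.data, weights["wm"])

    bg = tissues.background_mask
    if not bg.any():
        raise InputError("empty background mask")
    bg_vals = img.data[bg]
    sd_bg = float(np.std(bg_vals, ddof=1)) if bg_vals.size > 1 else 0.0

    contrast = abs(mu_wm - mu_gm)
    degenerate = contrast <= CONTRAST_TOL * max(abs(mu_wm), 1.0)
    if degenerate:
        logger.warning("scan %s: degenerate GM/WM contrast; CJV reported as missing", scan_id)

    snr = mu_wm / sd_wm if sd_wm > 0 else np.nan
    cnr = contrast / np.sqrt(sd_gm**2 + sd_wm**2 + sd_bg**2)
    cjv = np.nan if degenerate else (sd_wm + sd_gm) / contrast

    fg_vals = img.data[tissues.brain_mask]
    if fg_vals.size == 0:
        raise InputError("empty brain mask")
    bg_energy = float(np.median(bg_vals**2))
    fber = float(np.median(fg_vals**2) / bg_energy) if bg_energy > 0 else np.nan

    ai = asymmetry_index(img, tissues.brain_mask)
    iqr = image_quality_rating(img, tissues, mu_gm, mu_wm, sd_wm)

    csf_vals = img.data[tissues.binary("csf")]
    if csf_vals.size == 0:
        raise InputError("empty csf mask")
    if csf_vals.size > 3 and csf_vals.std() > 0:
        csf_k = float(stats.kurtosis(csf_vals, fisher=True, bias=False))
    else:
        csf_k = np.nan   # kurtosis undefined for constant intensities

    wm2max = mu_wm / float(np.percentile(img.data, 99.95))

    totals = {t: float(weights[t].sum()) for t in ("gm", "wm", "csf")}
    brain_total = sum(totals.values())

    features = {
        "SNR": snr,
        "CNR": cnr,
        "CJV": cjv,
        "FBER": fber,
        "AI_perc": ai,
        "IQR": iqr,
        "CSF_k": csf_k,
        "WM2MAX": wm2max,
        "GMfrac": totals["gm"] / brain_total,
        "WMfrac": totals["wm"] / brain_total,
        "CSFfrac": totals["csf"] / brain_total,
        "EFC": entropy_focus_criterion(img.data),
    }
    return QCRecord(scan_id=scan_id, modality="T1w", features=features,
                    domains=dict(T1W_DOMAINS))
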