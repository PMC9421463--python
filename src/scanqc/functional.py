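"""Motion and temporal-stability QC for 4D series.

Framewise displacement (FD) follows the Power formula: the sum of the
absolute backward differences of the three translations plus the three
rotations converted to arc length on a sphere of assumed head radius
(default 50 mm). The cohort-level exclusion rule flags any scan whose
mean FD exceeds the group mean by more than two sample SDs.

The per-scan panel holds 17 features: temporal ones from the series and
trace (tSNR, DVARS, FD summaries, drift, global-signal variability) and
spatial ones computed on the temporal-mean volume (SNR against the air
background, FBER, EFC, left-right asymmetry, smoothed-field CV as a bias
proxy). DVARS and the temporal-SD summary are normalized by the median
in-mask intensity so they are invariant to global intensity scaling.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

from .images import InputError, MotionTrace, SeriesImage
from .records import QCRecord
from .structural import entropy_focus_criterion

logger = logging.getLogger(__name__)

BOLD_DOMAINS = {
    "fd_mean": "motion",
    "fd_max": "motion",
    "fd_frac_gt_0p5": "motion",
    "dvars": "motion",
    "tsnr": "noise",
    "tsnr_p5": "noise",
    "tsnr_p95": "noise",
    "mean_snr": "noise",
    "global_sd_pct": "noise",
    "mean_fber": "inhomogeneity",
    "mean_bias_cv": "inhomogeneity",
    "mean_ai_perc": "asymmetry",
    "mean_efc": "descriptives",
    "tsd_p95": "descriptives",
    "global_drift_pct": "descriptives",
    "mean_fg_mean": "descriptives",
    "n_volumes": "descriptives",
}


@dataclasses.dataclass
class FDSeries:
    """Per-volume framewise displacement (mm) and its mean."""
    fd: np.ndarray
    mean: float
    head_radius: float


@dataclasses.dataclass
class FDExclusionResult:
    flags: np.ndarray        # True = excluded
    threshold: float
    group_mean: float
    group_sd: float


def framewise_displacement(trace: MotionTrace, head_radius: float = 50.0) -> FDSeries:
    """Power-style FD: FD_t = sum |d translations| + r * sum |d rotations|,
    with FD_1 = 0. Only parameter differences enter, so a constant offset
    on any parameter leaves FD unchanged."""
    if trace.n_volumes < 2:
        raise InputError("framewise displacement needs at least 2 volumes")
    d = np.diff(trace.params, axis=0)
    fd_tail = np.abs(d[:, :3]).sum(axis=1) + head_radius * np.abs(d[:, 3:]).sum(axis=1)
    fd = np.concatenate([[0.0], fd_tail])
    return FDSeries(fd=fd, mean=float(fd.mean()), head_radius=head_radius)


def fd_exclusion(mean_fds: np.ndarray) -> FDExclusionResult:
    """Flag scans whose mean FD exceeds group mean + 2 sample SD."""
    mean_fds = np.asarray(mean_fds, dtype=float).ravel()
    if mean_fds.size < 3:
        raise InputError(
            "fd_exclusion needs at least 3 scans to estimate the group SD; review manually")
    m = float(mean_fds.mean())
    sd = float(mean_fds.std(ddof=1))
    threshold = m + 2.0 * sd
    return FDExclusionResult(flags=mean_fds > threshold, threshold=threshold,
                             group_mean=m, group_sd=sd)


def temporal_features(series: SeriesImage, mask: np.ndarray, trace: MotionTrace,
                      scan_id: str = "", fd_threshold: float = 0.5,
                      head_radius: float = 50.0, lr_axis: int = 0) -> QCRecord:
    """Compute the 17 fMRI QC features for one scan.

    Voxels with zero temporal SD are excluded from the tSNR map; if every
    in-mask voxel is temporally constant, tSNR (and its percentiles) are
    reported missing rather than infinite.
    """
    if series.n_volumes < 2:
        raise InputError("temporal features need at least 2 volumes")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InputError("empty mask")
    if trace.n_volumes != series.n_volumes:
        raise InputError("motion trace length does not match the series")

    data = series.data[mask]                      # (n_vox, t)
    vox_mean = data.mean(axis=1)
    vox_sd = data.std(axis=1, ddof=1)
    median_int = float(np.median(np.abs(vox_mean)))
    if median_int == 0:
        raise InputError("in-mask median intensity is zero")

    usable = vox_sd > 0
    if usable.any():
        tsnr_map = vox_mean[usable] / vox_sd[usable]
        tsnr = float(tsnr_map.mean())
        tsnr_p5 = float(np.percentile(tsnr_map, 5))
        tsnr_p95 = float(np.percentile(tsnr_map, 95))
    else:
        logger.warning("scan %s: zero temporal variance everywhere; tSNR missing", scan_id)
        tsnr = tsnr_p5 = tsnr_p95 = np.nan

    diffs = np.diff(data, axis=1)
    dvars = float(np.sqrt((diffs**2).mean(axis=0)).mean() / median_int)
    tsd_p95 = float(np.percentile(vox_sd, 95) / median_int)

    global_signal = data.mean(axis=0)
    gmean = float(global_signal.mean())
    global_sd_pct = float(100.0 * global_signal.std(ddof=1) / abs(gmean))
    t = np.arange(series.n_volumes)
    slope = float(np.polyfit(t, global_signal, 1)[0])
    global_drift_pct = float(100.0 * slope * series.n_volumes / abs(gmean))

    fd = framewise_displacement(trace, head_radius=head_radius)

    # Spatial features of the temporal-mean volume.
    mean_vol = series.mean_volume()
    background = ndimage.binary_erosion(~mask, iterations=2, border_value=0)
    if not background.any():
        raise InputError("no background voxels after erosion")
    bg_vals = mean_vol[background]
    fg_vals = mean_vol[mask]
    bg_sd = float(bg_vals.std(ddof=1))
    mean_snr = float(fg_vals.mean() / bg_sd) if bg_sd > 0 else np.nan
    bg_energy = float(np.median(bg_vals**2))
    mean_fber = float(np.median(fg_vals**2) / bg_energy) if bg_energy > 0 else np.nan

    flipped = np.flip(mean_vol, axis=lr_axis)
    eps = 1e-6 * np.percentile(np.abs(fg_vals), 99)
    ai = float(100.0 * np.mean(
        np.abs(mean_vol - flipped)[mask] / (0.5 * (mean_vol + flipped)[mask] + eps)))

    smooth = ndimage.gaussian_filter(mean_vol * mask, 4.0)
    smooth_w = ndimage.gaussian_filter(mask.astype(float), 4.0)
    field = smooth[mask] / np.maximum(smooth_w[mask], 1e-12)
    mean_bias_cv = float(field.std() / max(abs(field.mean()), 1e-12))

    features = {
        "tsnr": tsnr,
        "tsnr_p5": tsnr_p5,
        "tsnr_p95": tsnr_p95,
        "dvars": dvars,
        "fd_mean": fd.mean,
        "fd_max": float(fd.fd.max()),
        "fd_frac_gt_0p5": float((fd.fd > fd_threshold).mean()),
        "tsd_p95": tsd_p95,
        "global_sd_pct": global_sd_pct,
        "global_drift_pct": global_drift_pct,
        "mean_snr": mean_snr,
        "mean_fber": mean_fber,
        "mean_efc": entropy_focus_criterion(mean_vol),
        "mean_ai_perc": ai,
        "mean_bias_cv": mean_bias_cv,
        "mean_fg_mean": float(fg_vals.mean()),
        "n_volumes": float(series.n_volumes),
    }
    return QCRecord(scan_id=scan_id, modality="bold", features=features,
                    domains=dict(BOLD_DOMAINS))
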