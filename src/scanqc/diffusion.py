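"""Diffusion tensor fitting and dMRI QC features.

The tensor is fitted voxelwise by ordinary (log-linear) least squares:
with signals S_i acquired at b-values b_i along unit directions g_i,

    log S_i = log S_0 - b_i * g_i' D g_i

is linear in the six unique tensor elements plus log S_0, so a single
7-column design matrix solves every voxel at once. Nonpositive signals
inside the mask are clamped to the smallest positive signal of that
voxel's series before the log (the clamp count is reported). Negative
eigenvalues are kept — they drive the FA-outlier QC metric — and FA is
clipped to [0, 1] only in the released map, with the pre-clip values
retained.

Scalar maps: MD = (l1+l2+l3)/3, AD = l1, RD = (l2+l3)/2,
FA = sqrt(3/2) * sqrt(sum((l_k - lbar)^2) / sum(l_k^2)).

The QC panel holds 20 features: per-axis motion summaries and outlier
percentage from the realignment trace, fit-residual (SSE) summaries,
FA/MD/AD/RD statistics in white matter, FA-outlier and
negative-eigenvalue percentages, and the b=0 temporal SNR.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .functional import framewise_displacement
from .images import DiffusionScheme, InputError, MotionTrace, SeriesImage
from .records import QCRecord

logger = logging.getLogger(__name__)

DWI_DOMAINS = {
    "motion_tx": "motion",
    "motion_ty": "motion",
    "motion_tz": "motion",
    "motion_rx": "motion",
    "motion_ry": "motion",
    "motion_rz": "motion",
    "fd_mean": "motion",
    "fd_max": "motion",
    "motion_outlier_pct": "motion",
    "sse_mean": "noise",
    "sse_p95": "noise",
    "b0_tsnr": "noise",
    "fa_sd_wm": "noise",
    "fa_mean_wm": "descriptives",
    "fa_outlier_pct": "descriptives",
    "neg_eig_pct": "descriptives",
    "md_mean_wm": "descriptives",
    "md_sd_wm": "descriptives",
    "ad_mean_wm": "descriptives",
    "rd_mean_wm": "descriptives",
}

#: Condition number above which the gradient design is treated as rank
#: deficient (collinear directions).
MAX_CONDITION = 1e6


def design_matrix(scheme: DiffusionScheme) -> np.ndarray:
    """7-column log-linear design: [1, -b gx^2, -b gy^2, -b gz^2,
    -2b gx gy, -2b gx gz, -2b gy gz]; column 0 estimates log S0."""
    b = scheme.bvals
    g = scheme.bvecs
    return np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])


def tensor_from_elements(d6: np.ndarray) -> np.ndarray:
    """(..., 6) [Dxx,Dyy,Dzz,Dxy,Dxz,Dyz] -> (..., 3, 3) symmetric tensors."""
    d6 = np.asarray(d6, dtype=float)
    out = np.zeros(d6.shape[:-1] + (3, 3))
    out[..., 0, 0] = d6[..., 0]
    out[..., 1, 1] = d6[..., 1]
    out[..., 2, 2] = d6[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = d6[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = d6[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = d6[..., 5]
    return out


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * sqrt(sum((l - lbar)^2) / sum(l^2)); zero tensors
    get FA = 0. Not clipped: negative eigenvalues can push FA above 1,
    which is exactly what the fa_outlier metric looks for."""
    evals = np.asarray(evals, dtype=float)
    lbar = evals.mean(axis=-1, keepdims=True)
    num = ((evals - lbar) ** 2).sum(axis=-1)
    den = (evals**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(np.where(den > 0, num / np.maximum(den, 1e-300), 0.0))
    return np.where(den > 0, fa, 0.0)


@dataclasses.dataclass
class TensorFitResult:
    """Voxelwise tensor fit: maps are full-grid arrays, defined inside
    ``mask`` and zero outside."""

    tensor_elements: np.ndarray   # (x, y, z, 6)
    eigenvalues: np.ndarray       # (x, y, z, 3), descending
    fa: np.ndarray                # clipped to [0, 1]
    fa_raw: np.ndarray            # pre-clip FA
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    sse: np.ndarray               # per-voxel residual sum of squares (log domain)
    mask: np.ndarray
    s0: np.ndarray                # fitted S0
    b0_volumes: np.ndarray        # (x, y, z, n_b0) raw b=0 data
    n_clamped: int
    condition_number: float


def fit_tensor(dwi: SeriesImage, scheme: DiffusionScheme, mask: np.ndarray) -> TensorFitResult:
    """Fit the diffusion tensor model in every masked voxel.

    Requires at least one b=0 volume and six non-collinear nonzero-b
    directions (checked via the design-matrix condition number).
    """
    if scheme.n_volumes != dwi.n_volumes:
        raise InputError(
            f"scheme has {scheme.n_volumes} volumes, series has {dwi.n_volumes}")
    if scheme.n_volumes < 7:
        raise InputError("tensor fit needs at least 7 volumes (1 b=0 + 6 directions)")
    if scheme.b0_indices.size < 1:
        raise InputError("tensor fit needs at least one b=0 volume")
    if (scheme.bvals > 0).sum() < 6:
        raise InputError("tensor fit needs at least 6 nonzero-b directions")

    design = design_matrix(scheme)
    cond = float(np.linalg.cond(design))
    if cond > MAX_CONDITION:
        raise InputError(
            f"gradient directions are (nearly) collinear: design condition number {cond:.3g}")

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InputError("empty fit mask")

    signals = dwi.data[mask]                       # (n_vox, n_vol)
    nonpos = signals <= 0
    n_clamped = int(nonpos.sum())
    if n_clamped:
        logger.warning("clamping %d nonpositive signals before log-transform", n_clamped)
        clamped = signals.copy()
        clamped[nonpos] = np.inf
        floor = clamped.min(axis=1, keepdims=True)   # smallest positive per voxel
        if not np.all(np.isfinite(floor)):
            raise InputError("a masked voxel has no positive signal at all")
        signals = np.where(nonpos, np.broadcast_to(floor, signals.shape), signals)

    logs = np.log(signals)                         # (n_vox, n_vol)
    coef, *_ = np.linalg.lstsq(design, logs.T, rcond=None)  # (7, n_vox)
    resid = logs.T - design @ coef
    sse_flat = (resid**2).sum(axis=0)

    d6 = coef[1:].T                                # (n_vox, 6)
    tensors = tensor_from_elements(d6)
    evals = np.linalg.eigvalsh(tensors)[:, ::-1]   # descending
    fa_raw_flat = fa_from_eigenvalues(evals)

    shape = dwi.data.shape[:3]

    def to_map(flat: np.ndarray, extra: tuple[int, ...] = ()) -> np.ndarray:
        out = np.zeros(shape + extra)
        out[mask] = flat
        return out

    md_flat = evals.mean(axis=1)
    return TensorFitResult(
        tensor_elements=to_map(d6, (6,)),
        eigenvalues=to_map(evals, (3,)),
        fa=to_map(np.clip(fa_raw_flat, 0.0, 1.0)),
        fa_raw=to_map(fa_raw_flat),
        md=to_map(md_flat),
        ad=to_map(evals[:, 0]),
        rd=to_map(evals[:, 1:].mean(axis=1)),
        sse=to_map(sse_flat),
        mask=mask,
        s0=to_map(np.exp(coef[0])),
        b0_volumes=dwi.data[..., scheme.b0_indices],
        n_clamped=n_clamped,
        condition_number=cond,
    )


def _b0_tsnr(fit: TensorFitResult, wm: np.ndarray) -> float:
    """Temporal SNR across b=0 volumes when >= 2 exist; with a single
    b=0, falls back to the spatial mean/SD ratio inside WM."""
    b0 = fit.b0_volumes
    if b0.shape[-1] >= 2:
        vals = b0[wm]
        sd = vals.std(axis=1, ddof=1)
        ok = sd > 0
        if not ok.any():
            return np.nan
        return float((vals[ok].mean(axis=1) / sd[ok]).mean())
    vals = b0[wm, 0]
    sd = float(vals.std(ddof=1))
    return float(vals.mean() / sd) if sd > 0 else np.nan


def dwi_qc_features(fit: TensorFitResult, wm_mask: np.ndarray, trace: MotionTrace,
                    scan_id: str = "", displacement_threshold: float = 1.0) -> QCRecord:
    """Compute the 20 dMRI QC features for one scan.

    ``motion_outlier_pct`` counts volumes whose Euclidean frame-to-frame
    translation step exceeds ``displacement_threshold`` (default 1 mm).
    """
    wm = np.asarray(wm_mask, dtype=bool) & fit.mask
    if not wm.any():
        raise InputError("wm_mask does not intersect the fit mask")

    t = np.abs(trace.translations).mean(axis=0)
    r = np.abs(trace.rotations).mean(axis=0)
    steps = np.linalg.norm(np.diff(trace.translations, axis=0), axis=1)
    outlier_pct = float(100.0 * (steps > displacement_threshold).mean()) if steps.size else 0.0
    fd = framewise_displacement(trace)

    fa_raw = fit.fa_raw[wm]
    fa = fit.fa[wm]
    sse = fit.sse[wm]
    evals = fit.eigenvalues[wm]

    features = {
        "motion_tx": float(t[0]),
        "motion_ty": float(t[1]),
        "motion_tz": float(t[2]),
        "motion_rx": float(r[0]),
        "motion_ry": float(r[1]),
        "motion_rz": float(r[2]),
        "fd_mean": fd.mean,
        "fd_max": float(fd.fd.max()),
        "motion_outlier_pct": outlier_pct,
        "sse_mean": float(sse.mean()),
        "sse_p95": float(np.percentile(sse, 95)),
        "b0_tsnr": _b0_tsnr(fit, wm),
        "fa_mean_wm": float(fa.mean()),
        "fa_sd_wm": float(fa.std(ddof=1)) if fa.size > 1 else 0.0,
        "fa_outlier_pct": float(100.0 * ((fa_raw < 0) | (fa_raw > 1)).mean()),
        "neg_eig_pct": float(100.0 * (evals < 0).any(axis=1).mean()),
        "md_mean_wm": float(fit.md[wm].mean()),
        "md_sd_wm": float(fit.md[wm].std(ddof=1)) if wm.sum() > 1 else 0.0,
        "ad_mean_wm": float(fit.ad[wm].mean()),
        "rd_mean_wm": float(fit.rd[wm].mean()),
    }
    return QCRecord(scan_id=scan_id, modality="dwi", features=features,
                    domains=dict(DWI_DOMAINS))
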