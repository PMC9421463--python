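"""Synthetic multi-site phantom cohorts with known ground truth.

Every pipeline stage is testable without any data download: structural
volumes are nested-ellipsoid CSF/GM/WM phantoms with site-scaled tissue
means, Gaussian (or Rician) noise, optional polynomial bias fields,
left-right intensity asymmetry and ghosting-style ripple; 4D series are
a static phantom plus temporal noise, drift and a random-walk motion
trace; DWI signals come from a known tensor field through
S = S0 * exp(-b g'Dg). A feature-level cohort simulator generates the
QC feature table directly (site offsets + corrupted scans shifted by a
stated number of within-site SDs), which is the natural scale for
testing the flagging and regression stages.

Defaults emulate a mid-size multi-site study: 4 sites x 50 scans,
site-to-site intensity/noise multipliers within ~10%, 5% artifact
prevalence, artifacts shifting 3 features by 4 within-site SDs.
Everything downstream of a spec + seed is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .images import (DiffusionScheme, InputError, MotionTrace, SeriesImage,
                     TissueMaps, VolumeImage, save_motion_trace, save_scheme,
                     save_series, save_volume)
from .structural import T1W_DOMAINS

# Baseline T1w tissue means (arbitrary units) and noise SD.
TISSUE_MEANS = {"csf": 150.0, "gm": 400.0, "wm": 600.0}
NOISE_SIGMA = 30.0

T1W_FEATURES = list(T1W_DOMAINS)


@dataclasses.dataclass
class CohortSpec:
    """Parameters of a synthetic multi-site cohort."""

    n_sites: int = 4
    scans_per_site: int = 50
    site_intensity: tuple[float, ...] = (1.00, 1.08, 0.95, 1.12)
    site_noise: tuple[float, ...] = (1.00, 1.15, 0.90, 1.25)
    noise_sigma: float = NOISE_SIGMA
    bias_amplitude: float = 0.05
    asymmetry_amp: float = 0.0
    artifact_prevalence: float = 0.05
    #: feature name -> shift in within-site SD units applied to corrupted scans
    artifact_profile: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"SNR": -4.0, "CNR": -4.0, "CJV": 4.0})
    grid_size: int = 64
    rician: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.artifact_prevalence <= 1:
            raise InputError("artifact_prevalence must be in [0, 1]")
        if any(m <= 0 for m in self.site_intensity + self.site_noise):
            raise InputError("site multipliers must be positive")
        if len(self.site_intensity) < self.n_sites or len(self.site_noise) < self.n_sites:
            raise InputError("need one intensity and noise multiplier per site")

    def rng_for(self, scan_index: int, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream, scan_index])


def _ellipsoid(shape: tuple[int, int, int], radii_frac: tuple[float, float, float],
               center_frac: tuple[float, float, float] = (0.5, 0.5, 0.5)) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    acc = np.zeros(shape)
    for g, n, r, c in zip(grids, shape, radii_frac, center_frac):
        acc += ((g - c * (n - 1)) / (r * n)) ** 2
    return acc <= 1.0


def _bias_field(shape: tuple[int, int, int], amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
    """Multiplicative low-frequency field 1 + amplitude * p(x, y, z) with
    p a random second-order polynomial scaled to unit max magnitude."""
    if amplitude == 0:
        return np.ones(shape)
    coords = np.meshgrid(*[np.linspace(-1, 1, n) for n in shape], indexing="ij")
    terms = [coords[0], coords[1], coords[2],
             coords[0] * coords[1], coords[0] * coords[2], coords[1] * coords[2],
             coords[0] ** 2, coords[1] ** 2, coords[2] ** 2]
    weights = rng.standard_normal(len(terms))
    poly = sum(w * t for w, t in zip(weights, terms))
    poly = poly / np.abs(poly).max()
    return 1.0 + amplitude * poly


def _add_noise(clean: np.ndarray, sigma: float, rician: bool,
               rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return clean.copy()
    if rician:
        return np.sqrt((clean + rng.normal(0, sigma, clean.shape)) ** 2
                       + rng.normal(0, sigma, clean.shape) ** 2)
    return clean + rng.normal(0, sigma, clean.shape)


def make_two_tissue_phantom(mu_gm: float = 400.0, sigma_gm: float = 40.0,
                            mu_wm: float = 600.0, sigma_wm: float = 30.0,
                            mu_csf: float = 150.0, sigma_csf: float = 15.0,
                            grid_size: int = 64, seed: int = 0,
                            ) -> tuple[VolumeImage, TissueMaps]:
    """A minimal phantom with independently specified per-tissue means
    and SDs — the fixture for brute-force feature-formula checks."""
    rng = np.random.default_rng(seed)
    shape = (grid_size,) * 3
    brain = _ellipsoid(shape, (0.42, 0.42, 0.42))
    wm_core = _ellipsoid(shape, (0.28, 0.28, 0.28))
    csf_core = _ellipsoid(shape, (0.10, 0.10, 0.10))
    wm = wm_core & ~csf_core
    gm = brain & ~wm_core
    data = np.zeros(shape)
    for mask, mu, sd in ((gm, mu_gm, sigma_gm), (wm, mu_wm, sigma_wm),
                         (csf_core, mu_csf, sigma_csf)):
        data[mask] = rng.normal(mu, sd, int(mask.sum()))
    data[~brain] = np.abs(rng.normal(0, 1.0, int((~brain).sum())))  # air noise floor
    img = VolumeImage(data=data)
    tissues = TissueMaps(gm=gm.astype(float), wm=wm.astype(float),
                         csf=csf_core.astype(float))
    return img, tissues


@dataclasses.dataclass
class GroundTruth:
    """Per-scan generative parameters, consistent with the emitted data
    by construction."""

    scan_id: str
    site: int
    is_corrupted: bool
    artifact: str = ""
    tissue_means: dict | None = None
    noise_sigma: float | None = None
    motion_step_sd: float | None = None
    tensors: np.ndarray | None = None


def make_t1_phantom(spec: CohortSpec, scan_index: int,
                    ) -> tuple[VolumeImage, TissueMaps, GroundTruth]:
    """Structural phantom for one scan of the cohort.

    Corrupted scans (per ``artifact_prevalence``, decided by a dedicated
    random stream so corruption status is stable across modalities) get
    tripled noise, a strong bias field and a ghosting-style ripple.
    """
    site = scan_index // spec.scans_per_site
    if site >= spec.n_sites:
        raise InputError(f"scan_index {scan_index} outside the cohort")
    rng = spec.rng_for(scan_index, stream=1)
    corrupt = spec.rng_for(scan_index, stream=9).random() < spec.artifact_prevalence

    shape = (spec.grid_size,) * 3
    brain = _ellipsoid(shape, (0.42, 0.42, 0.42))
    wm_core = _ellipsoid(shape, (0.28, 0.28, 0.28))
    csf_core = _ellipsoid(shape, (0.10, 0.10, 0.10))
    wm = wm_core & ~csf_core
    gm = brain & ~wm_core
    if not (gm.any() and wm.any() and csf_core.any()):
        raise InputError(f"degenerate geometry at grid_size {spec.grid_size}")

    means = {t: TISSUE_MEANS[t] * spec.site_intensity[site] for t in TISSUE_MEANS}
    clean = np.zeros(shape)
    clean[csf_core] = means["csf"]
    clean[gm] = means["gm"]
    clean[wm] = means["wm"]

    sigma = spec.noise_sigma * spec.site_noise[site]
    bias_amp = spec.bias_amplitude
    artifact = ""
    if corrupt:
        sigma *= 3.0
        bias_amp = max(bias_amp * 4.0, 0.2)
        artifact = "noise+bias+ripple"

    clean = clean * _bias_field(shape, bias_amp, rng)
    if spec.asymmetry_amp:
        x = np.linspace(-1, 1, shape[0])[:, None, None]
        clean = clean * (1.0 + spec.asymmetry_amp * x)
    if corrupt:   # ghosting-style ripple along the phase axis
        y = np.arange(shape[1])[None, :, None]
        clean = clean * (1.0 + 0.08 * np.sin(2 * np.pi * y / 8.0))
    data = _add_noise(clean, sigma, spec.rician, rng)
    data[~brain] += np.abs(rng.normal(0, 1.0, int((~brain).sum())))

    img = VolumeImage(data=data)
    tissues = TissueMaps(gm=gm.astype(float), wm=wm.astype(float),
                         csf=csf_core.astype(float))
    truth = GroundTruth(scan_id=f"sub-{scan_index:04d}", site=site, is_corrupted=corrupt,
                        artifact=artifact, tissue_means=means, noise_sigma=sigma)
    return img, tissues, truth


def make_motion_trace(n_volumes: int, step_sd_mm: float, step_sd_rad: float,
                      rng: np.random.Generator) -> MotionTrace:
    """Random-walk rigid-body trace: independent Gaussian increments per
    parameter, cumulated over volumes (volume 1 at the origin)."""
    steps = np.zeros((n_volumes, 6))
    steps[1:, :3] = rng.normal(0, step_sd_mm, (n_volumes - 1, 3))
    steps[1:, 3:] = rng.normal(0, step_sd_rad, (n_volumes - 1, 3))
    return MotionTrace(np.cumsum(steps, axis=0))


def make_fmri_series(spec: CohortSpec, scan_index: int, n_volumes: int = 100,
                     grid_size: int = 32, clean_step_sd: float = 0.02,
                     corrupted_step_sd: float = 0.5,
                     ) -> tuple[SeriesImage, MotionTrace, GroundTruth]:
    """4D phantom = static sphere + temporal noise + linear drift, with a
    random-walk motion trace; corrupted scans get the inflated step SD
    so their mean FD lands far (>= 4 SD) above the clean population."""
    if n_volumes < 2:
        raise InputError("need at least 2 volumes")
    site = scan_index // spec.scans_per_site
    rng = spec.rng_for(scan_index, stream=2)
    corrupt = spec.rng_for(scan_index, stream=9).random() < spec.artifact_prevalence

    shape = (grid_size,) * 3
    mask = _ellipsoid(shape, (0.4, 0.4, 0.4))
    static = np.where(mask, 500.0 * spec.site_intensity[site], 0.0)
    drift = 0.002 * np.arange(n_volumes)          # 0.2% of mean over the run
    data = (static[..., None] * (1.0 + drift)
            + rng.normal(0, 10.0 * spec.site_noise[site], shape + (n_volumes,)))

    step_sd = corrupted_step_sd if corrupt else clean_step_sd
    trace = make_motion_trace(n_volumes, step_sd, step_sd / 100.0, rng)
    series = SeriesImage(data=data, tr=2.0)
    truth = GroundTruth(scan_id=f"sub-{scan_index:04d}", site=site, is_corrupted=corrupt,
                        artifact="motion" if corrupt else "", motion_step_sd=step_sd)
    return series, trace, truth


def fibonacci_directions(n: int) -> np.ndarray:
    """n roughly uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def default_scheme(n_directions: int = 30, n_b0: int = 2, b: float = 1000.0,
                   ) -> DiffusionScheme:
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, b)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), fibonacci_directions(n_directions)])
    return DiffusionScheme(bvals=bvals, bvecs=bvecs)


def tensor_signal(tensors: np.ndarray, scheme: DiffusionScheme, s0: float = 1000.0,
                  ) -> np.ndarray:
    """Noiseless signals S = S0 exp(-b g'Dg) for (..., 3, 3) tensors."""
    quad = np.einsum("ia,...ab,ib->...i", scheme.bvecs, tensors, scheme.bvecs)
    return s0 * np.exp(-scheme.bvals * quad)


def anisotropic_tensor(fa_target_evals: tuple[float, float, float]) -> np.ndarray:
    return np.diag(np.asarray(fa_target_evals, dtype=float))


def make_dwi(spec: CohortSpec, scan_index: int, grid_size: int = 12,
             scheme: DiffusionScheme | None = None, snr: float = 30.0,
             ) -> tuple[SeriesImage, DiffusionScheme, GroundTruth]:
    """DWI phantom from a known tensor field.

    The inner half of the volume holds anisotropic white-matter-like
    tensors (eigenvalues 1.7/0.3/0.3 um^2/ms, FA ~ 0.80) with random
    principal directions; the outer shell holds isotropic tensors at the
    same mean diffusivity scale (FA ~ 0.2 via mild eigenvalue spread).
    Rician noise at SNR = S0/sigma (default 30); ``spec.rician=False``
    selects Gaussian noise instead.
    """
    site = scan_index // spec.scans_per_site
    rng = spec.rng_for(scan_index, stream=3)
    corrupt = spec.rng_for(scan_index, stream=9).random() < spec.artifact_prevalence
    scheme = scheme if scheme is not None else default_scheme()
    if (scheme.bvals > 0).sum() < 6 or scheme.b0_indices.size < 1:
        raise InputError("scheme needs >= 6 directions and >= 1 b=0 volume")

    shape = (grid_size,) * 3
    inner = _ellipsoid(shape, (0.35, 0.35, 0.35))
    tensors = np.zeros(shape + (3, 3))
    # FA ~0.80 region: random rotations of diag(1.7, 0.3, 0.3) um^2/ms.
    evals_aniso = np.array([1.7e-3, 0.3e-3, 0.3e-3])
    evals_iso = np.array([1.05e-3, 0.85e-3, 0.7e-3])   # FA ~ 0.2
    n_inner = int(inner.sum())
    for region, evals, n in ((inner, evals_aniso, n_inner),
                             (~inner, evals_iso, int((~inner).sum()))):
        mats = _random_rotations(n, rng)
        tensors[region] = mats @ np.diag(evals) @ np.transpose(mats, (0, 2, 1))

    s0 = 1000.0
    clean = tensor_signal(tensors, scheme, s0=s0)
    sigma = s0 / snr * (3.0 if corrupt else 1.0)
    data = _add_noise(clean, sigma, spec.rician, rng)
    series = SeriesImage(data=data, tr=7.0)
    truth = GroundTruth(scan_id=f"sub-{scan_index:04d}", site=site, is_corrupted=corrupt,
                        artifact="noise" if corrupt else "", noise_sigma=sigma,
                        tensors=tensors)
    return series, scheme, truth


def _random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """n random rotation matrices via QR of Gaussian matrices."""
    a = rng.standard_normal((n, 3, 3))
    q, r = np.linalg.qr(a)
    d = np.sign(np.einsum("nii->ni", r))
    q = q * d[:, None, :]
    det = np.linalg.det(q)
    q[:, :, 0] *= det[:, None]   # force det = +1
    return q


# ---------------------------------------------------------------------------
# Feature-level cohort simulation


def simulate_feature_cohort(spec: CohortSpec, seed: int | None = None,
                            feature_names: list[str] | None = None,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a QC feature table directly (no images).

    Per site, each feature f is N(base_f * site multiplier, sd_f); the
    artifact profile then shifts the named features of corrupted scans
    by the stated number of within-site SDs. Returns ``(cohort, truth)``
    frames indexed by scan_id; the cohort carries site plus plausible
    covariates (age, sex, MMSE, amyloid, APOE) drawn independently of
    the features.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    names = feature_names if feature_names is not None else T1W_FEATURES
    unknown = set(spec.artifact_profile) - set(names)
    if unknown:
        raise InputError(f"artifact profile names unknown features: {sorted(unknown)}")

    base = {f: 10.0 * (i + 1) for i, f in enumerate(names)}
    sd = {f: 1.0 + 0.1 * i for i, f in enumerate(names)}
    rows, truth_rows = [], []
    n_total = spec.n_sites * spec.scans_per_site
    corrupted = rng.random(n_total) < spec.artifact_prevalence
    for idx in range(n_total):
        site = idx // spec.scans_per_site
        scan_id = f"sub-{idx:04d}"
        row = {"scan_id": scan_id, "site": f"site{site:02d}"}
        for f in names:
            value = rng.normal(base[f] * spec.site_intensity[site],
                               sd[f] * spec.site_noise[site])
            if corrupted[idx] and f in spec.artifact_profile:
                value += spec.artifact_profile[f] * sd[f] * spec.site_noise[site]
            row[f] = value
        row.update({
            "age": float(np.round(rng.uniform(50, 88), 1)),
            "sex": str(rng.choice(["F", "M"])),
            "MMSE": int(rng.integers(24, 31)),
            "amyloid": int(rng.random() < 0.32),
            "APOE": int(rng.random() < 0.35),
        })
        rows.append(row)
        truth_rows.append({"scan_id": scan_id, "site": f"site{site:02d}",
                           "is_corrupted": bool(corrupted[idx]),
                           "artifact": "feature_shift" if corrupted[idx] else ""})
    cohort = pd.DataFrame(rows).set_index("scan_id")
    truth = pd.DataFrame(truth_rows).set_index("scan_id")
    return cohort, truth


# ---------------------------------------------------------------------------
# On-disk cohorts


def make_cohort(spec: CohortSpec, out_dir: str | Path,
                modalities: tuple[str, ...] = ("T1w",),
                fmri_volumes: int = 60, dwi_grid: int = 12) -> pd.DataFrame:
    """Materialize a BIDS-like directory of phantoms plus ground truth.

    Layout: ``sub-XXXX/ses-1/{anat,func,dwi}/`` with NIfTI images, JSON
    sidecars, tissue maps (anat), motion traces (func) and bval/bvec
    (dwi); ``ground_truth.tsv`` and ``participants.tsv`` at the root.
    Returns the ground-truth table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_rows = []
    n_total = spec.n_sites * spec.scans_per_site
    for idx in range(n_total):
        sub = f"sub-{idx:04d}"
        truth: GroundTruth | None = None
        if "T1w" in modalities:
            img, tissues, truth = make_t1_phantom(spec, idx)
            anat = out_dir / sub / "ses-1" / "anat"
            anat.mkdir(parents=True, exist_ok=True)
            save_volume(img, anat / f"{sub}_ses-1_T1w.nii.gz")
            for tissue in ("gm", "wm", "csf"):
                save_volume(getattr(tissues, tissue), anat / f"{sub}_ses-1_label-{tissue.upper()}_probseg.nii.gz")
            (anat / f"{sub}_ses-1_T1w.json").write_text(json.dumps(
                {"SeriesDescription": "t1_mprage_sag_p2", "EchoTime": 0.00295,
                 "RepetitionTime": 2.3, "Site": f"site{truth.site:02d}"}, indent=2))
        if "bold" in modalities:
            series, trace, truth_f = make_fmri_series(spec, idx, n_volumes=fmri_volumes)
            func = out_dir / sub / "ses-1" / "func"
            func.mkdir(parents=True, exist_ok=True)
            save_series(series, func / f"{sub}_ses-1_task-rest_bold.nii.gz")
            save_motion_trace(trace, func / f"{sub}_ses-1_task-rest_motion.txt")
            truth = truth or truth_f
        if "dwi" in modalities:
            series, scheme, truth_d = make_dwi(spec, idx, grid_size=dwi_grid)
            dwi = out_dir / sub / "ses-1" / "dwi"
            dwi.mkdir(parents=True, exist_ok=True)
            save_series(series, dwi / f"{sub}_ses-1_dwi.nii.gz")
            save_scheme(scheme, dwi / f"{sub}_ses-1_dwi.bval", dwi / f"{sub}_ses-1_dwi.bvec")
            truth = truth or truth_d
        truth_rows.append({"scan_id": sub, "site": f"site{truth.site:02d}",
                           "is_corrupted": truth.is_corrupted, "artifact": truth.artifact})
    truth_df = pd.DataFrame(truth_rows).set_index("scan_id")
    truth_df.reset_index().to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
    truth_df.reset_index()[["scan_id", "site"]].rename(
        columns={"scan_id": "participant_id"}).to_csv(
        out_dir / "participants.tsv", sep="\t", index=False)
    return truth_df
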