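# Methods

This note documents the models and procedures implemented in `scanqc`,
the defaults they use, and what the synthetic tests do and do not show.

## Scan-type recognition and session QC

Scan types are assigned by a priority-ordered table of case-insensitive
regular expressions matched against `SeriesDescription`, falling back to
`ProtocolName` + `ImageType`; the lowest priority number wins and an
unmatched scan is labelled `unknown`. The shipped default table is a
*reconstruction* of typical Siemens/Philips/GE sequence names; real
deployments should supply their own scanner-specific TSV
(`scan_type, pattern, priority, scanner_scope`).

Session-level QC emits four issue kinds: `studyid_discordant` (more than
one StudyID in a session), `duplicate_series` (shared series UID),
`incomplete_series` (`n_files` below an `expected_files` entry in the
acquisition parameters; skipped with a notice when no expectation is
recorded, since expected counts are sequence- and site-specific), and
`parameter_inconsistent` (an invariant parameter — echo time, repetition
time, voxel size, flip angle — differing across same-type scans). Issue
lists are deterministic and independent of input order.

## Structural (T1w) features

Twelve features, computed from the image plus aligned GM/WM/CSF
probability maps. Tissue means and SDs are probability-weighted
(reliability-weight correction `Σw(x−m)² / (V1 − V2/V1)`, which reduces
to the ddof=1 sample SD for hard masks); a hard-mask mode binarizes at
`prob_threshold` (default 0.5).

| feature | formula | domain |
|---|---|---|
| SNR | μ_WM / σ_WM | noise |
| CNR | \|μ_GM − μ_WM\| / √(σ²_GM + σ²_WM + σ²_bg) | noise |
| CJV | (σ_WM + σ_GM) / \|μ_WM − μ_GM\| | inhomogeneity |
| FBER | median(fg²) / median(bg²) | inhomogeneity |
| AI_perc | 100 · mean over brain of \|I − I_flip\| / (midpoint + ε) | asymmetry |
| IQR | composite noise/bias rating, see below | inhomogeneity |
| CSF_k | excess kurtosis of CSF intensities (bias-corrected) | descriptives |
| WM2MAX | μ_WM / P99.95(image) | inhomogeneity |
| GM/WM/CSFfrac | tissue probability mass / brain probability mass | descriptives |
| EFC | normalized Shannon entropy of the intensity distribution | descriptives |

Numerical choices:

- The background mask defaults to voxels with total brain probability
  < 0.05, eroded by two voxels (the erosion also strips a two-voxel rim
  at the image border, keeping edge and partial-volume voxels out of the
  noise estimate).
- AI_perc mirrors across the axis labelled L/R in the orientation
  metadata; ε = 10⁻⁶ × P99 of brain intensities guards the midpoint
  denominator.
- CJV is reported missing (NaN, with a logged warning) when
  |μ_WM − μ_GM| is below 10⁻⁹·|μ_WM| — the feature is undefined without
  tissue contrast.
- EFC is the intensity-distribution entropy normalized so a perfectly
  uniform image scores 1; blurring and ghosting push it up.

**IQR surrogate.** The original Image Quality Rating is a proprietary
composite; here IQR is the weighted RMS (weights 0.5/0.5) of two
logistic-mapped sub-scores: a noise-to-contrast ratio
σ_WM/|μ_WM − μ_GM| (logistic midpoint 0.3, width 0.1) and a bias
amplitude estimated as the coefficient of variation of the WM intensity
field after heavy Gaussian smoothing (σ = 6 voxels; midpoint 0.10,
width 0.05). Higher = worse. The mapping constants locate typical clean
phantom values on the lower logistic shoulder so that both sub-scores
respond monotonically over the realistic range; IQR increases strictly
with injected bias amplitude and with noise.

The four descriptives (three tissue fractions and EFC) complete the
12-feature panel; only eight feature identities are fixed by the
published panel, so this completion is a documented reconstruction.

## Functional (fMRI) features and motion exclusion

Framewise displacement uses the Power formula:
FD_t = |Δtx| + |Δty| + |Δtz| + r·(|Δrx| + |Δry| + |Δrz|), with assumed
head radius r = 50 mm (configurable) converting rotations to arc length,
and FD_1 = 0. FD is computed on raw realignment parameters. Motion
parameters are consumed as input (6-column whitespace text: tx ty tz in
mm, rx ry rz in radians); no realigner is bundled.

The 17-feature panel: tSNR (voxelwise mean/SD over time averaged in the
mask, with its 5th/95th percentiles), DVARS (RMS volume-to-volume
difference, normalized by median in-mask intensity), FD mean/max and the
fraction of frames with FD > 0.5 mm, P95 of the voxelwise temporal SD
(normalized), global-signal SD and linear drift (percent of mean), and
spatial features of the temporal-mean volume (SNR against the air
background, FBER, EFC, left-right asymmetry, smoothed-field CV as a
bias proxy, foreground mean, volume count). Only tSNR/DVARS/FD are fixed
by the published panel size; the completion is config-documented here.
Voxels with zero temporal SD are excluded from tSNR; an entirely
constant series reports tSNR as missing rather than infinite.

Cohort-level exclusion flags scan *i* when
mean FD_i > mean + 2·SD (sample SD) of the group; at least three scans
are required, otherwise the rule errors out and asks for manual review.

## Diffusion tensor fit and dMRI features

The tensor is fitted by ordinary log-linear least squares,
log S_i = log S₀ − b_i g_iᵀ D g_i, solving all masked voxels against one
7-column design matrix (log S₀ plus the six unique tensor elements).
Preconditions: ≥ 1 b = 0 volume, ≥ 6 non-collinear nonzero-b directions
(design condition number < 10⁶, reported in the error otherwise).
Nonpositive signals are clamped to the voxel's smallest positive signal
before the log, with the clamp count reported. Eigenvalues are sorted
descending; MD = (λ₁+λ₂+λ₃)/3, AD = λ₁, RD = (λ₂+λ₃)/2,
FA = √(3/2)·√(Σ(λ_k − λ̄)²/Σλ_k²). Negative eigenvalues are *kept* —
they are what the FA-outlier and negative-eigenvalue QC metrics look
for — and FA is clipped to [0, 1] only in the released map, with
pre-clip values retained.

The 20-feature panel: per-axis mean absolute translations and rotations,
FD mean/max, motion-outlier percentage (volumes whose Euclidean
translation step exceeds 1 mm — the threshold is a documented default,
configurable), SSE mean and P95 in white matter, b = 0 temporal SNR
(spatial mean/SD fallback when only one b = 0 exists), FA mean/SD in WM,
percentage of WM voxels with pre-clip FA outside [0, 1], percentage with
any negative eigenvalue, and MD/AD/RD statistics in WM.

## Site-wise flagging

Within each site, every feature is standardized by the site mean and
sample SD; features constant within a site get Z = 0 (logged) and
missing values stay missing. The ranking score is Σ_f |Z_if| over
non-missing features, rescaled by n_features/n_non-missing so partially
missing scans remain comparable. The top ceil(0.15·n_site) scans per
site are flagged; ceil (rather than floor) guarantees every site
contributes at least one reviewed scan. Ties at the boundary break by
lexicographic scan ID, so flagging is fully deterministic. A pooled
single-cut mode exists behind `per_site=False`; per-site is the default
because QC feature distributions differ strongly between sites, which is
also why the Z-scores are site-wise in the first place.

Matched inliers are drawn uniformly without replacement, stratified by
site to mirror the flagged counts (shortfalls logged), from a seeded
generator. The review batch shuffles flagged + matched scans with the
status withheld; a sealed key (position → status) supports post-hoc
unblinding. Visual labels are ordinal: poor < moderate < good.

## Feature informativeness

*Covariate screen.* One OLS model per feature on site (categorical),
age, sex, MMSE, amyloid and APOE; each term is tested by a type-II
F-test (identical to the Wald t-test for 1-df terms) and p-values are
Bonferroni-corrected across **all** feature × covariate tests. Models
are complete-case with a 10-row minimum; constant features are skipped
with a notice; rank-deficient designs error naming the covariates.

*Ordinal regression.* `OrdinalQCModel` wraps a proportional-odds
(cumulative logit) model, P(Y ≤ k|x) = logistic(θ_k − xᵀβ), maximized
by BFGS via statsmodels. Predictors are z-standardized internally for
conditioning; coefficients, Wald 95% CIs and odds ratios are reported
back on the raw feature scale (an affine reparametrization — the
likelihood, AIC and p-values are unchanged, as the tests assert to
1e-8). AIC = −2·loglik + 2·(n_features + n_cutpoints). A subclass
supplies the closed-form score; optimizer stops flagged as "precision
loss" are accepted when the mean per-observation gradient is below
10⁻⁶. Standardized coefficients above 30 raise a separation error
suggesting a penalized fit. A covariate-adjusted mode (`adjust=` columns
that are never elimination candidates) exists but has no reference
output.

*Backward AIC.* At each step every single-feature removal is refitted
(warm-started from the incumbent optimum, likelihood-only); the best
removal is accepted while it lowers AIC. The thresholds-only null model
(closed-form likelihood from label frequencies) is the final candidate,
making the procedure total; the reduced AIC can therefore never exceed
the full model's. Note a statistical property of this procedure, not of
its implementation: a truly null predictor is removed only when its LR
statistic is below 2, which happens with probability
P(χ²₁ < 2) ≈ 0.843 — so with four null predictors, all four are dropped
in only ≈ 50% of datasets, and one or two survivors are expected
routinely. The dMRI analysis is the same code path applied to the dwi
feature panel.

*Model comparison.* LR = 2(ℓ_full − ℓ_reduced) (clipped at 0 against
optimizer noise), df = feature-count difference, p from the χ² upper
tail; requires nested feature sets and identical observation counts —
row filtering happens once, upstream.

## Synthetic cohorts

The generator defines the conditions under which the pipeline is
validated:

- **T1w phantoms** (default 64³, 1 mm voxels): nested ellipsoids —
  brain, an inner WM core, a central CSF compartment — with tissue means
  CSF/GM/WM = 150/400/600 (arbitrary units), Gaussian noise σ = 30
  (Rician optional), per-site intensity multipliers
  (1.00, 1.08, 0.95, 1.12) and noise multipliers (1.00, 1.15, 0.90,
  1.25), a multiplicative random second-order polynomial bias field
  (default amplitude 0.05), optional left-right intensity gradient.
  Probability maps are the exact generating compartments.
- **fMRI** (default 32³ × 100 volumes, TR 2 s): static sphere + temporal
  Gaussian noise + 0.2% linear drift; motion traces are random walks
  with translation step SD 0.02 mm (clean) vs 0.5 mm (corrupted) — the
  corrupted scans' mean FD lands far above the clean population, which
  is what makes the 2-SD rule's recall testable.
- **DWI** (default 12³): signals S = S₀·exp(−b gᵀDg) from a known
  tensor field (inner region: randomly rotated 1.7/0.3/0.3 µm²/ms
  tensors, FA ≈ 0.80; outer region FA ≈ 0.2), a Fibonacci-sphere
  gradient scheme (30 directions + 2 b = 0 at b = 1000 s/mm²), Rician
  or Gaussian noise at SNR = S₀/σ = 30.
- **Feature-level cohorts**: 4 sites × 50 scans; each feature is drawn
  Gaussian with site-scaled mean and SD, and corrupted scans (5%
  prevalence) get the artifact profile added in within-site-SD units
  (default: 3 features shifted by 4 SD). This is the scale on which the
  flagging stage operates, so the 100-seed detection-power and
  regression studies run here; the image-level route (phantoms → feature
  extraction → flagging) is exercised end-to-end at reduced scale
  (2 sites × 12 scans, 32³, 3 seeds) to keep the suite fast.
- Corruption status is drawn from a dedicated random stream, so a scan
  is corrupted consistently across its modalities; everything downstream
  of (spec, seed) is bit-reproducible.

What the phantoms do **not** emulate: real head geometry, k-space
artifacts, partial-volume mixtures beyond compartment boundaries,
susceptibility distortion, physiological noise, or realistic covariate–
feature relationships (covariates are drawn independently of features).
Passing tests therefore demonstrate correctness of the formulas and the
statistical machinery under controlled conditions, not clinical
performance on real data.

## Problem sizes used by tests and the acceptance script

Feature-formula oracles run on one 64³ phantom; tensor recovery on 10³
voxels × 5 noise seeds; detection power on 100 feature-level cohorts of
200 scans; ordinal CI coverage on 300–500 simulations at n = 2000;
backward elimination on 50–100 simulated datasets of 12 predictors at
n = 2000. These sizes give Monte-Carlo standard errors comfortably below
the asserted margins while keeping a full run in the minutes range on
one CPU.

## Known limitations

- The IQR surrogate is *not* numerically comparable to CAT12's rating;
  only its qualitative behaviour (worse with noise and bias) matches.
- The fMRI and dMRI panel completions beyond the published feature names
  are reconstructions; panel membership is config-controlled.
- The tensor fit is unweighted log-linear least squares; no weighted or
  iterative refinement, no multi-shell models.
- The covariate screen uses linear models throughout, including for the
  bounded MMSE score.
- Backward-AIC retains each truly-null predictor with probability
  ≈ 0.16 by construction (see above); consumers wanting sparser models
  should swap in a BIC-style penalty.
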