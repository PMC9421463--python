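"""Site-wise outlier flagging for blinded visual QC.

Multi-site QC features carry strong scanner/site offsets, so each
feature is standardized within its site (Z-score against the site mean
and sample SD). Scans are ranked by the sum of absolute within-site
Z-scores over all features; the top fraction (default 15%) per site is
flagged "needing visual QC". To control for false negatives, an equally
sized, site-matched random subset of non-flagged scans is drawn, and the
combined set is shuffled into a blinded review batch with a sealed key
for post-hoc unblinding. Visual labels are ordinal:
poor < moderate < good.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .images import InputError

logger = logging.getLogger(__name__)

VISUAL_LABELS = ("poor", "moderate", "good")   # ordinal, worst first

STATUS_FLAGGED = "flagged"
STATUS_MATCHED = "matched_inlier"
STATUS_UNREVIEWED = "unreviewed"


@dataclasses.dataclass
class FlagResult:
    """Outcome of site-wise flagging.

    ``table`` is indexed by scan_id with columns ``site``, ``score``
    (summed |Z|) and ``status``; ``zscores`` holds the per-feature
    within-site Z matrix on the same index.
    """

    table: pd.DataFrame
    zscores: pd.DataFrame
    fraction: float
    per_site: bool
    seed: int | None = None

    @property
    def flagged_ids(self) -> list[str]:
        return sorted(self.table.index[self.table["status"] == STATUS_FLAGGED])

    @property
    def matched_inlier_ids(self) -> list[str]:
        return sorted(self.table.index[self.table["status"] == STATUS_MATCHED])

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.table.reset_index().to_csv(out_dir / "flags.tsv", sep="\t", index=False)
        self.zscores.reset_index().to_csv(out_dir / "zscores.tsv", sep="\t", index=False)
        manifest = {"fraction": self.fraction, "per_site": self.per_site,
                    "seed": self.seed, "n_flagged": len(self.flagged_ids)}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def site_zscores(cohort: pd.DataFrame, feature_cols: list[str] | None = None,
                 site_col: str = "site") -> pd.DataFrame:
    """Within-site Z-scores (site mean, site sample SD) per feature.

    Features that are constant within a site get Z = 0 for that site
    (logged); missing values stay missing. Any site with fewer than two
    scans is an error — its SD cannot be estimated.
    """
    if site_col not in cohort.columns:
        raise InputError(f"cohort table has no {site_col!r} column")
    if feature_cols is None:
        feature_cols = [c for c in cohort.columns
                        if c != site_col and pd.api.types.is_numeric_dtype(cohort[c])]
    if not feature_cols:
        raise InputError("no numeric feature columns found")

    counts = cohort.groupby(site_col).size()
    small = counts[counts < 2]
    if len(small):
        raise InputError(f"sites with a single scan cannot be Z-scored: {list(small.index)}")

    grouped = cohort.groupby(site_col)[feature_cols]
    mean = grouped.transform("mean")
    sd = grouped.transform("std")            # sample SD (ddof=1)
    constant = (sd == 0) & cohort[feature_cols].notna()
    if constant.any().any():
        cols = constant.any()[lambda s: s].index.tolist()
        logger.info("features constant within a site, Z set to 0: %s", cols)
    z = (cohort[feature_cols] - mean) / sd.replace(0.0, np.nan)
    z = z.mask(constant, 0.0)
    return z


def flag_outliers(z: pd.DataFrame, sites: pd.Series, fraction: float = 0.15,
                  per_site: bool = True) -> FlagResult:
    """Rank scans by summed |Z| and flag the top fraction.

    The score over non-missing features is rescaled by
    n_features / n_non_missing so partially missing scans stay
    comparable. Per site (default), ceil(fraction * n_site) scans are
    flagged; ties at the boundary break by lexicographic scan_id. A
    pooled-cohort mode (``per_site=False``) applies one global cut.
    """
    if not 0 < fraction < 1:
        raise InputError("fraction must be in (0, 1)")
    sites = sites.loc[z.index]
    n_features = z.shape[1]
    n_nonmiss = z.notna().sum(axis=1)
    if (n_nonmiss == 0).all():
        raise InputError("all scores missing: no non-missing features for any scan")
    score = z.abs().sum(axis=1, min_count=1) * (n_features / n_nonmiss)
    score = score.rename("score")
    if (score.groupby(sites).nunique() <= 1).any():
        logger.warning("uniform scores within a site: flagging decided by scan_id tie-break")

    table = pd.DataFrame({"site": sites, "score": score})
    table["status"] = STATUS_UNREVIEWED
    # Deterministic order: score descending, then scan_id ascending.
    ordered = (table.assign(_id=table.index.astype(str))
               .sort_values(["score", "_id"], ascending=[False, True], kind="mergesort"))
    if per_site:
        for site, group in ordered.groupby("site", sort=False):
            k = math.ceil(fraction * len(group))
            table.loc[group.index[:k], "status"] = STATUS_FLAGGED
    else:
        k = math.ceil(fraction * len(ordered))
        table.loc[ordered.index[:k], "status"] = STATUS_FLAGGED
    return FlagResult(table=table, zscores=z, fraction=fraction, per_site=per_site)


def sample_matched_inliers(flags: FlagResult, seed: int) -> FlagResult:
    """Draw a random non-flagged subset matching the flagged per-site
    counts (without replacement, reproducible from seed). If a site has
    fewer inliers than flagged scans, all its inliers are taken and the
    shortfall is logged."""
    table = flags.table.copy()
    if (table["status"] != STATUS_FLAGGED).sum() == 0:
        raise InputError("no non-flagged scans to sample from")
    rng = np.random.default_rng(seed)
    table.loc[table["status"] == STATUS_MATCHED, "status"] = STATUS_UNREVIEWED
    for site, group in table.groupby("site", sort=True):
        n_flagged = int((group["status"] == STATUS_FLAGGED).sum())
        pool = sorted(group.index[group["status"] == STATUS_UNREVIEWED])
        if n_flagged == 0 or not pool:
            continue
        k = min(n_flagged, len(pool))
        if k < n_flagged:
            logger.warning("site %s: only %d inliers available for %d flagged scans",
                           site, len(pool), n_flagged)
        chosen = rng.choice(len(pool), size=k, replace=False)
        table.loc[[pool[i] for i in chosen], "status"] = STATUS_MATCHED
    return FlagResult(table=table, zscores=flags.zscores, fraction=flags.fraction,
                      per_site=flags.per_site, seed=seed)


def build_review_batch(flags: FlagResult, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shuffle flagged + matched-inlier scans into a blinded review list.

    Returns ``(batch, key)``: the batch holds position and scan_id only
    (status withheld); the sealed key maps position -> status for
    post-hoc unblinding.
    """
    table = flags.table
    review = table[table["status"].isin([STATUS_FLAGGED, STATUS_MATCHED])]
    if review.empty:
        raise InputError("empty review set: flag scans (and sample inliers) first")
    ids = sorted(review.index)
    order = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in order]
    batch = pd.DataFrame({"position": np.arange(1, len(ids) + 1), "scan_id": shuffled})
    key = batch.assign(status=[table.loc[s, "status"] for s in shuffled])
    return batch, key


def unblind(batch: pd.DataFrame, key: pd.DataFrame) -> pd.DataFrame:
    """Re-join the sealed key to a review batch (e.g. after labels were
    entered against positions)."""
    return batch.merge(key[["position", "status"]], on="position", validate="1:1")
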