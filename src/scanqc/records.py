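"""The QCRecord container: one scan's named QC feature values, each
labelled with one of the five feature domains (motion, noise,
inhomogeneity, asymmetry, descriptives)."""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import pandas as pd

from .images import InputError

DOMAINS = ("motion", "noise", "inhomogeneity", "asymmetry", "descriptives")
MODALITIES = ("T1w", "bold", "dwi")


@dataclasses.dataclass
class QCRecord:
    """QC features for a single scan.

    ``features`` maps feature name -> scalar (NaN marks a feature that
    could not be computed, e.g. a degenerate-contrast CJV); ``domains``
    assigns every feature to one of the five domains.
    """

    scan_id: str
    modality: str
    features: dict[str, float]
    domains: dict[str, str]

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise InputError(f"unknown modality {self.modality!r}")
        missing = set(self.features) - set(self.domains)
        if missing:
            raise InputError(f"features without a domain label: {sorted(missing)}")
        bad = {f: d for f, d in self.domains.items() if d not in DOMAINS}
        if bad:
            raise InputError(f"invalid domain labels: {bad}")
        for name, value in self.features.items():
            value = float(value)
            if math.isinf(value):
                raise InputError(f"feature {name} is infinite")
            self.features[name] = value

    @property
    def feature_names(self) -> list[str]:
        return list(self.features)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scan_id": self.scan_id,
            "modality": self.modality,
            "features": {k: (None if math.isnan(v) else v) for k, v in self.features.items()},
            "domains": self.domains,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def records_to_table(records: list[QCRecord], extra: pd.DataFrame | None = None) -> pd.DataFrame:
    """Stack QCRecords into a cohort table, one row per scan, optionally
    joined with per-scan covariates (site, age, ...) indexed by scan_id."""
    if not records:
        raise InputError("no records to stack")
    df = pd.DataFrame([{"scan_id": r.scan_id, **r.features} for r in records]).set_index("scan_id")
    if extra is not None:
        df = df.join(extra, how="left")
    return df


def append_to_tsv(record: QCRecord, path: str | Path) -> None:
    """Append one scan's features as a row of a cohort TSV (header written
    on first use)."""
    path = Path(path)
    row = pd.DataFrame([{"scan_id": record.scan_id, "modality": record.modality,
                         **record.features}])
    row.to_csv(path, sep="\t", index=False, mode="a", header=not path.exists())
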