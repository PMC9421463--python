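"""Scan-type recognition and session-level consistency checks on
acquisition metadata.

Multi-scanner cohorts name the same sequence differently
(``t1_mprage_sag_p2``, ``3D_T1_BRAVO``, ...), so scan types are assigned
by a configurable table of regular expressions matched against the
series description (falling back to protocol name + image type). A
second pass checks each imaging session for duplicated series, study-ID
discordance, incomplete series and inconsistent acquisition parameters —
the metadata-level part of curating a raw multi-site archive.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path

import pandas as pd

from .images import InputError

logger = logging.getLogger(__name__)

SCAN_TYPES = (
    "T1w", "FLAIR", "T2w", "T2starw", "SWI", "bold", "dwi", "asl",
    "fieldmap-pepolar", "unknown",
)

#: Parameters that must agree across scans of the same type in a session.
INVARIANT_PARAMS = ("EchoTime", "RepetitionTime", "VoxelSize", "FlipAngle")


class ConfigurationError(ValueError):
    """A rule table entry is invalid (e.g. a regex that does not compile)."""


@dataclasses.dataclass
class ScanMetadata:
    scan_id: str
    session_id: str = ""
    study_id: str = ""
    series_description: str = ""
    protocol_name: str = ""
    image_type: str = ""
    series_uid: str = ""
    n_files: int = 0
    acquisition_params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_files < 0:
            raise InputError(f"scan {self.scan_id}: n_files must be >= 0")


@dataclasses.dataclass
class ScanTypeRule:
    scan_type: str
    pattern: str
    priority: int
    scanner_scope: str = ""

    def __post_init__(self) -> None:
        if self.scan_type not in SCAN_TYPES:
            raise ConfigurationError(f"unknown scan_type {self.scan_type!r}")
        try:
            self._compiled = re.compile(self.pattern, re.IGNORECASE)
        except re.error as exc:
            raise ConfigurationError(
                f"rule ({self.scan_type!r}, priority {self.priority}): "
                f"invalid pattern {self.pattern!r}: {exc}"
            ) from exc

    def matches(self, text: str) -> bool:
        return bool(self._compiled.search(text))


@dataclasses.dataclass
class SessionIssue:
    issue_kind: str  # studyid_discordant | duplicate_series | incomplete_series | parameter_inconsistent
    scan_ids: list[str]
    detail: str = ""

    def __post_init__(self) -> None:
        if not self.scan_ids:
            raise InputError("SessionIssue needs at least one scan_id")
        self.scan_ids = sorted(self.scan_ids)


# A reconstruction of typical vendor sequence names per scan type; real
# deployments replace this with a scanner-specific TSV.
DEFAULT_RULES = [
    ScanTypeRule("fieldmap-pepolar", r"pepolar|revph|reversed?_?pe|topup|_pa\b|invertpe", 5),
    ScanTypeRule("T1w", r"mprage|t1w|t1-?weighted|tfl3d|bravo|spgr|3d_?t1", 10),
    ScanTypeRule("FLAIR", r"flair", 20),
    ScanTypeRule("T2starw", r"t2\*|t2_?star|gre_2d", 25),
    ScanTypeRule("T2w", r"t2w|t2_?tse|tse2d|t2-?weighted", 30),
    ScanTypeRule("SWI", r"swi", 40),
    ScanTypeRule("bold", r"bold|fmri|rest(ing)?[-_ ]?state|ep2d_bold", 50),
    ScanTypeRule("dwi", r"dwi|dti|diff", 60),
    ScanTypeRule("asl", r"asl|pcasl|pasl|\bm0\b", 70),
]


def classify_scan_type(meta: ScanMetadata, rules: list[ScanTypeRule]) -> str:
    """Assign a scan type by the highest-priority (lowest number) matching
    rule; `series_description` is tried first, then protocol name
    combined with image type. Returns ``"unknown"`` when nothing matches."""
    if not rules:
        raise InputError("empty rule table")
    ordered = sorted(rules, key=lambda r: r.priority)
    for field in (meta.series_description, f"{meta.protocol_name} {meta.image_type}".strip()):
        if not field:
            continue
        for rule in ordered:
            if rule.matches(field):
                return rule.scan_type
    return "unknown"


def check_session_consistency(scans: list[ScanMetadata],
                              rules: list[ScanTypeRule] | None = None) -> list[SessionIssue]:
    """Session QC: study-ID concordance, duplicate/incomplete series and
    acquisition-parameter consistency within each scan type.

    Completeness uses an ``expected_files`` entry in acquisition_params;
    scans without it skip the check (with a logged notice). The returned
    issue list does not depend on the order of `scans`.
    """
    if not scans:
        raise InputError("empty scan list")
    scans = sorted(scans, key=lambda s: s.scan_id)
    sessions = {s.session_id for s in scans}
    if len(sessions) > 1:
        raise InputError(f"scans span multiple sessions: {sorted(sessions)}")
    issues: list[SessionIssue] = []

    study_ids = sorted({s.study_id for s in scans})
    if len(study_ids) > 1:
        issues.append(SessionIssue(
            "studyid_discordant", [s.scan_id for s in scans],
            detail=f"study_ids: {', '.join(study_ids)}"))

    by_uid: dict[str, list[str]] = {}
    for s in scans:
        if s.series_uid:
            by_uid.setdefault(s.series_uid, []).append(s.scan_id)
    for uid, ids in sorted(by_uid.items()):
        if len(ids) > 1:
            issues.append(SessionIssue("duplicate_series", ids, detail=f"series_uid {uid}"))

    for s in scans:
        expected = s.acquisition_params.get("expected_files")
        if expected is None:
            logger.info("scan %s: no expected_files entry; completeness check skipped", s.scan_id)
            continue
        if s.n_files < int(expected):
            issues.append(SessionIssue(
                "incomplete_series", [s.scan_id],
                detail=f"{s.n_files} of {int(expected)} files"))

    rule_table = rules if rules is not None else DEFAULT_RULES
    by_type: dict[str, list[ScanMetadata]] = {}
    for s in scans:
        by_type.setdefault(classify_scan_type(s, rule_table), []).append(s)
    for scan_type, group in sorted(by_type.items()):
        if len(group) < 2:
            continue
        for param in INVARIANT_PARAMS:
            values = {s.scan_id: s.acquisition_params.get(param)
                      for s in group if param in s.acquisition_params}
            if len(set(map(str, values.values()))) > 1:
                issues.append(SessionIssue(
                    "parameter_inconsistent", sorted(values),
                    detail=f"{scan_type}: {param} differs ({values})"))
    return issues


# ---------------------------------------------------------------------------
# TSV interfaces


def load_rule_table(path: str | Path) -> list[ScanTypeRule]:
    df = pd.read_csv(path, sep="\t")
    required = {"scan_type", "pattern", "priority"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"rule table needs columns {sorted(required)}")
    if df["priority"].duplicated().any():
        raise ConfigurationError("rule priorities must be unique")
    return [
        ScanTypeRule(row.scan_type, row.pattern, int(row.priority),
                     str(getattr(row, "scanner_scope", "") or ""))
        for row in df.itertuples()
    ]


def save_rule_table(rules: list[ScanTypeRule], path: str | Path) -> None:
    pd.DataFrame(
        [(r.scan_type, r.pattern, r.priority, r.scanner_scope) for r in rules],
        columns=["scan_type", "pattern", "priority", "scanner_scope"],
    ).to_csv(path, sep="\t", index=False)


def load_metadata_table(path: str | Path) -> list[ScanMetadata]:
    """Read scan metadata from a cohort TSV (one row per scan); columns
    beyond the named fields become acquisition_params."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    known = {"scan_id", "session_id", "study_id", "series_description",
             "protocol_name", "image_type", "series_uid", "n_files"}
    out = []
    for _, row in df.iterrows():
        params = {c: row[c] for c in df.columns if c not in known and row[c] != ""}
        out.append(ScanMetadata(
            scan_id=row.get("scan_id", ""),
            session_id=row.get("session_id", ""),
            study_id=row.get("study_id", ""),
            series_description=row.get("series_description", ""),
            protocol_name=row.get("protocol_name", ""),
            image_type=row.get("image_type", ""),
            series_uid=row.get("series_uid", ""),
            n_files=int(row["n_files"]) if row.get("n_files", "") else 0,
            acquisition_params=params,
        ))
    return out


def save_issues(issues: list[SessionIssue], session_id: str, path: str | Path) -> None:
    pd.DataFrame(
        [(session_id, i.issue_kind, ";".join(i.scan_ids), i.detail) for i in issues],
        columns=["session_id", "issue_kind", "scan_ids", "detail"],
    ).to_csv(path, sep="\t", index=False)
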