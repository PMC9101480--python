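"""Reading and writing fixation/saccade event reports and feature tables.

The canonical dialect is UTF-8, tab-separated, one header row, with the
column names below.  Vendor exports that use different header names are
handled through a :class:`DialectConfig` column mapping; the vendor schema
itself is not hard-coded anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .records import (
    CONDITIONS,
    ConfigError,
    FixationRecord,
    SaccadeRecord,
    Trial,
    ValidationError,
)

log = logging.getLogger(__name__)

FIXATION_COLUMNS = [
    "subject",
    "condition",
    "trial",
    "index",
    "t_start_ms",
    "duration_ms",
    "x_px",
    "y_px",
    "aoi",
]

SACCADE_COLUMNS = [
    "subject",
    "condition",
    "trial",
    "index",
    "t_start_ms",
    "duration_ms",
    "x_start_px",
    "y_start_px",
    "x_end_px",
    "y_end_px",
    "amplitude_deg",
    "velocity_degps",
]

META_COLUMNS = ["subject", "condition", "trial", "trigger_end_ms", "trial_end_ms"]


@dataclass
class DialectConfig:
    """How to read a particular report file.

    ``column_map`` translates the file's header names to the canonical ones,
    e.g. ``{"RECORDING_SESSION_LABEL": "subject"}``.  Columns already named
    canonically need no entry.
    """

    sep: str = "\t"
    column_map: dict[str, str] = field(default_factory=dict)


@dataclass
class RowIssue:
    """A data row that could not be parsed into a valid record."""

    row: int  # 1-based data-row number (header excluded)
    message: str


def _load_frame(path: str | Path, dialect: DialectConfig, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    df = df.rename(columns=dialect.column_map)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(
            f"report {path} is missing required column(s) {missing}; "
            f"found {list(df.columns)} after applying the dialect column map"
        )
    return df


def _report_issues(path: str | Path, issues: list[RowIssue], sink: list[RowIssue] | None) -> None:
    for issue in issues:
        log.warning("%s: row %d skipped: %s", path, issue.row, issue.message)
    if sink is not None:
        sink.extend(issues)


def read_fixation_report(
    path: str | Path,
    dialect: DialectConfig | None = None,
    *,
    issues: list[RowIssue] | None = None,
) -> list[FixationRecord]:
    """Parse a fixation report into records.

    Rows whose required fields fail to parse or violate an invariant are
    reported (logged, and appended to ``issues`` when given) rather than
    silently dropped; the remaining rows are returned.
    """
    dialect = dialect or DialectConfig()
    required = [c for c in FIXATION_COLUMNS if c != "aoi"]
    df = _load_frame(path, dialect, required)
    if df.empty:
        log.warning("%s: report contains a header but no data rows", path)
        return []

    records: list[FixationRecord] = []
    found: list[RowIssue] = []
    has_aoi = "aoi" in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=1):
        r = row._asdict()
        try:
            aoi_raw = r.get("aoi", "") if has_aoi else ""
            rec = FixationRecord(
                subject_id=str(r["subject"]),
                condition=str(r["condition"]),
                trial_id=str(r["trial"]),
                index=int(r["index"]),
                t_start=float(r["t_start_ms"]),
                duration=float(r["duration_ms"]),
                x=float(r["x_px"]),
                y=float(r["y_px"]),
                aoi=None if aoi_raw in ("", "NA", "none", "None", ".") else int(float(aoi_raw)),
            ).validate()
        except (ValueError, ValidationError) as exc:
            found.append(RowIssue(row=i, message=str(exc)))
            continue
        records.append(rec)
    _report_issues(path, found, issues)
    return records


def read_saccade_report(
    path: str | Path,
    dialect: DialectConfig | None = None,
    *,
    issues: list[RowIssue] | None = None,
) -> list[SaccadeRecord]:
    """Parse a saccade report; error handling mirrors the fixation reader."""
    dialect = dialect or DialectConfig()
    df = _load_frame(path, dialect, SACCADE_COLUMNS)
    if df.empty:
        log.warning("%s: report contains a header but no data rows", path)
        return []

    records: list[SaccadeRecord] = []
    found: list[RowIssue] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        r = row._asdict()
        try:
            rec = SaccadeRecord(
                subject_id=str(r["subject"]),
                condition=str(r["condition"]),
                trial_id=str(r["trial"]),
                index=int(r["index"]),
                t_start=float(r["t_start_ms"]),
                duration=float(r["duration_ms"]),
                x_start=float(r["x_start_px"]),
                y_start=float(r["y_start_px"]),
                x_end=float(r["x_end_px"]),
                y_end=float(r["y_end_px"]),
                amplitude=float(r["amplitude_deg"]),
                velocity=float(r["velocity_degps"]),
            ).validate()
        except (ValueError, ValidationError) as exc:
            found.append(RowIssue(row=i, message=str(exc)))
            continue
        records.append(rec)
    _report_issues(path, found, issues)
    return records


def _fixation_row(f: FixationRecord) -> dict:
    return {
        "subject": f.subject_id,
        "condition": f.condition,
        "trial": f.trial_id,
        "index": f.index,
        "t_start_ms": repr(float(f.t_start)),
        "duration_ms": repr(float(f.duration)),
        "x_px": repr(float(f.x)),
        "y_px": repr(float(f.y)),
        "aoi": "" if f.aoi is None else f.aoi,
    }


def _saccade_row(s: SaccadeRecord) -> dict:
    return {
        "subject": s.subject_id,
        "condition": s.condition,
        "trial": s.trial_id,
        "index": s.index,
        "t_start_ms": repr(float(s.t_start)),
        "duration_ms": repr(float(s.duration)),
        "x_start_px": repr(float(s.x_start)),
        "y_start_px": repr(float(s.y_start)),
        "x_end_px": repr(float(s.x_end)),
        "y_end_px": repr(float(s.y_end)),
        "amplitude_deg": repr(float(s.amplitude)),
        "velocity_degps": repr(float(s.velocity)),
    }


def write_fixation_report(records: list[FixationRecord], path: str | Path) -> None:
    df = pd.DataFrame([_fixation_row(f) for f in records], columns=FIXATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def write_saccade_report(records: list[SaccadeRecord], path: str | Path) -> None:
    df = pd.DataFrame([_saccade_row(s) for s in records], columns=SACCADE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def write_trial_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False, columns=META_COLUMNS)


def read_trial_meta(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "condition": str, "trial": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"meta file {path} is missing column(s) {missing}")
    return df


def assemble_trials(
    fixations: list[FixationRecord],
    saccades: list[SaccadeRecord],
    meta: pd.DataFrame,
) -> list[Trial]:
    """Group event records into one :class:`Trial` per (subject, condition, trial).

    ``meta`` supplies trigger and end times per trial (columns as in
    :data:`META_COLUMNS`).  Events referencing a trial absent from ``meta``
    are a hard error; a subject missing one of the four conditions yields a
    completeness warning but still returns the trials that exist.
    """
    meta_keys: dict[tuple[str, str, str], tuple[float, float]] = {}
    for r in meta.itertuples(index=False):
        meta_keys[(str(r.subject), str(r.condition), str(r.trial))] = (
            float(r.trigger_end_ms),
            float(r.trial_end_ms),
        )

    events_by_key: dict[tuple[str, str, str], tuple[list, list]] = {
        k: ([], []) for k in meta_keys
    }
    orphans: set[tuple[str, str, str]] = set()
    for f in fixations:
        k = (f.subject_id, f.condition, f.trial_id)
        if k not in events_by_key:
            orphans.add(k)
            continue
        events_by_key[k][0].append(f)
    for s in saccades:
        k = (s.subject_id, s.condition, s.trial_id)
        if k not in events_by_key:
            orphans.add(k)
            continue
        events_by_key[k][1].append(s)
    if orphans:
        raise ValidationError(
            "events reference trial(s) absent from meta: "
            + ", ".join("/".join(k) for k in sorted(orphans))
        )

    trials = []
    for key, (fixs, saccs) in events_by_key.items():
        trigger_end, trial_end = meta_keys[key]
        trials.append(
            Trial(
                subject_id=key[0],
                condition=key[1],
                trial_id=key[2],
                fixations=fixs,
                saccades=saccs,
                trigger_end=trigger_end,
                trial_end=trial_end,
            ).sorted()
        )
    trials.sort(key=lambda t: t.key)

    by_subject: dict[str, set[str]] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, set()).add(t.condition)
    for subj, conds in sorted(by_subject.items()):
        missing_conds = [c for c in CONDITIONS if c not in conds]
        if missing_conds:
            log.warning("subject %s is missing condition(s) %s", subj, missing_conds)
    return trials


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table CSV; schema is validated before writing.

    Expected columns: ``subject``, ``condition``, then exactly the 29
    feature names (import order from :mod:`stroopgaze.features`).
    """
    from .features import FEATURE_NAMES  # late import to avoid a cycle

    expected = ["subject", "condition"] + list(FEATURE_NAMES)
    if list(table.columns) != expected:
        extra = [c for c in table.columns if c not in expected]
        missing = [c for c in expected if c not in table.columns]
        raise ConfigError(
            f"feature table schema mismatch: missing {missing}, unexpected {extra}"
        )
    out = table.copy()
    for c in FEATURE_NAMES:
        out[c] = out[c].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    from .features import FEATURE_NAMES

    df = pd.read_csv(path, dtype={"subject": str, "condition": str})
    expected = ["subject", "condition"] + list(FEATURE_NAMES)
    if list(df.columns) != expected:
        raise ConfigError(
            f"feature table {path} has columns {list(df.columns)}, expected {expected}"
        )
    return df
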