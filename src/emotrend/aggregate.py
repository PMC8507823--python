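"""Record ingest, calendar-week assignment, cohort identification, and
weekly engagement/emotion series.

Week convention: weeks are consecutive 7-day blocks starting on the first
Thursday of the year (for 2020, Thursday 2 January). The partial week
containing 1 January and the partial days after the last complete block are
excluded; for 2020 this leaves exactly 52 complete weeks with both the
first and the last calendar weeks of the year incomplete.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import (
    COMMUNITIES,
    DELETED_MARKER,
    MH,
    MH_COMMUNITIES,
    NMH,
    TEEN_COMMUNITY,
)

logger = logging.getLogger(__name__)

__all__ = [
    "IngestReport",
    "CohortAssignment",
    "ingest_records",
    "week_bounds",
    "assign_week",
    "assign_weeks",
    "identify_cohort",
    "weekly_series",
    "percent_change",
    "describe_percent_change",
    "scale_for_display",
]

RECORD_FIELDS = ("id", "author", "community", "created_utc", "title", "body", "kind")

#: Weekday on which analysis weeks start (Monday=0). Thursday-start blocks
#: are the unique 7-day alignment for which 2020 has 52 complete weeks and
#: both the first and last partial weeks are excluded.
WEEK_START_WEEKDAY = 3


# ---------------------------------------------------------------------------
# week assignment


def week_bounds(year: int, week_start_weekday: int = WEEK_START_WEEKDAY) -> List[Tuple[dt.date, dt.date]]:
    """Start/end dates (inclusive) of every complete week inside ``year``."""
    jan1 = dt.date(year, 1, 1)
    offset = (week_start_weekday - jan1.weekday()) % 7
    start = jan1 + dt.timedelta(days=offset)
    bounds = []
    while start + dt.timedelta(days=6) <= dt.date(year, 12, 31):
        bounds.append((start, start + dt.timedelta(days=6)))
        start += dt.timedelta(days=7)
    return bounds


def _year_epoch_bounds(year: int) -> Tuple[int, int, int]:
    """(year start epoch, first complete week start epoch, n complete weeks)."""
    bounds = week_bounds(year)
    epoch = dt.datetime(1970, 1, 1, tzinfo=dt.timezone.utc)
    year_start = int((dt.datetime(year, 1, 1, tzinfo=dt.timezone.utc) - epoch).total_seconds())
    first = int(
        (dt.datetime.combine(bounds[0][0], dt.time(), tzinfo=dt.timezone.utc) - epoch).total_seconds()
    )
    return year_start, first, len(bounds)


def assign_week(timestamp, year: int) -> Optional[int]:
    """Map a UTC timestamp (epoch seconds or datetime) to its 1-based complete
    week index within ``year``, or None if it falls in an excluded partial
    week at either end of the year.

    Raises ValueError for timestamps outside the year.
    """
    if isinstance(timestamp, dt.datetime):
        if timestamp.tzinfo is None:
            timestamp = timestamp.replace(tzinfo=dt.timezone.utc)
        ts = timestamp.timestamp()
    else:
        ts = float(timestamp)
    year_start, first, n_weeks = _year_epoch_bounds(year)
    next_year_start = year_start + (366 if _is_leap(year) else 365) * 86400
    if not year_start <= ts < next_year_start:
        raise ValueError(f"timestamp {timestamp!r} outside year {year}")
    idx = math.floor((ts - first) / (7 * 86400))
    if idx < 0 or idx >= n_weeks:
        return None
    return int(idx) + 1


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def assign_weeks(created_utc: Iterable, year: int) -> pd.Series:
    """Vectorized :func:`assign_week`; excluded timestamps map to <NA>."""
    ts = pd.to_numeric(pd.Series(created_utc), errors="raise").astype(float)
    year_start, first, n_weeks = _year_epoch_bounds(year)
    next_year_start = year_start + (366 if _is_leap(year) else 365) * 86400
    if ((ts < year_start) | (ts >= next_year_start)).any():
        bad = ts[(ts < year_start) | (ts >= next_year_start)]
        raise ValueError(f"{len(bad)} timestamps outside year {year}")
    idx = np.floor((ts.to_numpy() - first) / (7 * 86400)).astype(int)
    week = pd.array(idx + 1, dtype="Int64")
    week[(idx < 0) | (idx >= n_weeks)] = pd.NA
    return pd.Series(week, index=ts.index, name="week")


# ---------------------------------------------------------------------------
# ingest


@dataclass
class IngestReport:
    n_read: int = 0
    n_kept: int = 0
    n_deleted_dropped: int = 0
    n_malformed: int = 0


def _validate_frame(df: pd.DataFrame, report: IngestReport) -> pd.DataFrame:
    missing = [c for c in RECORD_FIELDS if c not in df.columns]
    if missing:
        raise ValueError(f"input is missing required fields {missing}")
    score_cols = [c for c in ("anger", "fear", "happiness", "sadness", "surprise",
                              "compound", "n_tokens") if c in df.columns]
    df = df.loc[:, list(RECORD_FIELDS) + score_cols].copy()
    df["title"] = df["title"].fillna("")
    df["body"] = df["body"].fillna("")
    ok = (
        df["author"].notna()
        & (df["author"].astype(str).str.len() > 0)
        & df["community"].isin(COMMUNITIES)
        & df["kind"].isin(("post", "comment"))
        & pd.to_numeric(df["created_utc"], errors="coerce").notna()
    )
    report.n_malformed += int((~ok).sum())
    df = df.loc[ok]
    deleted = df["author"] == DELETED_MARKER
    report.n_deleted_dropped = int(deleted.sum())
    df = df.loc[~deleted].reset_index(drop=True)
    df["created_utc"] = pd.to_numeric(df["created_utc"]).astype(float)
    report.n_kept = len(df)
    return df


def ingest_records(
    path,
    format: Optional[str] = None,
    max_malformed_fraction: float = 0.05,
) -> Tuple[pd.DataFrame, IngestReport]:
    """Read and validate a corpus file (NDJSON or CSV).

    Records by deleted accounts (author == ``[deleted]``) are dropped with a
    logged count; malformed lines are counted and the run aborts if they
    exceed ``max_malformed_fraction`` of the input.
    """
    path = str(path)
    if format is None:
        format = "csv" if path.endswith(".csv") else "ndjson"
    report = IngestReport()
    if format == "ndjson":
        rows, malformed = [], 0
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                report.n_read += 1
                try:
                    rows.append(json.loads(line))
                except json.JSONDecodeError:
                    malformed += 1
        report.n_malformed = malformed
        df = pd.DataFrame(rows) if rows else pd.DataFrame(columns=RECORD_FIELDS)
    elif format == "csv":
        df = pd.read_csv(path, dtype={"title": str, "body": str}, keep_default_na=False, na_values=[""])
        report.n_read = len(df)
    else:
        raise ValueError(f"unknown format {format!r}")

    if report.n_read == 0:
        warnings.warn(f"{path}: empty input", stacklevel=2)
        return pd.DataFrame(columns=RECORD_FIELDS), report

    df = _validate_frame(df, report)
    if report.n_malformed > max_malformed_fraction * report.n_read:
        raise ValueError(
            f"{report.n_malformed}/{report.n_read} malformed records exceeds "
            f"the allowed fraction {max_malformed_fraction}"
        )
    if report.n_deleted_dropped:
        logger.info("dropped %d deleted-account records", report.n_deleted_dropped)
    return df, report


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortAssignment:
    """Username -> cohort map over teen-community authors.

    MH = teen-community authors with at least one item in any mental-health
    community within the year; NMH = the remaining teen-community authors.
    Mental-health-community authors never seen in the teen community are
    excluded from all analyses.
    """

    labels: Dict[str, str] = field(default_factory=dict)
    n_excluded_mh_only: int = 0

    @property
    def n_mh(self) -> int:
        return sum(1 for v in self.labels.values() if v == MH)

    @property
    def n_nmh(self) -> int:
        return sum(1 for v in self.labels.values() if v == NMH)

    @property
    def mh_fraction(self) -> float:
        return self.n_mh / len(self.labels) if self.labels else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["author", "cohort"]
        )


def identify_cohort(records: pd.DataFrame) -> CohortAssignment:
    """Username matching: label every teen-community author MH or NMH."""
    teen_authors = set(records.loc[records["community"] == TEEN_COMMUNITY, "author"])
    mh_authors = set(records.loc[records["community"].isin(MH_COMMUNITIES), "author"])
    labels = {a: (MH if a in mh_authors else NMH) for a in teen_authors}
    return CohortAssignment(labels=labels, n_excluded_mh_only=len(mh_authors - teen_authors))


# ---------------------------------------------------------------------------
# weekly series


def weekly_series(
    records: pd.DataFrame,
    key: str = "community",
    assignment: Optional[CohortAssignment] = None,
    n_weeks: int = 52,
    year: int = 2020,
) -> pd.DataFrame:
    """Tidy weekly engagement/emotion series.

    ``key='community'`` groups by community, keeping only username-matched
    (teen-community) authors in the mental-health communities.
    ``key='cohort'`` restricts to the teen community and groups by MH/NMH.

    Per week and key: ``n_participants`` (distinct authors), ``n_items``,
    ``posts_per_participant`` (NaN when no items), and ``mean_compound``
    (item-weighted mean of per-item compound scores when present).
    Exactly ``n_weeks`` rows are emitted per key; empty weeks are flagged
    via n_participants == 0.
    """
    if key not in ("community", "cohort"):
        raise ValueError("key must be 'community' or 'cohort'")
    df = records.copy()
    if "week" not in df.columns:
        df["week"] = assign_weeks(df["created_utc"], year)
    df = df.loc[df["week"].notna()]
    df["week"] = df["week"].astype(int)

    if assignment is None:
        assignment = identify_cohort(df)
    matched = set(assignment.labels)

    if key == "community":
        keep = (df["community"] == TEEN_COMMUNITY) | df["author"].isin(matched)
        df = df.loc[keep]
        df["key"] = df["community"]
        keys = list(COMMUNITIES)
    else:
        df = df.loc[df["community"] == TEEN_COMMUNITY]
        df["key"] = df["author"].map(assignment.labels)
        keys = [NMH, MH]

    has_scores = "compound" in df.columns
    agg = {"author": ("author", "nunique"), "n_items": ("id", "size")}
    if has_scores:
        agg["mean_compound"] = ("compound", "mean")
    grouped = df.groupby(["key", "week"]).agg(**agg).reset_index()
    grouped = grouped.rename(columns={"author": "n_participants"})

    full = pd.MultiIndex.from_product([keys, range(1, n_weeks + 1)], names=["key", "week"])
    out = grouped.set_index(["key", "week"]).reindex(full).reset_index()
    out["n_participants"] = out["n_participants"].fillna(0).astype(int)
    out["n_items"] = out["n_items"].fillna(0).astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["posts_per_participant"] = np.where(
            out["n_participants"] > 0, out["n_items"] / out["n_participants"], np.nan
        )
    if not has_scores:
        out["mean_compound"] = np.nan
    out.attrs["emotion_mean_weighting"] = "items"
    out.attrs["week_convention"] = "thursday-start complete weeks"
    return out


# ---------------------------------------------------------------------------
# small helpers


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def percent_change(v1: float, v2: float) -> int:
    """Signed integer percent change from ``v1`` to ``v2``, rounded
    half-away-from-zero. Requires ``v1 > 0``."""
    if v1 <= 0:
        raise ValueError(f"baseline value must be positive, got {v1}")
    return _round_half_away(100.0 * (v2 - v1) / v1)


def describe_percent_change(v1: float, v2: float) -> Tuple[int, str]:
    """Positive magnitude plus direction label ('increase'/'decline'/'none');
    declines are reported as ``round(100*(v1-v2)/v1)``."""
    pct = percent_change(v1, v2)
    if pct > 0:
        return pct, "increase"
    if pct < 0:
        return -pct, "decline"
    return 0, "none"


def scale_for_display(values, factor: float):
    """Multiply a series by a display factor (figures only; analysis paths
    never consume scaled values). Frames get ``attrs['display_scale']``."""
    if factor <= 0:
        raise ValueError("display scale factor must be positive")
    if isinstance(values, pd.DataFrame):
        out = values.copy()
        num = out.select_dtypes("number").columns
        out[num] = out[num] * factor
        out.attrs["display_scale"] = factor
        return out
    if isinstance(values, pd.Series):
        out = values * factor
        out.attrs["display_scale"] = factor
        return out
    return np.asarray(values, dtype=float) * factor
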