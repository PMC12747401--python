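"""Daily-report records: reading, validation, same-day merging, week indexing.

The raw unit is one submission by one participant on one calendar day: a
well-being score, a team-atmosphere score (both on the 11-point 0-10 grid)
and a short free-text diary. Participants may submit more than once per day;
same-day submissions are merged by averaging the scores and concatenating
the diaries. The analysis clock is a sequence of fixed seven-day windows
anchored at the study start date; the trailing window may be shorter when
the study length is not a multiple of seven.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from pathlib import Path
from typing import Iterable, Sequence

from pydantic import BaseModel, Field, field_validator

__all__ = [
    "DailyReport",
    "ParticipantDay",
    "WeekWindow",
    "IHSRecord",
    "SchemaError",
    "ValidationError",
    "read_reports",
    "write_reports",
    "merge_same_day",
    "assign_weeks",
    "week_windows",
    "read_ihs",
    "write_participant_days",
]

REPORT_FIELDS = ("participant_id", "team_id", "date", "wellbeing", "atmosphere", "diary")

N_IHS_ITEMS = 9


class SchemaError(ValueError):
    """A required column/key is missing from an input file."""


class ValidationError(ValueError):
    """A row holds an out-of-range or inconsistent value."""


class DailyReport(BaseModel):
    """One raw submission. Scores live on the closed interval [0, 10]."""

    participant_id: str
    team_id: str
    date: dt.date
    wellbeing: float = Field(ge=0, le=10)
    atmosphere: float = Field(ge=0, le=10)
    diary: str = ""
    submitted_at: dt.datetime | None = None

    @field_validator("participant_id", "team_id")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("identifier must be non-empty")
        return v


class ParticipantDay(BaseModel):
    """Same-day-merged record: one per (participant, date).

    Scores are arithmetic means of that day's submissions (possibly
    fractional); diaries are newline-joined in submission order.
    """

    participant_id: str
    team_id: str
    date: dt.date
    wellbeing: float = Field(ge=0, le=10)
    atmosphere: float = Field(ge=0, le=10)
    diary: str = ""
    n_submissions: int = Field(ge=1)
    week: int | None = None


class WeekWindow(BaseModel):
    """One analysis window: seven consecutive days (the last may be shorter)."""

    index: int = Field(ge=1)
    start_date: dt.date
    end_date: dt.date

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


class IHSRecord(BaseModel):
    """Nine-item interdependent-happiness responses for one participant.

    The response scale is whatever the administering survey used; the
    pipeline never assumes a particular ordinal range.
    """

    participant_id: str
    team_id: str
    items: list[float]

    @field_validator("items")
    @classmethod
    def _nine(cls, v: list[float]) -> list[float]:
        if len(v) != N_IHS_ITEMS:
            raise ValueError(f"expected {N_IHS_ITEMS} items, got {len(v)}")
        return v

    @property
    def score(self) -> float:
        """Individual score: the mean of the nine items."""
        return sum(self.items) / N_IHS_ITEMS


def _parse_report_row(row: dict, rownum: int) -> DailyReport:
    try:
        ts = row.get("submitted_at")
        return DailyReport(
            participant_id=str(row["participant_id"]),
            team_id=str(row["team_id"]),
            date=row["date"],
            wellbeing=float(row["wellbeing"]),
            atmosphere=float(row["atmosphere"]),
            diary=str(row.get("diary") or ""),
            submitted_at=ts if ts not in (None, "") else None,
        )
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"row {rownum}: {exc}") from exc


def read_reports(path: str | Path, format: str | None = None) -> list[DailyReport]:
    """Read daily reports from a CSV (header row) or JSONL file.

    ``format`` is ``"csv"`` or ``"jsonl"``; when omitted it is inferred from
    the file suffix. Missing columns raise :class:`SchemaError` naming the
    column; out-of-range scores raise :class:`ValidationError` with the row
    number (1-based, excluding the header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in {".jsonl", ".ndjson", ".json"} else "csv"
    if format not in {"csv", "jsonl"}:
        raise ValueError(f"unknown format {format!r}")

    rows: list[dict] = []
    if format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in REPORT_FIELDS if c not in header]
            if missing:
                raise SchemaError(f"missing column(s): {', '.join(missing)}")
            rows = list(reader)
    else:
        with path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                obj = json.loads(line)
                missing = [c for c in REPORT_FIELDS if c not in obj]
                if missing:
                    raise SchemaError(f"line {i}: missing key(s): {', '.join(missing)}")
                rows.append(obj)
    return [_parse_report_row(row, i) for i, row in enumerate(rows, start=1)]


def write_reports(reports: Iterable[DailyReport], path: str | Path, format: str | None = None) -> None:
    """Write reports in the same CSV/JSONL dialects :func:`read_reports` accepts."""
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in {".jsonl", ".ndjson", ".json"} else "csv"
    recs = [
        {
            "participant_id": r.participant_id,
            "team_id": r.team_id,
            "date": r.date.isoformat(),
            "wellbeing": repr(r.wellbeing),
            "atmosphere": repr(r.atmosphere),
            "diary": r.diary,
            "submitted_at": r.submitted_at.isoformat() if r.submitted_at else "",
        }
        for r in reports
    ]
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(REPORT_FIELDS) + ["submitted_at"])
            writer.writeheader()
            writer.writerows(recs)
    else:
        with path.open("w", encoding="utf-8") as fh:
            for rec in recs:
                rec = dict(rec)
                rec["wellbeing"] = float(rec["wellbeing"])
                rec["atmosphere"] = float(rec["atmosphere"])
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def merge_same_day(reports: Sequence[DailyReport]) -> list[ParticipantDay]:
    """Collapse same-day submissions into one record per (participant, date).

    Scores are averaged; diaries are joined with a newline, ordered by
    ``submitted_at`` when every same-day submission carries one, else by
    input order. Conflicting team ids within a (participant, date) group
    signal corrupted input and raise :class:`ValidationError`.
    """
    groups: dict[tuple[str, dt.date], list[tuple[int, DailyReport]]] = {}
    for pos, rep in enumerate(reports):
        groups.setdefault((rep.participant_id, rep.date), []).append((pos, rep))

    merged: list[ParticipantDay] = []
    for (pid, date), members in groups.items():
        teams = {r.team_id for _, r in members}
        if len(teams) > 1:
            raise ValidationError(
                f"participant {pid} on {date} reports conflicting team ids: {sorted(teams)}"
            )
        if all(r.submitted_at is not None for _, r in members):
            members = sorted(members, key=lambda pr: (pr[1].submitted_at, pr[0]))
        # else keep input order (stable: groups preserve it)
        reps = [r for _, r in members]
        merged.append(
            ParticipantDay(
                participant_id=pid,
                team_id=reps[0].team_id,
                date=date,
                wellbeing=sum(r.wellbeing for r in reps) / len(reps),
                atmosphere=sum(r.atmosphere for r in reps) / len(reps),
                diary="\n".join(r.diary for r in reps),
                n_submissions=len(reps),
            )
        )
    merged.sort(key=lambda m: (m.date, m.team_id, m.participant_id))
    return merged


def week_windows(anchor_date: dt.date, window_end: dt.date) -> list[WeekWindow]:
    """Enumerate the seven-day windows tiling [anchor_date, window_end]."""
    if anchor_date > window_end:
        raise ValueError("anchor_date must not be after window_end")
    windows = []
    start = anchor_date
    idx = 1
    while start <= window_end:
        end = min(start + dt.timedelta(days=6), window_end)
        windows.append(WeekWindow(index=idx, start_date=start, end_date=end))
        start = end + dt.timedelta(days=1)
        idx += 1
    return windows


def assign_weeks(
    records: Sequence[ParticipantDay],
    anchor_date: dt.date,
    window_end: dt.date,
) -> tuple[list[ParticipantDay], list[WeekWindow]]:
    """Annotate each record with its 1-based week index.

    week = floor((date - anchor)/7) + 1. A record dated outside
    [anchor_date, window_end] raises :class:`ValidationError` naming it.
    """
    windows = week_windows(anchor_date, window_end)
    out = []
    for rec in records:
        if not anchor_date <= rec.date <= window_end:
            raise ValidationError(
                f"record for participant {rec.participant_id} dated {rec.date} "
                f"falls outside the study window [{anchor_date}, {window_end}]"
            )
        week = (rec.date - anchor_date).days // 7 + 1
        out.append(rec.model_copy(update={"week": week}))
    return out, windows


def read_ihs(path: str | Path) -> list[IHSRecord]:
    """Read nine-item scale responses from CSV: participant_id, team_id, item_1..item_9."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        item_cols = [f"item_{i}" for i in range(1, N_IHS_ITEMS + 1)]
        missing = [c for c in ["participant_id", "team_id", *item_cols] if c not in header]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        out = []
        for i, row in enumerate(reader, start=1):
            try:
                out.append(
                    IHSRecord(
                        participant_id=str(row["participant_id"]),
                        team_id=str(row["team_id"]),
                        items=[float(row[c]) for c in item_cols],
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
    return out


def write_participant_days(days: Iterable[ParticipantDay], path: str | Path) -> None:
    """Audit output: the canonical merged table as CSV."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["participant_id", "team_id", "date", "week", "wellbeing", "atmosphere", "n_submissions", "diary"]
        )
        for d in days:
            writer.writerow(
                [
                    d.participant_id,
                    d.team_id,
                    d.date.isoformat(),
                    "" if d.week is None else d.week,
                    repr(d.wellbeing),
                    repr(d.atmosphere),
                    d.n_submissions,
                    d.diary,
                ]
            )
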