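"""End-to-end orchestration: raw reports -> indices -> correlation tables.

This is the library face of the command-line interface: each stage is a
plain function over DataFrames and record lists, so scripted analyses and
the CLI share one code path.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .association import (
    ALPHA_OVERALL,
    ALPHA_STRATA,
    MIN_WEEKLY_VALUES_IHS,
    MIN_WEEKS_PER_TEAM,
    SURROGATE_THRESHOLD,
    CorrelationResult,
    build_table,
    correlate_overall,
    correlate_per_team,
    correlate_per_week,
    team_ihs,
    validate_surrogate,
)
from .embeddings import EmbeddingTable
from .records import (
    DailyReport,
    IHSRecord,
    ParticipantDay,
    WeekWindow,
    assign_weeks,
    merge_same_day,
)
from .ssi import ssi_table
from .tsi import tsi_table

__all__ = [
    "PipelineConfig",
    "days_frame",
    "prepare_days",
    "compute_indices",
    "run_correlations",
    "correlation_frame",
    "write_manifest",
]


class PipelineConfig(BaseModel):
    """Run settings; defaults mirror the standard analysis conventions."""

    reports_path: str = "reports.csv"
    ihs_path: str = "ihs.csv"
    embeddings_path: str = "embeddings.txt"
    output_dir: str = "out"

    anchor_date: dt.date = dt.date(2022, 9, 1)
    end_date: dt.date = dt.date(2022, 10, 31)

    ddof_mode: str = "population"
    sim_transform: str = "neg"
    ground_metric: str = "euclidean"

    min_members_per_day: int = Field(default=2, ge=2)
    min_weeks_per_team: int = MIN_WEEKS_PER_TEAM
    min_weekly_values_ihs: int = MIN_WEEKLY_VALUES_IHS
    surrogate_threshold: float = SURROGATE_THRESHOLD
    alpha_overall: float = ALPHA_OVERALL
    alpha_strata: float = ALPHA_STRATA

    min_df: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = json.loads(self.model_dump_json())
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def content_hash(self) -> str:
        """Hash of the analysis settings (file locations excluded)."""
        data = self.model_dump(exclude={"reports_path", "ihs_path", "embeddings_path", "output_dir"})
        return hashlib.sha256(json.dumps(data, sort_keys=True, default=str).encode()).hexdigest()[:16]


def days_frame(days: Sequence[ParticipantDay]) -> pd.DataFrame:
    """Merged records as a DataFrame (one row per participant-day)."""
    return pd.DataFrame(
        {
            "participant_id": [d.participant_id for d in days],
            "team_id": [d.team_id for d in days],
            "date": [d.date for d in days],
            "week": [d.week for d in days],
            "wellbeing": [d.wellbeing for d in days],
            "atmosphere": [d.atmosphere for d in days],
            "diary": [d.diary for d in days],
            "n_submissions": [d.n_submissions for d in days],
        }
    )


def prepare_days(
    reports: Sequence[DailyReport],
    anchor_date: dt.date,
    end_date: dt.date,
) -> tuple[pd.DataFrame, list[WeekWindow]]:
    """Merge same-day submissions and attach week indices."""
    merged = merge_same_day(reports)
    annotated, windows = assign_weeks(merged, anchor_date, end_date)
    return days_frame(annotated), windows


def compute_indices(
    days: pd.DataFrame,
    windows: Sequence[WeekWindow],
    embeddings: EmbeddingTable | None = None,
    ddof_mode: str = "population",
    sim_transform: str = "neg",
    ground_metric: str = "euclidean",
) -> tuple[pd.DataFrame, list]:
    """SSI (+ TSI when embeddings are given) merged into the team-week table."""
    ssi = ssi_table(days, ddof_mode=ddof_mode)
    pairs: list = []
    tsi = None
    if embeddings is not None:
        tsi, pairs = tsi_table(days, embeddings, transform=sim_transform, metric=ground_metric)
    table = build_table(days, ssi, tsi, n_weeks=len(windows))
    return table, pairs


def run_correlations(
    table: pd.DataFrame,
    alpha_overall: float = ALPHA_OVERALL,
    alpha_strata: float = ALPHA_STRATA,
    min_weeks: int = MIN_WEEKS_PER_TEAM,
) -> list[CorrelationResult]:
    """Overall, per-team and per-week analyses for every present index."""
    results: list[CorrelationResult] = []
    for kind in ("ssi", "tsi"):
        if not table[f"{kind}_eligible"].any():
            continue
        overall = correlate_overall(table, kind, alpha=alpha_overall)
        results.append(
            CorrelationResult(
                scope=f"{kind}:{overall.scope}", r=overall.r, p=overall.p, n=overall.n,
                alpha=overall.alpha, significant=overall.significant,
            )
        )
        for res in correlate_per_team(table, kind, min_weeks=min_weeks, alpha=alpha_strata):
            results.append(
                CorrelationResult(
                    scope=f"{kind}:{res.scope}", r=res.r, p=res.p, n=res.n,
                    alpha=res.alpha, significant=res.significant,
                )
            )
        for res in correlate_per_week(table, kind, alpha=alpha_strata):
            results.append(
                CorrelationResult(
                    scope=f"{kind}:{res.scope}", r=res.r, p=res.p, n=res.n,
                    alpha=res.alpha, significant=res.significant,
                )
            )
    return results


def correlation_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scope": [r.scope for r in results],
            "r": [r.r for r in results],
            "p": [r.p for r in results],
            "n": [r.n for r in results],
            "alpha": [r.alpha for r in results],
            "significant": [r.significant for r in results],
        }
    )


def run_ihs_validation(
    table: pd.DataFrame,
    ihs_records: Sequence[IHSRecord],
    min_weekly_values: int = MIN_WEEKLY_VALUES_IHS,
    threshold: float = SURROGATE_THRESHOLD,
) -> pd.DataFrame:
    """Surrogate validation rows for each index present in the table."""
    scores = team_ihs(ihs_records)
    rows = []
    for kind in ("ssi", "tsi"):
        if not table[f"{kind}_eligible"].any():
            continue
        res, ok = validate_surrogate(
            table, kind, scores, min_weekly_values=min_weekly_values, threshold=threshold
        )
        rows.append(
            {"index": kind, "r": res.r, "p": res.p, "n_teams": res.n, "passes": ok, "threshold": threshold}
        )
    return pd.DataFrame(rows)


def write_manifest(
    path: str | Path,
    config: PipelineConfig,
    row_counts: dict[str, int],
    stage: str,
) -> None:
    """Plain-text run manifest: config hash, seed, version, row counts."""
    lines = [
        f"stage: {stage}",
        f"package_version: {__version__}",
        f"config_hash: {config.content_hash()}",
        f"seed: {config.seed}",
    ]
    for name, n in sorted(row_counts.items()):
        lines.append(f"rows.{name}: {n}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
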