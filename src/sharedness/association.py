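"""Team-week analysis table and correlation analyses.

The analysis unit is the team-week. The table enumerates every candidate
unit (each observed team crossed with each window), attaches the two
sharedness indices, flags eligibility separately for each (SSI needs at
least one day with two or more reporters; TSI needs at least two usable
weekly documents), and carries the weekly mean of individual well-being.
For SSI correlations the well-being mean is taken over the same eligible
days that fed the index; for week-level TSI eligibility it is taken over
all of the week's member-days, keeping predictor and outcome on a single
observation window.

Correlations are two-sided Pearson. The overall analysis uses alpha =
0.05; per-team and per-week strata are exploratory, reported at alpha =
0.10 with unadjusted p-values (a Benjamini-Hochberg adjustment is
available but off by default). Zero-variance strata are reported as
undefined (NaN), never as r = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import IHSRecord

__all__ = [
    "CorrelationResult",
    "TeamIHS",
    "build_table",
    "pearson",
    "correlate_overall",
    "correlate_per_team",
    "correlate_per_week",
    "team_ihs",
    "validate_surrogate",
    "adjust_bh",
]

ALPHA_OVERALL = 0.05
ALPHA_STRATA = 0.10
MIN_WEEKS_PER_TEAM = 4
MIN_WEEKLY_VALUES_IHS = 3
SURROGATE_THRESHOLD = 0.4

_WB_COL = {"ssi": "wb_eligible_days", "tsi": "wb_all_days"}


@dataclass(frozen=True)
class CorrelationResult:
    """One Pearson analysis: scope label, r, two-sided p, n, significance flag."""

    scope: str
    r: float
    p: float
    n: int
    alpha: float
    significant: bool

    @property
    def undefined(self) -> bool:
        return math.isnan(self.r)


@dataclass(frozen=True)
class TeamIHS:
    """Team-level harmony-scale score: individual nine-item means averaged within team."""

    team_id: str
    mean_ihs: float
    n_respondents: int


class DegenerateDataError(ValueError):
    """Correlation undefined: one side has zero variance (or too few points)."""


def pearson(x: Sequence[float], y: Sequence[float], scope: str = "overall", alpha: float = ALPHA_OVERALL) -> CorrelationResult:
    """Two-sided Pearson correlation with the t-distribution p-value.

    Requires n >= 3 and nonzero variance on both sides; degenerate input
    raises :class:`DegenerateDataError` naming the offending side.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    n = x.size
    if n < 3:
        raise DegenerateDataError(f"{scope}: need >= 3 paired observations, got {n}")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise DegenerateDataError(f"{scope}: zero variance on {name}")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(scope=scope, r=float(r), p=float(p), n=n, alpha=alpha, significant=bool(p < alpha))


def _undefined(scope: str, n: int, alpha: float) -> CorrelationResult:
    return CorrelationResult(scope=scope, r=math.nan, p=math.nan, n=n, alpha=alpha, significant=False)


def build_table(
    participant_days: pd.DataFrame,
    ssi_values: pd.DataFrame,
    tsi_values: pd.DataFrame | None = None,
    n_weeks: int | None = None,
) -> pd.DataFrame:
    """Assemble the team-week table over the full candidate grid.

    ``participant_days`` needs columns participant_id, team_id, date, week,
    wellbeing, atmosphere; ``ssi_values`` is the output of
    :func:`sharedness.ssi.ssi_table`; ``tsi_values`` (optional) needs
    team_id, week, tsi, n_tsi_members. Index values keyed to a (team, week)
    absent from the observed grid raise an error listing the orphans.
    """
    days = participant_days
    teams = sorted(days["team_id"].unique())
    if n_weeks is None:
        n_weeks = int(days["week"].max())
    grid = pd.MultiIndex.from_product([teams, range(1, n_weeks + 1)], names=["team_id", "week"])

    observed = set(map(tuple, days[["team_id", "week"]].drop_duplicates().itertuples(index=False)))
    for name, table in (("ssi", ssi_values), ("tsi", tsi_values)):
        if table is None:
            continue
        keys = set(map(tuple, table[["team_id", "week"]].itertuples(index=False)))
        orphans = sorted(k for k in keys if k not in observed)
        if orphans:
            raise KeyError(f"{name} values keyed to unobserved team-weeks: {orphans}")

    # daily reporter counts determine SSI-eligible days
    daily_n = days.groupby(["team_id", "week", "date"])["participant_id"].size().rename("n_reporters")
    days = days.join(daily_n, on=["team_id", "week", "date"])

    wb_all = days.groupby(["team_id", "week"])["wellbeing"].mean().rename("wb_all_days")
    elig = days[days["n_reporters"] >= 2]
    wb_elig = elig.groupby(["team_id", "week"])["wellbeing"].mean().rename("wb_eligible_days")

    out = pd.DataFrame(index=grid)
    out = out.join(wb_all).join(wb_elig)
    out = out.join(ssi_values.set_index(["team_id", "week"])[["ssi", "n_eligible_days", "n_member_days"]])
    if tsi_values is not None:
        cols = [c for c in ("tsi", "n_tsi_members") if c in tsi_values.columns]
        out = out.join(tsi_values.set_index(["team_id", "week"])[cols])
    else:
        out["tsi"] = math.nan
    out = out.reset_index()
    out["n_eligible_days"] = out["n_eligible_days"].fillna(0).astype(int)
    out["n_member_days"] = out["n_member_days"].fillna(0).astype(int)
    out["ssi_eligible"] = out["ssi"].notna()
    out["tsi_eligible"] = out["tsi"].notna()
    return out


def _eligible(table: pd.DataFrame, index_kind: str) -> pd.DataFrame:
    if index_kind not in _WB_COL:
        raise ValueError(f"index_kind must be 'ssi' or 'tsi', got {index_kind!r}")
    wb = _WB_COL[index_kind]
    sub = table[table[f"{index_kind}_eligible"]]
    return sub[sub[wb].notna()]


def correlate_overall(table: pd.DataFrame, index_kind: str, alpha: float = ALPHA_OVERALL) -> CorrelationResult:
    """Index vs mean well-being over all eligible team-weeks."""
    sub = _eligible(table, index_kind)
    return pearson(sub[index_kind], sub[_WB_COL[index_kind]], scope="overall", alpha=alpha)


def correlate_per_team(
    table: pd.DataFrame,
    index_kind: str,
    min_weeks: int = MIN_WEEKS_PER_TEAM,
    alpha: float = ALPHA_STRATA,
) -> list[CorrelationResult]:
    """One exploratory correlation per team contributing >= min_weeks units."""
    sub = _eligible(table, index_kind)
    out = []
    for team, grp in sub.groupby("team_id", sort=True):
        if len(grp) < min_weeks:
            continue
        scope = f"team:{team}"
        try:
            out.append(pearson(grp[index_kind], grp[_WB_COL[index_kind]], scope=scope, alpha=alpha))
        except DegenerateDataError:
            out.append(_undefined(scope, len(grp), alpha))
    return out


def correlate_per_week(
    table: pd.DataFrame,
    index_kind: str,
    min_teams: int = 3,
    alpha: float = ALPHA_STRATA,
) -> list[CorrelationResult]:
    """One exploratory correlation per week with >= min_teams eligible teams."""
    sub = _eligible(table, index_kind)
    out = []
    for week, grp in sub.groupby("week", sort=True):
        if len(grp) < min_teams:
            continue
        scope = f"week:{week}"
        try:
            out.append(pearson(grp[index_kind], grp[_WB_COL[index_kind]], scope=scope, alpha=alpha))
        except DegenerateDataError:
            out.append(_undefined(scope, len(grp), alpha))
    return out


def team_ihs(ihs_records: Sequence[IHSRecord]) -> list[TeamIHS]:
    """Average the nine items per respondent, then average within team."""
    by_team: dict[str, list[float]] = {}
    for rec in ihs_records:
        by_team.setdefault(rec.team_id, []).append(rec.score)
    return [
        TeamIHS(team_id=t, mean_ihs=float(np.mean(scores)), n_respondents=len(scores))
        for t, scores in sorted(by_team.items())
    ]


def validate_surrogate(
    table: pd.DataFrame,
    index_kind: str,
    team_scores: Sequence[TeamIHS],
    min_weekly_values: int = MIN_WEEKLY_VALUES_IHS,
    threshold: float = SURROGATE_THRESHOLD,
    alpha: float = ALPHA_OVERALL,
) -> tuple[CorrelationResult, bool]:
    """Team-level convergent validity against the harmony scale.

    Per-team index means are taken over all available weekly values; teams
    with fewer than ``min_weekly_values`` are excluded. Passes iff the
    team-level Pearson r meets the surrogate threshold (default 0.4).
    """
    sub = table[table[f"{index_kind}_eligible"]]
    counts = sub.groupby("team_id")[index_kind].agg(["mean", "size"])
    qualified = counts[counts["size"] >= min_weekly_values]["mean"]
    scale = {ts.team_id: ts.mean_ihs for ts in team_scores}
    common = [t for t in qualified.index if t in scale]
    res = pearson(
        [qualified[t] for t in common],
        [scale[t] for t in common],
        scope=f"ihs:{index_kind}",
        alpha=alpha,
    )
    return res, bool(res.r >= threshold)


def adjust_bh(results: Sequence[CorrelationResult]) -> list[CorrelationResult]:
    """Benjamini-Hochberg adjusted copies (optional; off by default upstream)."""
    defined = [r for r in results if not r.undefined]
    if not defined:
        return list(results)
    adj = stats.false_discovery_control([r.p for r in defined], method="bh")
    adj_iter = iter(adj)
    out = []
    for r in results:
        if r.undefined:
            out.append(r)
        else:
            q = float(next(adj_iter))
            out.append(replace(r, p=q, significant=bool(q < r.alpha)))
    return out
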