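"""Score-based sharedness index (SSI).

For a team-week, SSI is the negated mean of the daily within-team standard
deviations of the team-atmosphere scores, taken over the week's *eligible*
days — days on which at least two members reported. SSI is 0 when members
agree exactly on every eligible day, grows more negative as assessments
diverge, and is missing (NaN) for a team-week without a single eligible day.

The default standard deviation is the population SD (ddof=0): the members
reporting on a day are the complete enumeration of that day's raters, not a
sample from a larger pool. The sample SD (ddof=1) is available via
``ddof_mode="sample"`` for sensitivity analyses.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .records import ParticipantDay

__all__ = ["daily_sigma", "compute_ssi", "ssi_table", "MIN_MEMBERS_PER_DAY"]

MIN_MEMBERS_PER_DAY = 2

_DDOF = {"population": 0, "sample": 1}


def _ddof(ddof_mode: str) -> int:
    try:
        return _DDOF[ddof_mode]
    except KeyError:
        raise ValueError(f"ddof_mode must be one of {sorted(_DDOF)}, got {ddof_mode!r}") from None


def daily_sigma(atmosphere_scores: Sequence[float], ddof_mode: str = "population") -> float:
    """Within-team SD of one day's atmosphere scores (>= 2 scores required)."""
    scores = np.asarray(atmosphere_scores, dtype=float)
    if scores.size < MIN_MEMBERS_PER_DAY:
        raise ValueError(
            f"daily sigma needs >= {MIN_MEMBERS_PER_DAY} scores; days with fewer "
            "contributors must be excluded upstream"
        )
    return float(np.std(scores, ddof=_ddof(ddof_mode)))


def compute_ssi(records: Sequence[ParticipantDay], ddof_mode: str = "population") -> float:
    """SSI for one team-week's merged records; NaN when no day is eligible.

    All records must share one team and one week — the caller groups.
    """
    if not records:
        return math.nan
    teams = {r.team_id for r in records}
    weeks = {r.week for r in records}
    if len(teams) > 1 or len(weeks) > 1:
        raise ValueError(f"records span multiple teams/weeks: {sorted(teams)} x {sorted(weeks)}")
    by_day: dict = {}
    for r in records:
        by_day.setdefault(r.date, []).append(r.atmosphere)
    sigmas = [
        daily_sigma(scores, ddof_mode)
        for scores in by_day.values()
        if len(scores) >= MIN_MEMBERS_PER_DAY
    ]
    if not sigmas:
        return math.nan
    return -float(np.mean(sigmas))


def ssi_table(days: pd.DataFrame, ddof_mode: str = "population") -> pd.DataFrame:
    """Vectorised SSI over a merged-record table.

    ``days`` needs columns team_id, week, date, atmosphere, wellbeing,
    participant_id. Returns one row per (team_id, week) present, with
    ssi (NaN when no eligible day), n_eligible_days and n_member_days.
    """
    ddof = _ddof(ddof_mode)
    tmp = days.assign(_atm_sq=days["atmosphere"] ** 2)
    daily = tmp.groupby(["team_id", "week", "date"]).agg(
        n=("atmosphere", "size"), s1=("atmosphere", "sum"), s2=("_atm_sq", "sum")
    )
    eligible = daily[daily["n"] >= MIN_MEMBERS_PER_DAY].copy()
    var = eligible["s2"] / eligible["n"] - (eligible["s1"] / eligible["n"]) ** 2
    if ddof:
        var = var * eligible["n"] / (eligible["n"] - ddof)
    eligible["sigma"] = np.sqrt(np.clip(var, 0.0, None))
    ssi = -eligible.groupby(["team_id", "week"])["sigma"].mean()
    out = (
        days.groupby(["team_id", "week"])
        .agg(n_member_days=("participant_id", "size"))
        .join(ssi.rename("ssi"))
        .join(eligible.groupby(["team_id", "week"]).size().rename("n_eligible_days"))
        .reset_index()
    )
    out["n_eligible_days"] = out["n_eligible_days"].fillna(0).astype(int)
    return out
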