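import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_report
from sharedness.association import (
    CorrelationResult,
    DegenerateDataError,
    adjust_bh,
    build_table,
    correlate_overall,
    correlate_per_team,
    correlate_per_week,
    pearson,
    team_ihs,
    validate_surrogate,
    TeamIHS,
)
from sharedness.pipeline import prepare_days
from sharedness.records import IHSRecord
from sharedness.ssi import ssi_table


class TestPearson:
    def test_perfect_linearity(self):
        res = pearson([1, 2, 3, 4], [3, 5, 7, 9])
        assert res.r == pytest.approx(1.0)
        assert res.significant

    def test_hand_computed_example(self):
        res = pearson([1, 2, 3], [2, 4, 7])
        assert round(res.r, 5) == 0.99340

    def test_joint_permutation_invariance(self):
        x, y = [1.0, 4.0, 2.0, 8.0, 5.0], [2.0, 3.0, 7.0, 6.0, 1.0]
        base = pearson(x, y)
        perm = np.random.default_rng(0).permutation(len(x))
        shuffled = pearson([x[i] for i in perm], [y[i] for i in perm])
        assert shuffled.r == pytest.approx(base.r, abs=1e-12)
        assert shuffled.p == pytest.approx(base.p, abs=1e-12)

    def test_zero_variance_names_side(self):
        with pytest.raises(DegenerateDataError, match="zero variance on y"):
            pearson([1, 2, 3], [5, 5, 5])

    def test_too_few_points(self):
        with pytest.raises(DegenerateDataError, match=">= 3"):
            pearson([1, 2], [3, 4])


def _toy_table():
    """Hand-built team-week table with controllable eligibility."""
    rows = []
    rng = np.random.default_rng(3)
    for t in "ABCDE":
        for w in range(1, 10):
            ssi = -rng.uniform(0.2, 2.5)
            rows.append(
                {
                    "team_id": t, "week": w, "ssi": ssi, "tsi": ssi * 0.5 - 0.1,
                    "wb_eligible_days": 6 + 0.8 * ssi + rng.normal(0, 0.3),
                    "wb_all_days": 6 + 0.4 * ssi + rng.normal(0, 0.3),
                    "ssi_eligible": True, "tsi_eligible": True,
                }
            )
    return pd.DataFrame(rows)


class TestBuildTable:
    def test_candidate_grid_enumerates_teams_by_weeks(self, default_study):
        cfg, reports, _, _ = default_study
        days, windows = prepare_days(reports, cfg.anchor_date, cfg.end_date)
        table = build_table(days, ssi_table(days), None, n_weeks=len(windows))
        assert len(table) == days["team_id"].nunique() * 9 == 207

    def test_lone_reporter_weeks_present_but_ineligible(self):
        reports = [
            make_report("P1", "A", "2022-09-01", wb=6, atm=6),
            make_report("P1", "A", "2022-09-02", wb=7, atm=5),
            make_report("P2", "B", "2022-09-01", wb=4, atm=4),
            make_report("P3", "B", "2022-09-01", wb=8, atm=6),
        ]
        days, windows = prepare_days(reports, pd.Timestamp("2022-09-01").date(), pd.Timestamp("2022-09-14").date())
        table = build_table(days, ssi_table(days), None, n_weeks=len(windows))
        row_a = table[(table.team_id == "A") & (table.week == 1)].iloc[0]
        assert not row_a.ssi_eligible and math.isnan(row_a.ssi)
        row_b = table[(table.team_id == "B") & (table.week == 1)].iloc[0]
        assert row_b.ssi_eligible
        assert row_b.wb_eligible_days == pytest.approx(6.0)  # mean of 4 and 8

    def test_orphan_index_keys_rejected(self):
        reports = [make_report("P1", "A"), make_report("P2", "A")]
        days, windows = prepare_days(reports, pd.Timestamp("2022-09-01").date(), pd.Timestamp("2022-09-07").date())
        ssi = ssi_table(days)
        orphan = pd.concat([ssi, pd.DataFrame([{"team_id": "Z", "week": 1, "ssi": -1.0, "n_eligible_days": 1, "n_member_days": 2}])])
        with pytest.raises(KeyError, match="Z"):
            build_table(days, orphan, None, n_weeks=len(windows))


class TestCorrelateScopes:
    def test_overall_recovers_planted_slope_sign(self):
        res = correlate_overall(_toy_table(), "ssi")
        assert res.r > 0.5 and res.significant

    def test_duplicating_rows_keeps_r(self):
        table = _toy_table()
        doubled = pd.concat([table, table], ignore_index=True)
        r1, r2 = correlate_overall(table, "ssi"), correlate_overall(doubled, "ssi")
        assert r2.r == pytest.approx(r1.r, abs=1e-12)
        assert r2.p < r1.p  # documented hazard: pseudo-replication shrinks p

    def test_overall_invariant_under_affine_index_transform(self):
        table = _toy_table()
        scaled = table.assign(ssi=3.0 * table.ssi + 7.0)
        assert correlate_overall(scaled, "ssi").r == pytest.approx(
            correlate_overall(table, "ssi").r, abs=1e-12
        )

    def test_per_team_min_weeks_exclusion(self):
        table = _toy_table()
        table.loc[(table.team_id == "A") & (table.week > 3), "ssi_eligible"] = False
        scopes = {r.scope for r in correlate_per_team(table, "ssi")}
        assert "team:A" not in scopes and "team:B" in scopes

    def test_constant_index_reported_undefined(self):
        table = _toy_table()
        table.loc[table.team_id == "C", "ssi"] = -1.0
        res = {r.scope: r for r in correlate_per_team(table, "ssi")}
        assert res["team:C"].undefined and not res["team:C"].significant

    def test_per_week_sparse_week_excluded(self):
        table = _toy_table()
        table.loc[(table.week == 9) & (table.team_id != "A"), "ssi_eligible"] = False
        scopes = {r.scope for r in correlate_per_week(table, "ssi")}
        assert "week:9" not in scopes and "week:1" in scopes

    def test_eligibility_monotonicity(self):
        table = _toy_table()
        table.loc[(table.team_id == "A") & (table.week > 4), "ssi_eligible"] = False
        strict = {r.scope for r in correlate_per_team(table, "ssi", min_weeks=5)}
        relaxed = {r.scope for r in correlate_per_team(table, "ssi", min_weeks=4)}
        assert strict <= relaxed


class TestTeamIhs:
    def test_single_respondent(self):
        out = team_ihs([IHSRecord(participant_id="P1", team_id="A", items=[4.0] * 9)])
        assert out[0].mean_ihs == 4.0 and out[0].n_respondents == 1

    def test_mean_of_individual_means(self):
        recs = [
            IHSRecord(participant_id="P1", team_id="A", items=[3.0] * 9),
            IHSRecord(participant_id="P2", team_id="A", items=[5.0] * 9),
        ]
        assert team_ihs(recs)[0].mean_ihs == 4.0

    def test_equals_pooled_mean_with_complete_responses(self):
        rng = np.random.default_rng(1)
        recs = [
            IHSRecord(participant_id=f"P{i}", team_id="A", items=list(rng.integers(1, 6, 9).astype(float)))
            for i in range(5)
        ]
        pooled = np.mean([v for r in recs for v in r.items])
        assert team_ihs(recs)[0].mean_ihs == pytest.approx(pooled, abs=1e-12)


class TestSurrogate:
    def _table_with_team_means(self, means):
        rows = []
        for t, m in means.items():
            for w in range(1, 5):
                rows.append(
                    {"team_id": t, "week": w, "ssi": m + 0.01 * (w - 2.5), "tsi": np.nan,
                     "wb_eligible_days": 6.0, "wb_all_days": 6.0,
                     "ssi_eligible": True, "tsi_eligible": False}
                )
        return pd.DataFrame(rows)

    def test_pass_and_fail_straddle_threshold(self):
        rng = np.random.default_rng(8)
        means = {chr(65 + i): -0.5 - 0.2 * i for i in range(8)}
        table = self._table_with_team_means(means)
        aligned = [
            TeamIHS(team_id=t, mean_ihs=3.0 + means[t], n_respondents=3) for t in means
        ]
        res, ok = validate_surrogate(table, "ssi", aligned)
        assert ok and res.r > 0.99
        anti = [TeamIHS(team_id=t, mean_ihs=3.0 - means[t], n_respondents=3) for t in means]
        res2, ok2 = validate_surrogate(table, "ssi", anti)
        assert not ok2 and res2.r < 0

    def test_min_weekly_values_exclusion(self):
        means = {"A": -0.5, "B": -1.0, "C": -1.5, "D": -2.0}
        table = self._table_with_team_means(means)
        table = table[~((table.team_id == "A") & (table.week > 2))]  # A has 2 weekly values
        scores = [TeamIHS(team_id=t, mean_ihs=3.0 + means[t], n_respondents=2) for t in means]
        res, _ = validate_surrogate(table, "ssi", scores, min_weekly_values=3)
        assert res.n == 3

    def test_threshold_boundary(self):
        # synthetic correlation engineered just below/above 0.4
        res = CorrelationResult(scope="ihs:ssi", r=0.39, p=0.1, n=10, alpha=0.05, significant=False)
        assert not (res.r >= 0.4)
        res = CorrelationResult(scope="ihs:ssi", r=0.40, p=0.1, n=10, alpha=0.05, significant=False)
        assert res.r >= 0.4


class TestBh:
    def test_adjustment_only_raises_p(self):
        results = [
            CorrelationResult(scope=f"team:{i}", r=0.5, p=p, n=8, alpha=0.1, significant=p < 0.1)
            for i, p in enumerate([0.01, 0.04, 0.2, 0.8])
        ]
        adjusted = adjust_bh(results)
        for raw, adj in zip(results, adjusted):
            assert adj.p >= raw.p - 1e-12
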