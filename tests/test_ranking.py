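"""Criterion ranking, time banding, rank aggregation, elimination, Friedman-Nemenyi."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polypeval.ranking import (
    Criterion,
    aggregate_ranks,
    band_values,
    eliminate,
    friedman_nemenyi,
    rank_criterion,
)

# Per-split segmentation scores of the five analysed teams (leaderboard data).
SEG_SCORES = {
    "data1": {"aggcmab": 0.746, "AIM_CityU": 0.762, "HoLLYS_ETRI": 0.714,
              "MLC_SimulaMet": 0.741, "sruniga": 0.771},
    "data2": {"aggcmab": 0.849, "AIM_CityU": 0.777, "HoLLYS_ETRI": 0.777,
              "MLC_SimulaMet": 0.858, "sruniga": 0.830},
    "data4": {"aggcmab": 0.788, "AIM_CityU": 0.589, "HoLLYS_ETRI": 0.746,
              "MLC_SimulaMet": 0.781, "sruniga": 0.611},
}


class TestRankCriterion:
    def test_higher_better_direction(self):
        c = Criterion("s", "higher_better", {"a": 0.9, "b": 0.5})
        assert rank_criterion(c) == {"a": 1.0, "b": 2.0}

    def test_exact_ties_take_average_position(self):
        c = Criterion("s", "higher_better", {"a": 0.777, "b": 0.777, "c": 0.8})
        assert rank_criterion(c) == {"c": 1.0, "a": 2.5, "b": 2.5}

    def test_non_finite_value_names_team(self):
        with pytest.raises(ValueError, match="bad_team"):
            rank_criterion(Criterion("s", "lower_better", {"a": 1.0, "bad_team": np.nan}))

    def test_single_team_rejected(self):
        with pytest.raises(ValueError):
            rank_criterion(Criterion("s", "lower_better", {"a": 1.0}))

    def test_leaderboard_seg_rank_order(self):
        """Rank-averaging the three per-split segmentation scores recovers the
        published R_seg order of the five teams."""
        criteria = [
            Criterion(split, "higher_better", vals) for split, vals in SEG_SCORES.items()
        ]
        table = aggregate_ranks(criteria, round_means=False)
        order = [t for t, _ in sorted(table.final_rank.items(), key=lambda kv: kv[1])]
        assert order == ["aggcmab", "MLC_SimulaMet", "sruniga", "AIM_CityU", "HoLLYS_ETRI"]


class TestBandValues:
    @pytest.mark.parametrize("value, band", [(17, 1), (49.9, 1), (50, 1), (84, 2),
                                             (100, 2), (101, 3), (120, 3)])
    def test_default_time_bands(self, value, band):
        c = Criterion("time", "lower_better", {"t": value, "u": 1.0})
        assert band_values(c).values["t"] == band

    def test_banding_requires_lower_better(self):
        with pytest.raises(ValueError):
            band_values(Criterion("s", "higher_better", {"a": 1, "b": 2}))


class TestAggregateRanks:
    def test_single_criterion_passthrough(self):
        c = Criterion("s", "higher_better", {"a": 0.9, "b": 0.5, "c": 0.1})
        table = aggregate_ranks([c])
        assert table.final_rank == {"a": 1, "b": 2, "c": 3}

    # per-criterion ranks: a (1,2,3), b (2,3,2), c (3,4,1), d (4,1,4)
    ROUND_CRITS = [
        Criterion("c1", "lower_better", {"a": 1, "b": 2, "c": 3, "d": 4}),
        Criterion("c2", "lower_better", {"a": 2, "b": 3, "c": 4, "d": 1}),
        Criterion("c3", "lower_better", {"a": 3, "b": 2, "c": 1, "d": 4}),
    ]

    def test_rounding_merges_close_means(self):
        # means {a: 2.0, b: 2.33, c: 2.67, d: 3.0} -> rounded {2, 2, 3, 3}
        table = aggregate_ranks(self.ROUND_CRITS, round_means=True)
        assert table.mean_rank == pytest.approx(
            {"a": 2.0, "b": 7 / 3, "c": 8 / 3, "d": 3.0}
        )
        assert table.final_rank == {"a": 1, "b": 1, "c": 2, "d": 2}
        assert ("a", "b") in table.unresolved_ties

    def test_unrounded_means_stay_distinct(self):
        table = aggregate_ranks(self.ROUND_CRITS, round_means=False)
        assert table.final_rank == {"a": 1, "b": 2, "c": 3, "d": 4}

    def test_tiebreak_criterion_resolves_rounded_ties(self):
        crits = [
            Criterion("c1", "lower_better", {"a": 1, "b": 2, "c": 3}),
            Criterion("c2", "lower_better", {"a": 2, "b": 1, "c": 3}),
        ]
        tb = Criterion("seg", "higher_better", {"a": 0.6, "b": 0.8, "c": 0.7})
        table = aggregate_ranks(crits, round_means=True, tiebreak_criterion=tb)
        assert table.final_rank["b"] < table.final_rank["a"]
        assert not table.unresolved_ties

    def test_invariant_to_criterion_order(self):
        crits = [
            Criterion(split, "higher_better", vals) for split, vals in SEG_SCORES.items()
        ]
        t1 = aggregate_ranks(crits)
        t2 = aggregate_ranks(list(reversed(crits)))
        assert t1.final_rank == t2.final_rank

    def test_dominated_team_does_not_disturb_order(self):
        crits = [
            Criterion(split, "higher_better", vals) for split, vals in SEG_SCORES.items()
        ]
        base = aggregate_ranks(crits).final_rank
        worse = [
            Criterion(c.name, c.direction, {**c.values, "zzz": 0.0}) for c in crits
        ]
        extended = aggregate_ranks(worse).final_rank
        for a in base:
            for b in base:
                assert (base[a] < base[b]) == (extended[a] < extended[b])
        assert extended["zzz"] == max(extended.values())

    def test_improving_a_value_never_degrades_pairwise_order(self):
        """Improving one team's value on one criterion never drops it below a
        team it previously beat or tied.  (The dense-rank *number* itself can
        shift when the improvement splits ties among other teams, so the
        invariant is stated pairwise.)"""
        rng = np.random.default_rng(21)
        teams = ["a", "b", "c", "d"]
        for _ in range(20):
            crits = [
                Criterion(f"c{i}", "higher_better",
                          {t: float(rng.random()) for t in teams})
                for i in range(3)
            ]
            before = aggregate_ranks(crits).final_rank
            improved = [
                Criterion(
                    c.name, c.direction,
                    {**c.values, "a": c.values["a"] + 0.5} if i == 0 else c.values,
                )
                for i, c in enumerate(crits)
            ]
            after = aggregate_ranks(improved).final_rank
            for t in ("b", "c", "d"):
                if before["a"] <= before[t]:
                    assert after["a"] <= after[t]


class TestEliminate:
    def test_slow_team_eliminated_on_time(self):
        res = eliminate(
            ["fast", "slow"],
            {"fast": {"AP": 0.4}, "slow": {"AP": 0.4}},
            {"AP": 0.2},
            {"fast": 100, "slow": 2007},
        )
        assert res.survivors == ["fast"]
        assert res.eliminated["slow"] == ["time"]

    def test_score_floor_from_config(self):
        res = eliminate(
            ["ok", "weak"],
            {"ok": {"DSC": 0.7}, "weak": {"DSC": 0.49}},
            {"DSC": 0.55},
            {"ok": 10, "weak": 10},
            floors={"DSC": 0.50},
        )
        assert res.survivors == ["ok"]
        assert res.eliminated["weak"] == ["score floor:DSC"]

    def test_relative_margin_against_baseline_worst(self):
        # floor = 0.30 * 0.9 = 0.27
        res = eliminate(
            ["a", "b"],
            {"a": {"AP": 0.28}, "b": {"AP": 0.26}},
            {"AP": 0.30},
            {"a": 10, "b": 10},
        )
        assert res.survivors == ["a"]

    def test_all_above_thresholds_survive(self):
        res = eliminate(
            ["a", "b"],
            {"a": {"AP": 0.5}, "b": {"AP": 0.6}},
            {"AP": 0.3},
            {"a": 100, "b": 200},
        )
        assert res.survivors == ["a", "b"] and not res.eliminated


class TestFriedmanNemenyi:
    def test_identical_columns_give_no_evidence(self):
        data = np.tile(np.arange(10.0)[:, None], (1, 3))
        res = friedman_nemenyi(data)
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)
        assert (res.pairwise_pvalues.to_numpy() == 1.0).all()

    def test_dominant_method_matches_rank_formula(self):
        """One method beating the others on all 50 frames: the chi-square
        statistic equals the closed-form 12n/(k(k+1)) * sum (Rbar_j - (k+1)/2)^2."""
        rng = np.random.default_rng(4)
        n, k = 50, 3
        base = rng.random((n, k))
        base[:, 0] += 2.0  # method 0 dominates every frame
        res = friedman_nemenyi(base)
        ranks = np.apply_along_axis(stats.rankdata, 1, base)
        rbar = ranks.mean(axis=0)
        expected = 12 * n / (k * (k + 1)) * ((rbar - (k + 1) / 2) ** 2).sum()
        assert res.statistic == pytest.approx(expected)
        assert res.pvalue < 0.001
        assert res.pairwise_pvalues.iloc[0, 1] < 0.05

    def test_label_permutation_permutes_pairwise_matrix(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame(rng.random((20, 4)), columns=list("abcd"))
        res = friedman_nemenyi(data)
        perm = data[["c", "a", "d", "b"]]
        res_p = friedman_nemenyi(perm)
        for i in "abcd":
            for j in "abcd":
                assert res.pairwise_pvalues.loc[i, j] == pytest.approx(
                    res_p.pairwise_pvalues.loc[i, j]
                )

    def test_nemenyi_uses_studentized_range_constants(self):
        # q_{0.05} for k=3 at infinite df is 3.314 (published tables)
        assert stats.studentized_range.ppf(0.95, 3, np.inf) == pytest.approx(3.314, abs=2e-3)

    def test_missing_cells_rejected(self):
        data = np.ones((5, 3))
        data[2, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            friedman_nemenyi(data)

    def test_minimum_shape_enforced(self):
        with pytest.raises(ValueError):
            friedman_nemenyi(np.ones((5, 2)))
        with pytest.raises(ValueError):
            friedman_nemenyi(np.ones((1, 3)))
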