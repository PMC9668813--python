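"""Post-conflict classification, count bookkeeping and rate conversion."""
import math

import numpy as np
import pytest

from podnet import (
    SignedTemporalNetwork,
    classify_events,
    daily_probability,
    extract_episodes,
    prob_to_rate,
    rate_to_prob,
    spontaneous_counts,
)

from conftest import make_network


class TestEpisodes:
    def test_neutral_gap_does_not_split_an_episode(self, roster2):
        net = make_network(roster2, 1, {(0, 1): [1, 0, 1, 0, 0]})
        (ep,) = extract_episodes(net)
        assert (ep.start, ep.end, ep.sign, ep.n_active) == (1, 3, 1, 2)

    def test_valence_flip_finishes_an_episode(self, roster2):
        net = make_network(roster2, 1, {(0, 1): [-1, -1, 1, 1]})
        conflict, affiliation = extract_episodes(net)
        assert (conflict.sign, conflict.start, conflict.end) == (-1, 1, 2)
        assert (affiliation.sign, affiliation.start, affiliation.end) == (1, 3, 4)


class TestClassification:
    def test_affiliation_between_former_opponents_is_reconciliation(self, roster4):
        net = make_network(roster4, 1, {(0, 1): [-1, 1, 0]})
        counts = classify_events([net]).counts()
        assert counts["reconciliation"] == 1
        assert counts["spontaneous_aggression"] == 1  # the conflict itself

    def test_bystander_affiliation_closes_memory_then_spontaneous(self, roster4):
        # conflict(A,B)@1, affiliation(A,C)@2 -> new affiliation;
        # affiliation(A,B)@4 afterwards is spontaneous again
        net = make_network(
            roster4,
            1,
            {(0, 1): [-1, 0, 0, 1], (0, 2): [0, 1, 0, 0]},
        )
        counts = classify_events([net]).counts()
        assert counts["new_affiliation"] == 1
        assert counts["reconciliation"] == 0
        assert counts["spontaneous_affiliation"] == 1

    def test_day_without_conflicts_is_all_spontaneous(self, roster4):
        net = make_network(
            roster4,
            1,
            {(0, 1): [1, 0, 0], (2, 3): [0, 1, 0], (0, 2): [0, 0, 1]},
        )
        counts = classify_events([net]).counts()
        assert counts["spontaneous_affiliation"] == 3
        assert sum(counts.values()) == 3

    def test_aggression_involving_an_opponent_is_new_aggression(self, roster4):
        net = make_network(roster4, 1, {(0, 1): [-1, 0, 0], (1, 2): [0, -1, 0]})
        counts = classify_events([net]).counts()
        assert counts["new_aggression"] == 1
        assert counts["spontaneous_aggression"] == 1

    def test_same_sign_recurrence_is_one_episode_not_a_renewal(self, roster4):
        # (-1, 0, -1) on one dyad is a single continuing conflict: neutral
        # gaps do not finish an interaction, only a valence change does
        net = make_network(roster4, 1, {(0, 1): [-1, 0, -1]})
        counts = classify_events([net]).counts()
        assert counts["spontaneous_aggression"] == 1
        assert sum(counts.values()) == 1

    def test_renewed_same_pair_aggression_flag(self, roster4):
        # conflict(A,B)@1; conflict(B,C)@2 is redirected and opens its own
        # memory; affiliation(A,B)@3 attributes to the most recent memory
        # (B,C) as a new affiliation, so the (A,B) memory stays open; the
        # renewed conflict(A,B)@4 then hits its own pair's open memory
        links = {(0, 1): [-1, 0, 1, -1], (1, 2): [0, -1, 0, 0]}
        net = make_network(roster4, 1, links)
        with_renewed = classify_events([net], include_renewed=True).counts()
        assert with_renewed["new_aggression"] == 2
        assert with_renewed["new_affiliation"] == 1
        without = classify_events([net], include_renewed=False).counts()
        assert without["new_aggression"] == 1
        assert without["spontaneous_aggression"] == 2

    def test_memory_horizon_limits_attribution(self, roster4):
        # conflict@1, affiliation between opponents @5: reconciliation with
        # a same-day memory, spontaneous with a one-period horizon
        net = make_network(roster4, 1, {(0, 1): [-1, 0, 0, 0, 1]})
        assert classify_events([net]).counts()["reconciliation"] == 1
        short = classify_events([net], memory_horizon=1).counts()
        assert short["reconciliation"] == 0
        assert short["spontaneous_affiliation"] == 1

    def test_memory_does_not_cross_days(self, roster4):
        day1 = make_network(roster4, 1, {(0, 1): [-1, 0]})
        day2 = make_network(roster4, 2, {(0, 1): [1, 0]})
        counts = classify_events([day1, day2]).counts()
        assert counts["reconciliation"] == 0
        assert counts["spontaneous_affiliation"] == 1

    def test_category_sums_match_totals_on_random_days(self, roster4):
        rng = np.random.default_rng(9)
        nets = []
        for day in range(1, 31):
            arr = np.zeros((20, 4, 4), dtype=np.int8)
            for t in range(20):
                if rng.random() < 0.4:
                    i, j = sorted(rng.choice(4, 2, replace=False))
                    arr[t, i, j] = arr[t, j, i] = rng.choice([1, -1])
            nets.append(
                SignedTemporalNetwork(roster=roster4, day=day, periods=arr)
            )
        classification = classify_events(nets)
        counts = classification.counts()
        episodes = [ep for net in nets for ep in extract_episodes(net)]
        n_aff = sum(1 for e in episodes if e.sign > 0)
        n_agg = sum(1 for e in episodes if e.sign < 0)
        assert (
            counts["reconciliation"]
            + counts["new_affiliation"]
            + counts["spontaneous_affiliation"]
            == n_aff
        )
        assert counts["new_aggression"] + counts["spontaneous_aggression"] == n_agg


class TestSpontaneousCounts:
    @pytest.mark.parametrize(
        "totals,expected",
        [
            ((217, 133, 41, 35, 41), (141, 92)),  # four-animal group
            ((91, 44, 16, 17, 14), (58, 30)),  # five-animal group
            ((0, 0, 0, 0, 0), (0, 0)),
        ],
    )
    def test_subtraction_bookkeeping(self, totals, expected):
        assert spontaneous_counts(*totals) == expected

    def test_categories_resum_to_totals(self):
        for totals in [(217, 133, 41, 35, 41), (91, 44, 16, 17, 14)]:
            total_aff, total_agg, n_rec, n_na, n_ng = totals
            n_sa, n_sg = spontaneous_counts(*totals)
            assert n_rec + n_na + n_sa == total_aff
            assert n_ng + n_sg == total_agg

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            spontaneous_counts(10, 5, 8, 8, 0)
        with pytest.raises(ValueError):
            spontaneous_counts(-1, 0, 0, 0, 0)


class TestDailyProbability:
    def test_fraction_of_periods(self):
        assert daily_probability(2, 20) == pytest.approx(0.1)
        assert daily_probability(0, 20) == 0.0

    def test_zero_period_day_rejected(self):
        with pytest.raises(ValueError):
            daily_probability(0, 0)

    def test_count_above_periods_rejected(self):
        with pytest.raises(ValueError):
            daily_probability(21, 20)


class TestRates:
    def test_zero_probability_means_zero_rate(self):
        assert prob_to_rate(0.0, 3.0) == 0.0

    @pytest.mark.parametrize("p", [0.01, 0.04, 0.17])
    def test_round_trip_is_exact(self, p):
        assert rate_to_prob(prob_to_rate(p, 3.0), 3.0) == pytest.approx(p, rel=1e-14)

    def test_closed_form_value(self):
        # p = 0.04 over a 3-min period: r = -ln(0.96)/3 per minute
        assert prob_to_rate(0.04, 3.0) == pytest.approx(
            -math.log(0.96) / 3.0, rel=1e-12
        )
        assert prob_to_rate(0.04, 3.0) == pytest.approx(0.0136073, abs=5e-7)

    def test_certain_event_has_infinite_rate_and_is_rejected(self):
        with pytest.raises(ValueError):
            prob_to_rate(1.0, 3.0)
        with pytest.raises(ValueError):
            prob_to_rate(-0.1, 3.0)
        with pytest.raises(ValueError):
            rate_to_prob(-1.0, 3.0)

    def test_monotone(self):
        rates = [prob_to_rate(p, 3.0) for p in (0.0, 0.1, 0.5, 0.9)]
        assert rates == sorted(rates)
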