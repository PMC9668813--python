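"""Synthetic observation-data generator and its ground-truth ledger."""
import numpy as np
import pandas as pd
import pytest

from podnet import (
    ProbabilitySet,
    build_temporal_network,
    classify_events,
    compute_ia,
    estimate_probabilities,
    read_event_log,
    write_event_log,
)
from podnet.reference import complex_model_probs, roster_g1
from podnet.synth import (
    FIXTURE_G1_SEED,
    GeneratorSpec,
    fixture_g1,
    generate_event_log,
    generate_sampling_log,
)


def zero_memory_probs(p_sa, p_sg):
    return ProbabilitySet(
        p_spontaneous_affiliation=p_sa,
        p_spontaneous_aggression=p_sg,
        p_reconciliation=0.0,
        p_new_affiliation=0.0,
        p_new_aggression=0.0,
    )


def networks_from_events(events, roster, n_periods):
    by_day = {}
    for e in events:
        by_day.setdefault(e.day, []).append(e)
    return [
        build_temporal_network(evs, roster, n_periods)
        for _, evs in sorted(by_day.items())
    ]


class TestEventGeneration:
    def test_zero_probabilities_give_empty_log(self):
        spec = GeneratorSpec(
            roster=roster_g1(), probs=zero_memory_probs(0, 0), n_days=5, seed=0
        )
        events, ledger = generate_event_log(spec)
        assert events == [] and ledger.empty

    def test_certain_affiliation_gives_one_event_per_period(self):
        spec = GeneratorSpec(
            roster=roster_g1(), probs=zero_memory_probs(1.0, 0.0), n_days=3, seed=0
        )
        events, ledger = generate_event_log(spec)
        assert len(events) == 3 * 20
        assert all(e.valence == 1 for e in events)
        assert set(ledger["category"]) == {"spontaneous_affiliation"}

    def test_deterministic_under_seed(self):
        mk = lambda: GeneratorSpec(
            roster=roster_g1(), probs=complex_model_probs(), n_days=10, seed=33
        )
        ev_a, led_a = generate_event_log(mk())
        ev_b, led_b = generate_event_log(mk())
        assert ev_a == ev_b
        pd.testing.assert_frame_equal(led_a, led_b)

    def test_round_trips_through_the_io_layer(self, tmp_path):
        spec = GeneratorSpec(
            roster=roster_g1(), probs=complex_model_probs(), n_days=20, seed=2
        )
        events, _ = generate_event_log(spec)
        path = tmp_path / "events.csv"
        write_event_log(events, path)
        assert read_event_log(path, roster_g1()) == events

    def test_category_counts_near_binomial_expectation(self):
        # study probabilities over 80 days x 20 periods: spontaneous
        # category totals within 3 binomial SEs of n * p
        spec = GeneratorSpec(
            roster=roster_g1(), probs=complex_model_probs(), n_days=80, seed=6
        )
        _, ledger = generate_event_log(spec)
        n = 80 * 20
        totals = ledger["category"].value_counts()
        for cat, p in [
            ("spontaneous_affiliation", 0.05),
            ("spontaneous_aggression", 0.02),
        ]:
            se = np.sqrt(n * p * (1 - p))
            # first-write-wins can only remove a handful of draws
            assert abs(totals.get(cat, 0) - n * p) <= 3 * se + 3

    def test_variable_day_lengths_respected(self):
        spec = GeneratorSpec(
            roster=roster_g1(),
            probs=zero_memory_probs(1.0, 0.0),
            n_days=3,
            periods_per_day=[5, 10, 2],
            seed=0,
        )
        events, _ = generate_event_log(spec)
        per_day = pd.Series([e.day for e in events]).value_counts().sort_index()
        assert list(per_day) == [5, 10, 2]


class TestLedgerConservation:
    def test_classifier_matches_ledger_exactly_without_conflicts(self):
        # with no aggression at all nothing can be attributed to a
        # conflict, and the episode counts must match the ledger exactly
        spec = GeneratorSpec(
            roster=roster_g1(), probs=zero_memory_probs(0.3, 0.0), n_days=40, seed=14
        )
        events, ledger = generate_event_log(spec)
        nets = networks_from_events(events, roster_g1(), 20)
        counts = classify_events(nets, memory_horizon=1).counts()
        truth = _ledger_episode_counts(ledger)
        assert counts["spontaneous_affiliation"] == truth["spontaneous_affiliation"]
        assert sum(counts.values()) == counts["spontaneous_affiliation"]

    def test_sign_totals_conserved_between_ledger_and_classifier(self):
        # with conflicts present the category split of a single contact is
        # not identifiable from the networks, but the episode totals per
        # valence are conserved exactly
        spec = GeneratorSpec(
            roster=roster_g1(), probs=zero_memory_probs(0.3, 0.1), n_days=40, seed=14
        )
        events, ledger = generate_event_log(spec)
        nets = networks_from_events(events, roster_g1(), 20)
        counts = classify_events(nets, memory_horizon=1).counts()
        truth = _ledger_episode_counts(ledger)
        assert (
            counts["reconciliation"]
            + counts["new_affiliation"]
            + counts["spontaneous_affiliation"]
            == truth.get("spontaneous_affiliation", 0)
        )
        assert (
            counts["new_aggression"] + counts["spontaneous_aggression"]
            == truth.get("spontaneous_aggression", 0)
        )

    def test_classifier_agrees_with_ledger_at_study_probabilities(self):
        # at the study probabilities the latent category of a contact is
        # occasionally unidentifiable from the networks alone (a
        # spontaneous affiliation can land where a post-conflict contact
        # would); agreement is therefore close but not exact
        spec, events, ledger = fixture_g1()
        nets = networks_from_events(events, spec.roster, 20)
        counts = classify_events(nets, memory_horizon=1).counts()
        truth = _ledger_episode_counts(ledger)
        for cat in counts:
            assert abs(counts[cat] - truth.get(cat, 0)) <= 6, cat

    def test_moment_estimator_recovers_generating_probabilities(self):
        spec = GeneratorSpec(
            roster=roster_g1(), probs=complex_model_probs(), n_days=80, seed=10
        )
        events, _ = generate_event_log(spec)
        nets = networks_from_events(events, roster_g1(), 20)
        est = estimate_probabilities(nets)
        assert est.p_spontaneous_affiliation == pytest.approx(0.05, abs=0.02)
        assert est.p_spontaneous_aggression == pytest.approx(0.02, abs=0.015)


def _ledger_episode_counts(ledger: pd.DataFrame) -> dict:
    """Collapse per-period ledger events into episodes the way the
    classifier sees them: same-dyad events of one sign merge (neutral gaps
    included) until the dyad's valence flips; each episode carries the
    category of its first event."""
    counts: dict = {}
    for (_, _, _), sub in ledger.groupby(["day", "id1", "id2"]):
        sub = sub.sort_values("period")
        prev_sign = None
        for row in sub.itertuples():
            if row.valence == prev_sign:
                continue  # continuation of the same episode
            counts[row.category] = counts.get(row.category, 0) + 1
            prev_sign = row.valence
    return counts


class TestSamplingGeneration:
    def test_zero_rates_give_zero_ia_everywhere(self):
        spec = GeneratorSpec(
            roster=roster_g1(), probs=complex_model_probs(), n_days=5, seed=0
        )
        records = generate_sampling_log(spec)
        table = compute_ia(records, roster_g1())
        assert (table["IA"] == 0).all()

    def test_unit_rate_dyad_has_ia_one(self):
        spec = GeneratorSpec(
            roster=roster_g1(),
            probs=complex_model_probs(),
            n_days=5,
            ia_rates={("Estel", "Mateo"): 1.0},
            seed=0,
        )
        table = compute_ia(generate_sampling_log(spec), roster_g1())
        table = table.set_index(["id1", "id2"])
        assert table.loc[("Estel", "Mateo"), "IA"] == 1.0

    def test_out_of_range_rate_rejected(self):
        with pytest.raises(ValueError, match="IA rates"):
            GeneratorSpec(
                roster=roster_g1(),
                probs=complex_model_probs(),
                ia_rates={("Estel", "Mateo"): 1.2},
            )


class TestFixture:
    def test_fixture_loads_and_satisfies_type_invariants(self):
        spec, events, ledger = fixture_g1()
        assert spec.seed == FIXTURE_G1_SEED
        assert spec.roster.n == 4
        nets = networks_from_events(events, spec.roster, 20)
        assert len(nets) <= 80
        assert len(events) == len(ledger)

    def test_fixture_regeneration_is_byte_identical(self, tmp_path):
        _, events_a, _ = fixture_g1()
        _, events_b, _ = fixture_g1()
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_event_log(events_a, pa)
        write_event_log(events_b, pb)
        assert pa.read_bytes() == pb.read_bytes()
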