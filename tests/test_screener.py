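"""Screen assembly: distance bounds, extended budget, audit modes,
oracle equivalence and monotonicity."""

import numpy as np
import pytest

from alphscreen.motif_model import DistanceConstraints, builtin_matrix_set
from alphscreen.screener import (
    missing_motif_scan,
    screen_protein,
    screen_proteome,
    summarise_outcomes,
)
from alphscreen.synthetic_data import SyntheticSpec, generate

from conftest import build_fixture


class TestScreenProtein:
    def test_positive_fixture(self, positive_sequence):
        outcome = screen_protein("fix", positive_sequence)
        assert outcome.status == "alph"
        call = outcome.call
        assert [h.flavour_used for h in call.hits] == ["narrow"] * 6
        assert call.distances == (29, 26, 60, 40, 19)
        assert call.extended_count == 0
        assert call.hits[0].start == 10

    def test_ppp_arginine_in_motif2_kills_the_call(self):
        sequence = build_fixture({2: "GDLVDRG"})
        assert screen_protein("ppp", sequence).status == "negative"

    def test_short_motif1_to_2_spacing_is_rejected(self):
        sequence = build_fixture(d12="A" * 10)  # gap 10 < lower bound 14
        assert screen_protein("short", sequence).status == "negative"

    def test_extended_budget(self):
        # X-bearing windows match only the extended matrices.
        two_extended = build_fixture({1: "GDXHG", 3: "GNHX"})
        three_extended = build_fixture({1: "GDXHG", 3: "GNHX", 6: "LDXG"})
        assert screen_protein("two", two_extended).status == "alph"
        assert screen_protein("two", two_extended).call.extended_count == 2
        assert screen_protein("three", three_extended).status == "negative"
        assert (
            screen_protein("three", three_extended, extended_budget=3).status
            == "alph"
        )

    def test_budget_zero_rejects_any_extended_motif(self):
        sequence = build_fixture({1: "GDXHG"})
        assert screen_protein("x", sequence, extended_budget=0).status == "negative"

    def test_prefers_fewest_extended_then_leftmost(self):
        # An extra narrow motif-1 window earlier in the sequence must win
        # over the planted one (leftmost), and narrow must win over an
        # extended window at the same motif.
        sequence = "GDIHG" + "A" * 20 + build_fixture()
        outcome = screen_protein("tie", sequence)
        assert outcome.status == "alph"
        assert outcome.call.hits[0].start == 0
        assert outcome.call.hits[0].matched == "GDIHG"

    def test_start_to_start_convention_shifts_distances(self, positive_sequence):
        constraints = DistanceConstraints(convention="start_to_start")
        outcome = screen_protein("fix", positive_sequence, constraints=constraints)
        assert outcome.status == "alph"
        # start-to-start adds the upstream motif's length to each gap
        assert outcome.call.distances == (34, 33, 64, 43, 24)

    def test_empty_sequence_is_a_contract_violation(self):
        with pytest.raises(ValueError, match="empty"):
            screen_protein("empty", "   ")

    def test_multi_domain_flag_reports_second_domain_in_notes(
        self, positive_sequence
    ):
        tandem = positive_sequence + positive_sequence
        plain = screen_protein("tandem", tandem)
        flagged = screen_protein("tandem", tandem, multi_domain=True)
        assert plain.notes == ""
        assert "additional candidate ALPH domain" in flagged.notes
        # the call itself is unchanged
        assert flagged.call == plain.call


class TestMissingMotifScan:
    def test_mutated_terminal_motif_flags_c_truncation(self, positive_sequence):
        mutated = build_fixture({6: "QQQQ"})
        outcome = missing_motif_scan("trunc", mutated, missing=6)
        assert outcome.status == "missing_one"
        assert outcome.missing_index == 6
        assert outcome.truncated_terminal == "C"
        assert len(outcome.partial_hits) == 5

    def test_missing_motif1_flags_n_truncation(self):
        mutated = build_fixture({1: "QQQQQ"})
        outcome = missing_motif_scan("trunc", mutated, missing=1)
        assert outcome.status == "missing_one"
        assert outcome.truncated_terminal == "N"

    def test_random_sequence_is_negative_for_every_position(self, rng):
        sequence = "".join(
            rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200)
        )
        for missing in range(1, 7):
            assert (
                missing_motif_scan("rand", sequence, missing=missing).status
                == "negative"
            )

    def test_true_alph_is_negative_in_the_missing_scan(self, positive_sequence):
        outcome = missing_motif_scan("alph", positive_sequence, missing=3)
        assert outcome.status == "negative"
        assert "positive" in outcome.notes

    def test_waived_bound_allows_out_of_range_spacing(self):
        # With motif 6 destroyed, the 5->6 bound is waived even though the
        # remaining five motifs end far from anything.
        mutated = build_fixture({6: "QQQQ", "d56": "A" * 90})
        outcome = missing_motif_scan("waive", mutated, missing=6)
        assert outcome.status == "missing_one"

    def test_invalid_motif_index(self, positive_sequence):
        with pytest.raises(ValueError, match="1..6"):
            missing_motif_scan("bad", positive_sequence, missing=0)


class TestScreenProteome:
    def test_planted_ids_and_only_planted_ids_are_called(self):
        spec = SyntheticSpec(n_positive=30, n_decoy_per_class=8, seed=7)
        records = generate(spec)
        outcomes = list(screen_proteome(records_as_io(records)))
        assert [o.protein_id for o in outcomes] == [
            r.truth.record_id for r in records
        ]
        called = {o.protein_id for o in outcomes if o.status == "alph"}
        planted = {r.truth.record_id for r in records if r.truth.label == "alph"}
        assert called == planted

    def test_summary_counts(self):
        spec = SyntheticSpec(n_positive=25, n_decoy_per_class=5, seed=3)
        records = generate(spec)
        outcomes = list(screen_proteome(records_as_io(records)))
        summary = summarise_outcomes(outcomes)
        assert summary.n_records == len(records)
        assert summary.n_alph == 25
        assert summary.n_negative == len(records) - 25
        extended_calls = sum(
            1 for o in outcomes if o.call and o.call.extended_count
        )
        assert summary.extended_call_fraction == extended_calls / 25


def records_as_io(records):
    """Adapt synthetic records to the record_id/sequence protocol."""

    class _Rec:
        def __init__(self, record):
            self.record_id = record.truth.record_id
            self.sequence = record.sequence

    return [_Rec(r) for r in records]


class TestOracleEquivalence:
    def test_screener_equals_enumeration_on_fixture_variants(self, oracle):
        variants = [
            build_fixture(),
            build_fixture({1: "GDXHG"}),
            build_fixture(d12="A" * 10),
            build_fixture({2: "GDLVDRG"}),
            "GDIHG" + "A" * 20 + build_fixture(),
            build_fixture() + build_fixture(),
        ]
        for sequence in variants:
            expected = oracle(sequence)
            outcome = screen_protein("v", sequence)
            if expected is None:
                assert outcome.status == "negative"
            else:
                assert outcome.status == "alph"
                assert tuple(h.start for h in outcome.call.hits) == expected[1]
                assert outcome.call.extended_count == expected[0]

    def test_screener_equals_enumeration_on_random_sequences(self, oracle, rng):
        # biased alphabet so motif fragments actually occur
        alphabet = list("GDHNAVILTEQKFYSG")
        for _ in range(60):
            sequence = "".join(rng.choice(alphabet, size=int(rng.integers(50, 300))))
            expected = oracle(sequence)
            outcome = screen_protein("r", sequence)
            assert (outcome.status == "alph") == (expected is not None)
            if expected is not None:
                assert tuple(h.start for h in outcome.call.hits) == expected[1]


class TestMonotonicity:
    def test_wider_bounds_and_budget_never_lose_a_positive(self):
        spec = SyntheticSpec(n_positive=20, seed=5)
        records = generate(spec)
        wide = DistanceConstraints(
            bounds={(1, 2): (10, 200), (2, 3): (20, 120), (5, 6): (10, 80)}
        )
        for record in records:
            base = screen_protein(record.truth.record_id, record.sequence)
            assert base.status == "alph"
            assert (
                screen_protein(
                    record.truth.record_id, record.sequence, constraints=wide
                ).status
                == "alph"
            )
            assert (
                screen_protein(
                    record.truth.record_id, record.sequence, extended_budget=4
                ).status
                == "alph"
            )

    def test_every_emitted_call_revalidates(self):
        spec = SyntheticSpec(n_positive=20, n_decoy_per_class=4, seed=9)
        constraints = DistanceConstraints()
        matrices = builtin_matrix_set()
        for record in generate(spec):
            outcome = screen_protein(record.truth.record_id, record.sequence)
            if outcome.status != "alph":
                continue
            call = outcome.call
            # re-check every hit and distance against the matrices/bounds
            from alphscreen.motif_model import matches_at

            for hit in call.hits:
                window = record.sequence[hit.start : hit.end]
                assert window == hit.matched
                primary, relaxed = matrices.matrices(hit.motif_index)
                if hit.flavour_used == "narrow":
                    assert matches_at(window, primary)
                else:
                    assert matches_at(window, relaxed)
                    assert not matches_at(window, primary)
            for pair, distance in zip(
                ((1, 2), (2, 3), (3, 4), (4, 5), (5, 6)), call.distances
            ):
                assert constraints.satisfied(pair, distance)
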