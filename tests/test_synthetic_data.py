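"""Generator properties: determinism, clean labels, decoy semantics and
spec validation."""

import numpy as np
import pytest

from alphscreen.motif_model import builtin_matrices, matches_at
from alphscreen.screener import missing_motif_scan, screen_protein
from alphscreen.synthetic_data import (
    DistanceModel,
    SyntheticSpec,
    SyntheticSpecError,
    generate,
    perturb_to_missing,
    truth_frame,
    write_corpus,
)


class TestSpecValidation:
    def test_defaults_are_legal(self):
        SyntheticSpec()

    def test_distance_outside_legal_bounds_rejected(self):
        with pytest.raises(SyntheticSpecError, match="outside the legal bounds"):
            SyntheticSpec(d12=DistanceModel(((1.0, 5, 29),)))

    def test_bin_weights_must_sum_to_one(self):
        with pytest.raises(SyntheticSpecError, match="weights"):
            DistanceModel(((0.5, 20, 25),))

    def test_unknown_decoy_class_rejected(self):
        with pytest.raises(SyntheticSpecError, match="decoy"):
            SyntheticSpec(decoy_classes=("not_a_class",))

    def test_mixture_probabilities(self):
        model = DistanceModel(((0.8, 19, 19), (0.2, 17, 21)))
        assert model.probability_at(19) == pytest.approx(0.8 + 0.2 / 5)
        assert model.probability_in(17, 18) == pytest.approx(0.2 * 2 / 5)


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_output(self, tmp_path):
        spec = SyntheticSpec(n_positive=15, n_decoy_per_class=3, seed=42)
        for run in ("one", "two"):
            out = tmp_path / run
            write_corpus(generate(spec), out / "c.fasta", out / "t.tsv")
        assert (tmp_path / "one/c.fasta").read_bytes() == (
            tmp_path / "two/c.fasta"
        ).read_bytes()
        assert (tmp_path / "one/t.tsv").read_bytes() == (
            tmp_path / "two/t.tsv"
        ).read_bytes()

    def test_different_seeds_differ(self):
        a = generate(SyntheticSpec(n_positive=5, seed=1))
        b = generate(SyntheticSpec(n_positive=5, seed=2))
        assert [r.sequence for r in a] != [r.sequence for r in b]


class TestPlantedPositives:
    def test_spans_match_recorded_flavours(self):
        narrow = builtin_matrices("narrow")
        extended = builtin_matrices("extended")
        records = generate(SyntheticSpec(n_positive=40, seed=8))
        saw_extended = False
        for record in records:
            truth = record.truth
            for k, (span, flavour) in enumerate(
                zip(truth.spans, truth.flavours), start=1
            ):
                window = record.sequence[span[0] - 1 : span[1]]
                if flavour == "extended":
                    saw_extended = True
                    assert matches_at(window, extended[k - 1])
                    assert not matches_at(window, narrow[k - 1])
                else:
                    assert matches_at(window, narrow[k - 1])
        assert saw_extended  # the extended rate is high enough to appear

    def test_planted_distances_are_the_gaps_between_spans(self):
        for record in generate(SyntheticSpec(n_positive=10, seed=4)):
            spans = record.truth.spans
            gaps = tuple(
                spans[i + 1][0] - 1 - spans[i][1] for i in range(5)
            )
            assert gaps == record.truth.distances


class TestDecoys:
    def decoys(self, decoy_class, n=12, seed=13):
        spec = SyntheticSpec(
            n_positive=0, n_decoy_per_class=n, decoy_classes=(decoy_class,),
            seed=seed,
        )
        return generate(spec)

    def test_ppp_like_r6_decoys_are_never_called(self):
        for record in self.decoys("ppp_like_R6"):
            assert record.sequence[
                record.truth.spans[1][0] + 4
            ] == "R"  # position 6 of the motif-2 span
            assert screen_protein("d", record.sequence).status == "negative"

    def test_distance_violations_are_never_called(self):
        for record in self.decoys("distance_violation"):
            assert screen_protein("d", record.sequence).status == "negative"
            assert record.truth.violated_pair in ((1, 2), (2, 3), (5, 6))

    def test_one_missing_decoys_flag_exactly_their_position(self):
        for record in self.decoys("one_missing", n=8):
            missing = record.truth.missing_index
            assert screen_protein("d", record.sequence).status == "negative"
            outcome = missing_motif_scan("d", record.sequence, missing=missing)
            assert outcome.status == "missing_one"
            assert outcome.missing_index == missing

    def test_terminal_truncations_flag_their_terminus(self):
        for record in self.decoys("terminal_truncation", n=8):
            assert screen_protein("d", record.sequence).status == "negative"
            outcome = missing_motif_scan(
                "d", record.sequence, missing=record.truth.missing_index
            )
            assert outcome.status == "missing_one"
            assert outcome.truncated_terminal == record.truth.truncated_side

    def test_random_background_contains_no_motif_window_at_all(self):
        extended = builtin_matrices("extended")
        for record in self.decoys("random_background", n=6):
            for matrix in extended:
                for start in range(len(record.sequence) - matrix.length + 1):
                    window = record.sequence[start : start + matrix.length]
                    assert not matches_at(window, matrix)


class TestPerturbToMissing:
    def test_perturbed_motif_is_undetectable(self):
        (record,) = generate(SyntheticSpec(n_positive=1, seed=21))
        for missing in (1, 3, 6):
            perturbed = perturb_to_missing(record, missing, seed=5)
            assert screen_protein("p", perturbed.sequence).status == "negative"
            outcome = missing_motif_scan(
                "p", perturbed.sequence, missing=missing
            )
            assert outcome.status == "missing_one"
            assert outcome.missing_index == missing
            assert perturbed.truth.spans[missing - 1] is None

    def test_other_spans_untouched(self):
        (record,) = generate(SyntheticSpec(n_positive=1, seed=22))
        perturbed = perturb_to_missing(record, 6, seed=5)
        for k in range(1, 6):
            span = record.truth.spans[k - 1]
            assert (
                perturbed.sequence[span[0] - 1 : span[1]]
                == record.sequence[span[0] - 1 : span[1]]
            )

    def test_requires_a_positive(self):
        (record,) = self_decoy()
        with pytest.raises(ValueError, match="positive"):
            perturb_to_missing(record, 1, seed=0)


def self_decoy():
    return generate(
        SyntheticSpec(
            n_positive=0, n_decoy_per_class=1,
            decoy_classes=("random_background",), seed=1,
        )
    )


class TestTruthFrame:
    def test_one_row_per_record_with_spans(self):
        records = generate(SyntheticSpec(n_positive=4, n_decoy_per_class=2, seed=6))
        frame = truth_frame(records)
        assert len(frame) == len(records)
        positives = frame[frame["label"] == "alph"]
        assert positives["m1_start"].notna().all()
        assert (positives["m6_end"] <= positives["length"]).all()

    def test_multi_isoform_organisms_share_labels(self):
        rng_free = generate(
            SyntheticSpec(n_positive=60, seed=10, multi_isoform_rate=1.0)
        )
        frame = truth_frame(rng_free)
        counts = frame.groupby("organism").size()
        assert (counts == 2).all()
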