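import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import PALINDROME_40, PALINDROME_48
from oracles import brute_scan
from plastcub.repeats import RepeatHit, annotate_hits, revcomp, scan
from plastcub.seqio import FeatureSpan, GenomeRecord


class TestRevcomp:
    @pytest.mark.parametrize(
        "seq,expected", [("ATGC", "GCAT"), ("AT", "AT"), ("N", "N")]
    )
    def test_examples(self, seq, expected):
        assert revcomp(seq) == expected

    @given(st.text(alphabet="ACGTN", max_size=200))
    @settings(max_examples=50, derandomize=True)
    def test_involution(self, seq):
        assert revcomp(revcomp(seq)) == seq

    def test_rejects_non_dna(self):
        with pytest.raises(ValueError):
            revcomp("ACGU")


class TestScan:
    def test_non_complementary_homopolymer_has_no_hits(self):
        assert scan("AAAAAA", min_len=4, max_mismatch=0) == []

    def test_perfect_palindrome_found_at_full_length(self):
        hits = scan(PALINDROME_48, min_len=30, max_mismatch=0)
        assert any(h.length == 48 and h.mismatches == 0 for h in hits)

    def test_hit_coordinates_are_one_based_inclusive(self):
        seq = "TTTT" + "ACGCGT" + "TTTT"
        hits = scan(seq, min_len=4, max_mismatch=0)
        inner = [h for h in hits if h.sequence == "ACGCGT"]
        assert inner and (inner[0].start, inner[0].end) == (5, 10)

    def test_every_zero_mismatch_hit_is_its_own_reverse_complement(self):
        rng = np.random.default_rng(15)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        for hit in scan(seq, min_len=4, max_mismatch=0):
            assert hit.sequence == revcomp(hit.sequence)
            assert hit.kind == "palindrome"

    def test_mismatch_budget_reports_per_hit_counts(self):
        hits = scan("TATAAGTGAACTAGATAAAGCGGAATCAAGATTCCGTTTTATCTAGTTCACTTATA",
                    min_len=40, max_mismatch=2)
        assert max(h.length for h in hits) == 56
        full = [h for h in hits if h.length == 56]
        assert full[0].mismatches == 2
        assert full[0].kind == "inverted_repeat"

    def test_window_containing_n_never_matches(self):
        seq = PALINDROME_48[:20] + "N" + PALINDROME_48[21:]
        hits = scan(seq, min_len=30, max_mismatch=2)
        assert hits == []

    def test_odd_min_len_rejected(self):
        with pytest.raises(ValueError):
            scan("ACGT", min_len=5, max_mismatch=0)

    def test_circular_scan_finds_origin_spanning_hit(self):
        # place the 40-mer across the origin: last 20 bases + first 20
        rng = np.random.default_rng(16)
        middle = "".join(rng.choice(list("ACGT"), size=300))
        seq = PALINDROME_40[20:] + middle + PALINDROME_40[:20]
        linear = [h for h in scan(seq, min_len=40, max_mismatch=0)]
        circular = scan(seq, min_len=40, max_mismatch=0, circular=True,
                        wrap=60)
        assert not any(h.length >= 40 for h in linear)
        spanning = [h for h in circular if h.length == 40]
        assert spanning and spanning[0].sequence == PALINDROME_40
        assert spanning[0].start == len(seq) - 19
        assert spanning[0].end == 20

    @pytest.mark.parametrize("min_len", [10, 20])
    @pytest.mark.parametrize("max_mismatch", [0, 1, 2])
    def test_matches_all_substrings_oracle(self, min_len, max_mismatch):
        rng = np.random.default_rng(min_len * 10 + max_mismatch)
        for _ in range(8):
            seq = "".join(rng.choice(list("ACGTN"), size=500,
                                     p=[0.248, 0.248, 0.248, 0.248, 0.008]))
            ours = [(h.start, h.end, h.mismatches)
                    for h in scan(seq, min_len, max_mismatch)]
            assert ours == brute_scan(seq, min_len, max_mismatch)


class TestAnnotateHits:
    @pytest.fixture()
    def annotated_genome(self):
        seq = "A" * 400
        features = (
            FeatureSpan("CDS", "psbT", 11, 40, "+"),
            FeatureSpan("CDS", "psbN", 101, 130, "+"),
            FeatureSpan("CDS", "petD", 201, 320, "+",
                        parts=((201, 240), (301, 320))),
        )
        return GenomeRecord("ANNOT", seq, features)

    def test_hit_inside_a_cds_gets_the_gene_name(self, annotated_genome):
        hit = RepeatHit("ATAT", 15, 18, 0)
        assert annotate_hits([hit], annotated_genome)[0].region == "psbT"

    def test_intergenic_hit_is_labelled_by_flanking_genes(self, annotated_genome):
        hit = RepeatHit("ATAT", 50, 53, 0)
        assert annotate_hits([hit], annotated_genome)[0].region == "psbT-psbN"

    def test_hit_between_exons_is_an_intron_hit(self, annotated_genome):
        hit = RepeatHit("ATAT", 250, 253, 0)
        assert annotate_hits([hit], annotated_genome)[0].region == "petD (intron)"

    def test_out_of_bounds_hit_raises(self, annotated_genome):
        with pytest.raises(ValueError):
            annotate_hits([RepeatHit("ATAT", 398, 401, 0)], annotated_genome)


class TestPlantedRecovery:
    def test_planted_repeats_recovered_exactly_with_no_extras(
        self, planted_genome
    ):
        genome, truth = planted_genome
        hits = scan(genome.sequence, min_len=30, max_mismatch=0,
                    circular=True)
        found = {(h.start, h.end, h.sequence) for h in hits}
        planted = {(r.start, r.end, r.sequence) for r in truth.repeats}
        assert found == planted

    def test_planted_hits_sorted_by_start(self, planted_genome):
        genome, truth = planted_genome
        starts = [r.start for r in truth.repeats]
        assert starts == sorted(starts)
        hits = scan(genome.sequence, min_len=30, max_mismatch=0)
        assert [h.start for h in hits] == sorted(h.start for h in hits)
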