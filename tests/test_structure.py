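import numpy as np
import pytest

from plastmark._seq import revcomp
from plastmark.records import Feature, PlastomeRecord
from plastmark.simulate import assemble_synthetic_plastomes
from plastmark.structure import (
    DEFAULT_SSR_THRESHOLDS,
    AmbiguousInvertedRepeatError,
    NoQuadripartiteStructureError,
    find_dispersed_repeats,
    find_quadripartite,
    junction_report,
    scan_ssrs,
)

from _oracles import repeats_bruteforce, ssr_regex_oracle
from conftest import tiny_plastome_config


def random_seq(rng, n, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


class TestQuadripartite:
    def test_recovers_planted_template_exactly(self):
        ds = assemble_synthetic_plastomes(tiny_plastome_config(seed=2))
        truth = ds.truth.true_partition
        for record in ds.records:
            part = find_quadripartite(record)
            assert (part.lsc, part.irb, part.ssc, part.ira) == (
                truth.lsc,
                truth.irb,
                truth.ssc,
                truth.ira,
            )

    def test_rotated_genome_gives_same_partition_up_to_rotation(self):
        ds = assemble_synthetic_plastomes(tiny_plastome_config(seed=3))
        record = ds.records[0]
        truth = ds.truth.true_partition
        n = truth.genome_length
        shift = 2500
        rotated = record.sequence[shift:] + record.sequence[:shift]
        part = find_quadripartite(rotated)
        for name in ("lsc", "irb", "ssc", "ira"):
            t0, t1 = getattr(truth, name)
            f0, f1 = getattr(part, name)
            assert f0 % n == (t0 - shift) % n
            assert (f1 - f0) == (t1 - t0)

    def test_ir_copies_are_reverse_complements(self):
        ds = assemble_synthetic_plastomes(tiny_plastome_config(seed=4))
        seq = ds.records[0].sequence
        part = find_quadripartite(seq)
        lengths = part.lengths()
        assert lengths["IRa"] == lengths["IRb"]
        irb = seq[part.irb[0] : part.irb[1]]
        ira = seq[part.ira[0] : part.ira[1]]
        assert revcomp(ira) == irb

    def test_random_sequence_has_no_quadripartite_structure(self):
        rng = np.random.default_rng(0)
        with pytest.raises(NoQuadripartiteStructureError):
            find_quadripartite(random_seq(rng, 10_000), min_ir_len=1000)

    def test_equal_length_competing_pairs_are_ambiguous(self):
        # 'C' guards block every extension of the planted copies
        rng = np.random.default_rng(1)
        block_a = "G" + random_seq(rng, 1198) + "G"
        block_b = "G" + random_seq(rng, 1198) + "G"
        spacer = [random_seq(rng, 800) for _ in range(4)]
        genome = (
            spacer[0] + "C" + block_a + "C" + spacer[1]
            + "C" + revcomp(block_a) + "C" + spacer[2]
            + "C" + block_b + "C" + spacer[3]
            + "C" + revcomp(block_b) + "C"
        )
        with pytest.raises(AmbiguousInvertedRepeatError):
            find_quadripartite(genome, min_ir_len=1000)


class TestJunctionReport:
    def _toy(self):
        ds = assemble_synthetic_plastomes(tiny_plastome_config(seed=6))
        record = ds.records[0]
        part = ds.truth.true_partition
        jlb = part.junctions["JLB"]
        jsb = part.junctions["JSB"]
        features = [
            Feature("near_jlb", "gene", "+", [(jlb - 121, jlb - 21)]),
            Feature("spans_jsb", "gene", "+", [(jsb - 30, jsb + 12)]),
        ]
        toy = PlastomeRecord(record.accession, record.sequence, True, features)
        return toy, part

    def test_gene_ending_21_bp_before_junction_reports_distance_21(self):
        toy, part = self._toy()
        table = junction_report([(toy, part)])
        row = table[(table.junction == "JLB")].iloc[0]
        assert row.gene == "near_jlb"
        assert row.distance == 21
        assert not row.overlap

    def test_gene_containing_junction_reports_overlap_offset(self):
        toy, part = self._toy()
        table = junction_report([(toy, part)])
        row = table[(table.junction == "JSB")].iloc[0]
        assert row.gene == "spans_jsb"
        assert row.overlap
        assert row.distance == -12

    def test_empty_neighborhood_reports_na(self):
        toy, part = self._toy()
        table = junction_report([(toy, part)], max_distance=50)
        row = table[(table.junction == "JSA")].iloc[0]
        assert row.gene is None
        assert np.isnan(row.distance)


class TestSSRScanner:
    def embed(self, rng, tract, flank=300):
        left = random_seq(rng, flank)
        right = random_seq(rng, flank)
        # guard the flanks so the planted tract stays maximal
        return left + "G" + tract + "G" + right

    # fixed non-repetitive flank (no tandem unit reaches any threshold)
    FLANK = "GACTGCTAGCATCGATCGTACGTAGCGATC"

    def test_mononucleotide_threshold_is_ten(self):
        seq10 = self.FLANK + "C" + "A" * 10 + "C" + self.FLANK
        hits = [s for s in scan_ssrs(seq10) if s.motif == "A"]
        assert [(s.n_repeats, s.interval) for s in hits] == [(10, (31, 41))]
        seq9 = self.FLANK + "C" + "A" * 9 + "C" + self.FLANK
        assert not [s for s in scan_ssrs(seq9) if s.motif == "A"]

    def test_dinucleotide_threshold_is_five(self):
        seq = self.FLANK + "G" + "AT" * 5 + "G" + self.FLANK
        found = [s for s in scan_ssrs(seq) if s.unit_len == 2]
        assert [(s.motif, s.n_repeats) for s in found] == [("AT", 5)]
        seq4 = self.FLANK + "G" + "AT" * 4 + "G" + self.FLANK
        assert not [s for s in scan_ssrs(seq4) if s.unit_len == 2]

    def test_tandem_of_shorter_motif_never_reported_at_longer_unit(self):
        seq = self.FLANK + "G" + "AT" * 12 + "G" + self.FLANK
        found = scan_ssrs(seq)
        assert {s.unit_len for s in found} == {2}
        assert found[0].motif == "AT"

    def test_compound_flag_for_nearby_ssrs(self):
        gap = (self.FLANK + self.FLANK)[:50]
        seq = (
            self.FLANK + "G" + "AAT" * 4 + "C" + gap + "C" + "AG" * 6 + "C"
            + self.FLANK
        )
        found = scan_ssrs(seq, compound_gap=100)
        planted = [s for s in found if s.motif in ("AAT", "AG")]
        assert len(planted) == 2
        assert all(s.compound for s in planted)
        found_far = scan_ssrs(seq, compound_gap=10)
        planted_far = [s for s in found_far if s.motif in ("AAT", "AG")]
        assert not any(s.compound for s in planted_far)

    def test_agrees_with_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            seq = random_seq(rng, 2000, p=(0.35, 0.15, 0.15, 0.35))
            got = {
                (s.motif, s.unit_len, s.n_repeats, *s.interval)
                for s in scan_ssrs(seq)
            }
            expected = ssr_regex_oracle(seq, DEFAULT_SSR_THRESHOLDS)
            assert got == expected


class TestDispersedRepeats:
    @staticmethod
    def _covers(results, kind, start1, start2, length):
        return any(
            r.kind == kind
            and r.pos1 <= start1
            and r.pos1 + r.length >= start1 + length
            and r.pos2 <= start2
            and r.pos2 + r.length >= start2 + length
            for r in results
        )

    def test_planted_exact_forward_duplicate(self):
        rng = np.random.default_rng(5)
        block = random_seq(rng, 40)
        seq = random_seq(rng, 500) + block + random_seq(rng, 500) + block
        # exact copy at mismatches=0 when no budget is allowed
        found = find_dispersed_repeats(seq, min_len=40, max_mismatch=0)
        assert self._covers(found, "forward", 500, 1040, 40)
        assert all(r.mismatches == 0 for r in found)

    def test_planted_reverse_complement_copy_is_palindromic(self):
        rng = np.random.default_rng(6)
        block = random_seq(rng, 40)
        seq = (
            random_seq(rng, 400) + block + random_seq(rng, 400) + revcomp(block)
        )
        found = find_dispersed_repeats(seq, min_len=40, max_mismatch=0)
        assert self._covers(found, "palindromic", 400, 840, 40)

    def test_mismatch_budget_controls_detection(self):
        rng = np.random.default_rng(7)
        block = random_seq(rng, 40)
        mutated = list(block)
        for pos in (5, 15, 25, 35):
            original = mutated[pos]
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[original]
        seq = random_seq(rng, 300) + block + random_seq(rng, 300) + "".join(mutated)
        start1 = 300
        start2 = 300 + 40 + 300
        hit = lambda results: any(
            r.pos1 <= start1 < r.pos1 + r.length
            and r.pos2 <= start2 < r.pos2 + r.length
            and r.kind == "forward"
            and r.length >= 40
            for r in results
        )
        assert not hit(find_dispersed_repeats(seq, min_len=40, max_mismatch=3))
        assert hit(find_dispersed_repeats(seq, min_len=40, max_mismatch=4))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 700, p=(0.4, 0.1, 0.1, 0.4))
        block = random_seq(rng, 45)
        seq = seq[:200] + block + seq[200:500] + revcomp(block) + seq[500:]
        got = {
            (r.kind, r.pos1, r.pos2, r.length, r.mismatches)
            for r in find_dispersed_repeats(seq, min_len=25, max_mismatch=2)
        }
        expected = repeats_bruteforce(seq, min_len=25, max_mismatch=2)
        assert got == expected
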