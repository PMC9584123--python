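"""Seed decomposition, hotspot generation, verification and classification."""

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seedmap as sm
from seedmap.mapper import (MappingParams, alignment_from_transcript,
                            collect_hotspots, estimate_mismap_probability,
                            map_all, map_read, prioritize_hotspots,
                            reverse_complement, split_into_seeds,
                            verify_candidate, Hotspot)


def _genome(seq, name="g"):
    return sm.ReferenceSet(((name, seq),))


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestSeeds:
    @pytest.mark.parametrize("length,seed_length,offsets", [
        (12, 6, [0, 6]),                       # exact multiple
        (14, 6, [0, 6, 8]),                    # tail-anchored extra seed
        (100, 10, list(range(0, 100, 10))),    # ten non-overlapping seeds
        (5, 6, []),                            # too short
    ])
    def test_offsets(self, length, seed_length, offsets):
        seq = "".join("ACGT"[i % 4] for i in range(length))
        seeds = split_into_seeds(seq, seed_length)
        assert [s.read_offset for s in seeds] == offsets
        for s in seeds:
            assert s.kmer == seq[s.read_offset:s.read_offset + seed_length]

    def test_tail_seed_covers_every_base(self):
        for length in range(6, 40):
            seeds = split_into_seeds("A" * length, 6)
            covered = set()
            for s in seeds:
                covered.update(range(s.read_offset, s.read_offset + 6))
            assert covered == set(range(length))


class TestReverseComplement:
    @pytest.mark.parametrize("seq,expected", [
        ("ACGT", "ACGT"), ("AACN", "NGTT"), ("", ""),
    ])
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            reverse_complement("ACXT")

    @given(st.text(alphabet="ACGTN", max_size=50))
    @settings(deadline=None, derandomize=True)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestHotspots:
    def _deletion_read(self):
        """200 nt reference; 100 nt read missing the reference base at
        read offset 50 (deletion at a seed boundary)."""
        rng = np.random.default_rng(42)
        ref = _rand_seq(rng, 200)
        read = ref[50:100] + ref[101:151]
        return ref, read

    def test_error_free_read_gives_one_full_vote_hotspot(self):
        rng = np.random.default_rng(7)
        ref = _rand_seq(rng, 2000)
        refs = _genome(ref)
        idx = sm.build_index(refs, 10)
        read = ref[500:600]
        (hot,) = collect_hotspots(split_into_seeds(read, 10), idx, 5)
        assert hot.votes == 10
        assert hot.diagonal_spread == 0
        assert hot.candidate_start == 500

    def test_deletion_read_groups_into_one_banded_hotspot(self):
        ref, read = self._deletion_read()
        idx = sm.build_index(_genome(ref), 10)
        hits = [h for h in collect_hotspots(split_into_seeds(read, 10),
                                            idx, 3)
                if h.votes > 1]
        (hot,) = hits
        assert hot.diagonal_spread == 1
        assert hot.votes == 10  # seeds left imply start 50, right imply 51

    def test_deletion_read_splits_without_banding(self):
        ref, read = self._deletion_read()
        idx = sm.build_index(_genome(ref), 10)
        hits = [h for h in collect_hotspots(split_into_seeds(read, 10),
                                            idx, 0)
                if h.votes > 1]
        assert sorted(h.votes for h in hits) == [5, 5]
        assert sorted(h.candidate_start for h in hits) == [50, 51]

    def test_prioritization_is_total_and_deterministic(self):
        hs = [Hotspot(0, "+", 30, 3, 0), Hotspot(1, "-", 10, 7, 0),
              Hotspot(0, "+", 20, 7, 0), Hotspot(0, "-", 20, 7, 0)]
        ordered = prioritize_hotspots(hs)
        assert [h.votes for h in ordered] == [7, 7, 7, 3]
        assert ordered[0] == Hotspot(0, "+", 20, 7, 0)  # ref asc, + first
        assert ordered[1] == Hotspot(0, "-", 20, 7, 0)
        assert ordered[2] == Hotspot(1, "-", 10, 7, 0)
        assert prioritize_hotspots([]) == []


class TestVerify:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.ref = _rand_seq(rng, 400)
        self.refs = _genome(self.ref)
        self.params = MappingParams(max_errors=5)

    def test_identical_window(self):
        read = self.ref[100:200]
        aln = verify_candidate(read, self.refs, Hotspot(0, "+", 100, 10, 0),
                               5, self.params)
        assert (aln.edit_distance, aln.mismatches, aln.ref_start,
                aln.ref_end) == (0, 0, 100, 200)

    def test_single_substitution(self):
        read = list(self.ref[100:200])
        orig = read[40]
        read[40] = {"A": "C", "C": "G", "G": "T", "T": "A"}[orig]
        aln = verify_candidate("".join(read), self.refs,
                               Hotspot(0, "+", 100, 9, 0), 5, self.params)
        assert aln.edit_distance == 1
        assert aln.mismatches == 1
        assert aln.indel_events == ()
        assert aln.alignment_string == f"40={read[40].lower()}59="

    def test_two_nt_deletion_agrees_with_unbanded_dp(self):
        read = self.ref[100:150] + self.ref[152:202]
        aln = verify_candidate(read, self.refs,
                               Hotspot(0, "+", 100, 10, 2), 5, self.params)
        assert aln.edit_distance == 2
        assert aln.indel_events == (("del", 150, 2),)
        # independent oracle: unbanded infix alignment over the whole ref
        oracle = edlib.align(read, self.ref, mode="HW")
        assert oracle["editDistance"] == aln.edit_distance

    def test_beyond_allowance_returns_none(self):
        rng = np.random.default_rng(11)
        read = _rand_seq(rng, 100)
        d = edlib.align(read, self.ref, mode="HW")["editDistance"]
        assert d > 5  # random read is far from this reference
        assert verify_candidate(read, self.refs, Hotspot(0, "+", 100, 1, 0),
                                5, self.params) is None

    def test_hamming_mode_when_indels_off(self):
        params = MappingParams(max_errors=5, allow_indels=False)
        read = self.ref[100:150] + self.ref[152:202]  # needs a deletion
        assert verify_candidate(read, self.refs, Hotspot(0, "+", 100, 10, 0),
                                5, params) is None

    def test_read_overhanging_reference_end(self):
        read = self.ref[-50:] + "ACGTACGTAC"
        assert verify_candidate(read, self.refs,
                                Hotspot(0, "+", len(self.ref) - 50, 5, 0),
                                5, self.params) is None


class TestMapRead:
    def test_verbatim_read_maps_uniquely(self, small_genome, small_index):
        seq = small_genome.sequences[0][4000:4100]
        rec = map_read(sm.Read("q", seq), small_index, MappingParams())
        assert rec.status == "unique"
        (aln,) = rec.alignments
        assert (aln.ref_start, aln.strand, aln.edit_distance) == (4000, "+", 0)

    def test_reverse_strand_read(self, small_genome, small_index):
        seq = reverse_complement(small_genome.sequences[0][4000:4100])
        rec = map_read(sm.Read("q", seq), small_index, MappingParams())
        (aln,) = rec.alignments
        assert (aln.ref_start, aln.strand) == (4000, "-")

    def test_duplicated_locus_is_multi_with_two_alignments(self):
        rng = np.random.default_rng(3)
        unit = _rand_seq(rng, 150)
        ref = _rand_seq(rng, 500) + unit + _rand_seq(rng, 500) + unit \
            + _rand_seq(rng, 500)
        idx = sm.build_index(_genome(ref), 10)
        rec = map_read(sm.Read("q", unit[20:120]), idx, MappingParams())
        assert rec.status == "multi"
        assert len(rec.alignments) == 2
        assert len({a.edit_distance for a in rec.alignments}) == 1

    def test_random_read_is_unmapped(self, small_genome, small_index):
        rng = np.random.default_rng(8)
        for _ in range(5):
            read = _rand_seq(rng, 100)
            best = min(
                edlib.align(s, small_genome.sequences[0],
                            mode="HW")["editDistance"]
                for s in (read, reverse_complement(read)))
            if best > 5:
                rec = map_read(sm.Read("q", read), small_index,
                               MappingParams(max_errors=5))
                assert rec.status == "unmapped"

    def test_too_short_read(self, small_index):
        rec = map_read(sm.Read("q", "ACGT"), small_index, MappingParams())
        assert rec.status == "unmapped"
        assert rec.reason == "too_short"

    def test_percent_allowance_scales_with_read_length(self, small_genome,
                                                       small_index):
        seq = list(small_genome.sequences[0][2000:2100])
        for pos in (10, 30, 50, 70):  # 4 substitutions
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        read = sm.Read("q", "".join(seq))
        # 3% of 100 nt allows 3 errors -> unmapped; 5% allows 5 -> mapped
        strict = MappingParams(max_errors=None, error_percent=0.03)
        loose = MappingParams(max_errors=None, error_percent=0.05)
        assert map_read(read, small_index, strict).status == "unmapped"
        assert map_read(read, small_index, loose).status == "unique"


class TestMapAll:
    def test_error_free_reads_all_map(self, small_genome, small_index):
        reads, _ = sm.simulate_reads(small_genome, 100, 100, seed=5)
        _, summary = map_all(reads, small_index, MappingParams())
        assert summary.mapping_rate == 1.0

    def test_counts_conserve(self, small_genome, small_index):
        reads, _ = sm.simulate_reads(small_genome, 200, 100, sub_rate=0.03,
                                     ins_rate=0.005, del_rate=0.005, seed=6)
        records, summary = map_all(reads, small_index, MappingParams())
        assert summary.unique + summary.multi + summary.unmapped == \
            summary.total == len(records)

    def test_empty_input(self, small_index):
        records, summary = map_all([], small_index, MappingParams())
        assert records == []
        assert summary.total == 0
        assert summary.mapping_rate == 0.0
        assert summary.empty_input

    def test_mapping_rate_monotone_in_allowance(self, small_genome,
                                                small_index):
        reads, _ = sm.simulate_reads(small_genome, 300, 100, sub_rate=0.04,
                                     seed=9)
        rates = []
        for allow in range(3, 8):
            _, summary = map_all(reads, small_index,
                                 MappingParams(max_errors=allow))
            rates.append(summary.mapping_rate)
        assert rates == sorted(rates)

    def test_per_read_independence(self, small_genome, small_index):
        reads, _ = sm.simulate_reads(small_genome, 100, 100, sub_rate=0.02,
                                     seed=10)
        records, _ = map_all(reads, small_index, MappingParams())
        shuffled = list(reversed(reads))
        records2, _ = map_all(shuffled, small_index, MappingParams())
        assert {r.read_id: r for r in records} == \
            {r.read_id: r for r in records2}


class TestMismapProbability:
    def test_zero_error_rate_gives_zero(self):
        assert estimate_mismap_probability(100, 10, 0.0) == 0.0

    def test_formula_value(self):
        q = 1 - 0.99 ** 10
        expected = q ** 10
        got = estimate_mismap_probability(100, 10, 0.01)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(6.43e-11, rel=0.01)

    def test_single_seed_reduction(self):
        assert estimate_mismap_probability(10, 10, 0.1) == \
            pytest.approx(1 - 0.9 ** 10)

    def test_per_seed_corruption_matches_monte_carlo(self):
        # the q = 1-(1-p)^s factor checked by direct simulation
        rng = np.random.default_rng(0)
        p, s, trials = 0.05, 10, 200_000
        corrupted = (rng.random((trials, s)) < p).any(axis=1).mean()
        assert corrupted == pytest.approx(1 - 0.95 ** 10, abs=0.005)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            estimate_mismap_probability(100, 10, 1.0)


class TestParams:
    def test_exactly_one_allowance_mode(self):
        with pytest.raises(ValueError):
            MappingParams(max_errors=5, error_percent=0.05)
        with pytest.raises(ValueError):
            MappingParams(max_errors=None, error_percent=None)

    def test_seed_length_range(self):
        with pytest.raises(ValueError):
            MappingParams(seed_length=5)
        with pytest.raises(ValueError):
            MappingParams(seed_length=15)

    def test_band_zero_when_indels_off(self):
        params = MappingParams(allow_indels=False, indel_band=5)
        assert params.indel_band == 0

    def test_percent_allowance_floor(self):
        params = MappingParams(max_errors=None, error_percent=0.07)
        assert params.allowance(100) == 7
        assert params.allowance(99) == 6
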