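"""Aligner: pigeonhole index, <=1-mismatch placement, tie-breaks, SAM I/O."""

from __future__ import annotations

import numpy as np
import pytest

from oracles import brute_force_alignments
from visrna.align import (
    AlignmentRecord,
    ReferenceIndex,
    align_library,
    align_read,
    build_index,
    count_mismatches,
    enumerate_alignments,
    read_sam,
    write_sam,
)
from visrna.preprocess import TrimmedRead
from visrna.simulate import revcomp


def kept_read(seq: str, rid: str = "r") -> TrimmedRead:
    return TrimmedRead(rid, seq, len(seq), True, "none")


def random_reads(reference: str, rng, n: int, mutate: int = 0, decoy: bool = False):
    """Planted reads (0 or 1 substitution) or unrelated decoys."""
    reads = []
    for i in range(n):
        length = int(rng.integers(19, 34))
        if decoy:
            seq = "".join("ACGT"[j] for j in rng.integers(0, 4, size=length))
        else:
            start = int(rng.integers(0, len(reference) - length + 1))
            seq = reference[start : start + length]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            chars = list(seq)
            for _ in range(mutate):
                pos = int(rng.integers(length))
                chars[pos] = "ACGT"[(("ACGT".index(chars[pos])) + 1 + int(rng.integers(3))) % 4]
            seq = "".join(chars)
        reads.append(seq)
    return reads


class TestIndex:
    def test_enumerated_lookup(self):
        index = build_index("r", "ACGTACGT", seed_len=4)
        assert index.lookup("ACGT") == (0, 4)
        assert index.lookup("CGTA") == (1,)
        assert index.lookup("TTTT") == ()

    def test_rebuild_deterministic(self, random_genome):
        a = build_index("r", random_genome)
        b = build_index("r", random_genome)
        assert a._table == b._table

    def test_every_substring_found_at_all_true_positions(self, random_genome):
        index = build_index("r", random_genome, seed_len=9)
        for start in range(len(random_genome) - 9 + 1):
            kmer = random_genome[start : start + 9]
            true_positions = tuple(
                p
                for p in range(len(random_genome) - 8)
                if random_genome[p : p + 9] == kmer
            )
            assert index.lookup(kmer) == true_positions

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            build_index("r", "")


class TestAlignRead:
    REF = "AAAACCCCGGGGTTTTAAAACCCCGGGG"

    def test_exact_forward_placement(self, rng):
        # the read matches exactly at +4; its reverse complement also occurs
        # at 16 in this repetitive reference, so both are valid placements
        index = build_index("r", self.REF)
        candidates = enumerate_alignments("CCCCGGGGTTTT", index)
        assert ("+", 4, 0) in candidates
        rec = align_read("CCCCGGGGTTTT", index, rng)
        assert rec.mismatches == 0
        assert (rec.strand, rec.start) in {("+", 4), ("-", 16)}

    def test_reverse_complement_placement(self, rng):
        index = build_index("r", self.REF)
        rec = align_read(revcomp(self.REF[4:16]), index, rng)
        assert (rec.strand, rec.start, rec.mismatches) == ("-", 4, 0)
        assert rec.sequence == self.REF[4:16]  # stored reference-forward

    def test_unmapped_returns_none(self, rng, random_genome):
        index = build_index("r", random_genome)
        assert align_read("T" * 25, index, rng) is None

    def test_n_counts_as_mismatch(self, rng, random_genome):
        index = build_index("r", random_genome)
        seq = random_genome[100:125]
        one_n = seq[:5] + "N" + seq[6:]
        rec = align_read(one_n, index, rng)
        assert rec is not None and rec.mismatches == 1
        two_n = "N" + seq[1:5] + "N" + seq[6:]
        candidates = enumerate_alignments(two_n, index)
        assert all(start != 100 or strand != "+" for strand, start, _ in candidates)

    def test_candidate_sets_match_brute_force(self, random_genome):
        rng = np.random.default_rng(99)
        reads = (
            random_reads(random_genome, rng, 60, mutate=0)
            + random_reads(random_genome, rng, 60, mutate=1)
            + random_reads(random_genome, rng, 40, mutate=2)
            + random_reads(random_genome, rng, 40, decoy=True)
        )
        index = build_index("r", random_genome)
        for seq in reads:
            assert enumerate_alignments(seq, index) == brute_force_alignments(
                seq, random_genome
            )

    def test_no_false_negatives_for_planted_reads(self, random_genome):
        rng = np.random.default_rng(5)
        index = build_index("r", random_genome)
        for seq in random_reads(random_genome, rng, 100, mutate=1):
            assert align_read(seq, index, np.random.default_rng(0)) is not None

    def test_strand_mirror(self, random_genome):
        rng = np.random.default_rng(17)
        index = build_index("r", random_genome)
        for seq in random_reads(random_genome, rng, 50, mutate=0):
            if len(enumerate_alignments(seq, index)) != 1:
                continue  # mirror is only well-defined for unique mappers
            fwd = align_read(seq, index, np.random.default_rng(0))
            rev = align_read(revcomp(seq), index, np.random.default_rng(0))
            assert (rev.start, rev.read_length) == (fwd.start, fwd.read_length)
            assert {rev.strand, fwd.strand} == {"+", "-"}

    def test_best_stratum_preferred(self, rng):
        reference = "ACGTACGTACGTACGTACGTACC" + "ACGTACGTACGTACGTACGTACG"
        index = build_index("r", reference)
        read = "ACGTACGTACGTACGTACGTACG"  # exact at 23, 1-mismatch at 0
        rec = align_read(read, index, rng)
        assert rec.mismatches == 0 and rec.start == 23

    def test_tiebreak_is_seeded_and_uniform(self):
        reference = "TTTT" + "ACGTTGCAACGTACGTACGTA" + "CC" + "ACGTTGCAACGTACGTACGTA" + "TTTT"
        read = "ACGTTGCAACGTACGTACGTA"
        index = build_index("r", reference)
        rec1 = align_read(read, index, np.random.default_rng(3))
        rec2 = align_read(read, index, np.random.default_rng(3))
        assert rec1 == rec2
        starts = [
            align_read(read, index, np.random.default_rng(i)).start for i in range(200)
        ]
        counts = {s: starts.count(s) for s in set(starts)}
        assert set(counts) == {4, 27}
        assert min(counts.values()) > 50  # roughly uniform over the tie set


class TestAlignLibrary:
    def test_zero_library_total_rejected(self, random_genome):
        index = build_index("v", random_genome)
        with pytest.raises(ValueError):
            align_library([], {"v": index}, library_total=0)

    def test_host_only_library_maps_nowhere(self, random_genome):
        rng = np.random.default_rng(8)
        host = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3000))
        reads = [kept_read(s, f"h{i}") for i, s in enumerate(random_reads(host, rng, 50))]
        index = build_index("v", random_genome)
        result = align_library(reads, {"v": index}, library_total=50)
        assert result["v"].n_mapped == 0
        assert result["v"].n_unmapped == 50

    def test_planted_reads_all_map_and_runs_are_deterministic(self, random_genome):
        rng = np.random.default_rng(21)
        reads = [
            kept_read(s, f"p{i}")
            for i, s in enumerate(random_reads(random_genome, rng, 200, mutate=0))
        ]
        index = build_index("v", random_genome)
        a = align_library(reads, {"v": index}, library_total=200, seed=4)
        b = align_library(reads, {"v": index}, library_total=200, seed=4)
        assert a["v"].n_mapped == 200
        assert a["v"].records == b["v"].records


class TestSam:
    def make_alignment(self, random_genome):
        records = [
            AlignmentRecord("fwd", "v", "+", 0, 21, 0, random_genome[0:21]),
            AlignmentRecord("rev", "v", "-", 4, 12, 1, random_genome[4:16]),
        ]
        from visrna.align import LibraryAlignment

        return LibraryAlignment("v", len(random_genome), records, library_total=1000)

    def test_sam_conventions(self, tmp_path, random_genome):
        alignment = self.make_alignment(random_genome)
        path = tmp_path / "out.sam"
        write_sam(alignment, path)
        lines = path.read_text().splitlines()
        assert any(l.startswith("@SQ") and f"LN:{len(random_genome)}" in l for l in lines)
        body = [l.split("\t") for l in lines if not l.startswith("@")]
        fwd = next(f for f in body if f[0] == "fwd")
        rev = next(f for f in body if f[0] == "rev")
        assert (fwd[1], fwd[3]) == ("0", "1")  # FLAG 0, POS 1-based
        assert (rev[1], rev[3]) == ("16", "5")
        assert rev[9] == random_genome[4:16]  # SEQ reference-forward
        assert "NM:i:1" in rev

    def test_round_trip(self, tmp_path, random_genome):
        alignment = self.make_alignment(random_genome)
        path = tmp_path / "out.sam"
        write_sam(alignment, path)
        back = read_sam(path)
        assert back.records == alignment.records
        assert back.library_total == 1000
        assert back.reference_length == len(random_genome)


def test_count_mismatches_n_rule():
    assert count_mismatches("ACGT", "ACGT") == 0
    assert count_mismatches("ACGT", "ACGA") == 1
    assert count_mismatches("NCGT", "ACGT") == 1
    assert count_mismatches("NCGT", "NCGT") == 1  # N vs N still a mismatch
    assert count_mismatches("AAAA", "TTTT", limit=1) == 2  # early exit caps at limit+1
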