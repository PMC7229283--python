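"""Pileup construction, SAM/FASTA round trips, majority-vote baseline."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polishnet import pileup, simgen
from polishnet.pileup import AlignedRead, build_pileup, majority_vote
from .conftest import random_reads


def brute_force_consensus(contig, reads):
    """Independent oracle: recount symbols per column directly from the edit
    scripts and apply the stated majority rule (ties A<C<G<T<gap; insertion
    slot emitted when its count strictly exceeds half the left-flank depth)."""
    n = len(contig)
    cols = [collections.Counter() for _ in range(n)]
    ins = [collections.Counter() for _ in range(n)]
    ins_n = [0] * n
    depth = [0] * n
    for r in reads:
        pos, qi = r.start, 0
        for op, ln in r.cigar:
            if op == "M":
                for k in range(ln):
                    cols[pos + k][r.sequence[qi + k]] += 1
                pos += ln
                qi += ln
            elif op == "D":
                for k in range(ln):
                    cols[pos + k]["-"] += 1
                pos += ln
            else:
                if pos - 1 >= 0:
                    ins[pos - 1][r.sequence[qi]] += 1
                    ins_n[pos - 1] += 1
                qi += ln
        for p in range(r.start, pos):
            depth[p] += 1
    order = "ACGT-"
    out = []
    for i in range(n):
        if depth[i] == 0:
            out.append(contig[i])
        else:
            best = max(order, key=lambda s: (cols[i][s], -order.index(s)))
            if best != "-":
                out.append(best)
        if ins_n[i] * 2 > depth[i]:
            best = max("ACGT", key=lambda s: (ins[i][s], -order.index(s)))
            out.append(best)
    return "".join(out)


class TestIO:
    def test_fasta_round_trip(self, tmp_path, tiny_genome):
        path = tmp_path / "x.fa"
        pileup.write_fasta(path, {"c1": tiny_genome, "c2": "ACGT"})
        back = pileup.load_assembly(path)
        assert back == {"c1": tiny_genome, "c2": "ACGT"}

    def test_sam_round_trip_lossless(self, tmp_path, tiny_genome, rng):
        reads = random_reads(rng, tiny_genome, 30)
        contigs = {"contig": tiny_genome}
        path = tmp_path / "x.sam"
        pileup.write_alignments(path, reads, contigs)
        back, skipped = pileup.load_alignments(path, contigs)
        assert skipped == 0
        assert [
            (r.read_id, r.contig_id, r.start, r.strand, tuple(r.cigar), r.sequence)
            for r in back
        ] == [
            (r.read_id, r.contig_id, r.start, r.strand, tuple(r.cigar), r.sequence)
            for r in reads
        ]

    def test_sam_pos_is_one_based_on_disk(self, tmp_path):
        contigs = {"c": "ACGTA"}
        r = AlignedRead("r1", "c", 0, "+", [("M", 5)], "ACGTA")
        path = tmp_path / "x.sam"
        pileup.write_alignments(path, [r], contigs)
        line = [l for l in open(path) if not l.startswith("@")][0]
        assert line.split("\t")[3] == "1"  # POS is 1-based in SAM
        back, _ = pileup.load_alignments(path, contigs)
        assert back[0].start == 0 and back[0].cigar == [("M", 5)]

    def test_unmapped_records_skipped_and_counted(self, tmp_path):
        contigs = {"c": "ACGTACGT"}
        path = tmp_path / "x.sam"
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\n@SQ\tSN:c\tLN:8\n")
            fh.write("r1\t0\tc\t1\t60\t4M\t*\t0\t0\tACGT\tIIII\n")
            fh.write("r2\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n")  # unmapped
        reads, skipped = pileup.load_alignments(path, contigs)
        assert len(reads) == 1
        assert skipped == 1

    def test_soft_clips_excluded(self, tmp_path):
        contigs = {"c": "ACGTACGT"}
        path = tmp_path / "x.sam"
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\n@SQ\tSN:c\tLN:8\n")
            fh.write("r1\t0\tc\t3\t60\t2S4M1S\t*\t0\t0\tTTACGTC\tIIIIIII\n")
        reads, _ = pileup.load_alignments(path, contigs)
        assert reads[0].start == 2
        assert reads[0].cigar == [("M", 4)]
        assert reads[0].sequence == "ACGT"

    def test_cigar_sequence_mismatch_raises(self):
        with pytest.raises(ValueError, match="r1"):
            AlignedRead("r1", "c", 0, "+", [("M", 5)], "ACG")


class TestBuildPileup:
    def test_perfect_read_bookkeeping(self):
        contig = "ACGTACGTAC"
        r = AlignedRead("r", "contig", 0, "+", [("M", 10)], contig)
        pl = build_pileup(contig, [r])
        assert (pl.depth == 1).all()
        for i, b in enumerate(contig):
            assert pl.counts[i, 0, "ACGT".index(b)] == 1
            assert pl.counts[i].sum() == 1

    def test_deletion_bookkeeping(self):
        contig = "ACGTACGT"
        reads = [
            AlignedRead("a", "c", 0, "+", [("M", 8)], contig),
            AlignedRead("b", "c", 0, "+", [("M", 4), ("D", 1), ("M", 3)], "ACGTCGT"),
            AlignedRead("c", "c", 0, "-", [("M", 8)], contig),
        ]
        pl = build_pileup(contig, reads)
        assert pl.depth[4] == 3
        assert pl.counts[4, :, 4].sum() == 1  # one gap
        assert pl.counts[4, :, :4].sum() == 2

    def test_insertion_slot(self):
        contig = "ACGT"
        r = AlignedRead("r", "c", 0, "+", [("M", 2), ("I", 2), ("M", 2)], "ACTTGT")
        pl = build_pileup(contig, [r])
        assert pl.ins_count[1, 0] == 1
        assert pl.ins_first[1, 0, 3] == 1  # first inserted base T
        assert pl.ins_len_sum[1, 0] == 2

    def test_overhanging_read_raises(self):
        with pytest.raises(ValueError, match="rx"):
            build_pileup("ACGT", [AlignedRead("rx", "c", 2, "+", [("M", 4)], "ACGT")])

    def test_counts_equal_depth_fuzz(self, rng, tiny_genome):
        """Conservation: per-position symbol counts sum to spanning-read depth."""
        contig = tiny_genome[:50]
        for _ in range(20):
            reads = random_reads(rng, contig, int(rng.integers(1, 9)))
            pl = build_pileup(contig, reads)
            assert (pl.counts.sum(axis=(1, 2)) == pl.depth).all()
            assert pl.depth.sum() == sum(r.end - r.start for r in reads)

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_conservation_hypothesis(self, seed):
        rng = np.random.default_rng(seed)
        contig = simgen.simulate_genome(30, 0.5, seed=seed)
        reads = random_reads(rng, contig, int(rng.integers(1, 10)))
        pl = build_pileup(contig, reads)
        assert (pl.counts.sum(axis=(1, 2)) == pl.depth).all()


class TestMajorityVote:
    def test_simple_majority(self):
        contig = "AAAA"
        reads = [
            AlignedRead(f"r{i}", "c", 0, "+", [("M", 4)], s)
            for i, s in enumerate(["AAAA", "AAAA", "ACAA", "AAAA"])
        ]
        assert majority_vote(build_pileup(contig, reads)) == "AAAA"

    def test_gap_majority_drops_position(self):
        contig = "ACGT"
        reads = [
            AlignedRead(f"r{i}", "c", 0, "+", [("M", 1), ("D", 1), ("M", 2)], "AGT")
            for i in range(4)
        ] + [AlignedRead("r9", "c", 0, "+", [("M", 4)], "ACGT")]
        assert majority_vote(build_pileup(contig, reads)) == "AGT"

    def test_zero_depth_passes_draft_through(self):
        contig = "ACGTACGT"
        r = AlignedRead("r", "c", 0, "+", [("M", 4)], "ACGT")
        assert majority_vote(build_pileup(contig, [r])) == contig

    def test_error_free_reads_reproduce_template(self, tiny_genome):
        prof = simgen.ErrorProfile(sub_rate=0, ins_rate=0, del_rate=0,
                                   homopolymer_del_boost=1.0)
        reads = simgen.simulate_reads(tiny_genome, 8.0, prof, mean_len=300, seed=3)
        aligned = pileup.to_aligned_reads(reads, "contig")
        assert majority_vote(build_pileup(tiny_genome, aligned)) == tiny_genome

    def test_matches_brute_force_oracle(self, rng, tiny_genome):
        for _ in range(60):
            contig = tiny_genome[: int(rng.integers(3, 11))]
            reads = random_reads(rng, contig, int(rng.integers(1, 9)))
            assert majority_vote(build_pileup(contig, reads)) == brute_force_consensus(
                contig, reads
            )


class TestRealignBanded:
    def test_realign_recovers_alignment(self, tiny_genome):
        reads = simgen.simulate_reads(tiny_genome, 5.0, simgen.ErrorProfile(),
                                      mean_len=300, seed=7)
        template_reads = pileup.to_aligned_reads(reads, "contig")
        realigned = pileup.realign_banded(template_reads, tiny_genome)
        assert len(realigned) == len(reads)
        pl = build_pileup(tiny_genome, realigned)
        # re-aligned evidence still supports the template almost everywhere
        summed = pl.counts.sum(axis=1)
        covered = pl.depth > 2
        best = summed.argmax(axis=1)
        ref = np.array(["ACGT".index(b) for b in tiny_genome])
        assert (best[covered] == ref[covered]).mean() > 0.97
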