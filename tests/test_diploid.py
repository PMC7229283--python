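"""Het-site detection, greedy phasing and the diploid pipeline reductions."""

import numpy as np
import pytest

from polishnet import diploid, network, pileup, simgen, tensorize
from polishnet.diploid import HetSite, detect_het_sites, phase_reads
from polishnet.pileup import AlignedRead, build_pileup


def _snp_reads(contig, alleles_by_hap, n_per_hap=6, read_len=None):
    """Clean reads per haplotype differing only at the given SNP positions."""
    read_len = read_len or len(contig)
    reads = []
    for hap, alleles in alleles_by_hap.items():
        seq = list(contig)
        for pos, base in alleles.items():
            seq[pos] = base
        hap_seq = "".join(seq)
        for i in range(n_per_hap):
            reads.append(
                AlignedRead(
                    read_id=f"{hap}_{i}",
                    contig_id="c",
                    start=0,
                    strand="+" if i % 2 else "-",
                    cigar=[("M", read_len)],
                    sequence=hap_seq[:read_len],
                )
            )
    return reads


class TestDetectHetSites:
    def test_balanced_split_detected(self):
        contig = "A" * 29
        reads = [
            AlignedRead(f"r{i}", "c", 0, "+", [("M", 29)],
                        ("C" if i < 14 else "A") + "A" * 28)
            for i in range(29)
        ]
        sites = detect_het_sites(build_pileup(contig, reads), min_depth=10, min_af=0.25)
        assert [s.position for s in sites] == [0]
        assert {sites[0].allele_a, sites[0].allele_b} == {"A", "C"}
        assert sites[0].depth == 29

    def test_low_minor_fraction_not_reported(self):
        contig = "A" * 29
        reads = [
            AlignedRead(f"r{i}", "c", 0, "+", [("M", 29)],
                        ("C" if i < 2 else "A") + "A" * 28)
            for i in range(29)
        ]
        assert detect_het_sites(build_pileup(contig, reads)) == []

    def test_min_depth_respected(self):
        contig = "AAAA"
        reads = [
            AlignedRead(f"r{i}", "c", 0, "+", [("M", 4)], ("C" if i < 3 else "A") * 1 + "AAA")
            for i in range(6)
        ]
        assert detect_het_sites(build_pileup(contig, reads), min_depth=10) == []


class TestPhaseReads:
    def test_clean_bipartition_up_to_label_swap(self, tiny_genome):
        contig = tiny_genome[:100]
        sites_pos = [10, 30, 50, 70, 90]
        aA = {p: "A" for p in sites_pos}
        aB = {p: "C" for p in sites_pos}
        reads = _snp_reads(contig, {"X": aA, "Y": aB}, n_per_hap=8)
        pl = build_pileup(contig, reads)
        sites = detect_het_sites(pl)
        assert len(sites) == 5
        assign = phase_reads(reads, sites)
        groups = {
            hap: {rid.split("_")[0] for rid, h in assign.assignment.items() if h == hap}
            for hap in ("H1", "H2")
        }
        assert groups["H1"] != set() and groups["H2"] != set()
        assert (groups["H1"], groups["H2"]) in ((({"X"}), ({"Y"})), (({"Y"}), ({"X"})))

    def test_read_without_sites_unassigned(self, tiny_genome):
        contig = tiny_genome[:100]
        reads = _snp_reads(contig, {"X": {10: "A"}, "Y": {10: "C"}}, n_per_hap=8)
        stray = AlignedRead("stray", "c", 40, "+", [("M", 20)], contig[40:60])
        sites = detect_het_sites(build_pileup(contig, reads + [stray]))
        assign = phase_reads(reads + [stray], sites)
        assert assign.assignment["stray"] == diploid.UNASSIGNED

    def test_no_sites_all_unassigned(self, tiny_genome):
        contig = tiny_genome[:50]
        reads = _snp_reads(contig, {"X": {}}, n_per_hap=4)
        assign = phase_reads(reads, [])
        assert set(assign.assignment.values()) == {diploid.UNASSIGNED}

    def test_indel_sites_excluded_from_phasing(self):
        site = HetSite(position=5, allele_a="A", allele_b="-", count_a=10,
                       count_b=10, depth=20)
        assert site.is_indel
        reads = [AlignedRead("r0", "c", 0, "+", [("M", 10)], "A" * 10)]
        assign = phase_reads(reads, [site])
        assert assign.assignment["r0"] == diploid.UNASSIGNED


class TestHetRecallOnSimulatedDiploid:
    def test_recall_of_true_het_snvs(self):
        """Simulated diploid at 30x: detection recovers >= 90% of true het SNVs."""
        ref = simgen.simulate_genome(50_000, 0.5, seed=60)
        h1, h2, variants = simgen.simulate_diploid(ref, 0.001, 0.0001, seed=61)
        prof = simgen.ErrorProfile()
        reads = simgen.simulate_reads(h1, 15.0, prof, 5000, 62, haplotype="H1",
                                      id_prefix="a")
        reads += simgen.simulate_reads(h2, 15.0, prof, 5000, 63, haplotype="H2",
                                       id_prefix="b")
        aligned = pileup.map_reads(
            pileup.to_aligned_reads(reads, "ref"), ref, contig_id="ref"
        )
        pl = build_pileup(ref, aligned, contig_id="ref")
        sites = detect_het_sites(pl)
        detected = {s.position for s in sites if not s.is_indel}
        true_snv = [v.position for v in variants
                    if len(v.ref_allele) == 1 and len(v.alt_allele) == 1]
        near = set()
        for p in detected:
            near.update((p - 1, p, p + 1))
        recall = sum(1 for p in true_snv if p in near) / len(true_snv)
        assert recall >= 0.9
        # and the phasing on these sites is nearly perfect
        assign = phase_reads(aligned, sites)
        truth = {r.read_id: r.haplotype for r in reads}
        labels = [(truth[rid], h) for rid, h in assign.assignment.items()
                  if h != diploid.UNASSIGNED]
        same = sum(1 for t, h in labels if t == h)
        assert min(same, len(labels) - same) / len(labels) < 0.05


@pytest.fixture(scope="module")
def small_model():
    return network.init_model(network.ModelConfig(seed=1))


class TestDiploidConsensus:

    def test_homozygous_reduces_to_haploid(self, tiny_genome, small_model):
        prof = simgen.ErrorProfile(sub_rate=0, ins_rate=0, del_rate=0,
                                   homopolymer_del_boost=1.0)
        reads = simgen.simulate_reads(tiny_genome, 6.0, prof, mean_len=300, seed=3)
        aligned = pileup.to_aligned_reads(reads, "contig")
        res = diploid.diploid_consensus(
            tiny_genome, aligned, small_model, iterations=1, mapping="banded",
            polish_first=False,
        )
        hap = network.polish(tiny_genome, aligned, small_model, iterations=1)
        assert res.hap1 == res.hap2 == hap.sequence

    def test_oracle_phasing_recovers_truth_haplotypes(self, tiny_genome):
        """With truth phasing and oracle posteriors, outputs equal the truth pair."""
        ref = tiny_genome
        h1, h2, variants = simgen.simulate_diploid(ref, 0.01, 0.0, seed=4)
        prof = simgen.ErrorProfile(sub_rate=0, ins_rate=0, del_rate=0,
                                   homopolymer_del_boost=1.0)
        r1 = simgen.simulate_reads(h1, 8.0, prof, mean_len=400, seed=5,
                                   haplotype="H1", id_prefix="a")
        r2 = simgen.simulate_reads(h2, 8.0, prof, mean_len=400, seed=6,
                                   haplotype="H2", id_prefix="b")
        # oracle: draft = h1, truth labels route each read set to its haplotype
        for hap_truth, own in ((h1, r1), (h2, r2)):
            aligned = pileup.realign_banded(
                pileup.to_aligned_reads(own, "contig"), h1, contig_id="contig"
            )
            pl = build_pileup(h1, aligned)
            labels, _ = tensorize.alignment_labels(h1, hap_truth, method="banded")
            seq = network.decode(tensorize.one_hot_posteriors(labels))
            assert seq == hap_truth


class TestPhasingIO:
    def test_phasing_tsv_round_trip(self, tmp_path):
        a = diploid.HaplotypeAssignment(
            {"r1": "H1", "r2": "H2", "r3": diploid.UNASSIGNED},
            {"r1": 1.0, "r2": 0.9, "r3": 0.0},
            [],
        )
        path = tmp_path / "p.tsv"
        diploid.write_phasing(a, path)
        back = diploid.read_phasing(path)
        assert back.assignment == a.assignment
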