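"""Phased diploid consensus: het-site detection, read phasing, per-haplotype polish.

Diploid regions confuse a single-sequence consensus: at a heterozygous locus
roughly half the reads support each allele and any one output sequence is
wrong for one haplotype. This module detects candidate heterozygous sites
from the pileup, partitions reads into two haplotypes with a greedy seeded
2-coloring (a self-contained stand-in for an external read-based phaser such
as WhatsHap; an externally produced read->haplotype table can be substituted),
and runs the haploid consensus network once per haplotype. Haplotype labels
are exchangeable: every downstream metric must be invariant under H1<->H2.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import network as network_mod
from . import pileup as pileup_mod
from .pileup import SYMBOLS, AlignedRead, PileupMatrix, build_pileup

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"


@dataclasses.dataclass
class HetSite:
    position: int  # 0-based draft index
    allele_a: str  # most frequent symbol (A/C/G/T/-)
    allele_b: str
    count_a: int
    count_b: int
    depth: int

    @property
    def minor_fraction(self) -> float:
        return self.count_b / self.depth if self.depth else 0.0

    @property
    def is_indel(self) -> bool:
        return "-" in (self.allele_a, self.allele_b)


@dataclasses.dataclass
class HaplotypeAssignment:
    assignment: Dict[str, str]  # read_id -> H1 | H2 | UNASSIGNED
    agreement: Dict[str, float]  # fraction of informative sites agreeing with the haplotype
    switch_points: List[int]  # informative-site indices where a new phase block was seeded

    def reads_for(self, hap: str, reads: Sequence[AlignedRead]) -> List[AlignedRead]:
        """Reads assigned to ``hap`` plus UNASSIGNED reads (kept in both haplotypes)."""
        return [
            r
            for r in reads
            if self.assignment.get(r.read_id, UNASSIGNED) in (hap, UNASSIGNED)
        ]

    def n_assigned(self, hap: str) -> int:
        return sum(1 for v in self.assignment.values() if v == hap)


def detect_het_sites(
    pileup: PileupMatrix,
    min_depth: int = 10,
    min_af: float = 0.25,
    max_other_af: float = 0.15,
) -> List[HetSite]:
    """Positions whose two most frequent symbols each reach ``min_af`` of depth.

    Columns where base symbols beyond the top two exceed ``max_other_af`` of
    depth are rejected: genuine heterozygous sites are two-allele mixtures,
    whereas alignment wobble around indels produces impure multi-symbol
    columns. The default 0.15 is ~5x the expected substitution noise (3%).
    """
    summed = pileup.counts.sum(axis=1)  # (n, 5)
    depth = pileup.depth
    gap = summed[:, 4]
    bases = np.sort(summed[:, :4], axis=1)
    b1, b2 = bases[:, -1], bases[:, -2]
    rest = bases[:, 0] + bases[:, 1]  # bases beyond the top two
    # SNV-type: two bases split the column; gap noise (nanopore deletions,
    # typically 5-10% of depth) is tolerated up to half the column
    snv = (
        (depth >= min_depth)
        & (b2 >= min_af * depth)
        & (b2 > 0)
        & (rest <= max_other_af * depth)
        & (gap <= 0.5 * depth)
    )
    # indel-type: top base vs gap
    indel = (
        (depth >= min_depth)
        & ~snv
        & (gap >= min_af * depth)
        & (b1 >= min_af * depth)
        & (summed[:, :4].sum(axis=1) - b1 <= max_other_af * depth)
    )
    sites: List[HetSite] = []
    for i in np.flatnonzero(snv | indel):
        row = summed[i]
        if snv[i]:
            order = sorted(range(4), key=lambda s: (-row[s], s))
            a, b = order[0], order[1]
        else:
            a = min(range(4), key=lambda s: (-row[s], s))
            a, b = ((a, 4) if row[a] >= row[4] else (4, a))
        sites.append(
            HetSite(
                position=int(i),
                allele_a=SYMBOLS[a],
                allele_b=SYMBOLS[b],
                count_a=int(row[a]),
                count_b=int(row[b]),
                depth=int(depth[i]),
            )
        )
    return sites


def _read_alleles(
    read: AlignedRead, positions: np.ndarray
) -> List[Tuple[int, str]]:
    """(site_index, observed symbol) for every het position the read spans."""
    lo = int(np.searchsorted(positions, read.start, side="left"))
    hi = int(np.searchsorted(positions, read.end, side="left"))
    if hi <= lo:
        return []
    wanted = positions[lo:hi]
    out: List[Tuple[int, str]] = []
    pos, qi, w = read.start, 0, 0
    for op, ln in read.cigar:
        if w >= wanted.size:
            break
        if op == "M":
            while w < wanted.size and wanted[w] < pos + ln:
                out.append((lo + w, read.sequence[qi + int(wanted[w]) - pos]))
                w += 1
            pos += ln
            qi += ln
        elif op == "D":
            while w < wanted.size and wanted[w] < pos + ln:
                out.append((lo + w, "-"))
                w += 1
            pos += ln
        else:  # I
            qi += ln
    return out


def _greedy_pass(reads_sorted, obs_by_read, S, allowed_codes, min_agreement):
    """One left-to-right greedy coloring pass; returns assignment pieces."""
    assignment: Dict[str, str] = {}
    agreement: Dict[str, float] = {}
    switch_points: List[int] = []
    prof = np.zeros((2, S, 4), dtype=np.int32)  # per-hap allele support

    def majority(h: int, s: int) -> Optional[int]:
        row = prof[h, s]
        if row.sum() == 0:
            other = prof[1 - h, s]
            if other.sum() == 0:
                return None
            om = int(other.argmax())
            implied = [c for c in allowed_codes[s] if c != om]
            return implied[0] if len(implied) == 1 else None
        return int(row.argmax())

    for read in reads_sorted:
        obs = obs_by_read[read.read_id]
        if len(obs) < 2:
            continue
        agree = [0, 0]
        n_eval = 0
        for s, c in obs:
            known = False
            for h in (0, 1):
                m = majority(h, s)
                if m is not None:
                    known = True
                    if c == m:
                        agree[h] += 1
            if known:
                n_eval += 1
        if n_eval == 0:
            # no overlap with any established block: seed a new one on H1
            switch_points.append(obs[0][0])
            hap = 0
            agreement[read.read_id] = 1.0
        else:
            if agree[0] == agree[1]:
                continue
            hap = 0 if agree[0] > agree[1] else 1
            ratio = agree[hap] / n_eval
            if ratio < min_agreement:
                continue
            agreement[read.read_id] = ratio
        assignment[read.read_id] = "H1" if hap == 0 else "H2"
        for s, c in obs:
            prof[hap, s, c] += 1
    return assignment, agreement, switch_points, prof


def phase_reads(
    reads: Sequence[AlignedRead],
    het_sites: Sequence[HetSite],
    min_agreement: float = 0.6,
    min_concordance: float = 0.8,
) -> HaplotypeAssignment:
    """Greedy seeded bipartition of reads over SNV het sites, with one
    site-filtering refinement pass.

    Sites are processed left to right through the reads (sorted by start, then
    read_id, so the result is deterministic). Each read votes with its
    observed alleles against the running per-haplotype allele profiles; it
    joins the haplotype with the higher agreement, provided it covers >= 2
    informative sites and its agreement ratio reaches ``min_agreement``.
    Indel het sites are excluded from the informative set (indel-noise
    dominated). A read with no profile overlap seeds a new phase block.

    After the first pass, sites whose alleles do not separate the two
    haplotypes (same majority on both sides, or observation concordance with
    the partition below ``min_concordance``) are dropped — these are
    typically false candidate sites from residual alignment wobble — and the
    coloring is rerun on the filtered set.
    """
    snv_sites = [s for s in het_sites if not s.is_indel]
    base_assignment: Dict[str, str] = {r.read_id: UNASSIGNED for r in reads}
    base_agreement: Dict[str, float] = {r.read_id: 0.0 for r in reads}
    if not snv_sites:
        return HaplotypeAssignment(base_assignment, base_agreement, [])
    code = {b: i for i, b in enumerate("ACGT")}
    reads_sorted = sorted(reads, key=lambda r: (r.start, r.read_id))

    def collect_obs(sites):
        positions = np.array([s.position for s in sites], dtype=np.int64)
        allowed = [{code[a] for a in (s.allele_a, s.allele_b)} for s in sites]
        obs_by_read = {}
        for read in reads_sorted:
            obs_by_read[read.read_id] = [
                (s, code[b])
                for s, b in _read_alleles(read, positions)
                if b != "-" and code[b] in allowed[s]
            ]
        return obs_by_read, allowed

    obs_by_read, allowed = collect_obs(snv_sites)
    assignment, agreement, switches, prof = _greedy_pass(
        reads_sorted, obs_by_read, len(snv_sites), allowed, min_agreement
    )
    # refinement: keep only sites that cleanly separate the two haplotypes
    kept = []
    for s in range(len(snv_sites)):
        m1 = int(prof[0, s].argmax()) if prof[0, s].sum() else -1
        m2 = int(prof[1, s].argmax()) if prof[1, s].sum() else -2
        if m1 == m2 or (m1 < 0 and m2 < 0):
            continue
        total = int(prof[:, s].sum())
        concordant = int(prof[0, s, m1] if m1 >= 0 else 0) + int(
            prof[1, s, m2] if m2 >= 0 else 0
        )
        if total >= 4 and concordant / total >= min_concordance:
            kept.append(snv_sites[s])
    if kept and len(kept) < len(snv_sites):
        obs_by_read, allowed = collect_obs(kept)
        assignment, agreement, switches, _prof = _greedy_pass(
            reads_sorted, obs_by_read, len(kept), allowed, min_agreement
        )
    base_assignment.update(assignment)
    base_agreement.update(agreement)
    return HaplotypeAssignment(base_assignment, base_agreement, switches)


@dataclasses.dataclass
class DiploidResult:
    hap1: str
    hap2: str
    het_sites: List[HetSite]  # positions on ``base_sequence``
    phasing: HaplotypeAssignment
    hap_results: Tuple[network_mod.PolishResult, network_mod.PolishResult]
    base_sequence: str = ""  # the (haploid-polished) sequence phasing ran on


def diploid_consensus(
    draft: str,
    reads: Sequence[AlignedRead],
    model: network_mod.ConsensusModel,
    iterations: int = 2,
    min_depth: int = 10,
    min_af: float = 0.25,
    mapping: str = "auto",
    phasing: Optional[HaplotypeAssignment] = None,
    polish_first: bool = True,
    contig_id: str = "contig",
) -> DiploidResult:
    """Phased diploid consensus of one contig.

    Pipeline: run the haploid consensus first (``iterations`` rounds) and
    re-align the reads to it — het detection on a raw ~88% draft is swamped
    by false sites from alignment wobble around draft indels, whereas the
    polished sequence gives clean two-allele columns. Then detect het sites,
    phase the reads, and run one per-haplotype polish from the haploid
    consensus (UNASSIGNED reads contribute to both haplotypes, preserving
    depth in homozygous regions). With no het sites, or no assigned reads,
    the haploid consensus is returned for both haplotypes (logged), so the
    homozygous case reduces byte-identically.
    """
    if polish_first:
        hap_res = network_mod.polish(
            draft, reads, model, iterations=iterations, mapping=mapping, contig_id=contig_id
        )
        base = hap_res.sequence
        base_reads = pileup_mod.map_reads(reads, base, contig_id=contig_id, method=mapping)
    else:
        hap_res = None
        base = draft
        base_reads = list(reads)
    pl = build_pileup(base, base_reads, contig_id=contig_id)
    sites = detect_het_sites(pl, min_depth=min_depth, min_af=min_af)
    assign = phasing if phasing is not None else phase_reads(base_reads, sites)

    def haploid() -> network_mod.PolishResult:
        if hap_res is not None:
            return hap_res
        return network_mod.polish(
            draft, reads, model, iterations=iterations, mapping=mapping, contig_id=contig_id
        )

    n1, n2 = assign.n_assigned("H1"), assign.n_assigned("H2")
    if not sites or (n1 == 0 and n2 == 0):
        res = haploid()
        return DiploidResult(res.sequence, res.sequence, sites, assign, (res, res),
                             base_sequence=base)
    results = []
    for hap, n_hap in (("H1", n1), ("H2", n2)):
        if n_hap == 0:
            logger.warning("haplotype %s has no assigned reads; haploid fallback", hap)
            results.append(haploid())
            continue
        hap_reads = assign.reads_for(hap, base_reads)
        results.append(
            network_mod.polish(
                base, hap_reads, model, iterations=1, mapping=mapping, contig_id=contig_id
            )
        )
    return DiploidResult(
        results[0].sequence, results[1].sequence, sites, assign,
        (results[0], results[1]), base_sequence=base,
    )


# ---------------------------------------------------------------------------
# plain-text interchange
# ---------------------------------------------------------------------------

def write_het_sites(sites: Sequence[HetSite], bed_path, tsv_path) -> None:
    """Het sites as BED (0-based, half-open) plus an allele/count TSV."""
    with open(bed_path, "w") as bed:
        for s in sites:
            bed.write(f"contig\t{s.position}\t{s.position + 1}\n")
    with open(tsv_path, "w") as tsv:
        tsv.write("position\tallele_a\tallele_b\tcount_a\tcount_b\tdepth\n")
        for s in sites:
            tsv.write(
                f"{s.position}\t{s.allele_a}\t{s.allele_b}\t{s.count_a}\t{s.count_b}\t{s.depth}\n"
            )


def write_phasing(assign: HaplotypeAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\thaplotype\tagreement\n")
        for rid, hap in assign.assignment.items():
            fh.write(f"{rid}\t{hap}\t{assign.agreement.get(rid, 0.0):.3f}\n")


def read_phasing(path) -> HaplotypeAssignment:
    """Load an externally produced read -> haplotype table (e.g. from WhatsHap)."""
    assignment: Dict[str, str] = {}
    agreement: Dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError("phasing TSV must start with a read_id header line")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            assignment[parts[0]] = parts[1]
            agreement[parts[0]] = float(parts[2]) if len(parts) > 2 else 0.0
    return HaplotypeAssignment(assignment, agreement, [])
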