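"""Alignment I/O, strand-aware pileup construction and the majority-vote baseline.

Coordinates are 0-based, half-open everywhere internally; SAM's 1-based POS is
converted at the boundary. The pileup records, per draft position and strand,
counts of A/C/G/T and gap (deleted draft base), and per inter-position slot i
(between draft positions i and i+1) the number of reads carrying an insertion
there together with the identity of the first inserted base and a mean-length
accumulator.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import shutil
import subprocess
import tempfile
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import BandOverflowError, banded_align
from .edits import cigar_consumes, revcomp, script_to_cigar

logger = logging.getLogger(__name__)

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i

SYMBOLS = "ACGT-"  # column symbol order; '-' is the gap (deleted draft base)
GAP = 4


@dataclasses.dataclass
class AlignedRead:
    """A read aligned to a draft contig, sequence in reference-forward orientation."""

    read_id: str
    contig_id: str
    start: int  # 0-based on the draft
    strand: str  # '+' | '-'
    cigar: List[Tuple[str, int]]  # M/I/D in draft coordinates
    sequence: str

    def __post_init__(self):
        q, _ = cigar_consumes(self.cigar)
        if q != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: cigar consumes {q} query bases, sequence has "
                f"{len(self.sequence)}"
            )

    @property
    def ref_span(self) -> int:
        _, t = cigar_consumes(self.cigar)
        return t

    @property
    def end(self) -> int:
        return self.start + self.ref_span


@dataclasses.dataclass
class PileupMatrix:
    contig_id: str
    ref_seq: str
    counts: np.ndarray  # (n, 2, 5) int32: strand (+,-) x symbol (A,C,G,T,gap)
    ins_count: np.ndarray  # (n, 2) int32: insertions at slot i (after position i)
    ins_first: np.ndarray  # (n, 2, 4) int32: identity of the first inserted base
    ins_len_sum: np.ndarray  # (n, 2) int64: total inserted bases per slot (mean-length acc.)
    depth: np.ndarray  # (n,) int32: reads spanning each position

    @property
    def n_positions(self) -> int:
        return len(self.ref_seq)


# ---------------------------------------------------------------------------
# FASTA / FASTQ / SAM I/O
# ---------------------------------------------------------------------------

def load_assembly(path) -> Dict[str, str]:
    """Contigs of a FASTA file, in file order, uppercased."""
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}
    if not contigs:
        raise ValueError(f"no sequences found in {path}")
    return contigs


def write_fasta(path, contigs: Dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in contigs.items()]
    SeqIO.write(records, os.fspath(path), "fasta")


def write_fastq(path, reads: Iterable[Tuple[str, str]]) -> None:
    """Reads as FASTQ with a constant 'I' quality (the simulator has no quality model)."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def _sam_header(contigs: Dict[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": len(seq)} for name, seq in contigs.items()],
        }
    )


def write_alignments(path, reads: Sequence[AlignedRead], contigs: Dict[str, str]) -> None:
    """AlignedReads as a plain-text SAM file (1-based POS, M/I/D CIGAR, 0x10 for '-')."""
    header = _sam_header(contigs)
    names = list(contigs)
    with pysam.AlignmentFile(os.fspath(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = names.index(r.contig_id)
            a.reference_start = r.start
            a.mapping_quality = 60
            a.cigarstring = "".join(f"{n}{o}" for o, n in r.cigar)
            out.write(a)


_CIGAR_OPS = {0: "M", 1: "I", 2: "D", 7: "M", 8: "M"}


def _segment_to_read(a: pysam.AlignedSegment, contigs: Dict[str, str]) -> AlignedRead:
    if a.reference_name not in contigs:
        raise ValueError(f"read {a.query_name}: unknown contig {a.reference_name!r}")
    if a.query_sequence is None:
        raise ValueError(f"read {a.query_name}: SAM record carries no sequence")
    cigar: List[Tuple[str, int]] = []
    seq = a.query_sequence
    qstart = 0
    qend = len(seq)
    first = True
    for code, ln in a.cigartuples:
        if code == 4:  # soft clip: excluded from the edit script
            if first:
                qstart += ln
            else:
                qend -= ln
            first = False
            continue
        if code == 5:  # hard clip: bases never present
            continue
        op = _CIGAR_OPS.get(code)
        if op is None:
            raise ValueError(f"read {a.query_name}: unsupported CIGAR op code {code}")
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + ln)
        else:
            cigar.append((op, ln))
        first = False
    seq = seq[qstart:qend]
    return AlignedRead(
        read_id=a.query_name,
        contig_id=a.reference_name,
        start=a.reference_start,
        strand="-" if a.is_reverse else "+",
        cigar=cigar,
        sequence=seq,
    )


def load_alignments(path, contigs: Dict[str, str]) -> Tuple[List[AlignedRead], int]:
    """Load SAM alignments; returns (reads, skipped_count).

    Unmapped, secondary and supplementary records are skipped (counted and
    logged); malformed records raise with the offending read name.
    """
    reads: List[AlignedRead] = []
    skipped = 0
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                skipped += 1
                continue
            reads.append(_segment_to_read(a, contigs))
    if skipped:
        logger.info("skipped %d unmapped/secondary/supplementary SAM records", skipped)
    return reads, skipped


def to_aligned_reads(sim_reads, contig_id: str) -> List[AlignedRead]:
    """Convert simulator reads (with truth scripts) to template-coordinate alignments."""
    out = []
    for r in sim_reads:
        seq_fwd = r.sequence if r.strand == "+" else revcomp(r.sequence)
        out.append(
            AlignedRead(
                read_id=r.read_id,
                contig_id=contig_id,
                start=r.true_start,
                strand=r.strand,
                cigar=script_to_cigar(r.truth_cigar),
                sequence=seq_fwd,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Read mapping: minimap2 when available, anchored banded re-alignment otherwise
# ---------------------------------------------------------------------------

def minimap2_available() -> bool:
    return shutil.which("minimap2") is not None


def map_reads_minimap2(
    seqs: Dict[str, str], target: str, contig_id: str = "contig"
) -> List[AlignedRead]:
    """Map read sequences to a single-contig target with minimap2 (map-ont, primary only)."""
    with tempfile.TemporaryDirectory() as tmp:
        ref = os.path.join(tmp, "ref.fa")
        rds = os.path.join(tmp, "reads.fa")
        sam = os.path.join(tmp, "out.sam")
        write_fasta(ref, {contig_id: target})
        write_fasta(rds, seqs)
        with open(sam, "w") as out:
            subprocess.run(
                ["minimap2", "-a", "-x", "map-ont", "--secondary=no", "-t", "1", ref, rds],
                stdout=out,
                stderr=subprocess.DEVNULL,
                check=True,
            )
        reads, _ = load_alignments(sam, {contig_id: target})
    return reads


def map_sequence_minimap2(query: str, target: str):
    """Primary minimap2 alignment of one sequence pair.

    Returns ``(cigar, target_start, clip_head, clip_tail)`` with an M/I/D
    cigar over the unclipped query core, or None when minimap2 finds no
    primary alignment.
    """
    with tempfile.TemporaryDirectory() as tmp:
        ref = os.path.join(tmp, "ref.fa")
        qf = os.path.join(tmp, "q.fa")
        sam = os.path.join(tmp, "out.sam")
        write_fasta(ref, {"target": target})
        write_fasta(qf, {"query": query})
        with open(sam, "w") as out:
            subprocess.run(
                ["minimap2", "-a", "--secondary=no", "-t", "1", ref, qf],
                stdout=out,
                stderr=subprocess.DEVNULL,
                check=True,
            )
        with pysam.AlignmentFile(sam, "r", check_sq=False) as fh:
            recs = [
                a for a in fh
                if not (a.is_unmapped or a.is_secondary or a.is_supplementary)
            ]
    if not recs:
        return None
    a = recs[0]
    if a.is_reverse:
        return None
    ct = a.cigartuples
    clip_head = ct[0][1] if ct[0][0] in (4, 5) else 0
    clip_tail = ct[-1][1] if len(ct) > 1 and ct[-1][0] in (4, 5) else 0
    cigar: List[Tuple[str, int]] = []
    for code, ln in ct:
        op = _CIGAR_OPS.get(code)
        if op is None:
            continue
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + ln)
        else:
            cigar.append((op, ln))
    return cigar, a.reference_start, clip_head, clip_tail


def realign_banded(
    reads: Sequence[AlignedRead],
    new_target: str,
    coord_map: Optional[Sequence[int]] = None,
    band_frac: float = 0.15,
    contig_id: str = "contig",
) -> List[AlignedRead]:
    """Re-align reads to ``new_target`` with the banded aligner, anchored on their
    previous coordinates (optionally translated through ``coord_map``, a
    previous-coordinate -> new-coordinate table)."""
    n = len(new_target)
    out: List[AlignedRead] = []
    for r in reads:
        s, e = r.start, r.end
        if coord_map is not None:
            s = coord_map[min(s, len(coord_map) - 1)]
            e = coord_map[min(e, len(coord_map) - 1)]
        pad = max(100, int(0.05 * len(r.sequence)))
        ws = max(0, s - pad)
        we = min(n, e + pad)
        window = new_target[ws:we]
        if not window:
            logger.warning("read %s: empty target window, dropped", r.read_id)
            continue
        band = max(32, int(band_frac * max(len(r.sequence), len(window))))
        try:
            aln = banded_align(r.sequence, window, band_width=band, free_target_ends=True)
            if aln.touched_band_edge:
                aln = banded_align(
                    r.sequence, window, band_width=band * 2, free_target_ends=True
                )
        except BandOverflowError:
            logger.warning("read %s: band overflow during re-alignment, dropped", r.read_id)
            continue
        cig = list(aln.cigar)
        start = ws + aln.target_start
        while cig and cig[0][0] == "D":  # residual margin
            start += cig[0][1]
            cig.pop(0)
        while cig and cig[-1][0] == "D":
            cig.pop()
        if not cig:
            continue
        out.append(
            AlignedRead(
                read_id=r.read_id,
                contig_id=contig_id,
                start=start,
                strand=r.strand,
                cigar=cig,
                sequence=r.sequence,
            )
        )
    return out


def map_reads(
    reads: Sequence[AlignedRead],
    new_target: str,
    coord_map: Optional[Sequence[int]] = None,
    contig_id: str = "contig",
    method: str = "auto",
) -> List[AlignedRead]:
    """Dispatch read mapping: minimap2 when on PATH (``auto``), else anchored banded."""
    if method == "auto":
        method = "minimap2" if minimap2_available() else "banded"
    if method == "minimap2":
        return map_reads_minimap2(
            {r.read_id: r.sequence if r.strand == "+" else revcomp(r.sequence) for r in reads},
            new_target,
            contig_id,
        )
    if method == "banded":
        return realign_banded(reads, new_target, coord_map=coord_map, contig_id=contig_id)
    raise ValueError(f"unknown mapping method {method!r}")


# ---------------------------------------------------------------------------
# Pileup construction and the majority-vote baseline
# ---------------------------------------------------------------------------

def build_pileup(
    contig_seq: str, reads: Sequence[AlignedRead], contig_id: str = "contig"
) -> PileupMatrix:
    """Strand-aware pileup of M/I/D alignments over one contig.

    M ops count the read base at each draft position; D ops count a gap at
    each deleted draft position; an I op of length k after draft position i
    counts once at slot i, recording the first inserted base and accumulating
    k. Depth is the number of reads spanning each position.
    """
    n = len(contig_seq)
    counts = np.zeros((n, 2, 5), dtype=np.int32)
    ins_count = np.zeros((n, 2), dtype=np.int32)
    ins_first = np.zeros((n, 2, 4), dtype=np.int32)
    ins_len_sum = np.zeros((n, 2), dtype=np.int64)
    depth_diff = np.zeros(n + 1, dtype=np.int32)
    for r in reads:
        if r.end > n or r.start < 0:
            raise ValueError(
                f"read {r.read_id} overhangs contig end ({r.start}..{r.end} vs {n})"
            )
        si = 0 if r.strand == "+" else 1
        pos, qi = r.start, 0
        codes = _ENC[np.frombuffer(r.sequence.encode(), dtype=np.uint8)]
        for op, ln in r.cigar:
            if op == "M":
                counts[np.arange(pos, pos + ln), si, codes[qi : qi + ln]] += 1
                pos += ln
                qi += ln
            elif op == "D":
                counts[pos : pos + ln, si, GAP] += 1
                pos += ln
            elif op == "I":
                slot = pos - 1
                if slot >= 0:
                    ins_count[slot, si] += 1
                    ins_first[slot, si, codes[qi]] += 1
                    ins_len_sum[slot, si] += ln
                qi += ln
            else:
                raise ValueError(f"read {r.read_id}: unexpected op {op!r} in pileup")
        depth_diff[r.start] += 1
        depth_diff[r.end] -= 1
    depth = np.cumsum(depth_diff[:-1]).astype(np.int32)
    return PileupMatrix(
        contig_id=contig_id,
        ref_seq=contig_seq,
        counts=counts,
        ins_count=ins_count,
        ins_first=ins_first,
        ins_len_sum=ins_len_sum,
        depth=depth,
    )


def majority_vote(pileup: PileupMatrix) -> str:
    """Trivial consensus: per-position argmax over strand-summed A/C/G/T/gap counts.

    Gap-majority positions are dropped; an inter-position slot emits the argmax
    first-insertion base when the insertion count strictly exceeds half the
    local depth (the left flank's depth). Ties break in the fixed symbol order
    A < C < G < T < gap. Zero-depth positions pass the draft base through.
    """
    n = pileup.n_positions
    if n == 0:
        raise ValueError("empty pileup")
    summed = pileup.counts.sum(axis=1)  # (n, 5)
    best = summed.argmax(axis=1)
    ref_codes = _ENC[np.frombuffer(pileup.ref_seq.encode(), dtype=np.uint8)]
    base_out = np.where(pileup.depth == 0, ref_codes, best).astype(np.int64)
    ins_tot = pileup.ins_count.sum(axis=1)
    ins_slots = np.flatnonzero(ins_tot * 2 > pileup.depth)
    ins_base = pileup.ins_first.sum(axis=1).argmax(axis=1)
    lut = np.frombuffer(b"ACGT-", dtype=np.uint8)
    parts = []
    last = 0
    for slot in ins_slots:
        slot = int(slot)
        parts.append(base_out[last : slot + 1])
        parts.append(np.array([ins_base[slot]], dtype=np.int64))
        last = slot + 1
    parts.append(base_out[last:])
    flat = np.concatenate(parts) if parts else base_out
    keep = flat != GAP
    return bytes(lut[flat[keep]]).decode()
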