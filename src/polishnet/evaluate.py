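"""Accuracy statistics: alignment identity, error breakdowns, diploid comparison.

Identity is defined on the optimal (within-band) global pairwise alignment as
matches / aligned columns, where aligned columns = matches + mismatches +
inserted + deleted bases — an internal, dependency-free substitute for
QUAST-style identity. Deletions are bases of the truth missing from the
consensus; insertions are extra consensus bases.

The diploid-vs-haploid comparison treats every aligned column as an
independent Bernoulli trial and applies a pooled two-proportion z-test:
p_hat = (Lh*Ah + Ld*Ad) / (Lh + Ld), z = (Ad - Ah) / sqrt(p_hat(1-p_hat)(1/Lh+1/Ld)),
with a one-sided p-value in the observed direction.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.stats import norm

from .align import BandedAlignment, BandOverflowError, banded_align


@dataclasses.dataclass
class IdentityResult:
    matches: int
    mismatches: int
    inserted: int
    deleted: int
    cigar: list = dataclasses.field(repr=False, default_factory=list)

    @property
    def aligned_length(self) -> int:
        return self.matches + self.mismatches + self.inserted + self.deleted

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_length if self.aligned_length else 1.0

    @property
    def errors(self) -> int:
        return self.mismatches + self.inserted + self.deleted


def identity(consensus: str, truth: str, band_width: Optional[int] = None) -> IdentityResult:
    """Alignment identity of ``consensus`` (query) against ``truth`` (target).

    The band follows the straight diagonal between the corners, which already
    absorbs the net length difference, so the starting band only needs to
    cover local drift of the optimal path (scaling like the square root of
    the length); it doubles (up to 3 retries) whenever the optimal path is
    pinned against the band edge or the corners cannot be connected.
    """
    m, n = len(consensus), len(truth)
    if m == 0 or n == 0:
        raise ValueError("sequences must be non-empty")
    band = band_width or max(128, int(3 * np.sqrt(max(m, n))))
    aln: Optional[BandedAlignment] = None
    for attempt in range(4):
        full = band >= max(m, n)
        try:
            aln = banded_align(consensus, truth, band_width=min(band, max(m, n)))
        except BandOverflowError:
            aln = None
        if aln is not None and (full or not aln.touched_band_edge):
            break
        if full:
            break
        band *= 2
    if aln is None:
        raise BandOverflowError(
            "alignment failed even at full band width; consider splitting the sequences"
        )
    return IdentityResult(
        matches=aln.matches,
        mismatches=aln.mismatches,
        inserted=aln.inserted,
        deleted=aln.deleted,
        cigar=aln.cigar,
    )


@dataclasses.dataclass
class ErrorBreakdown:
    """Histograms of consensus errors against the truth.

    ``deletion_events`` is keyed by the exact maximal-run length of each
    deletion event; ``homopolymer_errors`` by the exact truth homopolymer run
    length (>= 2) the error touches. ``binned`` views collapse to the
    conventional 1..5+ and 2..8+ groupings.
    """

    deletion_events: Dict[int, int]
    homopolymer_errors: Dict[int, int]
    total_deleted_bases: int
    total_errors: int

    @property
    def total_deletion_events(self) -> int:
        return sum(self.deletion_events.values())

    def deletion_hist_binned(self, cap: int = 5) -> Dict[int, int]:
        out: Dict[int, int] = {k: 0 for k in range(1, cap + 1)}
        for ln, c in self.deletion_events.items():
            out[min(ln, cap)] += c
        return out

    def homopolymer_hist_binned(self, cap: int = 8) -> Dict[int, int]:
        out: Dict[int, int] = {k: 0 for k in range(2, cap + 1)}
        for ln, c in self.homopolymer_errors.items():
            out[min(ln, cap)] += c
        return out


def error_breakdown(
    consensus: str, truth: str, alignment: Optional[IdentityResult] = None
) -> ErrorBreakdown:
    """Group consensus errors by deletion-event length and homopolymer context.

    A deletion event is a maximal run of consecutive deleted truth bases. An
    error (mismatch, insertion or deletion) is a homopolymer error iff it
    touches a truth homopolymer run of length >= 2; an event touching several
    runs is attributed to the longest (ties to the leftmost).
    """
    from .simgen import homopolymer_run_lengths

    aln = alignment or identity(consensus, truth)
    rl = homopolymer_run_lengths(truth)
    n = len(truth)
    del_hist: Dict[int, int] = {}
    hp_hist: Dict[int, int] = {}

    def touch(lengths):
        lens = [int(x) for x in lengths if x >= 2]
        if lens:
            run = max(lens)
            hp_hist[run] = hp_hist.get(run, 0) + 1

    qi = ti = 0
    cig = aln.cigar
    for idx, (op, ln) in enumerate(cig):
        if op == "M":
            qa = np.frombuffer(consensus[qi : qi + ln].encode(), dtype=np.uint8)
            ta = np.frombuffer(truth[ti : ti + ln].encode(), dtype=np.uint8)
            for off in np.flatnonzero(qa != ta):
                touch([rl[ti + int(off)]])
            qi += ln
            ti += ln
        elif op == "I":
            cands = []
            if ti - 1 >= 0:
                cands.append(rl[ti - 1])
            if ti < n:
                cands.append(rl[ti])
            touch(cands)
            qi += ln
        elif op == "D":
            del_hist[ln] = del_hist.get(ln, 0) + 1
            touch(rl[ti : ti + ln])
            ti += ln
    return ErrorBreakdown(
        deletion_events=del_hist,
        homopolymer_errors=hp_hist,
        total_deleted_bases=aln.deleted,
        total_errors=aln.errors,
    )


@dataclasses.dataclass
class DiploidAccuracy:
    Lh: float
    Ah: float
    Ld: float
    Ad: float
    pooled: float
    z: float
    p_value: float
    pairing: Tuple[str, str]  # which truth haplotype each consensus was scored against
    hap_results: Tuple[IdentityResult, IdentityResult]
    haploid_result: Optional[IdentityResult] = None

    @property
    def diploid_errors(self) -> int:
        return sum(r.errors for r in self.hap_results)


def diploid_accuracy(
    hapA: str, hapB: str, truth_h1: str, truth_h2: str
) -> Tuple[float, float, Tuple[str, str], Tuple[IdentityResult, IdentityResult]]:
    """Ld, Ad and the label-swap-invariant consensus/truth pairing.

    The pairing of the two consensus sequences to the two truth haplotypes is
    the one maximizing total matches, so the result is identical under an
    H1<->H2 relabeling. Ld is the arithmetic mean of the two aligned lengths;
    Ad pools matches over both haplotypes.
    """
    a1 = identity(hapA, truth_h1)
    a2 = identity(hapA, truth_h2)
    b1 = identity(hapB, truth_h1)
    b2 = identity(hapB, truth_h2)
    if a1.matches + b2.matches >= a2.matches + b1.matches:
        rA, rB, pairing = a1, b2, ("H1", "H2")
    else:
        rA, rB, pairing = a2, b1, ("H2", "H1")
    Ld = (rA.aligned_length + rB.aligned_length) / 2.0
    Ad = (rA.matches + rB.matches) / (rA.aligned_length + rB.aligned_length)
    return Ld, Ad, pairing, (rA, rB)


def two_proportion_test(Lh: float, Ah: float, Ld: float, Ad: float) -> Tuple[float, float]:
    """Pooled two-proportion z-test of diploid vs haploid accuracy.

    Returns ``(z, p)`` with z signed in the direction Ad - Ah and p the
    one-sided tail in the observed direction, Phi(-|z|). Degenerate pooled
    proportions (0 or 1) give z = 0, p = 0.5.
    """
    if Lh <= 0 or Ld <= 0:
        raise ValueError("aligned lengths must be positive")
    if not (0.0 <= Ah <= 1.0 and 0.0 <= Ad <= 1.0):
        raise ValueError("accuracies must lie in [0, 1]")
    pooled = (Lh * Ah + Ld * Ad) / (Lh + Ld)
    if pooled <= 0.0 or pooled >= 1.0:
        return 0.0, 0.5
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / Lh + 1.0 / Ld))
    if se == 0.0:  # subnormal pooled proportion: numerically degenerate
        return 0.0, 0.5
    z = (Ad - Ah) / se
    p = float(norm.sf(abs(z)))
    return z, p


def compare_haploid_diploid(
    haploid: str, hapA: str, hapB: str, truth_h1: str, truth_h2: str
) -> DiploidAccuracy:
    """Full haploid-vs-diploid record for one contig.

    The haploid consensus is scored against the closer truth haplotype
    (maximum matches), matching how a single merged consensus of a diploid
    region is conventionally evaluated.
    """
    h1 = identity(haploid, truth_h1)
    h2 = identity(haploid, truth_h2)
    hres = h1 if h1.matches >= h2.matches else h2
    Lh, Ah = float(hres.aligned_length), hres.identity
    Ld, Ad, pairing, hap_results = diploid_accuracy(hapA, hapB, truth_h1, truth_h2)
    z, p = two_proportion_test(Lh, Ah, Ld, Ad)
    pooled = (Lh * Ah + Ld * Ad) / (Lh + Ld)
    return DiploidAccuracy(
        Lh=Lh,
        Ah=Ah,
        Ld=Ld,
        Ad=Ad,
        pooled=pooled,
        z=z,
        p_value=p,
        pairing=pairing,
        hap_results=hap_results,
        haploid_result=hres,
    )


def assembly_identity(results: List[IdentityResult]) -> float:
    """Aligned-length-weighted mean identity over contigs."""
    L = sum(r.aligned_length for r in results)
    if L == 0:
        return 1.0
    return sum(r.matches for r in results) / L


def write_report(results: Dict[str, IdentityResult], tsv_path, json_path=None) -> None:
    """Per-contig TSV report (L, matches, mismatches, ins, del, identity) + JSON summary."""
    with open(tsv_path, "w") as fh:
        fh.write("contig\taligned_length\tmatches\tmismatches\tinserted\tdeleted\tidentity\n")
        for name, r in results.items():
            fh.write(
                f"{name}\t{r.aligned_length}\t{r.matches}\t{r.mismatches}\t"
                f"{r.inserted}\t{r.deleted}\t{r.identity:.6f}\n"
            )
    if json_path is not None:
        summary = {
            "contigs": len(results),
            "identity": assembly_identity(list(results.values())),
            "total_errors": sum(r.errors for r in results.values()),
        }
        with open(json_path, "w") as fh:
            json.dump(summary, fh, indent=2)
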