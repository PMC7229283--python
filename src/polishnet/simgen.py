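"""Synthetic genomes, diploid haplotypes, nanopore-like reads and noisy drafts.

The simulator emulates the deletion-dominant error profile of nanopore reads
(deletion events 5.74% per base, insertion 2.48% by default) and a miniasm-like
noisy draft at a target identity (~88.65% for the headline operating point), so
the whole polishing pipeline is testable with no external data.

Error model: at each template base (an "opportunity") an insertion event, a
deletion event and a substitution are drawn independently; indel event lengths
are geometric(p_len) capped at ``max_event_len``; bases skipped by a deletion
event receive no further draws. Inside homopolymer runs of length >= 3 the
deletion probability is multiplied by ``homopolymer_del_boost``.
"""

from __future__ import annotations

import dataclasses
from typing import List, NamedTuple, Optional, Tuple

import numpy as np

from .edits import BASES, replay, revcomp, script_identity

_MIN_READ_LEN = 50


@dataclasses.dataclass(frozen=True)
class ErrorProfile:
    """Per-base event probabilities of the read simulator."""

    sub_rate: float = 0.03
    ins_rate: float = 0.0248
    del_rate: float = 0.0574
    homopolymer_del_boost: float = 2.0
    max_event_len: int = 5
    p_len: float = 0.7

    def __post_init__(self):
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.sub_rate + self.ins_rate + self.del_rate * self.homopolymer_del_boost >= 1.0:
            raise ValueError("combined per-base event probability must stay below 1")
        if self.max_event_len < 1:
            raise ValueError("max_event_len must be >= 1")
        if not 0.0 < self.p_len <= 1.0:
            raise ValueError("p_len must lie in (0, 1]")

    def scaled(self, k: float) -> "ErrorProfile":
        return dataclasses.replace(
            self, sub_rate=self.sub_rate * k, ins_rate=self.ins_rate * k, del_rate=self.del_rate * k
        )


@dataclasses.dataclass
class SimRead:
    read_id: str
    haplotype: str  # "H1" | "H2" | "NA"
    true_start: int  # 0-based on the forward template
    strand: str  # "+" | "-"
    sequence: str  # as sequenced (reverse-complemented for "-" reads)
    truth_cigar: list  # generative edit script vs template[true_start:], forward orientation


class Variant(NamedTuple):
    position: int  # 0-based on the reference
    ref_allele: str
    alt_allele: str
    phase: str  # "H1" | "H2"


def homopolymer_mask(seq: str, min_run: int = 3) -> np.ndarray:
    """Boolean mask of positions inside a homopolymer run of length >= min_run."""
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = a.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    breaks = np.flatnonzero(a[1:] != a[:-1]) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [n]))
    mask = np.zeros(n, dtype=bool)
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            mask[s:e] = True
    return mask


def homopolymer_run_lengths(seq: str) -> np.ndarray:
    """Per-position length of the maximal homopolymer run containing the position."""
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = a.size
    out = np.zeros(n, dtype=np.int32)
    if n == 0:
        return out
    breaks = np.flatnonzero(a[1:] != a[:-1]) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [n]))
    for s, e in zip(starts, ends):
        out[s:e] = e - s
    return out


def simulate_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """Random genome with the requested G+C fraction; deterministic per seed."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return "".join(BASES[c] for c in codes) if length < 64 else bytes(
        np.frombuffer(b"ACGT", dtype=np.uint8)[codes]
    ).decode()


def _geom_len(rng: np.random.Generator, p_len: float, cap: int) -> int:
    return int(min(rng.geometric(p_len), cap))


def _rand_base(rng: np.random.Generator, exclude: Optional[str] = None) -> str:
    if exclude is None:
        return BASES[rng.integers(4)]
    choices = BASES.replace(exclude, "")
    return choices[rng.integers(3)]


def _apply_errors(
    template: str,
    profile: ErrorProfile,
    rng: np.random.Generator,
    scale: float = 1.0,
    p_del_eff: Optional[np.ndarray] = None,
) -> list:
    """Generative edit script corrupting ``template`` under ``profile`` (rates x scale).

    ``p_del_eff`` optionally supplies the per-position deletion probability
    (before scaling), e.g. with the homopolymer boost already applied.
    """
    n = len(template)
    if p_del_eff is None:
        p_del_eff = np.where(
            homopolymer_mask(template),
            profile.del_rate * profile.homopolymer_del_boost,
            profile.del_rate,
        )
    u_ins = rng.random(n)
    u_del = rng.random(n)
    u_sub = rng.random(n)
    ins_mask = u_ins < profile.ins_rate * scale
    del_mask = u_del < p_del_eff * scale
    sub_mask = u_sub < profile.sub_rate * scale
    event_pos = np.flatnonzero(ins_mask | del_mask | sub_mask)

    script = []
    cur = 0

    def emit(op, data):
        if op == "=" and script and script[-1][0] == "=":
            script[-1] = ("=", script[-1][1] + data)
        else:
            script.append((op, data))

    for e in event_pos:
        e = int(e)
        if e < cur:
            continue  # consumed by a previous deletion event
        if e > cur:
            emit("=", e - cur)
            cur = e
        if ins_mask[e]:
            L = _geom_len(rng, profile.p_len, profile.max_event_len)
            emit("I", "".join(_rand_base(rng) for _ in range(L)))
        if del_mask[e]:
            L = min(_geom_len(rng, profile.p_len, profile.max_event_len), n - e)
            emit("D", L)
            cur = e + L
        elif sub_mask[e]:
            emit("X", _rand_base(rng, exclude=template[e]))
            cur = e + 1
        # insertion-only events leave the base itself to the next '=' run
    if cur < n:
        emit("=", n - cur)
    return script


def simulate_reads(
    template: str,
    coverage: float,
    profile: ErrorProfile = ErrorProfile(),
    mean_len: int = 5000,
    seed: int = 0,
    haplotype: str = "NA",
    id_prefix: str = "read",
) -> List[SimRead]:
    """Nanopore-like reads to an expected sequencing depth of ``coverage``.

    Read lengths are lognormal (sigma=0.5) around ``mean_len``; reads shorter
    than 50 bp are rejected and redrawn. Minus-strand reads are stored
    reverse-complemented with the truth script kept on the forward template.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if mean_len < _MIN_READ_LEN:
        raise ValueError("mean_len must be >= 50")
    L = len(template)
    if L < _MIN_READ_LEN:
        raise ValueError("template shorter than the minimum read length (50)")
    rng = np.random.default_rng(seed)
    p_del_eff = np.where(
        homopolymer_mask(template),
        profile.del_rate * profile.homopolymer_del_boost,
        profile.del_rate,
    )
    sigma = 0.5
    mu = np.log(mean_len) - sigma**2 / 2
    reads: List[SimRead] = []
    total = 0
    target = coverage * L
    idx = 0
    while total < target:
        span = int(round(float(rng.lognormal(mu, sigma))))
        if span < _MIN_READ_LEN:
            continue
        # raw start may be negative so contig edges get full coverage
        raw = int(rng.integers(1 - span, L))
        start = max(0, raw)
        span = min(L, raw + span) - start
        if span < _MIN_READ_LEN:
            continue
        sub_tpl = template[start : start + span]
        script = _apply_errors(sub_tpl, profile, rng, p_del_eff=p_del_eff[start : start + span])
        seq_fwd = replay(sub_tpl, script)
        if len(seq_fwd) < _MIN_READ_LEN:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        seq = seq_fwd if strand == "+" else revcomp(seq_fwd)
        reads.append(
            SimRead(
                read_id=f"{id_prefix}{idx:06d}",
                haplotype=haplotype,
                true_start=start,
                strand=strand,
                sequence=seq,
                truth_cigar=script,
            )
        )
        total += len(seq_fwd)
        idx += 1
    return reads


def simulate_diploid(
    ref: str,
    snv_rate: float = 0.001,
    indel_rate: float = 0.0001,
    seed: int = 0,
    max_indel_len: int = 3,
) -> Tuple[str, str, List[Variant]]:
    """Two haplotypes derived from ``ref`` by phased heterozygous variants.

    Each variant is applied to exactly one haplotype (fair coin). Overlapping
    candidates are resolved by rejection, so the emitted set is sorted and
    non-overlapping. Indel alleles are VCF-style (anchored on the ref base).
    """
    if snv_rate + indel_rate >= 0.05:
        raise ValueError("combined variant rate must stay below 0.05")
    L = len(ref)
    rng = np.random.default_rng(seed)
    u = rng.random(L)
    snv_at = u < snv_rate
    indel_at = (u >= snv_rate) & (u < snv_rate + indel_rate)
    variants: List[Variant] = []
    blocked_until = 0
    for pos in np.flatnonzero(snv_at | indel_at):
        pos = int(pos)
        if pos < blocked_until:
            continue
        phase = "H1" if rng.random() < 0.5 else "H2"
        if snv_at[pos]:
            alt = _rand_base(rng, exclude=ref[pos])
            variants.append(Variant(pos, ref[pos], alt, phase))
            blocked_until = pos + 1
        else:
            ln = _geom_len(rng, 0.7, max_indel_len)
            if rng.random() < 0.5 or pos + 1 + ln > L:
                # insertion after the anchor base
                ins = "".join(_rand_base(rng) for _ in range(ln))
                variants.append(Variant(pos, ref[pos], ref[pos] + ins, phase))
                blocked_until = pos + 1
            else:
                variants.append(Variant(pos, ref[pos : pos + 1 + ln], ref[pos], phase))
                blocked_until = pos + 1 + ln
    hap1 = apply_variants(ref, variants, "H1")
    hap2 = apply_variants(ref, variants, "H2")
    return hap1, hap2, variants


def apply_variants(ref: str, variants: List[Variant], phase: str) -> str:
    """Apply the variants carrying ``phase`` to ``ref``."""
    out = []
    cur = 0
    for v in variants:
        if v.position < cur:
            raise ValueError("variants overlap or are unsorted")
        if v.phase != phase:
            continue
        out.append(ref[cur : v.position])
        if ref[v.position : v.position + len(v.ref_allele)] != v.ref_allele:
            raise ValueError(f"ref allele mismatch at {v.position}")
        out.append(v.alt_allele)
        cur = v.position + len(v.ref_allele)
    out.append(ref[cur:])
    return "".join(out)


def corrupt_draft(
    truth: str,
    target_identity: float = 0.8865,
    seed: int = 0,
    profile: ErrorProfile = ErrorProfile(),
    tol: float = 0.005,
) -> Tuple[str, list]:
    """Corrupt ``truth`` into a miniasm-like draft at ``target_identity``.

    A global multiplier on the (deletion-dominant) error profile is calibrated
    by bisection against the identity implied by the generated edit script,
    then refined with up to 3 secant steps against the optimal-alignment
    identity of :func:`polishnet.evaluate.identity`, which is what the +-0.01
    contract is stated in terms of. Returns ``(draft, truth->draft script)``.
    """
    if not 0.5 < target_identity <= 1.0:
        raise ValueError("target_identity must lie in (0.5, 1]")
    if target_identity == 1.0:
        return truth, [("=", len(truth))]
    p_del_eff = np.where(
        homopolymer_mask(truth), profile.del_rate * profile.homopolymer_del_boost, profile.del_rate
    )
    k_max = 0.999 / (
        profile.sub_rate + profile.ins_rate + profile.del_rate * profile.homopolymer_del_boost
    )

    def gen(k):
        rng = np.random.default_rng(seed)  # common random numbers: monotone in k
        return _apply_errors(truth, profile, rng, scale=k, p_del_eff=p_del_eff)

    def bisect_to(script_target):
        lo, hi = 0.0, k_max
        if script_identity(gen(hi)) > script_target:
            raise ValueError("target identity unreachable with this profile")
        for _ in range(30):
            mid = (lo + hi) / 2
            if script_identity(gen(mid)) >= script_target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    script_target = target_identity
    k = bisect_to(script_target)
    script = gen(k)
    if abs(script_identity(script) - script_target) > 2 * tol:
        raise ValueError("target identity not reachable at this truth length (granularity)")
    draft = replay(truth, script)

    from . import evaluate  # deferred: evaluate depends on the aligner only

    for _ in range(3):
        measured = evaluate.identity(draft, truth).identity
        if abs(measured - target_identity) <= tol:
            break
        script_target += target_identity - measured
        k = bisect_to(script_target)
        script = gen(k)
        draft = replay(truth, script)
    return draft, script
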