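"""Seeded end-to-end benchmarks on simulated data.

These drive the whole pipeline at desk scale: simulate a genome and
deletion-dominant nanopore-like reads, corrupt a draft to a miniasm-like
identity (~88.65%), train the consensus network on one genome, and polish a
disjoint genome, measuring identity against the truth. The diploid benchmark
additionally simulates two haplotypes, phases the reads and compares the
phased consensus to the merged haploid one.

Training is two-stage within the epoch budget: the second half of the epochs
continues on a mixture that includes tensors from a once-polished draft, so
later polish iterations see in-distribution inputs.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import List, Optional, Tuple

import numpy as np

from . import diploid as diploid_mod
from . import evaluate, network, simgen, tensorize
from . import pileup as pileup_mod
from .edits import template_to_derived_map

logger = logging.getLogger(__name__)

DEFAULT_LENGTH = 100_000
DEFAULT_COVERAGE = 30.0
DEFAULT_MEAN_LEN = 5000
DEFAULT_DRAFT_IDENTITY = 0.8865


def _map_initial(reads, draft, script, mapping: str, contig_id="draft"):
    """Align simulated reads to the draft: minimap2, or banded anchored through
    the truth->draft coordinate map of the corruption script."""
    if mapping == "auto":
        mapping = "minimap2" if pileup_mod.minimap2_available() else "banded"
    if mapping == "minimap2":
        return pileup_mod.map_reads_minimap2(
            {r.read_id: r.sequence for r in reads}, draft, contig_id
        )
    truth_len = sum(ln for op, ln in script if op == "=") + sum(
        ln for op, ln in script if op == "D"
    ) + sum(len(d) for op, d in script if op == "X")
    coord_map = template_to_derived_map(script, truth_len)
    template_reads = pileup_mod.to_aligned_reads(reads, contig_id)
    return pileup_mod.realign_banded(
        template_reads, draft, coord_map=coord_map, contig_id=contig_id
    )


@dataclasses.dataclass
class HaploidScenario:
    truth: str
    draft: str
    reads: list
    aligned: list
    draft_identity: float


def make_scenario(
    seed: int,
    length: int = DEFAULT_LENGTH,
    coverage: float = DEFAULT_COVERAGE,
    mean_len: int = DEFAULT_MEAN_LEN,
    draft_identity: float = DEFAULT_DRAFT_IDENTITY,
    profile: Optional[simgen.ErrorProfile] = None,
    mapping: str = "auto",
) -> HaploidScenario:
    profile = profile or simgen.ErrorProfile()
    truth = simgen.simulate_genome(length, seed=seed)
    draft, script = simgen.corrupt_draft(truth, draft_identity, seed=seed + 1)
    reads = simgen.simulate_reads(truth, coverage, profile, mean_len=mean_len, seed=seed + 2)
    aligned = _map_initial(reads, draft, script, mapping)
    return HaploidScenario(
        truth=truth,
        draft=draft,
        reads=reads,
        aligned=aligned,
        draft_identity=evaluate.identity(draft, truth).identity,
    )


def train_model(
    scenario: HaploidScenario,
    epochs: int = 10,
    seed: int = 0,
    mapping: str = "auto",
    two_stage: bool = True,
) -> Tuple[network.ConsensusModel, List[network.TrainReport]]:
    """Train a consensus model on one scenario within the total epoch budget."""
    pl = pileup_mod.build_pileup(scenario.draft, scenario.aligned, contig_id="draft")
    tensors = tensorize.window_tensors(pl)
    labels, info = tensorize.alignment_labels(scenario.draft, scenario.truth, method=mapping)
    logger.info("stage-1 labels: %d phase-2-truncated bases", info.truncated_bases)
    model = network.init_model(network.ModelConfig(seed=seed))
    reports = []
    e1 = epochs if not two_stage else max(1, epochs // 2)
    model, rep = network.train(model, tensors, labels, epochs=e1, seed=seed)
    reports.append(rep)
    if two_stage and epochs - e1 > 0:
        res = network.polish(scenario.draft, scenario.aligned, model, iterations=1,
                             mapping=mapping)
        realigned = pileup_mod.map_reads(
            scenario.aligned, res.sequence, method=mapping, contig_id="draft"
        )
        pl2 = pileup_mod.build_pileup(res.sequence, realigned, contig_id="draft")
        tensors2 = tensorize.window_tensors(pl2)
        labels2, _ = tensorize.alignment_labels(res.sequence, scenario.truth, method=mapping)
        mix_x = np.concatenate([tensors, tensors2], axis=0)
        mix_y = np.concatenate([labels, labels2], axis=0)
        model, rep2 = network.train(model, mix_x, mix_y, epochs=epochs - e1, seed=seed + 1)
        reports.append(rep2)
    return model, reports


@dataclasses.dataclass
class PolishBenchmark:
    draft_identity: float
    baseline_identity: float
    identities: List[float]  # per polish iteration
    deleted_phase1_only: int
    deleted_with_phase2: int
    final_sequence: str
    baseline_sequence: str


def run_polish_benchmark(
    model: network.ConsensusModel,
    scenario: HaploidScenario,
    iterations: int = 2,
    mapping: str = "auto",
) -> PolishBenchmark:
    """Polish a scenario's draft and measure everything the evaluation defines."""
    baseline = pileup_mod.majority_vote(
        pileup_mod.build_pileup(scenario.draft, scenario.aligned, contig_id="draft")
    )
    res = network.polish(
        scenario.draft, scenario.aligned, model, iterations=iterations,
        truth=scenario.truth, mapping=mapping,
    )
    res_p1 = network.polish(
        scenario.draft, scenario.aligned, model, iterations=1, use_phase2=False,
        mapping=mapping,
    )
    bd_p1 = evaluate.error_breakdown(res_p1.sequence, scenario.truth)
    bd_p2 = evaluate.error_breakdown(res.per_iteration[0], scenario.truth)
    return PolishBenchmark(
        draft_identity=scenario.draft_identity,
        baseline_identity=evaluate.identity(baseline, scenario.truth).identity,
        identities=res.identities,
        deleted_phase1_only=bd_p1.total_deleted_bases,
        deleted_with_phase2=bd_p2.total_deleted_bases,
        final_sequence=res.sequence,
        baseline_sequence=baseline,
    )


@dataclasses.dataclass
class DiploidBenchmark:
    n_het_sites_true: int
    n_het_sites_detected: int
    het_recall: float
    misassignment_rate: float
    assigned_fraction: float
    haploid_errors: int
    diploid_errors: int
    stats: evaluate.DiploidAccuracy


def run_diploid_benchmark(
    model: network.ConsensusModel,
    seed: int,
    length: int = DEFAULT_LENGTH,
    coverage: float = DEFAULT_COVERAGE,
    mean_len: int = DEFAULT_MEAN_LEN,
    snv_rate: float = 0.001,
    draft_identity: float = DEFAULT_DRAFT_IDENTITY,
    iterations: int = 2,
    mapping: str = "auto",
) -> DiploidBenchmark:
    """Phased diploid consensus vs merged haploid consensus on simulated diploid data."""
    profile = simgen.ErrorProfile()
    ref = simgen.simulate_genome(length, seed=seed)
    hap1, hap2, variants = simgen.simulate_diploid(ref, snv_rate=snv_rate, seed=seed + 1)
    draft, script = simgen.corrupt_draft(ref, draft_identity, seed=seed + 2)
    reads = simgen.simulate_reads(hap1, coverage / 2, profile, mean_len, seed + 3,
                                  haplotype="H1", id_prefix="h1_")
    reads += simgen.simulate_reads(hap2, coverage / 2, profile, mean_len, seed + 4,
                                   haplotype="H2", id_prefix="h2_")
    if mapping == "auto":
        mapping = "minimap2" if pileup_mod.minimap2_available() else "banded"
    if mapping == "minimap2":
        aligned = pileup_mod.map_reads_minimap2(
            {r.read_id: r.sequence for r in reads}, draft, "draft"
        )
    else:
        # anchor haplotype reads through the ref->draft coordinate map
        coord_map = template_to_derived_map(script, len(ref))
        template_reads = pileup_mod.to_aligned_reads(reads, "draft")
        aligned = pileup_mod.realign_banded(template_reads, draft, coord_map=coord_map,
                                            contig_id="draft")
    truth_hap = {r.read_id: r.haplotype for r in reads}

    dip = diploid_mod.diploid_consensus(
        draft, aligned, model, iterations=iterations, mapping=mapping
    )

    # het-SNV recall: detected sites live on the haploid-polished sequence;
    # translate them to reference coordinates through an alignment
    true_snv = [
        v.position for v in variants if len(v.ref_allele) == 1 and len(v.alt_allele) == 1
    ]
    base = dip.base_sequence
    base_to_ref = _query_to_target_map(evaluate.identity(base, ref).cigar, len(base))
    detected = {s.position for s in dip.het_sites if not s.is_indel}
    near = set()
    for p in detected:
        r = base_to_ref[min(p, len(base) - 1)]
        near.update((r - 2, r - 1, r, r + 1, r + 2))
    recall = (
        sum(1 for p in true_snv if p in near) / len(true_snv) if true_snv else 1.0
    )

    assign = dip.phasing
    labels = [(truth_hap[rid], hap) for rid, hap in assign.assignment.items()
              if hap != diploid_mod.UNASSIGNED and truth_hap.get(rid) in ("H1", "H2")]
    if labels:
        same = sum(1 for t, h in labels if t == h)
        mis = min(same, len(labels) - same) / len(labels)
    else:
        mis = 0.0
    assigned_frac = len(labels) / max(len(aligned), 1)

    stats = evaluate.compare_haploid_diploid(base, dip.hap1, dip.hap2, hap1, hap2)
    return DiploidBenchmark(
        n_het_sites_true=len(true_snv),
        n_het_sites_detected=len(detected),
        het_recall=recall,
        misassignment_rate=mis,
        assigned_fraction=assigned_frac,
        haploid_errors=stats.haploid_result.errors,
        diploid_errors=stats.diploid_errors,
        stats=stats,
    )


def _query_to_target_map(cigar, query_len: int) -> np.ndarray:
    """Per-query-position target coordinate implied by an M/I/D cigar."""
    out = np.zeros(query_len, dtype=np.int64)
    qi = ti = 0
    for op, ln in cigar:
        if op == "M":
            out[qi : qi + ln] = np.arange(ti, ti + ln)
            qi += ln
            ti += ln
        elif op == "I":
            out[qi : qi + ln] = ti
            qi += ln
        else:
            ti += ln
    return out
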