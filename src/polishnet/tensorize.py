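"""Pileup columns -> spatial window tensors, and truth labels for training.

Each pileup column i becomes a 21-dimensional feature vector:

===========  ================================================================
indices      meaning
===========  ================================================================
0..4, 5..9   +/- strand counts of A, C, G, T, gap, divided by depth[i]
10, 15       +/- strand insertion count at slot i, divided by depth[i]
11..14,      +/- strand first-inserted-base counts (A..T), divided by depth[i]
16..19
20, 21       +/- strand mean insertion length at slot i, divided by the
             profile-scale cap (5); evidence for multi-base recovery
22           min(depth, depth_cap) / depth_cap
===========  ================================================================

A window tensor at position i concatenates the feature vectors of columns
i-1, i, i+1 (window size W=3; out-of-range columns are all-zero), so spatial
context of the pileup survives the per-position conversion.

Labels: phase1 in {A, C, G, T, DEL} is the truth base aligned to the draft
position (DEL when the draft base has no truth counterpart); phase2 encodes
up to two truth bases falling between consecutive draft-aligned positions
(the bases a polisher must re-insert), attached to the slot on their left.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Tuple

import numpy as np

from .pileup import PileupMatrix

PER_COLUMN_FEATURES = 23
DEPTH_CAP = 100
INS_LEN_CAP = 5.0
DEL = 4  # phase-1 class index of "draft base absent from truth"
PHASE1_CLASSES = "ACGT-"
PHASE2_CLASSES = ".ACGT"  # '.' = no insertion

_CODE = {b: i for i, b in enumerate("ACGT")}


class ConsensusLabel(NamedTuple):
    phase1: int  # 0..4 over A,C,G,T,DEL
    phase2_first: int  # 0..4 over none,A,C,G,T
    phase2_second: int


def feature_matrix(pileup: PileupMatrix, depth_cap: int = DEPTH_CAP) -> np.ndarray:
    """(n_positions, 21) float32 feature matrix; zero-depth columns are all zero."""
    n = pileup.n_positions
    depth = pileup.depth.astype(np.float32)
    safe = np.maximum(depth, 1.0)[:, None]
    F = np.zeros((n, PER_COLUMN_FEATURES), dtype=np.float32)
    F[:, 0:10] = pileup.counts.reshape(n, 10) / safe
    F[:, 10] = pileup.ins_count[:, 0] / safe[:, 0]
    F[:, 11:15] = pileup.ins_first[:, 0, :] / safe
    F[:, 15] = pileup.ins_count[:, 1] / safe[:, 0]
    F[:, 16:20] = pileup.ins_first[:, 1, :] / safe
    ins_n = np.maximum(pileup.ins_count, 1)
    F[:, 20:22] = np.minimum(
        pileup.ins_len_sum / ins_n / INS_LEN_CAP, 1.0
    ) * (pileup.ins_count > 0)
    F[:, 22] = np.minimum(depth, depth_cap) / depth_cap
    return F


def featurize_column(pileup: PileupMatrix, i: int) -> np.ndarray:
    """Feature vector of a single pileup column (see module docstring for layout)."""
    if not 0 <= i < pileup.n_positions:
        raise IndexError(f"column {i} out of range")
    return feature_matrix(pileup)[i]


def window_tensors(pileup: PileupMatrix, W: int = 3) -> np.ndarray:
    """(n_positions, W*21) tensors; window centered per position, zero-padded at ends."""
    if W < 1 or W % 2 == 0:
        raise ValueError("window size must be odd and >= 1")
    F = feature_matrix(pileup)
    return window_from_features(F, W)


def window_from_features(F: np.ndarray, W: int = 3) -> np.ndarray:
    if W < 1 or W % 2 == 0:
        raise ValueError("window size must be odd and >= 1")
    n, f = F.shape
    half = W // 2
    padded = np.zeros((n + 2 * half, f), dtype=F.dtype)
    padded[half : half + n] = F
    return np.concatenate([padded[k : k + n] for k in range(W)], axis=1)


@dataclasses.dataclass
class LabelInfo:
    truncated_bases: int  # truth bases beyond the 2-per-slot phase-2 capacity
    dropped_prefix: int  # truth bases before the first draft position (no left slot)


def make_labels(draft: str, truth: str, script) -> Tuple[np.ndarray, LabelInfo]:
    """Per-draft-position training labels from a truth -> draft generative script.

    Returns an (len(draft), 3) int8 array of (phase1, phase2_first,
    phase2_second) class indices, plus counters for what the 2-base phase-2
    capacity could not represent.
    """
    n = len(draft)
    labels = np.zeros((n, 3), dtype=np.int8)
    truncated = 0
    dropped = 0
    ti = di = 0
    for op, data in script:
        if op in ("=", "X"):
            ln = data if op == "=" else len(data)
            for k in range(ln):
                labels[di + k, 0] = _CODE[truth[ti + k]]
            ti += ln
            di += ln
        elif op == "I":
            ln = len(data)
            labels[di : di + ln, 0] = DEL
            di += ln
        elif op == "D":
            ln = data
            slot = di - 1
            if slot < 0:
                dropped += ln
            else:
                placed = 0
                if labels[slot, 1] == 0:
                    labels[slot, 1] = _CODE[truth[ti]] + 1
                    placed = 1
                    if ln >= 2 and labels[slot, 2] == 0:
                        labels[slot, 2] = _CODE[truth[ti + 1]] + 1
                        placed = 2
                elif labels[slot, 2] == 0:
                    labels[slot, 2] = _CODE[truth[ti]] + 1
                    placed = 1
                truncated += ln - placed
            ti += ln
        else:
            raise ValueError(f"unknown edit op {op!r}")
    if ti != len(truth) or di != n:
        raise ValueError(
            f"edit script does not replay truth into draft (consumed {ti}/{len(truth)} "
            f"truth, produced {di}/{n} draft)"
        )
    return labels, LabelInfo(truncated_bases=truncated, dropped_prefix=dropped)


def cigar_to_script(cigar, draft: str, truth_skip_head: int = 0, truth_skip_tail: int = 0,
                    clip_head: int = 0, clip_tail: int = 0) -> list:
    """Draft-vs-truth M/I/D cigar -> generative truth->draft script.

    M ops become '=' runs (phase-1 labels read the truth bases, so the
    match/mismatch distinction is immaterial); clipped draft ends become
    insertions (DEL labels) and unaligned truth ends become deletions.
    """
    script = []
    if truth_skip_head:
        script.append(("D", truth_skip_head))
    if clip_head:
        script.append(("I", draft[:clip_head]))
    qi = clip_head
    for op, ln in cigar:
        if op == "M":
            script.append(("=", ln))
            qi += ln
        elif op == "I":
            script.append(("I", draft[qi : qi + ln]))
            qi += ln
        elif op == "D":
            script.append(("D", ln))
        else:
            raise ValueError(f"unexpected cigar op {op!r}")
    if clip_tail:
        script.append(("I", draft[len(draft) - clip_tail :]))
    if truth_skip_tail:
        script.append(("D", truth_skip_tail))
    return script


def alignment_script(draft: str, truth: str, method: str = "auto") -> list:
    """Truth -> draft generative script from an alignment of the two sequences.

    Labels must share the indel-placement convention of the read aligner: the
    position of an indel inside a repeat is conventional, so labels derived
    from the raw corruption script are systematically unlearnable there. Uses
    minimap2 when available (the read-mapping default), the internal banded
    aligner otherwise.
    """
    from . import pileup as pileup_mod

    if method == "auto":
        method = "minimap2" if pileup_mod.minimap2_available() else "banded"
    if method == "minimap2":
        rec = pileup_mod.map_sequence_minimap2(draft, truth)
        if rec is not None:
            cigar, t_start, clip_head, clip_tail = rec
            t_cons = sum(ln for op, ln in cigar if op in "MD")
            return cigar_to_script(
                cigar,
                draft,
                truth_skip_head=t_start,
                truth_skip_tail=len(truth) - t_start - t_cons,
                clip_head=clip_head,
                clip_tail=clip_tail,
            )
        # unmapped / fragmented: fall through to the global banded aligner
    from . import evaluate

    aln = evaluate.identity(draft, truth)
    return cigar_to_script(aln.cigar, draft)


def alignment_labels(draft: str, truth: str, method: str = "auto"):
    """Training labels from an alignment-derived script (see alignment_script)."""
    return make_labels(draft, truth, alignment_script(draft, truth, method=method))


def one_hot_posteriors(labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oracle posteriors: exact one-hot tracks from a label array."""
    n = labels.shape[0]
    p1 = np.zeros((n, 5), dtype=np.float32)
    p2f = np.zeros((n, 5), dtype=np.float32)
    p2s = np.zeros((n, 5), dtype=np.float32)
    r = np.arange(n)
    p1[r, labels[:, 0]] = 1.0
    p2f[r, labels[:, 1]] = 1.0
    p2s[r, labels[:, 2]] = 1.0
    return p1, p2f, p2s


def save_arrays(path, **named_arrays) -> None:
    """Persist tensors/labels keyed by contig in a compressed numeric archive."""
    np.savez_compressed(path, **named_arrays)


def load_arrays(path) -> dict:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}
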