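"""The two-phase consensus model: training, chunked inference, decoding, polishing.

Phase 1 classifies every draft position as A/C/G/T (the corrected base) or DEL
(an extra draft base to drop). Phase 2 is the base-recovery phase: two extra
heads sharing the recurrent trunk predict up to two bases that are missing
from the draft immediately after the position. Decoding emits the phase-1
call (unless DEL) and appends the recovered phase-2 bases, so a single pass
both corrects and re-inserts bases; iterating the whole polish (re-aligning
reads to the intermediate consensus) resolves longer deletions progressively.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import pileup as pileup_mod
from . import tensorize
from .nn import Adam, BiGRUNet

logger = logging.getLogger(__name__)

_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclasses.dataclass
class ModelConfig:
    window: int = 3
    feature_dim: int = 3 * tensorize.PER_COLUMN_FEATURES
    rnn_layers: int = 1
    hidden_size: int = 64
    head1_classes: int = 5
    head2_first_classes: int = 5
    head2_second_classes: int = 5
    chunk_len: int = 1000
    chunk_overlap: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if self.feature_dim != self.window * tensorize.PER_COLUMN_FEATURES:
            raise ValueError(
                f"feature_dim must be window * {tensorize.PER_COLUMN_FEATURES} "
                f"(= {self.window * tensorize.PER_COLUMN_FEATURES}), got {self.feature_dim}"
            )
        if self.rnn_layers != 1:
            raise ValueError("only a single bidirectional recurrent layer is supported")
        if not self.chunk_overlap < self.chunk_len / 2:
            raise ValueError("chunk_overlap must be < chunk_len / 2")


@dataclasses.dataclass
class TrainReport:
    epoch_losses: List[float]
    val_accuracy: List[float]
    epoch_seconds: List[float]


class ConsensusModel:
    """Config + BiGRU network; the object trained, checkpointed and polished with."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.net = BiGRUNet(
            input_dim=config.feature_dim,
            hidden=config.hidden_size,
            head_classes=(
                config.head1_classes,
                config.head2_first_classes,
                config.head2_second_classes,
            ),
            seed=config.seed,
        )

    def parameter_count(self) -> int:
        return self.net.parameter_count()

    def save(self, path) -> None:
        arrays = {f"param_{k}": v for k, v in self.net.params.items()}
        np.savez(
            path,
            format_version=np.array("polishnet-ckpt-1"),
            config=np.array(json.dumps(dataclasses.asdict(self.config))),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "ConsensusModel":
        with np.load(path) as data:
            version = str(data["format_version"])
            if version != "polishnet-ckpt-1":
                raise ValueError(f"unknown checkpoint format {version!r}")
            config = ModelConfig(**json.loads(str(data["config"])))
            model = cls(config)
            for k in model.net.params:
                model.net.params[k] = data[f"param_{k}"]
        return model


def init_model(config: Optional[ModelConfig] = None) -> ConsensusModel:
    """Fresh model; identical seeds give bitwise-identical parameters."""
    model = ConsensusModel(config or ModelConfig())
    logger.info("initialized model with %d parameters", model.parameter_count())
    return model


def _chunk(tensors: np.ndarray, labels: np.ndarray, chunk_len: int):
    n = tensors.shape[0]
    xs, ys, ms = [], [], []
    for s in range(0, n, chunk_len):
        e = min(s + chunk_len, n)
        x = np.zeros((chunk_len, tensors.shape[1]), dtype=np.float32)
        y = np.zeros((chunk_len, 3), dtype=np.int8)
        m = np.zeros(chunk_len, dtype=np.float32)
        x[: e - s] = tensors[s:e]
        y[: e - s] = labels[s:e]
        m[: e - s] = 1.0
        xs.append(x)
        ys.append(y)
        ms.append(m)
    return np.stack(xs), np.stack(ys), np.stack(ms)


def train(
    model: ConsensusModel,
    tensors: np.ndarray,
    labels: np.ndarray,
    epochs: int = 10,
    lr: float = 2e-3,
    batch_size: int = 8,
    seed: int = 0,
    val_fraction: float = 0.05,
    train_chunk_len: int = 250,
) -> Tuple[ConsensusModel, TrainReport]:
    """Train on per-position (tensor, label) pairs, chunked into fixed windows.

    Cross-entropy is summed over the three heads and averaged over positions;
    Adam with gradient clipping at global norm 5. Training chunks are shorter
    than the inference chunks (BPTT over 250 positions, many more optimizer
    steps per epoch). A small tail of chunks is held out to report phase-1
    validation accuracy per epoch.
    """
    if tensors.shape[0] == 0:
        raise ValueError("empty training set")
    if tensors.shape[0] != labels.shape[0]:
        raise ValueError("tensors and labels must be aligned per position")
    X, Y, M = _chunk(tensors, labels, train_chunk_len)
    n_chunks = X.shape[0]
    if n_chunks < 2:
        raise ValueError("need at least 2 chunks of data to train")
    rng = np.random.default_rng(seed)
    n_val = min(max(1, int(round(n_chunks * val_fraction))), n_chunks - 1)
    perm = rng.permutation(n_chunks)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    opt = Adam(model.net.params, lr=lr, clip_norm=5.0)
    report = TrainReport([], [], [])
    for _epoch in range(epochs):
        t0 = time.perf_counter()
        order = rng.permutation(train_idx)
        losses = []
        for s in range(0, order.size, batch_size):
            idx = order[s : s + batch_size]
            loss, grads, _acc = model.net.loss_and_grads(X[idx], Y[idx], M[idx])
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            opt.step(grads)
            losses.append(loss)
        p1, _, _ = model.net.predict_proba(X[val_idx])
        val_acc = float(
            ((p1.argmax(axis=2) == Y[val_idx][:, :, 0]) * M[val_idx]).sum()
            / max(M[val_idx].sum(), 1.0)
        )
        report.epoch_losses.append(float(np.mean(losses)))
        report.val_accuracy.append(val_acc)
        report.epoch_seconds.append(time.perf_counter() - t0)
        logger.info(
            "epoch %d: loss %.4f, val phase-1 accuracy %.4f",
            _epoch + 1,
            report.epoch_losses[-1],
            val_acc,
        )
    return model, report


def predict(
    model: ConsensusModel, tensors: np.ndarray, batch_size: int = 32
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-position posteriors of the three heads, computed in overlapping chunks.

    Chunks of ``chunk_len`` positions advance by ``chunk_len - 2*overlap``;
    only each chunk's central region is emitted, so every reported position
    has at least ``overlap`` positions of recurrent context on both sides
    (except at the contig ends).
    """
    n, D = tensors.shape
    if D != model.config.feature_dim:
        raise ValueError(f"feature dimension {D} != model's {model.config.feature_dim}")
    L = model.config.chunk_len
    ov = model.config.chunk_overlap
    if n <= L:
        p1, p2f, p2s = model.net.predict_proba(tensors[None].astype(np.float32))
        return p1[0], p2f[0], p2s[0]
    core = L - 2 * ov
    starts = list(range(0, n, core))
    windows = []
    spans = []  # (emit_from, emit_to) within each window
    for s in starts:
        ws = max(0, s - ov)
        we = min(n, s + core + ov)
        x = np.zeros((L, D), dtype=np.float32)
        x[: we - ws] = tensors[ws:we]
        windows.append(x)
        spans.append((s - ws, min(we, s + core) - ws))
    Xb = np.stack(windows)
    outs = [np.empty((n, c), dtype=np.float32) for c in model.net.head_classes]
    pos = 0
    for b in range(0, Xb.shape[0], batch_size):
        probs = model.net.predict_proba(Xb[b : b + batch_size])
        for k in range(probs[0].shape[0]):
            a, e = spans[b + k]
            ln = e - a
            for track, p in zip(outs, probs):
                track[pos : pos + ln] = p[k, a:e]
            pos += ln
    assert pos == n
    return tuple(outs)


def decode(
    posteriors: Tuple[np.ndarray, np.ndarray, np.ndarray],
    use_phase2: bool = True,
    return_map: bool = False,
):
    """Two-phase decode of per-position posteriors into a consensus sequence.

    Phase 1: emit the argmax base, or nothing for DEL. Phase 2 (base
    recovery): a base is recovered at a slot when the posterior mass of "some
    base" exceeds that of "no base" (P(none) < 1/2), and its identity is the
    argmax over A..T — marginal MAP on existence, then on identity. This
    emits a best-guess base even when the identity is uncertain, which a later
    polish iteration can correct as a simple mismatch; a missing base, by
    contrast, needs re-discovering. The second slot base is only considered
    when the first was emitted. Optionally returns the draft -> output
    coordinate map (length n+1) used to anchor re-alignment.
    """
    p1, p2f, p2s = posteriors
    n = p1.shape[0]
    a1 = p1.argmax(axis=1)
    keep = a1 != tensorize.DEL
    if use_phase2:
        a2f = p2f[:, 1:].argmax(axis=1) + 1
        a2s = p2s[:, 1:].argmax(axis=1) + 1
        ins1 = p2f[:, 0] < 0.5
        ins2 = ins1 & (p2s[:, 0] < 0.5)
    else:
        ins1 = ins2 = np.zeros(n, dtype=bool)
        a2f = a2s = np.zeros(n, dtype=np.int64)
    emitted = keep.astype(np.int64) + ins1 + ins2
    pos_map = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(emitted, out=pos_map[1:])
    total = int(pos_map[-1])
    out = np.empty(total, dtype=np.uint8)
    idx = pos_map[:-1]
    out[idx[keep]] = _LUT[a1[keep]]
    out[(idx + keep)[ins1]] = _LUT[a2f[ins1] - 1]
    out[(idx + keep + 1)[ins2]] = _LUT[a2s[ins2] - 1]
    seq = bytes(out).decode()
    return (seq, pos_map) if return_map else seq


@dataclasses.dataclass
class PolishResult:
    sequence: str
    per_iteration: List[str]
    identities: List[float]  # vs truth, when supplied


def polish(
    draft: str,
    reads: Sequence["pileup_mod.AlignedRead"],
    model: ConsensusModel,
    iterations: int = 1,
    truth: Optional[str] = None,
    mapping: str = "auto",
    use_phase2: bool = True,
    contig_id: str = "contig",
) -> PolishResult:
    """Iterative consensus polishing of one contig.

    Iteration 1 consumes the supplied alignments; later iterations re-align
    the reads to the previous iteration's output (minimap2 when available,
    otherwise the internal banded aligner anchored through the decode
    coordinate map). If an iteration's alignment fails the contig is passed
    through unpolished and logged.
    """
    from . import evaluate

    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    current = draft
    current_reads = list(reads)
    per_iter: List[str] = []
    idents: List[float] = []
    for it in range(iterations):
        try:
            pl = pileup_mod.build_pileup(current, current_reads, contig_id=contig_id)
            tensors = tensorize.window_tensors(pl, W=model.config.window)
            posts = predict(model, tensors)
            new_seq, pos_map = decode(posts, use_phase2=use_phase2, return_map=True)
        except Exception:
            logger.exception("iteration %d failed; contig passed through unpolished", it + 1)
            per_iter.append(current)
            if truth is not None:
                idents.append(evaluate.identity(current, truth).identity)
            continue
        current = new_seq
        per_iter.append(current)
        if truth is not None:
            idents.append(evaluate.identity(current, truth).identity)
        if it + 1 < iterations:
            current_reads = pileup_mod.map_reads(
                current_reads, current, coord_map=pos_map, contig_id=contig_id, method=mapping
            )
    return PolishResult(sequence=current, per_iteration=per_iter, identities=idents)
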