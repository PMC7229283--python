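"""Banded global pairwise alignment with affine gaps (Needleman-Wunsch style).

The band follows the straight line from (0, 0) to (len(query), len(target)) in
the DP matrix. That line absorbs the net length difference between the
sequences, so the band only needs to cover the local drift of the optimal
path around it, and sequences of very different lengths still align in
O(len * band) time and memory.

Three affine states per cell (M = diagonal, X = gap in the target /
query-consuming, Y = gap in the query / target-consuming); gap open applies
from M or the opposite gap state, extend within a state. Scores are integers,
so comparisons and traceback are exact. The inner loop is a numba-compiled
scalar sweep over the band; the traceback runs over a packed uint8
pointer matrix (2 bits per state).
"""

from __future__ import annotations

import dataclasses
from typing import List, Tuple

import numpy as np
from numba import njit

from .edits import cigar_counts

NEG = -1.0e15

_ENC = np.full(256, 200, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i


class BandOverflowError(RuntimeError):
    """The band was too narrow for an alignment path between the corners."""


@dataclasses.dataclass
class BandedAlignment:
    cigar: List[Tuple[str, int]]  # M/I/D, query = first argument, target = second
    score: float
    matches: int
    mismatches: int
    inserted: int
    deleted: int
    touched_band_edge: bool
    target_start: int = 0  # aligned target span (non-trivial with free target ends)
    target_end: int = 0

    @property
    def aligned_length(self) -> int:
        return self.matches + self.mismatches + self.inserted + self.deleted

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_length if self.aligned_length else 1.0


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@njit(cache=False)
def _dp_band(q, t, centers, bw, match, mismatch, go, ge, free_ends):  # pragma: no cover
    m = q.size
    n = t.size
    Wb = 2 * bw + 1
    TB = np.zeros((m + 1, Wb), dtype=np.uint8)
    Mp = np.full(Wb, NEG)
    Xp = np.full(Wb, NEG)
    Yp = np.full(Wb, NEG)
    Mc = np.full(Wb, NEG)
    Xc = np.full(Wb, NEG)
    Yc = np.full(Wb, NEG)
    # row 0: only horizontal gaps; j = k - bw (free when target ends are free)
    for k in range(Wb):
        j = k - bw
        if j == 0:
            Mp[k] = 0.0
        elif 1 <= j <= n:
            Yp[k] = 0.0 if free_ends else go + (j - 1) * ge
            TB[0, k] = (0 if j == 1 else 2) << 4
    for i in range(1, m + 1):
        ci = centers[i]
        sh = ci - centers[i - 1]
        qc = q[i - 1]
        for k in range(Wb):
            Mc[k] = NEG
            Xc[k] = NEG
            Yc[k] = NEG
            j = ci + k - bw
            if j < 0 or j > n:
                TB[i, k] = 0
                continue
            bits = 0
            # M: diagonal from (i-1, j-1) -> prev row offset k + sh - 1
            kd = k + sh - 1
            if j >= 1 and 0 <= kd < Wb:
                vm, vx, vy = Mp[kd], Xp[kd], Yp[kd]
                if vm >= vx and vm >= vy:
                    best = vm
                    src = 0
                elif vx >= vy:
                    best = vx
                    src = 1
                else:
                    best = vy
                    src = 2
                if best > NEG / 2:
                    s = match if t[j - 1] == qc else mismatch
                    Mc[k] = best + s
                    bits |= src
            # X: vertical from (i-1, j) -> prev row offset k + sh
            ku = k + sh
            if 0 <= ku < Wb:
                cm = Mp[ku] + go
                cy = Yp[ku] + go
                cx = Xp[ku] + ge
                if cm >= cy and cm >= cx:
                    Xc[k] = cm
                elif cy >= cx:
                    Xc[k] = cy
                    bits |= 1 << 2
                else:
                    Xc[k] = cx
                    bits |= 2 << 2
            # Y: horizontal from (i, j-1) -> same row offset k - 1
            if j >= 1 and k >= 1:
                cm = Mc[k - 1] + go
                cx = Xc[k - 1] + go
                cy = Yc[k - 1] + ge
                if cm >= cx and cm >= cy:
                    Yc[k] = cm
                elif cy >= cx:
                    Yc[k] = cy
                    bits |= 2 << 4
                else:
                    Yc[k] = cx
                    bits |= 1 << 4
            TB[i, k] = bits
        Mp, Mc = Mc, Mp
        Xp, Xc = Xc, Xp
        Yp, Yc = Yc, Yp
    if free_ends:
        # best query-complete cell anywhere on the last row; the target
        # suffix beyond it is unaligned
        best = NEG
        best_k = -1
        best_state = 0
        for k in range(Wb):
            j = centers[m] + k - bw
            if j < 0 or j > n:
                continue
            if Mp[k] > best:
                best, best_k, best_state = Mp[k], k, 0
            if Xp[k] > best:
                best, best_k, best_state = Xp[k], k, 1
        return TB, best, float(best_k), float(best_state)
    k_end = n - centers[m] + bw
    fm = Mp[k_end] if 0 <= k_end < Wb else NEG
    fx = Xp[k_end] if 0 <= k_end < Wb else NEG
    fy = Yp[k_end] if 0 <= k_end < Wb else NEG
    return TB, fm, fx, fy


def banded_align(
    query: str,
    target: str,
    band_width: int | None = None,
    match: int = 2,
    mismatch: int = -4,
    gap_open: int = -4,
    gap_extend: int = -2,
    free_target_ends: bool = False,
) -> BandedAlignment:
    """Optimal-within-band global alignment of ``query`` against ``target``.

    The returned edit script (M/I/D cigar) replays ``target`` into ``query``:
    M consumes both, I consumes query (extra bases in the query), D consumes
    target (bases of the target missing from the query). Raises
    :class:`BandOverflowError` when no path connects the corners inside the
    band; the result's ``touched_band_edge`` flags paths pinned against the
    band boundary, which callers may treat as a cue to widen and retry.

    With ``free_target_ends`` the alignment is semi-global: unaligned target
    prefix/suffix cost nothing (read-to-window mapping), the cigar covers
    only ``target[target_start:target_end]``, and the query is still
    consumed end to end.
    """
    m, n = len(query), len(target)
    if m == 0 or n == 0:
        raise ValueError("both sequences must be non-empty")
    if band_width is None:
        band_width = max(16, int(np.ceil(0.15 * max(m, n))))
    bw = int(band_width)
    if bw < 1:
        raise ValueError("band_width must be >= 1")
    q = _encode(query)
    t = _encode(target)
    centers = np.rint(np.arange(m + 1, dtype=np.float64) * (n / m)).astype(np.int64)
    TB, fm, fx, fy = _dp_band(
        q, t, centers, bw, float(match), float(mismatch), float(gap_open),
        float(gap_extend), free_target_ends,
    )
    Wb = 2 * bw + 1
    if free_target_ends:
        score, best_k, state = float(fm), int(fx), int(fy)
        if best_k < 0 or score < NEG / 2:
            raise BandOverflowError("band too narrow to place the query")
        j_end = int(centers[m]) + best_k - bw
    else:
        finals = (fm, fx, fy)
        state = int(np.argmax(np.array(finals)))
        score = float(finals[state])
        j_end = n
        if score < NEG / 2:
            raise BandOverflowError("band too narrow to connect corners")
    ops: List[Tuple[str, int]] = []
    touched = False

    def emit(op):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))

    i, j = m, j_end
    guard = m + n + 5
    while (i > 0 or (j > 0 and not free_target_ends)) and guard > 0:
        guard -= 1
        k = j - int(centers[i]) + bw
        if (k <= 0 or k >= Wb - 1) and (i, j) != (m, j_end):
            touched = True
        if i == 0:
            emit("D")
            j -= 1
            continue
        if j == 0:
            emit("I")
            i -= 1
            continue
        bits = int(TB[i, k])
        if state == 0:
            emit("M")
            state = bits & 3
            i -= 1
            j -= 1
        elif state == 1:
            emit("I")
            s = (bits >> 2) & 3
            state = 0 if s == 0 else (2 if s == 1 else 1)
            i -= 1
        else:
            emit("D")
            s = (bits >> 4) & 3
            state = 0 if s == 0 else (1 if s == 1 else 2)
            j -= 1
    if guard == 0:
        raise BandOverflowError("traceback failed to reach the origin")
    ops.reverse()
    t_start = j
    mt, mm, ins, dl = cigar_counts(query, target, ops, t0=t_start)
    return BandedAlignment(
        cigar=ops,
        score=score,
        matches=mt,
        mismatches=mm,
        inserted=ins,
        deleted=dl,
        touched_band_edge=touched,
        target_start=t_start,
        target_end=j_end,
    )
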