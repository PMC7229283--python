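"""Edit-script primitives shared by the simulator, aligner and label maker.

Two flavours of edit script are used in this package:

* a *generative* script: a list of ``(op, data)`` tuples with ops
  ``'='`` (copy ``data`` template bases), ``'X'`` (substitute; ``data`` is the
  replacement string), ``'I'`` (insert ``data`` into the derived sequence) and
  ``'D'`` (delete ``data`` template bases).  It carries the inserted/substituted
  bases, so the derived sequence is fully reproducible from template + script.

* an *alignment cigar*: a list of ``(op, length)`` tuples over ``'M'/'I'/'D'``
  in SAM semantics (query = derived sequence, target = template; ``I`` consumes
  query only, ``D`` consumes target only).  Base identities live in the query.
"""

from __future__ import annotations

BASES = "ACGT"
_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def replay(template: str, script) -> str:
    """Apply a generative edit script to ``template``, returning the derived sequence."""
    out = []
    t = 0
    for op, data in script:
        if op == "=":
            out.append(template[t : t + data])
            t += data
        elif op == "X":
            out.append(data)
            t += len(data)
        elif op == "I":
            out.append(data)
        elif op == "D":
            t += data
        else:
            raise ValueError(f"unknown edit op {op!r}")
    if t > len(template):
        raise ValueError("edit script overruns template")
    return "".join(out)


def script_counts(script):
    """(matches, mismatches, inserted, deleted) bases implied by a generative script."""
    m = x = i = d = 0
    for op, data in script:
        if op == "=":
            m += data
        elif op == "X":
            x += len(data)
        elif op == "I":
            i += len(data)
        elif op == "D":
            d += data
    return m, x, i, d


def script_identity(script) -> float:
    """matches / aligned-columns for a generative script."""
    m, x, i, d = script_counts(script)
    L = m + x + i + d
    return m / L if L else 1.0


def script_to_cigar(script):
    """Collapse a generative script to a SAM-style M/I/D cigar (X folds into M)."""
    cig = []
    for op, data in script:
        if op in ("=", "X"):
            o, n = "M", data if op == "=" else len(data)
        elif op == "I":
            o, n = "I", len(data)
        else:
            o, n = "D", data
        if n == 0:
            continue
        if cig and cig[-1][0] == o:
            cig[-1] = (o, cig[-1][1] + n)
        else:
            cig.append((o, n))
    return cig


def cigar_consumes(cigar):
    """(query_bases, target_bases) consumed by an M/I/D cigar."""
    q = sum(n for o, n in cigar if o in "MI")
    t = sum(n for o, n in cigar if o in "MD")
    return q, t


def cigar_counts(query: str, target: str, cigar, q0: int = 0, t0: int = 0):
    """(matches, mismatches, inserted, deleted) of an M/I/D cigar over real sequences."""
    import numpy as np

    m = x = ins = dele = 0
    qi, ti = q0, t0
    for op, n in cigar:
        if op == "M":
            qa = np.frombuffer(query[qi : qi + n].encode(), dtype=np.uint8)
            ta = np.frombuffer(target[ti : ti + n].encode(), dtype=np.uint8)
            eq = int((qa == ta).sum())
            m += eq
            x += n - eq
            qi += n
            ti += n
        elif op == "I":
            ins += n
            qi += n
        elif op == "D":
            dele += n
            ti += n
        else:
            raise ValueError(f"unknown cigar op {op!r}")
    return m, x, ins, dele


def template_to_derived_map(script, template_len: int):
    """Map template coordinates to derived-sequence coordinates under a script.

    Returns an int array-like list ``pos`` of length ``template_len + 1`` where
    ``pos[i]`` is the derived coordinate of the first derived base at or after
    template position ``i`` (so slices map as ``derived[pos[a]:pos[b]]``).
    """
    pos = [0] * (template_len + 1)
    t = 0
    q = 0
    for op, data in script:
        if op in ("=", "X"):
            n = data if op == "=" else len(data)
            for k in range(n):
                pos[t + k] = q + k
            t += n
            q += n
        elif op == "I":
            q += len(data)
        elif op == "D":
            for k in range(data):
                pos[t + k] = q
            t += data
    for i in range(t, template_len + 1):
        pos[i] = q
    return pos
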