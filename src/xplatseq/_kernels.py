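"""Dynamic-programming alignment kernel.

Scores are integers; an alignment's score is ``match_s`` per matched base
and ``err_s`` per error, where an error is one mismatched, inserted, or
deleted base.  The reference start is always free (row 0 initialised to 0);
the read may be required to align fully (glocal mode) or allowed to stop
anywhere (free read end, used for partial/anchor alignment).

All working arrays are allocated by the Python wrapper and passed into the
jitted kernel, which returns scalars only.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1_000_000_000

# traceback op codes
OP_MATCH = 1
OP_MISMATCH = 2
OP_INS = 3   # read base not aligned to reference
OP_DEL = 4   # reference base skipped


@njit(cache=False)
def _dp_kernel(read, win, match_s, err_s, free_read_end, score, ptr, ops):
    m = read.shape[0]
    n = win.shape[0]
    for j in range(n + 1):
        score[0, j] = 0
        ptr[0, j] = 0
    best = NEG
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        score[i, 0] = score[i - 1, 0] + err_s
        ptr[i, 0] = 2
        for j in range(1, n + 1):
            d = score[i - 1, j - 1] + (match_s if read[i - 1] == win[j - 1] else err_s)
            u = score[i - 1, j] + err_s
            l = score[i, j - 1] + err_s
            b = d
            p = 1
            if u > b:
                b = u
                p = 2
            if l > b:
                b = l
                p = 3
            score[i, j] = b
            ptr[i, j] = p
        if free_read_end:
            for j in range(n + 1):
                if score[i, j] > best:
                    best = score[i, j]
                    bi = i
                    bj = j
    if not free_read_end:
        bi = m
        for j in range(n + 1):
            if score[m, j] > best:
                best = score[m, j]
                bj = j
    # traceback (ops recorded from the alignment end backwards)
    nmatch = 0
    nerr = 0
    nops = 0
    i = bi
    j = bj
    while i > 0:
        p = ptr[i, j]
        if p == 1:
            if read[i - 1] == win[j - 1]:
                nmatch += 1
                ops[nops] = OP_MATCH
            else:
                nerr += 1
                ops[nops] = OP_MISMATCH
            i -= 1
            j -= 1
        elif p == 2:
            nerr += 1
            ops[nops] = OP_INS
            i -= 1
        else:
            nerr += 1
            ops[nops] = OP_DEL
            j -= 1
        nops += 1
    return best, bi, nmatch, nerr, j, bj, nops


def dp_align(read: np.ndarray, win: np.ndarray, match_s: int, err_s: int,
             free_read_end: bool):
    """Align ``read`` within the reference window ``win``.

    Returns ``(score, read_consumed, n_match, n_error, win_start, win_end,
    ops, n_ops)`` where the first ``n_ops`` entries of ``ops`` list the
    traceback operations from the alignment end backwards.  Ties are broken
    deterministically towards the smallest coordinates.
    """
    m = read.shape[0]
    n = win.shape[0]
    score = np.empty((m + 1, n + 1), dtype=np.int32)
    ptr = np.empty((m + 1, n + 1), dtype=np.uint8)
    ops = np.empty(m + n + 2, dtype=np.uint8)
    best, bi, nmatch, nerr, js, bj, nops = _dp_kernel(
        np.ascontiguousarray(read), np.ascontiguousarray(win),
        np.int32(match_s), np.int32(err_s), free_read_end, score, ptr, ops,
    )
    return int(best), int(bi), int(nmatch), int(nerr), int(js), int(bj), ops, int(nops)


def cigar_from_ops(ops: np.ndarray) -> str:
    """Collapse backward traceback ops into a forward CIGAR string."""
    if ops.size == 0:
        return ""
    sym = {OP_MATCH: "M", OP_MISMATCH: "M", OP_INS: "I", OP_DEL: "D"}
    parts: list[str] = []
    run_sym = sym[int(ops[-1])]
    run_len = 0
    for op in ops[::-1]:
        s = sym[int(op)]
        if s == run_sym:
            run_len += 1
        else:
            parts.append(f"{run_len}{run_sym}")
            run_sym = s
            run_len = 1
    parts.append(f"{run_len}{run_sym}")
    return "".join(parts)
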