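"""Independent oracles used by the test suite.

These are deliberately written without reference to the package's aligner
or duplicate machinery: plain dynamic programming over every start
position, and brute-force counting over explicit keys.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np


def glocal_score(read: str, ref: str) -> int:
    """Exhaustive DP: best 5*matches - 4*errors score of the full read
    placed anywhere in ``ref`` (free reference start and end, gaps allowed,
    every error - mismatch, inserted or deleted base - costs 4)."""
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    s = np.frombuffer(ref.encode(), dtype=np.uint8)
    m, n = r.size, s.size
    idx4 = 4 * np.arange(n + 1, dtype=np.int64)
    prev = np.zeros(n + 1, dtype=np.int64)
    for i in range(m):
        sub = np.where(s == r[i], 5, -4).astype(np.int64)
        cand = np.empty(n + 1, dtype=np.int64)
        cand[0] = prev[0] - 4
        cand[1:] = np.maximum(prev[:-1] + sub, prev[1:] - 4)
        # resolve the within-row (deletion) dependency with a prefix max
        prev = np.maximum.accumulate(cand + idx4) - idx4
    return int(prev.max())


def best_nscore(read: str, reference: dict[str, str]) -> float:
    """Best achievable NScore of ``read`` against any reference sequence."""
    best = max(glocal_score(read, seq) for seq in reference.values())
    return best / len(read)


def brute_force_duplicates(records, mode: str):
    """Reference implementation of duplicate partitioning.

    Returns (kept_ids, removed_ids) keeping the lexicographically smallest
    read id per duplicate key.
    """
    groups = defaultdict(list)
    for rec in records:
        key = (rec.reference_id, rec.ref_start)
        if mode == "locus_and_length":
            key = key + (rec.read_length,)
        groups[key].append(rec.read_id)
    kept, removed = set(), set()
    for ids in groups.values():
        ids = sorted(ids)
        kept.add(ids[0])
        removed.update(ids[1:])
    return kept, removed


def per_base_coverage(records, ref_length: int) -> np.ndarray:
    cov = np.zeros(ref_length, dtype=np.int64)
    for rec in records:
        cov[rec.ref_start : rec.ref_start + rec.read_length] += 1
    return cov
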