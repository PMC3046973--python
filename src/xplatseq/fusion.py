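"""De novo gene-fusion discovery from single reads.

Chimeric transcripts are found from the reads that fail to align anywhere:

1. each non-mapping read is partially re-aligned against the transcriptome,
   keeping the best prefix-anchored and suffix-anchored partial alignment
   with an anchor of at least ``min_anchor`` (default 18) nucleotides — the
   unaligned remainder of the read is its *overhang*;
2. partial alignments sharing a reference breakpoint and anchor side are
   clustered and a consensus overhang is voted per column;
3. cluster pairs are cross-matched: a junction is declared when each
   cluster's consensus overhang matches the reference sequence flanking the
   partner cluster's breakpoint;
4. remaining non-mapping reads are rescued by aligning them against the
   reconstructed junction sequences.

The search runs against the transcriptome only, on the forward strand (the
simulators emit forward reads); contaminant references are excluded.  All
coordinates are 0-based, half-open.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._kernels import dp_align
from .align import AlignerPreset, AlignmentRecord, ReferenceIndex, _candidate_windows, encode_seq
from .reference import TranscriptRecord, is_contaminant_id, write_fasta
from .simulate import ReadRecord

logger = logging.getLogger(__name__)

PREFIX = "read_prefix"
SUFFIX = "read_suffix"


@dataclass(frozen=True)
class PartialAlignment:
    """A read anchored at one end to the reference, with an overhang.

    ``breakpoint`` is the reference coordinate at the anchor's
    unaligned-facing end: the anchor's exclusive end for a prefix anchor,
    its inclusive start for a suffix anchor.
    """

    read_id: str
    reference_id: str
    anchor_start: int
    anchor_end: int
    anchor_length: int          # read bases in the anchor
    anchor_side: str            # PREFIX or SUFFIX
    breakpoint: int
    overhang_seq: str
    n_errors: int = 0


@dataclass
class BreakpointCluster:
    """Partial alignments sharing (reference, breakpoint, anchor side)."""

    reference_id: str
    breakpoint: int
    anchor_side: str
    members: list[PartialAlignment]
    consensus_overhang: str = ""

    @property
    def read_ids(self) -> set[str]:
        return {m.read_id for m in self.members}


@dataclass
class FusionJunction:
    """A reconstructed chimeric junction with its supporting evidence."""

    five_prime: tuple[str, int]
    three_prime: tuple[str, int]
    junction_seq: str
    junction_offset: int        # junction position within junction_seq
    supporting_reads: int
    supporting_read_ids: set[str] = field(default_factory=set)
    rescued_reads: int = 0
    rescued_read_ids: set[str] = field(default_factory=set)


def collect_nonmapping(
    reads: Sequence[ReadRecord],
    alignments: Sequence[AlignmentRecord],
    filter_log: Sequence[tuple[str, str]] = (),
) -> list[ReadRecord]:
    """Reads with zero surviving alignments after the standard filters.

    Reads excluded by the length window never entered alignment and are not
    part of the non-mapping set (they are logged separately upstream).
    """
    aligned = {rec.read_id for rec in alignments}
    length_filtered = {rid for rid, reason in filter_log if reason == "length"}
    return [r for r in reads
            if r.read_id not in aligned and r.read_id not in length_filtered]


_ANCHOR_PRESET = AlignerPreset(name="anchor", gapped=True, seed_step=3, band=8)


def partial_align(
    unmapped_reads: Sequence[ReadRecord],
    index: ReferenceIndex,
    min_anchor: int = 18,
    max_error_rate: float = 0.15,
) -> list[PartialAlignment]:
    """Best prefix- and suffix-anchored partial alignments per unmapped read.

    Anchors are scored +1 per match, -2 per error (so random sequence does
    not extend them), must consume at least ``min_anchor`` read bases, fewer
    than the whole read, and at most ``max_error_rate`` errors per anchored
    base.  Both ends of a read may yield a partial alignment.
    """
    if min_anchor < index.k:
        raise ValueError("min_anchor must be at least the seed size")
    out: list[PartialAlignment] = []
    for read in unmapped_reads:
        codes = encode_seq(read.sequence)
        m = codes.size
        if m < min_anchor + 1:
            continue
        windows = _candidate_windows(index, codes, _ANCHOR_PRESET)
        best: dict[str, tuple[int, PartialAlignment]] = {}
        for ridx, ranges in windows.items():
            if index.is_contaminant(ridx):
                continue
            ref_name = index.ids[ridx]
            for smin, smax in ranges:
                win, wlo = index.window(
                    ridx, smin - _ANCHOR_PRESET.band, smax + m + _ANCHOR_PRESET.band
                )
                if win.size == 0:
                    continue
                # prefix anchor: read start fixed, free read end
                score, bi, nm, ne, js, je, _, _ = dp_align(codes, win, 1, -2, True)
                if min_anchor <= bi < m and ne <= max_error_rate * bi:
                    pa = PartialAlignment(
                        read.read_id, ref_name, wlo + int(js), wlo + int(je),
                        int(bi), PREFIX, wlo + int(je),
                        read.sequence[int(bi):], int(ne),
                    )
                    if PREFIX not in best or score > best[PREFIX][0]:
                        best[PREFIX] = (int(score), pa)
                # suffix anchor: align the reversed read in the reversed window
                rscore, rbi, rnm, rne, rjs, rje, _, _ = dp_align(
                    codes[::-1].copy(), win[::-1].copy(), 1, -2, True
                )
                if min_anchor <= rbi < m and rne <= max_error_rate * rbi:
                    n = win.size
                    a_start = wlo + n - int(rje)
                    a_end = wlo + n - int(rjs)
                    pa = PartialAlignment(
                        read.read_id, ref_name, a_start, a_end,
                        int(rbi), SUFFIX, a_start,
                        read.sequence[: m - int(rbi)], int(rne),
                    )
                    if SUFFIX not in best or rscore > best[SUFFIX][0]:
                        best[SUFFIX] = (int(rscore), pa)
        for _, pa in best.values():
            out.append(pa)
    return out


def _consensus(overhangs: Sequence[str], align: str = "left") -> str:
    """Per-column majority vote; consensus length is the longest overhang's.

    Overhangs hanging off a prefix anchor all start at the junction and are
    voted left-aligned; overhangs of suffix anchors all *end* at the
    junction and are voted right-aligned.
    """
    if not overhangs:
        return ""
    if align == "right":
        return _consensus([o[::-1] for o in overhangs], "left")[::-1]
    length = max(len(o) for o in overhangs)
    cols = []
    for i in range(length):
        votes = Counter(o[i] for o in overhangs if len(o) > i)
        top = max(votes.values())
        cols.append(min(b for b, c in votes.items() if c == top))
    return "".join(cols)


def cluster_breakpoints(
    partials: Sequence[PartialAlignment], tolerance: int = 0
) -> list[BreakpointCluster]:
    """Group partial alignments by (reference, breakpoint, anchor side).

    With ``tolerance`` > 0, breakpoints within that many bp (same reference
    and side) are merged into one cluster whose breakpoint is the most
    common member coordinate.  The default is exact grouping.
    """
    grouped: dict[tuple[str, str], list[PartialAlignment]] = defaultdict(list)
    for p in partials:
        grouped[(p.reference_id, p.anchor_side)].append(p)
    clusters: list[BreakpointCluster] = []
    for (ref, side), members in sorted(grouped.items()):
        members.sort(key=lambda p: (p.breakpoint, p.read_id))
        runs: list[list[PartialAlignment]] = []
        for p in members:
            if runs and p.breakpoint - runs[-1][-1].breakpoint <= tolerance:
                runs[-1].append(p)
            else:
                runs.append([p])
        for run in runs:
            bp_votes = Counter(p.breakpoint for p in run)
            top = max(bp_votes.values())
            bp = min(b for b, c in bp_votes.items() if c == top)
            align = "left" if side == PREFIX else "right"
            clusters.append(BreakpointCluster(
                ref, bp, side, run, _consensus([p.overhang_seq for p in run], align)
            ))
    return clusters


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(1 for x, y in zip(a[:n], b[:n]) if x == y) / n


def _overhang_matches_flank(
    overhang: str, flank: str, min_overhang: int, min_identity: float,
    align: str = "left",
) -> bool:
    """Gap-tolerant similarity between a consensus overhang and a flank.

    Consensus overhangs carry occasional dark-base deletions, so the
    comparison aligns the overhang against the partner flank with the
    indel-tolerant kernel (match +1, error -2) and accepts when at least
    ``min_overhang`` bases match with ``matches / (matches + errors)`` at or
    above ``min_identity``.  ``align="right"`` anchors the comparison at the
    junction-facing (right) end instead.
    """
    if align == "right":
        return _overhang_matches_flank(
            overhang[::-1], flank[::-1], min_overhang, min_identity, "left"
        )
    if not overhang or not flank:
        return False
    _, _, _, _, _, _, ops, nops = dp_align(
        encode_seq(overhang), encode_seq(flank), 1, -2, True
    )
    ops = ops[:nops]
    # walk the alignment path from the junction outwards: the overhang only
    # needs to match cleanly near the junction, not over its noisy far tail
    nm = ne = 0
    for op in ops[::-1]:
        if op == 1:  # match
            nm += 1
        else:
            ne += 1
        if nm >= min_overhang and nm / (nm + ne) >= min_identity:
            return True
    return False


def _cluster_matches_flank(
    cluster: BreakpointCluster, flank: str, min_overhang: int,
    min_identity: float, align: str,
) -> bool:
    """Vote the cluster's members against the partner flank.

    Individual member overhangs are compared (rather than only the
    consensus) because dark-base deletions and anchor-boundary wobble
    corrupt a column-wise consensus near the junction; the pair is accepted
    when at least half of the members with a long-enough overhang match.
    """
    eligible = [m.overhang_seq for m in cluster.members
                if len(m.overhang_seq) >= min_overhang]
    if not eligible:
        return False
    hits = sum(
        _overhang_matches_flank(o, flank, min_overhang, min_identity, align)
        for o in eligible
    )
    return hits >= 1 and hits >= 0.5 * len(eligible)


def match_overhangs(
    clusters: Sequence[BreakpointCluster],
    reference: Mapping[str, TranscriptRecord],
    min_overhang: int = 10,
    min_identity: float = 0.9,
    flank: int = 100,
    merge_window: int = 15,
) -> list[FusionJunction]:
    """Cross-match cluster overhangs against partner flanks to call junctions.

    For a 5'-side cluster A (prefix anchors; overhang is the read suffix)
    and a 3'-side cluster B (suffix anchors; overhang is the read prefix), a
    junction is declared when A's consensus overhang matches the reference
    immediately downstream of B's breakpoint AND B's consensus overhang
    matches the reference immediately upstream of A's breakpoint, each with
    ungapped identity >= ``min_identity`` over >= ``min_overhang`` bases.
    Junction pairs on one reference within ``2 * flank`` bp are skipped
    (they would merely re-discover the reference itself), and near-duplicate
    junctions within ``merge_window`` bp are collapsed onto the
    best-supported call.
    """
    five_side = [c for c in clusters
                 if c.anchor_side == PREFIX and len(c.consensus_overhang) >= min_overhang]
    three_side = [c for c in clusters
                  if c.anchor_side == SUFFIX and len(c.consensus_overhang) >= min_overhang]
    junctions: list[FusionJunction] = []
    for a in five_side:
        seq_a = reference[a.reference_id].sequence
        for b in three_side:
            if a.reference_id == b.reference_id and abs(a.breakpoint - b.breakpoint) <= 2 * flank:
                continue
            seq_b = reference[b.reference_id].sequence
            # A overhangs should continue into the 3' partner past its breakpoint
            max_a = max(len(m.overhang_seq) for m in a.members)
            down = seq_b[b.breakpoint : b.breakpoint + max_a + 8]
            if not _cluster_matches_flank(a, down, min_overhang, min_identity, "left"):
                continue
            # B overhangs should end at the 5' partner's breakpoint
            max_b = max(len(m.overhang_seq) for m in b.members)
            up = seq_a[max(0, a.breakpoint - max_b - 8) : a.breakpoint]
            if not _cluster_matches_flank(b, up, min_overhang, min_identity, "right"):
                continue
            j_five = seq_a[max(0, a.breakpoint - flank) : a.breakpoint]
            j_three = seq_b[b.breakpoint : b.breakpoint + flank]
            read_ids = a.read_ids | b.read_ids
            junctions.append(FusionJunction(
                (a.reference_id, a.breakpoint), (b.reference_id, b.breakpoint),
                j_five + j_three, len(j_five), len(read_ids), read_ids,
            ))
    # collapse near-duplicate calls (breakpoint smear from chance matches)
    junctions.sort(key=lambda j: (-j.supporting_reads, j.five_prime, j.three_prime))
    kept: list[FusionJunction] = []
    for j in junctions:
        dup = any(
            k.five_prime[0] == j.five_prime[0]
            and k.three_prime[0] == j.three_prime[0]
            and abs(k.five_prime[1] - j.five_prime[1]) <= merge_window
            and abs(k.three_prime[1] - j.three_prime[1]) <= merge_window
            for k in kept
        )
        if not dup:
            kept.append(j)
    return kept


def rescue_junction_reads(
    remaining_reads: Sequence[ReadRecord],
    junctions: Sequence[FusionJunction],
    min_side_overlap: int = 8,
    min_nscore: float = 4.0,
) -> list[FusionJunction]:
    """Align leftover non-mapping reads against the reconstructed junctions.

    A read is rescued by a junction when its full-read alignment to the
    junction sequence reaches ``min_nscore`` and crosses the junction point
    with at least ``min_side_overlap`` reference bases on each side.  Reads
    already supporting the junction are not double-counted.
    """
    updated: list[FusionJunction] = []
    for j in junctions:
        jcodes = encode_seq(j.junction_seq)
        rescued: set[str] = set()
        for read in remaining_reads:
            if read.read_id in j.supporting_read_ids:
                continue
            codes = encode_seq(read.sequence)
            if codes.size == 0:
                continue
            score, _, nm, ne, js, je, _, _ = dp_align(codes, jcodes, 5, -4, False)
            if score / codes.size < min_nscore:
                continue
            if js <= j.junction_offset - min_side_overlap and je >= j.junction_offset + min_side_overlap:
                rescued.add(read.read_id)
        updated.append(replace(
            j, rescued_reads=len(rescued), rescued_read_ids=rescued
        ))
    return updated


def discover_fusions(
    reads: Sequence[ReadRecord],
    alignments: Sequence[AlignmentRecord],
    filter_log: Sequence[tuple[str, str]],
    index: ReferenceIndex,
    min_anchor: int = 18,
    max_error_rate: float = 0.15,
    cluster_tolerance: int = 0,
    min_overhang: int = 10,
    min_identity: float = 0.9,
    flank: int = 100,
    min_side_overlap: int = 8,
) -> list[FusionJunction]:
    """Run the full non-mapping-read fusion discovery pipeline."""
    unmapped = collect_nonmapping(reads, alignments, filter_log)
    partials = partial_align(unmapped, index, min_anchor, max_error_rate)
    clusters = cluster_breakpoints(partials, cluster_tolerance)
    junctions = match_overhangs(
        clusters, index.records, min_overhang, min_identity, flank
    )
    supporting = {rid for j in junctions for rid in j.supporting_read_ids}
    remaining = [r for r in unmapped if r.read_id not in supporting]
    return rescue_junction_reads(remaining, junctions, min_side_overlap)


def junctions_to_tsv(junctions: Sequence[FusionJunction], path: str | Path) -> None:
    """Write the fusion report (coordinates 0-based, half-open)."""
    rows = [{
        "five_prime_ref": j.five_prime[0],
        "five_prime_breakpoint": j.five_prime[1],
        "three_prime_ref": j.three_prime[0],
        "three_prime_breakpoint": j.three_prime[1],
        "supporting_reads": j.supporting_reads,
        "rescued_reads": j.rescued_reads,
    } for j in junctions]
    with open(path, "w") as fh:
        fh.write("# breakpoint coordinates are 0-based, half-open\n")
        pd.DataFrame(rows, columns=[
            "five_prime_ref", "five_prime_breakpoint", "three_prime_ref",
            "three_prime_breakpoint", "supporting_reads", "rescued_reads",
        ]).to_csv(fh, sep="\t", index=False)


def junctions_to_fasta(junctions: Sequence[FusionJunction], path: str | Path) -> None:
    recs = [
        TranscriptRecord(
            f"JUNC_{j.five_prime[0]}_{j.five_prime[1]}_{j.three_prime[0]}_{j.three_prime[1]}",
            j.junction_seq,
        )
        for j in junctions
    ]
    write_fasta(recs, path)
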