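"""Seed-and-extend read alignment with NScore filtering.

One aligner, two presets emulating the documented behaviour of the tools
used on each platform:

* ``indexdp_like`` — gapped (tolerates insertions/deletions, as required by
  SMS dark-base gaps), keeps alignments with NScore >= 4.
* ``bowtie_like`` — ungapped, at most two mismatches within a 32-base seed
  region, first base trimmed.

NScore is the alignment quality score
``(5 * n_match - 4 * n_error) / read_length`` where ``n_error`` counts
mismatched plus inserted plus deleted bases, one per base.  A perfect
full-length alignment scores 5 regardless of read length.

Both presets report at most ``max_alignments`` placements per read and the
analyses downstream use single-best mappings only (highest NScore, random
uniform choice among exact ties).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from ._kernels import cigar_from_ops, dp_align
from .reference import TranscriptRecord, is_contaminant_id
from .simulate import ReadRecord

logger = logging.getLogger(__name__)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i
_COMP = np.array([3, 2, 1, 0, 255], dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Map a nucleotide string to 2-bit codes (255 for non-ACGT)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes.copy()
    valid = out != 255
    out[valid] = 3 - out[valid]
    return out[::-1].copy()


def nscore(n_match: int, n_error: int, read_length: int) -> float:
    """The alignment quality score ``(5*n_match - 4*n_error)/read_length``."""
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if n_match < 0 or n_error < 0:
        raise ValueError("counts must be >= 0")
    return (5.0 * n_match - 4.0 * n_error) / read_length


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-reference placement (coordinates 0-based, half-open)."""

    read_id: str
    reference_id: str
    ref_start: int
    ref_end: int
    n_match: int
    n_error: int
    read_length: int
    nscore: float
    strand: str = "+"
    cigar: str = ""
    is_contaminant_hit: bool = False
    is_single_best: bool = False


@dataclass(frozen=True)
class AlignerPreset:
    """Aligner behaviour knobs for one technology.

    ``usable_length_window`` is applied to the raw read length before any
    trimming; reads outside it are excluded from alignment and logged.
    """

    name: str
    gapped: bool
    max_alignments: int = 25
    min_nscore: float | None = None
    seed_mismatch_limit: int | None = None
    seed_region: int = 32
    usable_length_window: tuple[int, int] = (1, 10**9)
    trim_first_base: bool = False
    seed_k: int = 12
    seed_step: int = 4
    band: int = 10
    both_strands: bool = True
    # retry reads without a surviving alignment using shorter, denser seeds
    # (k=8, step 2) under the same scoring and filters; rescues reads whose
    # every primary seed k-mer is disrupted by dark-base deletions
    rescue_seeding: bool = True

    def __post_init__(self) -> None:
        if self.max_alignments < 1:
            raise ValueError("max_alignments must be >= 1")
        lo, hi = self.usable_length_window
        if lo > hi:
            raise ValueError("usable_length_window is empty")


def indexdp_like(**overrides) -> AlignerPreset:
    """Gapped preset: indel-tolerant extension, NScore >= 4 filter."""
    kw = dict(name="indexdp_like", gapped=True, min_nscore=4.0,
              usable_length_window=(25, 64), trim_first_base=False,
              seed_step=4, band=10)
    kw.update(overrides)
    return AlignerPreset(**kw)


def bowtie_like(**overrides) -> AlignerPreset:
    """Ungapped preset: <=2 mismatches in the 32-base seed, first base trimmed."""
    kw = dict(name="bowtie_like", gapped=False, min_nscore=None,
              seed_mismatch_limit=2, seed_region=32,
              usable_length_window=(34, 64), trim_first_base=True,
              seed_step=12, band=3)
    kw.update(overrides)
    return AlignerPreset(**kw)


class ReferenceIndex:
    """Exact k-mer index over a merged (transcriptome + contaminant) reference."""

    def __init__(self, reference: Mapping[str, TranscriptRecord], k: int = 12):
        if not reference:
            raise ValueError("reference index is empty")
        self.k = k
        self.ids: list[str] = list(reference.keys())
        self.records = reference
        self.lengths = np.array([reference[t].length for t in self.ids], dtype=np.int64)
        self.offsets = np.concatenate(([0], np.cumsum(self.lengths)))[:-1]
        self.total = int(self.lengths.sum())
        self.codes = np.empty(self.total, dtype=np.uint8)
        for i, t in enumerate(self.ids):
            o = self.offsets[i]
            self.codes[o : o + self.lengths[i]] = encode_seq(reference[t].sequence)
        self._contaminant = np.array([is_contaminant_id(t) for t in self.ids])
        self._dense: "ReferenceIndex | None" = None
        self._build_kmer_index()

    def dense(self, k: int = 8) -> "ReferenceIndex":
        """A shorter-seed companion index for sensitive re-seeding."""
        if self._dense is None or self._dense.k != k:
            self._dense = ReferenceIndex(self.records, k=k)
        return self._dense

    def _build_kmer_index(self) -> None:
        k, N = self.k, self.total
        if N < k:
            self._index: dict[int, np.ndarray] = {}
            return
        h = np.zeros(N - k + 1, dtype=np.int64)
        valid = np.ones(N - k + 1, dtype=bool)
        for j in range(k):
            c = self.codes[j : N - k + 1 + j].astype(np.int64)
            valid &= c != 255
            h = (h << 2) | (c & 3)
        # exclude k-mers straddling a transcript boundary
        pos = np.arange(N - k + 1)
        ridx = np.searchsorted(self.offsets, pos, side="right") - 1
        ends = self.offsets[ridx] + self.lengths[ridx]
        valid &= pos + k <= ends
        pos = pos[valid]
        h = h[valid]
        order = np.argsort(h, kind="stable")
        h = h[order]
        pos = pos[order]
        uniq, starts = np.unique(h, return_index=True)
        bounds = np.append(starts, h.size)
        self._index = {int(u): pos[bounds[i] : bounds[i + 1]]
                       for i, u in enumerate(uniq)}

    def lookup(self, codes: np.ndarray, offset: int) -> np.ndarray:
        """Positions of the k-mer at ``codes[offset:offset+k]`` (empty if absent)."""
        k = self.k
        window = codes[offset : offset + k]
        if window.size < k or np.any(window == 255):
            return _EMPTY
        h = 0
        for c in window:
            h = (h << 2) | int(c)
        return self._index.get(h, _EMPTY)

    def locate(self, gpos: int) -> int:
        """Transcript index containing global position ``gpos``."""
        return int(np.searchsorted(self.offsets, gpos, side="right") - 1)

    def is_contaminant(self, ridx: int) -> bool:
        return bool(self._contaminant[ridx])

    def window(self, ridx: int, lo: int, hi: int) -> tuple[np.ndarray, int]:
        """Reference codes for transcript-local [lo, hi) clamped to bounds."""
        L = int(self.lengths[ridx])
        lo = max(0, lo)
        hi = min(L, hi)
        o = int(self.offsets[ridx])
        return self.codes[o + lo : o + hi], lo


_EMPTY = np.empty(0, dtype=np.int64)


def _read_kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit hashes of every k-mer in the read plus a validity mask."""
    m = codes.size
    h = np.zeros(m - k + 1, dtype=np.int64)
    valid = np.ones(m - k + 1, dtype=bool)
    for j in range(k):
        c = codes[j : m - k + 1 + j].astype(np.int64)
        valid &= c != 255
        h = (h << 2) | (c & 3)
    return h, valid


def _candidate_windows(
    index: ReferenceIndex, codes: np.ndarray, preset: AlignerPreset
) -> dict[int, list[tuple[int, int]]]:
    """Merged candidate start ranges per transcript from exact seed hits."""
    m = codes.size
    k = index.k
    if m < k:
        return {}
    hashes, valid = _read_kmer_hashes(codes, k)
    offsets = list(range(0, m - k + 1, preset.seed_step))
    if offsets[-1] != m - k:
        offsets.append(m - k)
    gpos: list[np.ndarray] = []
    goff: list[np.ndarray] = []
    for off in offsets:
        if not valid[off]:
            continue
        pos = index._index.get(int(hashes[off]))
        if pos is None:
            continue
        gpos.append(pos)
        goff.append(np.full(pos.size, off, dtype=np.int64))
    if not gpos:
        return {}
    g = np.concatenate(gpos)
    off = np.concatenate(goff)
    ridx = np.searchsorted(index.offsets, g, side="right") - 1
    start = g - index.offsets[ridx] - off
    order = np.lexsort((start, ridx))
    ridx = ridx[order]
    start = start[order]
    windows: dict[int, list[tuple[int, int]]] = {}
    gap = preset.band + 1
    i = 0
    n = ridx.size
    while i < n:
        r = int(ridx[i])
        merged: list[tuple[int, int]] = []
        lo = hi = int(start[i])
        j = i + 1
        while j < n and ridx[j] == r:
            s = int(start[j])
            if s - hi <= gap:
                hi = s
            else:
                merged.append((lo, hi))
                lo = hi = s
            j += 1
        merged.append((lo, hi))
        windows[r] = merged
        i = j
    return windows


def _align_ungapped(
    index: ReferenceIndex, ridx: int, win_lo: int, win_hi: int,
    codes: np.ndarray, preset: AlignerPreset,
) -> tuple[float, int, int, int] | None:
    """Best ungapped placement of the read inside the window, or None."""
    m = codes.size
    win, lo = index.window(ridx, win_lo, win_hi)
    if win.size < m:
        return None
    view = np.lib.stride_tricks.sliding_window_view(win, m)
    mism = (view != codes).sum(axis=1)
    if preset.seed_mismatch_limit is not None:
        sr = min(preset.seed_region, m)
        seed_mism = (view[:, :sr] != codes[:sr]).sum(axis=1)
        ok = seed_mism <= preset.seed_mismatch_limit
        if not ok.any():
            return None
        mism = np.where(ok, mism, m + 1)
    best = int(np.argmin(mism))
    mm = int(mism[best])
    if mm > m:
        return None
    ns = nscore(m - mm, mm, m)
    return ns, lo + best, m - mm, mm


def _evaluate_candidates(
    index: ReferenceIndex,
    preset: AlignerPreset,
    read_id: str,
    strands: list[tuple[str, np.ndarray]],
    m: int,
) -> list[AlignmentRecord]:
    cands: list[AlignmentRecord] = []
    for strand, codes in strands:
        for ridx, ranges in _candidate_windows(index, codes, preset).items():
            rid_name = index.ids[ridx]
            contam = index.is_contaminant(ridx)
            for smin, smax in ranges:
                win_lo = smin - preset.band
                win_hi = smax + m + preset.band
                if preset.gapped:
                    win, wlo = index.window(ridx, win_lo, win_hi)
                    if win.size == 0:
                        continue
                    score, _, nm, ne, js, je, ops, nops = dp_align(codes, win, 5, -4, False)
                    ns = score / m
                    if preset.min_nscore is not None and ns < preset.min_nscore - 1e-12:
                        continue
                    cands.append(AlignmentRecord(
                        read_id, rid_name, wlo + int(js), wlo + int(je),
                        int(nm), int(ne), m, ns, strand,
                        cigar_from_ops(ops[:nops]), contam,
                    ))
                else:
                    hit = _align_ungapped(index, ridx, win_lo, win_hi, codes, preset)
                    if hit is None:
                        continue
                    ns, start, nm, ne = hit
                    if preset.min_nscore is not None and ns < preset.min_nscore - 1e-12:
                        continue
                    cands.append(AlignmentRecord(
                        read_id, rid_name, start, start + m,
                        nm, ne, m, ns, strand, f"{m}M", contam,
                    ))
    return cands


def align_reads(
    reads: Sequence[ReadRecord],
    index: ReferenceIndex,
    preset: AlignerPreset,
    seed: int = 0,
) -> tuple[list[AlignmentRecord], list[tuple[str, str]]]:
    """Align reads against the indexed reference under ``preset``.

    Returns the alignment records (at most ``preset.max_alignments`` per
    read, sorted per read by descending NScore) and a filter log of
    ``(read_id, reason)`` rows for reads excluded by the length window
    (``"length"``) or left without a surviving alignment (``"unaligned"``).
    ``seed`` is accepted for interface symmetry; alignment itself is
    deterministic.
    """
    lo_len, hi_len = preset.usable_length_window
    records: list[AlignmentRecord] = []
    filter_log: list[tuple[str, str]] = []
    for read in reads:
        raw_len = len(read.sequence)
        if not (lo_len <= raw_len <= hi_len):
            filter_log.append((read.read_id, "length"))
            continue
        seq = read.sequence[1:] if preset.trim_first_base else read.sequence
        fwd = encode_seq(seq)
        m = fwd.size
        strands = [("+", fwd)]
        if preset.both_strands:
            strands.append(("-", revcomp_codes(fwd)))
        cands = _evaluate_candidates(index, preset, read.read_id, strands, m)
        if not cands and preset.rescue_seeding and m >= 8:
            dense = replace(preset, seed_k=8, seed_step=2)
            cands = _evaluate_candidates(index.dense(), dense, read.read_id,
                                         strands, m)
        # dedupe identical placements, keep the better-scoring strand
        best_by_pos: dict[tuple[str, int], AlignmentRecord] = {}
        for rec in cands:
            key = (rec.reference_id, rec.ref_start)
            old = best_by_pos.get(key)
            if old is None or (rec.nscore, rec.strand == "+") > (old.nscore, old.strand == "+"):
                best_by_pos[key] = rec
        kept = sorted(
            best_by_pos.values(),
            key=lambda r: (-r.nscore, r.reference_id, r.ref_start, r.strand),
        )[: preset.max_alignments]
        if kept:
            records.extend(kept)
        else:
            filter_log.append((read.read_id, "unaligned"))
    return records, filter_log


def group_by_read(records: Iterable[AlignmentRecord]) -> dict[str, list[AlignmentRecord]]:
    grouped: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in records:
        grouped[rec.read_id].append(rec)
    return dict(grouped)


def single_best(
    records: Iterable[AlignmentRecord], seed: int = 0
) -> list[AlignmentRecord]:
    """Select at most one highest-NScore alignment per read.

    Exact NScore ties are resolved by a uniform random draw using ``seed``;
    the draw order is canonical (reads in sorted id order, tied candidates
    in coordinate order) so the selection is reproducible.
    """
    rng = np.random.default_rng(seed)
    chosen: list[AlignmentRecord] = []
    grouped = group_by_read(records)
    for read_id in sorted(grouped):
        group = grouped[read_id]
        top = max(r.nscore for r in group)
        ties = sorted(
            (r for r in group if r.nscore >= top - 1e-12),
            key=lambda r: (r.reference_id, r.ref_start, r.strand),
        )
        pick = ties[0] if len(ties) == 1 else ties[int(rng.integers(0, len(ties)))]
        chosen.append(replace(pick, is_single_best=True))
    return chosen


def partition_by_contaminant(
    records: Iterable[AlignmentRecord],
) -> tuple[list[AlignmentRecord], list[AlignmentRecord]]:
    """Split single-best records into (usable, contaminant) by best hit.

    A read whose single-best alignment is to a contaminant reference is
    removed from the usable set entirely.
    """
    usable: list[AlignmentRecord] = []
    contaminant: list[AlignmentRecord] = []
    for rec in records:
        (contaminant if rec.is_contaminant_hit else usable).append(rec)
    return usable, contaminant


def compute_sample_stats(
    reads: Sequence[ReadRecord],
    records: Sequence[AlignmentRecord],
    filter_log: Sequence[tuple[str, str]] = (),
) -> dict:
    """Summary statistics of one aligned sample.

    Reports total reads, the contaminant percentage (reads whose best hit is
    a contaminant), the usable aligned percentage, the unique-mapping rate
    (% of aligned reads with exactly one reported alignment), and the raw
    read-length histogram.
    """
    total = len(reads)
    grouped = group_by_read(records)
    aligned = len(grouped)
    n_unique = sum(1 for g in grouped.values() if len(g) == 1)
    contam_reads = sum(
        1 for g in grouped.values()
        if max(g, key=lambda r: r.nscore).is_contaminant_hit
    )
    hist = Counter(len(r.sequence) for r in reads)
    unique_defined = aligned > 0
    return {
        "total_reads": total,
        "aligned_reads": aligned,
        "pct_contaminant": 100.0 * contam_reads / total if total else 0.0,
        "pct_aligned_usable": 100.0 * (aligned - contam_reads) / total if total else 0.0,
        "unique_rate_pct": 100.0 * n_unique / aligned if unique_defined else 0.0,
        "unique_rate_defined": unique_defined,
        "length_histogram": dict(sorted(hist.items())),
        "n_length_filtered": sum(1 for _, reason in filter_log if reason == "length"),
        "n_unaligned": sum(1 for _, reason in filter_log if reason == "unaligned"),
    }


# ---------------------------------------------------------------------------
# SAM IO
# ---------------------------------------------------------------------------

def _sam_header(reference: Mapping[str, TranscriptRecord]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": t, "LN": rec.length} for t, rec in reference.items()],
    }


def write_sam(
    records: Sequence[AlignmentRecord],
    reference: Mapping[str, TranscriptRecord],
    path: str | Path,
    duplicate_ids: set[str] | None = None,
) -> None:
    """Write alignment records as SAM (1-based POS per the standard).

    NScore is emitted as the ``ZN`` float tag, match/error counts as
    ``ZM``/``ZE``, the read length as ``ZL``; reads in ``duplicate_ids``
    get the standard duplicate flag.
    """
    header = pysam.AlignmentHeader.from_dict(_sam_header(reference))
    tid = {t: i for i, t in enumerate(reference)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.read_id
            seg.reference_id = tid[rec.reference_id]
            seg.reference_start = rec.ref_start
            seg.mapping_quality = 255
            seg.cigarstring = rec.cigar or f"{rec.read_length}M"
            flag = 0
            if rec.strand == "-":
                flag |= 0x10
            if duplicate_ids and rec.read_id in duplicate_ids:
                flag |= 0x400
            seg.flag = flag
            seg.set_tags([
                ("ZN", float(rec.nscore), "f"),
                ("ZM", int(rec.n_match), "i"),
                ("ZE", int(rec.n_error), "i"),
                ("ZL", int(rec.read_length), "i"),
                ("ZB", 1 if rec.is_single_best else 0, "i"),
            ])
            fh.write(seg)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read alignment records back from a SAM produced by :func:`write_sam`."""
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            rid = seg.reference_name
            out.append(AlignmentRecord(
                read_id=seg.query_name,
                reference_id=rid,
                ref_start=seg.reference_start,
                ref_end=seg.reference_end,
                n_match=seg.get_tag("ZM"),
                n_error=seg.get_tag("ZE"),
                read_length=seg.get_tag("ZL"),
                nscore=float(seg.get_tag("ZN")),
                strand="-" if seg.is_reverse else "+",
                cigar=seg.cigarstring or "",
                is_contaminant_hit=is_contaminant_id(rid),
                is_single_best=bool(seg.get_tag("ZB")),
            ))
    return out


def write_filter_log(filter_log: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\treason\n")
        for read_id, reason in filter_log:
            fh.write(f"{read_id}\t{reason}\n")
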