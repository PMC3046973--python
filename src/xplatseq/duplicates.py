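"""Duplicate-read identification, removal, and AS-vs-SMS summaries.

A duplicate read is a read in excess of one per *duplicate key*.  Two key
modes are supported:

* ``locus`` — key is (reference, alignment start): at most one read may
  start at each locus.  After removal, per-base coverage of a transcript
  cannot exceed the read length (each position is covered by at most
  ``read_length`` distinct start loci).
* ``locus_and_length`` — key additionally includes the read length, so two
  reads starting at the same locus with different lengths both survive.

Removal keeps the lexicographically smallest read id per key, which makes
the procedure deterministic; no downstream statistic depends on which copy
survives.  Strand is ignored (transcript-space alignments).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentRecord
from .reference import TranscriptRecord

MODES = ("locus", "locus_and_length")


def _key(rec: AlignmentRecord, mode: str):
    if mode == "locus":
        return (rec.reference_id, rec.ref_start)
    if mode == "locus_and_length":
        return (rec.reference_id, rec.ref_start, rec.read_length)
    raise ValueError(f"unknown duplicate mode {mode!r}")


def mark_duplicates(
    records: Sequence[AlignmentRecord], mode: str = "locus_and_length"
) -> tuple[list[AlignmentRecord], list[AlignmentRecord]]:
    """Partition single-best alignments into (kept, removed) per key.

    Exactly one read is kept per duplicate key (the lexicographically
    smallest read id); the rest are the removed duplicates.
    """
    best: dict[tuple, AlignmentRecord] = {}
    for rec in records:
        k = _key(rec, mode)
        old = best.get(k)
        if old is None or rec.read_id < old.read_id:
            best[k] = rec
    kept_ids = {id(rec) for rec in best.values()}
    kept: list[AlignmentRecord] = []
    removed: list[AlignmentRecord] = []
    for rec in records:
        (kept if id(rec) in kept_ids else removed).append(rec)
    return kept, removed


@dataclass
class DuplicateProfile:
    """Duplicate counts binned by normalised transcript position [0, 1)."""

    bins: np.ndarray          # per-bin duplicate read counts, length n_bins
    total_duplicates: int

    def normalised(self) -> np.ndarray:
        if self.total_duplicates == 0:
            return np.zeros_like(self.bins, dtype=float)
        return self.bins / self.total_duplicates


def duplicate_profile(
    records: Sequence[AlignmentRecord],
    reference: Mapping[str, TranscriptRecord],
    n_bins: int = 50,
    mode: str = "locus_and_length",
) -> DuplicateProfile:
    """Positional distribution of duplicate reads along transcripts.

    Each duplicate (read in excess of one per key) is assigned to bin
    ``floor(n_bins * ref_start / ref_length)``, aggregated across
    transcripts.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    _, removed = mark_duplicates(records, mode)
    bins = np.zeros(n_bins, dtype=np.int64)
    for rec in removed:
        L = reference[rec.reference_id].length
        b = min(n_bins - 1, int(n_bins * rec.ref_start / L))
        bins[b] += 1
    return DuplicateProfile(bins, len(removed))


def per_transcript_duplicates(
    records: Sequence[AlignmentRecord], mode: str = "locus"
) -> dict[str, int]:
    """Duplicate-read count per transcript (reads minus distinct keys)."""
    reads: Counter[str] = Counter()
    keys: dict[str, set] = defaultdict(set)
    for rec in records:
        reads[rec.reference_id] += 1
        keys[rec.reference_id].add(_key(rec, mode))
    return {t: reads[t] - len(keys[t]) for t in reads}


def duplication_summary(
    as_records: Sequence[AlignmentRecord],
    sms_records: Sequence[AlignmentRecord],
    mode: str = "locus",
) -> dict:
    """Compare duplication between technologies.

    Reports per-transcript duplicate counts, the per-technology medians over
    transcripts observed (>= 1 read) in both technologies, their AS:SMS
    ratio, and the fraction of reads removed by ``locus``-mode duplicate
    removal in each technology.  The ratio is NaN when the SMS median is 0.
    """
    as_dup = per_transcript_duplicates(as_records, mode)
    sms_dup = per_transcript_duplicates(sms_records, mode)
    common = sorted(set(as_dup) & set(sms_dup))
    as_median = float(np.median([as_dup[t] for t in common])) if common else 0.0
    sms_median = float(np.median([sms_dup[t] for t in common])) if common else 0.0
    ratio = as_median / sms_median if sms_median > 0 else float("nan")

    def _removed_fraction(records: Sequence[AlignmentRecord]) -> float:
        if not records:
            return 0.0
        _, removed = mark_duplicates(records, "locus")
        return len(removed) / len(records)

    return {
        "per_transcript": {"AS": as_dup, "SMS": sms_dup},
        "median_duplicates": {"AS": as_median, "SMS": sms_median},
        "as_sms_median_ratio": ratio,
        "pct_reads_removed_locus": {
            "AS": 100.0 * _removed_fraction(as_records),
            "SMS": 100.0 * _removed_fraction(sms_records),
        },
        "n_transcripts_compared": len(common),
    }


def summary_to_tsv(summary: dict, path: str | Path) -> None:
    rows = []
    for tech in ("AS", "SMS"):
        rows.append({
            "technology": tech,
            "median_duplicates": summary["median_duplicates"][tech],
            "pct_reads_removed_locus": summary["pct_reads_removed_locus"][tech],
        })
    df = pd.DataFrame(rows)
    df["as_sms_median_ratio"] = summary["as_sms_median_ratio"]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
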