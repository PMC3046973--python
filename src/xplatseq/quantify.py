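"""Gene-level expression tables: read counts, RPM, RPKM, coverage.

All quantities derive from single-best, non-contaminant alignments:

* ``rpm`` — reads per million usable reads: ``count / usable_total * 1e6``,
  where *usable* reads are those surviving the length-window, alignment and
  contaminant filters (the normalisation denominator for every sample).
* ``rpkm`` — per isoform, ``count / (isoform_kb * usable_millions)``; the
  gene value is the sum over its isoforms.  The length denominator is the
  plain isoform length (no effective-length correction).
* ``coverage`` — summed aligned read lengths over all isoforms divided by
  the gene's mean isoform length.

A read aligning to several isoforms of a gene is counted once, on its
single-best isoform.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import AlignmentRecord
from .reference import GeneModel, TranscriptRecord, mean_isoform_length


@dataclass
class ExpressionTable:
    """Per-gene expression values for one sample/technology.

    ``data`` is indexed by gene symbol with columns ``read_count``, ``rpm``,
    ``rpkm``, ``coverage``, sorted by gene ascending.
    """

    data: pd.DataFrame
    sample_id: str
    technology: str
    usable_total: int

    def rpm(self) -> pd.Series:
        return self.data["rpm"]

    def rpkm(self) -> pd.Series:
        return self.data["rpkm"]

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "technology", self.technology)
        out.insert(0, "sample_id", self.sample_id)
        with open(path, "w") as fh:
            fh.write(f"# usable_total={self.usable_total}\n")
            out.to_csv(fh, sep="\t", index_label="gene", float_format="%.8g")


def count_per_transcript(
    single_best_alignments: Iterable[AlignmentRecord],
) -> dict[str, int]:
    """Count reads per transcript from single-best alignments.

    Raises ``ValueError`` if any record is not flagged single-best (the
    caller must select mappings first) — counting multi-alignments would
    double-count reads.
    """
    counts: Counter[str] = Counter()
    for rec in single_best_alignments:
        if not rec.is_single_best:
            raise ValueError(f"non-single-best alignment for read {rec.read_id!r}")
        counts[rec.reference_id] += 1
    return dict(counts)


def gene_tables(
    transcript_counts: Mapping[str, int],
    alignments: Iterable[AlignmentRecord],
    genes: Sequence[GeneModel],
    reference: Mapping[str, TranscriptRecord],
    usable_total: int,
    sample_id: str = "sample",
    technology: str = "NA",
) -> ExpressionTable:
    """Aggregate transcript counts into a gene-level expression table."""
    total_counts = sum(transcript_counts.values())
    if usable_total == 0 and total_counts > 0:
        raise ValueError("usable_total is 0 but counts are non-zero")
    if usable_total < total_counts:
        raise ValueError("usable_total smaller than the sum of counts")

    aligned_len: Counter[str] = Counter()
    for rec in alignments:
        aligned_len[rec.reference_id] += rec.read_length

    millions = usable_total / 1e6
    rows = []
    for g in sorted(genes, key=lambda g: g.gene_symbol):
        count = sum(transcript_counts.get(t, 0) for t in g.isoform_ids)
        rpkm = 0.0
        if count > 0:
            for t in g.isoform_ids:
                c = transcript_counts.get(t, 0)
                kb = reference[t].length / 1000.0
                rpkm += c / (kb * millions)
        rpm = count / usable_total * 1e6 if usable_total else 0.0
        cov = sum(aligned_len.get(t, 0) for t in g.isoform_ids) / mean_isoform_length(
            g, reference
        )
        rows.append((g.gene_symbol, count, rpm, rpkm, cov))
    df = pd.DataFrame(rows, columns=["gene", "read_count", "rpm", "rpkm", "coverage"])
    df = df.set_index("gene")
    return ExpressionTable(df, sample_id, technology, usable_total)


def read_expression_tsv(path: str | Path) -> ExpressionTable:
    with open(path) as fh:
        header = fh.readline()
        usable_total = int(header.strip().split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t", index_col="gene")
    sample_id = str(df["sample_id"].iloc[0])
    technology = str(df["technology"].iloc[0])
    df = df.drop(columns=["sample_id", "technology"])
    return ExpressionTable(df, sample_id, technology, usable_total)
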