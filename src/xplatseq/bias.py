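"""Comparative AS-vs-SMS analyses.

Implements the core platform-bias comparisons on paired expression tables:

* quartile partition of genes by AS expression and per-quartile read
  fractions (the signature of amplification bias: the highest-expression
  quartile absorbs a larger share of AS reads, the lower quartiles a larger
  share of SMS reads);
* quantile-quantile comparison with a top-decile divergence statistic;
* a detection-threshold sweep (0.1..3.0 RPKM) counting genes detected in
  only one technology, stratified by transcript length class;
* recurrence analysis of over-represented genes across samples;
* nomination of genes detectable only by one technology, with long-read,
  read-dispersion and alternate-mapping diagnostics;
* the read-redistribution arithmetic: the fold-change in a low quartile's
  read sum when a small fraction of the top quartile's reads is moved to it.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentRecord, group_by_read
from .quantify import ExpressionTable
from .reference import GeneModel, TranscriptRecord

logger = logging.getLogger(__name__)

LENGTH_CLASSES = ((0, 300), (300, 3000), (3000, None))
LENGTH_CLASS_LABELS = ("0-300", "300-3000", "3000+")


def gene_universe(as_table: ExpressionTable, sms_table: ExpressionTable) -> list[str]:
    """Genes with AS rpm > 0 plus genes observed in SMS (zero-filled in AS)."""
    as_pos = set(as_table.data.index[as_table.data["rpm"] > 0])
    sms_pos = set(sms_table.data.index[sms_table.data["rpm"] > 0])
    return sorted(as_pos | sms_pos)


def quartile_partition(
    as_table: ExpressionTable, universe: Sequence[str] | None = None
) -> pd.Series:
    """Assign genes to quartiles 1..4 by descending AS expression.

    Q1 holds the highest-expressing genes.  Genes are sorted by AS rpm
    descending with ties broken by gene name ascending, then split into four
    contiguous blocks of equal size (remainder going to earlier quartiles).
    """
    genes = list(universe) if universe is not None else list(as_table.data.index)
    if len(genes) < 4:
        raise ValueError("need at least 4 genes to form quartiles")
    rpm = as_table.data["rpm"].reindex(genes).fillna(0.0)
    ordered = sorted(genes, key=lambda g: (-rpm[g], g))
    n = len(ordered)
    sizes = [n // 4 + (1 if i < n % 4 else 0) for i in range(4)]
    labels = np.repeat([1, 2, 3, 4], sizes)
    return pd.Series(labels, index=pd.Index(ordered, name="gene"), name="quartile")


@dataclass
class QuartileSummary:
    """Per-quartile rpm sums and fractions for both technologies."""

    table: pd.DataFrame   # index Q1..Q4; columns as_rpm, sms_rpm, as_fraction, sms_fraction

    def fraction(self, technology: str, quartiles: Iterable[int]) -> float:
        col = f"{technology.lower()}_fraction"
        return float(self.table.loc[[f"Q{q}" for q in quartiles], col].sum())


def quartile_read_fractions(
    as_table: ExpressionTable,
    sms_table: ExpressionTable,
    quartiles: pd.Series,
) -> QuartileSummary:
    """Sum rpm per quartile per technology and normalise to fractions."""
    genes = quartiles.index
    as_rpm = as_table.data["rpm"].reindex(genes)
    sms_rpm = sms_table.data["rpm"].reindex(genes)
    for name, col in (("AS", as_rpm), ("SMS", sms_rpm)):
        missing = col.isna()
        if missing.any():
            logger.warning("%d genes missing from %s table treated as 0", missing.sum(), name)
    as_rpm = as_rpm.fillna(0.0)
    sms_rpm = sms_rpm.fillna(0.0)
    rows = []
    for q in (1, 2, 3, 4):
        sel = quartiles == q
        rows.append((f"Q{q}", as_rpm[sel].sum(), sms_rpm[sel].sum()))
    df = pd.DataFrame(rows, columns=["quartile", "as_rpm", "sms_rpm"]).set_index("quartile")
    for tech in ("as", "sms"):
        total = df[f"{tech}_rpm"].sum()
        df[f"{tech}_fraction"] = df[f"{tech}_rpm"] / total if total > 0 else 0.0
    return QuartileSummary(df)


def redistribution_factor(
    q_low_over_q_high: float, moved_fraction_of_q_high: float
) -> float:
    """Fold-change of a low quartile's read sum after redistributing reads.

    If the low quartile's rpm sum is ``q_low_over_q_high`` times the top
    quartile's, moving ``moved_fraction_of_q_high`` of the top quartile's
    reads into it multiplies the low quartile's sum by
    ``(q_low_over_q_high + moved_fraction_of_q_high) / q_low_over_q_high``.
    """
    if q_low_over_q_high <= 0:
        raise ValueError("q_low_over_q_high must be > 0")
    if moved_fraction_of_q_high < 0:
        raise ValueError("moved fraction must be >= 0")
    return (q_low_over_q_high + moved_fraction_of_q_high) / q_low_over_q_high


def qq_compare(
    as_table: ExpressionTable,
    sms_table: ExpressionTable,
    universe: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Rank-for-rank quantile pairs of log2(rpm + 1) plus a divergence stat.

    Returns the sorted quantile pairs (ascending) and the mean AS - SMS
    difference over the top decile of ranks — positive when AS
    over-represents its most abundant genes relative to SMS.
    """
    genes = list(universe) if universe is not None else gene_universe(as_table, sms_table)
    as_q = np.sort(np.log2(as_table.data["rpm"].reindex(genes).fillna(0.0).to_numpy() + 1.0))
    sms_q = np.sort(np.log2(sms_table.data["rpm"].reindex(genes).fillna(0.0).to_numpy() + 1.0))
    df = pd.DataFrame({"as_log2_rpm": as_q, "sms_log2_rpm": sms_q})
    n = len(df)
    top = max(1, n // 10)
    divergence = float((as_q[-top:] - sms_q[-top:]).mean())
    return df, divergence


@dataclass
class DetectionSweepResult:
    """Single-technology detection counts across RPKM thresholds."""

    table: pd.DataFrame  # columns: threshold, sms_only, as_only, and per-class splits

    def at(self, threshold: float) -> pd.Series:
        idx = (self.table["threshold"] - threshold).abs().idxmin()
        return self.table.loc[idx]


def detection_sweep(
    as_table: ExpressionTable,
    sms_table: ExpressionTable,
    gene_length: Mapping[str, float],
    thresholds: Sequence[float] | None = None,
) -> DetectionSweepResult:
    """Count genes above threshold in exactly one technology, per threshold.

    For each threshold ``t``, SMS-only genes have ``sms_rpkm >= t`` and
    ``as_rpkm < t`` (AS-only symmetric); each count is stratified into
    transcript length classes 0-300, 300-3000, 3000+ bp using the gene's
    maximum isoform length.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(1, 31) * 0.1, 1)
    genes = sorted(set(as_table.data.index) | set(sms_table.data.index))
    as_rpkm = as_table.data["rpkm"].reindex(genes).fillna(0.0).to_numpy()
    sms_rpkm = sms_table.data["rpkm"].reindex(genes).fillna(0.0).to_numpy()
    lengths = np.array([gene_length.get(g, 0.0) for g in genes])
    class_idx = np.digitize(lengths, [300, 3000])  # 0,1,2

    rows = []
    for t in thresholds:
        sms_only = (sms_rpkm >= t) & (as_rpkm < t)
        as_only = (as_rpkm >= t) & (sms_rpkm < t)
        row = {"threshold": float(t),
               "sms_only": int(sms_only.sum()),
               "as_only": int(as_only.sum())}
        for ci, label in enumerate(LENGTH_CLASS_LABELS):
            row[f"sms_only_{label}"] = int((sms_only & (class_idx == ci)).sum())
            row[f"as_only_{label}"] = int((as_only & (class_idx == ci)).sum())
        rows.append(row)
    return DetectionSweepResult(pd.DataFrame(rows))


@dataclass
class RecurrenceResult:
    """Per-sample top-k over-represented gene lists and the recurrent set."""

    per_sample: list[list[str]]
    recurrent: set[str] = field(default_factory=set)
    min_samples: int = 0


def recurrent_overrepresentation(
    samples: Sequence[tuple[ExpressionTable, ExpressionTable]],
    top_k: int = 500,
    recurrence_fraction: float = 0.4,
) -> RecurrenceResult:
    """Find genes recurrently over-represented in AS across samples.

    Per sample, genes are ranked by ``as_rpm - sms_rpm`` descending (ties by
    gene name) and the top ``top_k`` taken; the recurrent set contains genes
    appearing in at least ``ceil(recurrence_fraction * n_samples)`` lists.
    The difference is used rather than a ratio to stay defined at SMS
    dropouts.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples for recurrence analysis")
    per_sample: list[list[str]] = []
    for as_table, sms_table in samples:
        genes = sorted(set(as_table.data.index) | set(sms_table.data.index))
        diff = (as_table.data["rpm"].reindex(genes).fillna(0.0)
                - sms_table.data["rpm"].reindex(genes).fillna(0.0))
        k = top_k
        if k > len(genes):
            logger.warning("top_k=%d larger than gene universe (%d); clamped", k, len(genes))
            k = len(genes)
        ranked = sorted(genes, key=lambda g: (-diff[g], g))
        per_sample.append(ranked[:k])
    min_samples = math.ceil(recurrence_fraction * len(samples))
    counts = Counter(g for lst in per_sample for g in set(lst))
    recurrent = {g for g, c in counts.items() if c >= min_samples}
    return RecurrenceResult(per_sample, recurrent, min_samples)


def nominate_single_tech_candidates(
    sms_tables: Sequence[ExpressionTable],
    as_tables: Sequence[ExpressionTable],
    sms_single_best: Sequence[AlignmentRecord],
    sms_all_alignments: Sequence[AlignmentRecord],
    genes: Sequence[GeneModel],
    reference: Mapping[str, TranscriptRecord],
    threshold: float = 0.3,
    top_n: int = 50,
    long_read_min: int = 37,
    long_read_fraction_min: float = 0.3,
    dispersion_bin: int = 50,
) -> pd.DataFrame:
    """Nominate genes detected by SMS but not AS, with mapping diagnostics.

    A candidate has mean SMS RPKM >= ``threshold`` across replicates and
    mean AS RPKM below it.  Each candidate is annotated with its long-read
    fraction (reads of >= ``long_read_min`` bp), a read-dispersion statistic
    (fraction of ``dispersion_bin``-bp transcript bins containing at least
    one read start), and the distribution of next-best alignment references
    for its reads (a mis-mapping diagnostic).  Candidates whose long-read
    fraction falls below ``long_read_fraction_min`` are dropped — genes
    supported only by short, ambiguously mapping reads are likely noise —
    and the list is truncated to ``top_n`` rows sorted by RPKM difference.
    """
    if not sms_tables or not as_tables:
        raise ValueError("need at least one replicate table per technology")
    all_genes = sorted(set().union(*[set(t.data.index) for t in sms_tables + list(as_tables)]))
    sms_mean = pd.concat(
        [t.data["rpkm"].reindex(all_genes).fillna(0.0) for t in sms_tables], axis=1
    ).mean(axis=1)
    as_mean = pd.concat(
        [t.data["rpkm"].reindex(all_genes).fillna(0.0) for t in as_tables], axis=1
    ).mean(axis=1)
    candidates = [g for g in all_genes if sms_mean[g] >= threshold and as_mean[g] < threshold]

    by_transcript: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in sms_single_best:
        by_transcript[rec.reference_id].append(rec)
    grouped_all = group_by_read(sms_all_alignments)

    rows = []
    for g in genes:
        if g.gene_symbol not in candidates:
            continue
        recs = [r for t in g.isoform_ids for r in by_transcript.get(t, [])]
        n_reads = len(recs)
        long_fraction = (
            sum(1 for r in recs if r.read_length >= long_read_min) / n_reads
            if n_reads else 0.0
        )
        # dispersion: occupied 50 bp start bins over all isoforms
        total_bins = 0
        occupied: set[tuple[str, int]] = set()
        for t in g.isoform_ids:
            total_bins += max(1, math.ceil(reference[t].length / dispersion_bin))
        for r in recs:
            occupied.add((r.reference_id, r.ref_start // dispersion_bin))
        dispersion = len(occupied) / total_bins if total_bins else 0.0
        # next-best alignment references for this gene's reads
        alt: Counter[str] = Counter()
        iso = set(g.isoform_ids)
        for r in recs:
            others = [a for a in grouped_all.get(r.read_id, [])
                      if (a.reference_id, a.ref_start) != (r.reference_id, r.ref_start)]
            if others:
                second = max(others, key=lambda a: a.nscore)
                alt[second.reference_id] += 1
        alt_str = ";".join(f"{t}:{c}" for t, c in alt.most_common(3))
        rows.append({
            "gene": g.gene_symbol,
            "mean_sms_rpkm": float(sms_mean[g.gene_symbol]),
            "mean_as_rpkm": float(as_mean[g.gene_symbol]),
            "rpkm_difference": float(sms_mean[g.gene_symbol] - as_mean[g.gene_symbol]),
            "n_sms_reads": n_reads,
            "long_read_fraction": long_fraction,
            "dispersion": dispersion,
            "next_best_references": alt_str,
        })
    df = pd.DataFrame(rows, columns=[
        "gene", "mean_sms_rpkm", "mean_as_rpkm", "rpkm_difference",
        "n_sms_reads", "long_read_fraction", "dispersion", "next_best_references",
    ])
    if df.empty:
        return df
    df = df[df["long_read_fraction"] >= long_read_fraction_min]
    df = df.sort_values(["rpkm_difference", "gene"], ascending=[False, True])
    return df.head(top_n).reset_index(drop=True)
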