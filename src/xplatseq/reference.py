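"""Transcriptome reference handling.

The analyses in this package operate on transcript sequences (not genomic
coordinates): a reference is a set of transcript records plus a
transcript-to-gene mapping that downstream quantification aggregates over,
in the style of the UCSC knownGene / kgXref tables.  Contaminant references
(homopolymer oligomers, optional user-supplied mitochondrial/rRNA/adapter
sets) live alongside the transcriptome and are distinguished by a reserved
identifier prefix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Reference-name prefix identifying contaminant records in merged references.
CONTAMINANT_PREFIX = "CONTAM_"

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class TranscriptRecord:
    """A single reference transcript: identifier plus its nucleotide sequence."""

    transcript_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"transcript {self.transcript_id!r} has empty sequence")
        if not _VALID_BASES.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - _VALID_BASES)
            raise ValueError(
                f"transcript {self.transcript_id!r} contains non-ACGT characters: {bad}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene symbol with the ordered set of its isoform transcript ids."""

    gene_symbol: str
    isoform_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.isoform_ids) < 1:
            raise ValueError(f"gene {self.gene_symbol!r} has no isoforms")
        if len(set(self.isoform_ids)) != len(self.isoform_ids):
            raise ValueError(f"gene {self.gene_symbol!r} lists duplicate isoforms")


@dataclass
class ContaminantSet:
    """Contaminant reference records with one category label per record.

    Categories follow the conventional contaminant classes filtered out of
    RNA-seq data before quantification: mitochondrial DNA, ribosomal RNA,
    adapter sequence, and homopolymer oligomers.
    """

    records: list[TranscriptRecord] = field(default_factory=list)
    categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) != len(self.categories):
            raise ValueError("records and categories must have equal length")

    def ids(self) -> list[str]:
        return [r.transcript_id for r in self.records]


def load_fasta(path: str | Path) -> dict[str, TranscriptRecord]:
    """Read a multi-record FASTA into an ordered ``{id: TranscriptRecord}`` map.

    Raises ``ValueError`` on duplicate identifiers or empty sequences.
    """
    reference: dict[str, TranscriptRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in reference:
            raise ValueError(f"duplicate transcript id {rec.id!r} in {path}")
        reference[rec.id] = TranscriptRecord(rec.id, str(rec.seq).upper())
    return reference


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write transcript records to FASTA (unwrapped lines)."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.transcript_id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta-2line")


def _read_gene_map(path: str | Path) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"gene map {path}: expected 2 tab-separated columns, got {len(parts)}"
                )
            rows.append((parts[0], parts[1]))
    return rows


def load_reference(
    transcriptome_fasta: str | Path,
    gene_map_tsv: str | Path | None,
) -> tuple[dict[str, TranscriptRecord], list[GeneModel]]:
    """Load a transcriptome FASTA plus transcript→gene-symbol map.

    Parameters
    ----------
    transcriptome_fasta:
        Multi-record FASTA of transcript sequences.
    gene_map_tsv:
        Two-column tab-separated file (transcript_id, gene_symbol); lines
        starting with ``#`` are ignored.  ``None`` means no mapping at all.

    Returns
    -------
    (reference, genes):
        The validated ``{transcript_id: TranscriptRecord}`` map and the gene
        models, ordered by gene symbol.  Transcripts absent from the map are
        retained as singleton genes named after their transcript id (and
        logged), so that every alignment stays attributable to a gene.

    Map rows referencing a transcript missing from the FASTA are dropped
    with a warning.
    """
    reference = load_fasta(transcriptome_fasta)

    rows = _read_gene_map(gene_map_tsv) if gene_map_tsv is not None else []
    by_gene: dict[str, list[str]] = {}
    mapped: set[str] = set()
    for tid, symbol in rows:
        if tid not in reference:
            logger.warning("gene map row for unknown transcript %r dropped", tid)
            continue
        if tid in mapped:
            logger.warning("transcript %r mapped more than once; first mapping kept", tid)
            continue
        mapped.add(tid)
        by_gene.setdefault(symbol, []).append(tid)

    for tid in reference:
        if tid not in mapped:
            logger.warning(
                "transcript %r missing from gene map; kept as singleton gene", tid
            )
            by_gene.setdefault(tid, []).append(tid)

    genes = [
        GeneModel(symbol, tuple(tids)) for symbol, tids in sorted(by_gene.items())
    ]
    return reference, genes


def mean_isoform_length(
    gene: GeneModel, reference: Mapping[str, TranscriptRecord]
) -> float:
    """Arithmetic mean of the gene's isoform lengths, in bp."""
    lengths = []
    for tid in gene.isoform_ids:
        if tid not in reference:
            raise KeyError(f"isoform {tid!r} of gene {gene.gene_symbol!r} not in reference")
        lengths.append(reference[tid].length)
    return sum(lengths) / len(lengths)


def build_contaminants(
    homopolymer_length: int = 100,
    extra_fastas: Mapping[str, str | Path] | None = None,
) -> ContaminantSet:
    """Build the contaminant reference set.

    Always contains the four homopolymer oligomer records (poly-A/-C/-G/-T)
    of ``homopolymer_length`` bp; ``extra_fastas`` maps a category label
    (e.g. ``"rRNA"``, ``"mitochondrial"``, ``"adapter"``) to a FASTA whose
    records are added under that label.  All contaminant ids carry the
    ``CONTAM_`` prefix so merged references can be partitioned by name.
    """
    if homopolymer_length < 1:
        raise ValueError("homopolymer_length must be >= 1")
    records: list[TranscriptRecord] = []
    categories: list[str] = []
    for base in "ACGT":
        records.append(
            TranscriptRecord(f"{CONTAMINANT_PREFIX}poly{base}", base * homopolymer_length)
        )
        categories.append("homopolymer")
    if extra_fastas:
        for category, path in extra_fastas.items():
            for rec in load_fasta(path).values():
                tid = rec.transcript_id
                if not tid.startswith(CONTAMINANT_PREFIX):
                    tid = CONTAMINANT_PREFIX + tid
                records.append(TranscriptRecord(tid, rec.sequence))
                categories.append(category)
    ids = [r.transcript_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contaminant record ids")
    return ContaminantSet(records, categories)


def merge_references(
    reference: Mapping[str, TranscriptRecord], contaminants: ContaminantSet
) -> dict[str, TranscriptRecord]:
    """Combine transcriptome and contaminants into one alignment reference.

    Raises ``ValueError`` on any id collision between the two sets.
    """
    merged = dict(reference)
    for rec in contaminants.records:
        if rec.transcript_id in merged:
            raise ValueError(
                f"contaminant id {rec.transcript_id!r} collides with transcriptome"
            )
        merged[rec.transcript_id] = rec
    return merged


def is_contaminant_id(reference_id: str) -> bool:
    return reference_id.startswith(CONTAMINANT_PREFIX)


def gene_lengths(
    genes: Sequence[GeneModel],
    reference: Mapping[str, TranscriptRecord],
    statistic: str = "max",
) -> dict[str, int | float]:
    """Per-gene transcript length: ``max`` isoform length (default) or ``mean``."""
    out: dict[str, int | float] = {}
    for g in genes:
        ls = [reference[t].length for t in g.isoform_ids]
        out[g.gene_symbol] = max(ls) if statistic == "max" else sum(ls) / len(ls)
    return out
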