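"""Synthetic read-library generation for the AS/SMS platform comparison.

One abundance ground truth drives two simulated libraries:

* **AS** (amplification-based): fixed-length reads taken from ~300 bp
  size-selected fragments, with two amplification knobs — a selection bias
  that draws fragments with weight ``abundance**(1+beta)``, and PCR
  duplication that re-emits each fragment ``1 + K`` times with
  ``K ~ Poisson(lambda * abundance / max_abundance)``.  This is the simplest
  two-parameter model that reproduces both amplification phenomena of
  interest: over-representation of high-abundance transcripts, and
  abundance-linked duplicate reads sharing an exact start locus.
* **SMS** (single-molecule): variable-length reads (discretised triangular
  length distribution), no duplication, per-base "dark base" deletions —
  bases incorporated without detectable signal, which appear as random gaps
  relative to the reference — and an elevated contaminant fraction.

Every emitted read carries a :class:`TruthRecord` so downstream claims
(duplicate ratios, quartile bias, detection sensitivity, fusion recovery)
can be checked against the generative truth.  All coordinates are 0-based,
half-open; generation is fully deterministic given the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import (
    CONTAMINANT_PREFIX,
    GeneModel,
    TranscriptRecord,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Default contaminant read fractions per technology (free parameters of the
# generator; defaults chosen to mirror the median contaminant loads seen in
# single-molecule vs amplified libraries: ~22% vs ~4%).
SMS_CONTAMINANT_FRACTION = 0.22
AS_CONTAMINANT_FRACTION = 0.042

#: Default PCR duplication intensity.  Calibrated once (see docs/methods.md)
#: so that under the package's standard comparison conditions (100-gene
#: single-isoform toy transcriptome, lognormal sigma 0.5, 50,000 reads per
#: technology) the AS:SMS per-transcript duplicate median ratio is ~3.
DEFAULT_DUPLICATION_RATE = 1.5


@dataclass(frozen=True)
class AbundanceProfile:
    """Relative molar abundances over a set of transcripts (sum to 1)."""

    ids: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.ids) != w.size:
            raise ValueError("ids and weights differ in length")
        if not np.all(w > 0):
            raise ValueError("all abundance weights must be > 0")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("abundance weights must sum to 1")
        object.__setattr__(self, "weights", w)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.ids, self.weights))

    def weight(self, transcript_id: str) -> float:
        return self.as_dict()[transcript_id]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated library.

    Probabilities are per base or per read as noted; lengths in bp.
    """

    n_reads: int = 10000
    as_read_length: int = 36
    sms_length_range: tuple[int, int] = (25, 64)
    sms_length_mode: int = 33
    bias_exponent: float = 0.5          # beta: AS selection weight ~ w**(1+beta)
    duplication_rate: float = DEFAULT_DUPLICATION_RATE  # lambda of the PCR copy model
    dark_base_rate: float = 0.05        # per-base deletion probability (SMS)
    contaminant_fraction: float = 0.0   # per-read probability of a contaminant read
    size_selection_window: tuple[int, int] = (280, 320)
    error_rate: float = 0.005           # per-base substitution probability
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dark_base_rate", "contaminant_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.bias_exponent < 0 or self.duplication_rate < 0:
            raise ValueError("bias_exponent and duplication_rate must be >= 0")
        lo, hi = self.sms_length_range
        if not (1 <= lo <= hi):
            raise ValueError("sms_length_range must be a non-empty positive range")
        if not (lo <= self.sms_length_mode <= hi):
            raise ValueError("sms_length_mode must lie within sms_length_range")
        lo, hi = self.size_selection_window
        if not (1 <= lo <= hi):
            raise ValueError("size_selection_window must be a non-empty positive range")


def default_as_config(n_reads: int, seed: int, **overrides) -> SimConfig:
    """AS library config with the technology's default contaminant load."""
    return SimConfig(
        n_reads=n_reads, seed=seed,
        contaminant_fraction=overrides.pop("contaminant_fraction", AS_CONTAMINANT_FRACTION),
        **overrides,
    )


def default_sms_config(n_reads: int, seed: int, **overrides) -> SimConfig:
    """SMS library config with the technology's default contaminant load."""
    return SimConfig(
        n_reads=n_reads, seed=seed,
        contaminant_fraction=overrides.pop("contaminant_fraction", SMS_CONTAMINANT_FRACTION),
        **overrides,
    )


@dataclass(frozen=True)
class TruthRecord:
    """Generative provenance of one simulated read."""

    read_id: str
    origin: str                 # transcript id, contaminant id, or fusion id
    origin_start: int           # 0-based offset on the origin sequence
    extent: int                 # reference bases consumed (pre dark-base deletion)
    emitted_copies: int = 1     # PCR lineage size (1 for SMS / contaminants)
    is_contaminant: bool = False
    is_fusion_spanning: bool = False


@dataclass(frozen=True)
class ReadRecord:
    """One simulated read ready for FASTQ output."""

    read_id: str
    sequence: str


@dataclass(frozen=True)
class FusionSpec:
    """A chimeric transcript joining a 5' prefix to a 3' suffix.

    The junction sits between fused coordinates ``five_prime_break - 1`` and
    ``five_prime_break``; the fused sequence is
    ``five'[0:five_prime_break] + three'[three_prime_break:]``.
    """

    five_prime_id: str
    five_prime_break: int
    three_prime_id: str
    three_prime_break: int
    fusion_abundance: float

    def __post_init__(self) -> None:
        if self.fusion_abundance <= 0:
            raise ValueError("fusion_abundance must be > 0")


# ---------------------------------------------------------------------------
# toy transcriptome and abundance ground truth
# ---------------------------------------------------------------------------

def make_toy_transcriptome(
    n_genes: int,
    seed: int,
    length_range: tuple[int, int] = (500, 2500),
    max_isoforms: int = 2,
) -> tuple[dict[str, TranscriptRecord], list[GeneModel]]:
    """Generate a random toy transcriptome with 1..max_isoforms per gene.

    Isoform sequences are independent uniform-random nucleotide strings
    (no shared exon structure), so multi-mapping between isoforms is rare;
    see docs/methods.md for what this does and does not emulate.
    """
    rng = np.random.default_rng(seed)
    reference: dict[str, TranscriptRecord] = {}
    genes: list[GeneModel] = []
    t = 0
    for g in range(n_genes):
        n_iso = int(rng.integers(1, max_isoforms + 1))
        tids = []
        for _ in range(n_iso):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            seq = bytes(_BASES[rng.integers(0, 4, size=length)]).decode()
            tid = f"T{t:06d}"
            reference[tid] = TranscriptRecord(tid, seq)
            tids.append(tid)
            t += 1
        genes.append(GeneModel(f"G{g:05d}", tuple(tids)))
    return reference, genes


def gene_map_rows(genes: Sequence[GeneModel]) -> list[tuple[str, str]]:
    """Flatten gene models into (transcript_id, gene_symbol) map rows."""
    return [(tid, g.gene_symbol) for g in genes for tid in g.isoform_ids]


def write_gene_map(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#transcript_id\tgene_symbol\n")
        for tid, symbol in gene_map_rows(genes):
            fh.write(f"{tid}\t{symbol}\n")


def sample_abundances(
    transcript_ids: Sequence[str] | int,
    lognormal_sigma: float,
    seed: int,
) -> AbundanceProfile:
    """Draw a heavy-tailed (log-normal) abundance profile.

    ``transcript_ids`` may be an explicit id sequence or an integer count
    (generic ids are then generated).  ``lognormal_sigma=0`` yields a flat
    profile; larger values concentrate abundance on few transcripts, as in
    real transcriptomes where a handful of genes dominate the mRNA pool.
    """
    if isinstance(transcript_ids, int):
        if transcript_ids < 1:
            raise ValueError("need at least one transcript")
        ids: tuple[str, ...] = tuple(f"T{i:06d}" for i in range(transcript_ids))
    else:
        ids = tuple(transcript_ids)
        if len(ids) < 1:
            raise ValueError("need at least one transcript")
    if lognormal_sigma < 0:
        raise ValueError("lognormal_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    w = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=len(ids))
    return AbundanceProfile(ids, w / w.sum())


# ---------------------------------------------------------------------------
# fusion spiking
# ---------------------------------------------------------------------------

def fusion_id(spec: FusionSpec) -> str:
    return f"FUSION_{spec.five_prime_id}_{spec.three_prime_id}"


def spike_fusion(
    reference: Mapping[str, TranscriptRecord], spec: FusionSpec
) -> tuple[dict[str, TranscriptRecord], TranscriptRecord, int]:
    """Add the chimeric transcript defined by ``spec`` to the reference.

    Returns the augmented reference, the fusion record, and the junction
    offset on the fused sequence (equal to ``five_prime_break``).  Breaks at
    0 or at the partner's full length are degenerate and rejected.
    """
    try:
        five = reference[spec.five_prime_id]
        three = reference[spec.three_prime_id]
    except KeyError as e:
        raise KeyError(f"fusion partner {e.args[0]!r} not in reference") from e
    if not (0 < spec.five_prime_break < five.length):
        raise ValueError("five_prime_break must be strictly inside the 5' partner")
    if not (0 < spec.three_prime_break < three.length):
        raise ValueError("three_prime_break must be strictly inside the 3' partner")
    seq = five.sequence[: spec.five_prime_break] + three.sequence[spec.three_prime_break :]
    rec = TranscriptRecord(fusion_id(spec), seq)
    if rec.transcript_id in reference:
        raise ValueError(f"fusion id {rec.transcript_id!r} already in reference")
    augmented = dict(reference)
    augmented[rec.transcript_id] = rec
    return augmented, rec, spec.five_prime_break


def choose_clean_fusion(
    reference: Mapping[str, TranscriptRecord],
    five_prime_id: str,
    three_prime_id: str,
    five_prime_break: int,
    three_prime_break: int,
    fusion_abundance: float,
) -> FusionSpec:
    """Nudge breakpoints so the junction carries no breakpoint homology.

    Real fusion breakpoints are coordinate-ambiguous when the sequence
    flanking the junction resembles the partner's continuation: gapped
    anchors then extend through the junction and the call smears over the
    homologous stretch, for this package exactly as for any split-read
    caller.  For a benchmark fixture we therefore shift the 5' break
    forward (at most a few hundred bp) until no profitable anchor-scoring
    (+1 match / -2 error) extension across the junction exists in either
    direction, making the truth coordinates unique.
    """
    five = reference[five_prime_id].sequence
    three = reference[three_prime_id].sequence
    b5, b3 = five_prime_break, three_prime_break

    def _extension_score(read_side: str, ref_side: str) -> int:
        # best gapped (+1 match / -2 error) alignment score of one flank
        # continuing into the partner's flank, contiguous from the junction
        # (both sequences anchored at offset 0), free far ends
        m, n = len(read_side), len(ref_side)
        if m == 0 or n == 0:
            return 0
        prev = [-2 * j for j in range(n + 1)]
        best = 0
        for i in range(1, m + 1):
            cur = [-2 * i] + [0] * n
            for j in range(1, n + 1):
                d = prev[j - 1] + (1 if read_side[i - 1] == ref_side[j - 1] else -2)
                cur[j] = max(d, prev[j] - 2, cur[j - 1] - 2)
                if cur[j] > best:
                    best = cur[j]
            prev = cur
        return best

    w = 24
    for shift in range(256):
        cand = b5 + shift
        if cand >= len(five) - w:
            break
        if five[cand] == three[b3] or five[cand - 1] == three[b3 - 1]:
            continue
        # prefix anchors on the 5' partner: the read continues with 3'
        # content; reject if that content aligns profitably past the break
        if _extension_score(three[b3 : b3 + w], five[cand : cand + w]) > 0:
            continue
        # suffix anchors on the 3' partner: reject if 5' upstream content
        # aligns profitably backwards past the break
        if _extension_score(five[cand - w : cand][::-1], three[b3 - w : b3][::-1]) > 0:
            continue
        return FusionSpec(five_prime_id, cand, three_prime_id, b3, fusion_abundance)
    raise ValueError("could not find a homology-free breakpoint near the request")


def with_fusion(
    profile: AbundanceProfile, fusion_transcript_id: str, fusion_abundance: float
) -> AbundanceProfile:
    """Return a profile extended with the fusion transcript and renormalised."""
    ids = profile.ids + (fusion_transcript_id,)
    w = np.append(profile.weights, fusion_abundance)
    return AbundanceProfile(ids, w / w.sum())


# ---------------------------------------------------------------------------
# library simulators
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _apply_substitutions(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0 or codes.size == 0:
        return codes
    hits = np.nonzero(rng.random(codes.size) < rate)[0]
    if hits.size == 0:
        return codes
    codes = codes.copy()
    for i in hits:
        choices = _BASES[_BASES != codes[i]]
        codes[i] = choices[rng.integers(0, 3)]
    return codes


def _spanning(start: int, extent: int, junction: int | None) -> bool:
    # overlap of >= 1 base on both sides of the junction coordinate
    return junction is not None and start < junction and start + extent > junction


def _draw_sms_length(cfg: SimConfig, rng: np.random.Generator) -> int:
    lo, hi = cfg.sms_length_range
    if lo == hi:
        return lo
    x = rng.triangular(lo, cfg.sms_length_mode, hi + 1)
    return int(min(hi, max(lo, int(x))))


def simulate_sms_library(
    reference: Mapping[str, TranscriptRecord],
    profile: AbundanceProfile,
    cfg: SimConfig,
    junctions: Mapping[str, int] | None = None,
) -> tuple[list[ReadRecord], list[TruthRecord]]:
    """Simulate a single-molecule library.

    Per non-contaminant read: transcript drawn proportional to abundance,
    start uniform, target length from the truncated triangular distribution,
    then per-base dark-base deletions at ``dark_base_rate`` followed by
    substitution errors at ``error_rate``.  Contaminant reads (probability
    ``contaminant_fraction``) are homopolymer fragments.  No PCR duplication:
    every read has ``emitted_copies == 1``.

    ``junctions`` maps spiked fusion transcript ids to their junction offset
    and controls the ``is_fusion_spanning`` truth flag.
    """
    rng = np.random.default_rng(cfg.seed)
    min_len = cfg.sms_length_range[0]
    ids = [t for t in profile.ids if reference[t].length >= min_len]
    if len(ids) < len(profile.ids):
        dropped = set(profile.ids) - set(ids)
        logger.warning("%d transcripts shorter than %d bp excluded from SMS sampling: %s",
                       len(dropped), min_len, sorted(dropped))
    if not ids:
        raise ValueError("no transcript long enough for the SMS length range")
    wmap = profile.as_dict()
    weights = np.array([wmap[t] for t in ids])
    weights = weights / weights.sum()
    codes = {t: _encode(reference[t].sequence) for t in ids}
    junctions = junctions or {}

    reads: list[ReadRecord] = []
    truth: list[TruthRecord] = []
    for i in range(cfg.n_reads):
        rid = f"SMS_{i:07d}"
        if rng.random() < cfg.contaminant_fraction:
            base = "ACGT"[rng.integers(0, 4)]
            length = _draw_sms_length(cfg, rng)
            reads.append(ReadRecord(rid, base * length))
            truth.append(TruthRecord(rid, f"{CONTAMINANT_PREFIX}poly{base}", 0,
                                     length, 1, is_contaminant=True))
            continue
        t = ids[rng.choice(len(ids), p=weights)]
        L = reference[t].length
        target = min(_draw_sms_length(cfg, rng), L)
        start = int(rng.integers(0, L - target + 1))
        frag = codes[t][start : start + target]
        if cfg.dark_base_rate > 0:
            frag = frag[rng.random(target) >= cfg.dark_base_rate]
        frag = _apply_substitutions(frag, cfg.error_rate, rng)
        reads.append(ReadRecord(rid, bytes(frag).decode()))
        truth.append(TruthRecord(
            rid, t, start, target, 1,
            is_fusion_spanning=_spanning(start, target, junctions.get(t)),
        ))
    return reads, truth


def simulate_as_library(
    reference: Mapping[str, TranscriptRecord],
    profile: AbundanceProfile,
    cfg: SimConfig,
    junctions: Mapping[str, int] | None = None,
) -> tuple[list[ReadRecord], list[TruthRecord]]:
    """Simulate an amplification-based library.

    Transcripts shorter than the size-selection window's lower bound are
    excluded (the ~300 bp gel excision step).  Fragments are drawn with
    selection weight ``abundance**(1 + bias_exponent)``; each fragment emits
    ``1 + K`` identical-coordinate copies with
    ``K ~ Poisson(duplication_rate * abundance / max_abundance)``, then one
    fixed-length read is taken from the fragment's 5' end and substitution
    errors are applied independently per copy.
    """
    rng = np.random.default_rng(cfg.seed)
    sel_lo, sel_hi = cfg.size_selection_window
    ids = []
    for t in profile.ids:
        if reference[t].length >= sel_lo:
            ids.append(t)
        else:
            logger.warning("transcript %s (%d bp) below size selection window; no AS reads",
                           t, reference[t].length)
    if not ids:
        raise ValueError("no transcript survives the size-selection window")
    wmap = profile.as_dict()
    w = np.array([wmap[t] for t in ids])
    sel = w ** (1.0 + cfg.bias_exponent)
    sel = sel / sel.sum()
    max_w = w.max()
    codes = {t: _encode(reference[t].sequence) for t in ids}
    junctions = junctions or {}

    reads: list[ReadRecord] = []
    truth: list[TruthRecord] = []
    i = 0
    while i < cfg.n_reads:
        rid_base = i
        if rng.random() < cfg.contaminant_fraction:
            base = "ACGT"[rng.integers(0, 4)]
            rid = f"AS_{i:07d}"
            reads.append(ReadRecord(rid, base * cfg.as_read_length))
            truth.append(TruthRecord(rid, f"{CONTAMINANT_PREFIX}poly{base}", 0,
                                     cfg.as_read_length, 1, is_contaminant=True))
            i += 1
            continue
        k = ids[rng.choice(len(ids), p=sel)]
        L = reference[k].length
        flen = int(rng.integers(sel_lo, min(sel_hi, L) + 1))
        fstart = int(rng.integers(0, L - flen + 1))
        lam = cfg.duplication_rate * wmap[k] / max_w
        copies = 1 + (int(rng.poisson(lam)) if lam > 0 else 0)
        copies = min(copies, cfg.n_reads - i)
        span = _spanning(fstart, cfg.as_read_length, junctions.get(k))
        for _ in range(copies):
            rid = f"AS_{i:07d}"
            frag = codes[k][fstart : fstart + cfg.as_read_length]
            frag = _apply_substitutions(frag, cfg.error_rate, rng)
            reads.append(ReadRecord(rid, bytes(frag).decode()))
            truth.append(TruthRecord(rid, k, fstart, cfg.as_read_length, copies,
                                     is_fusion_spanning=span))
            i += 1
    return reads, truth


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    """Write reads as FASTQ with constant 'I' qualities (qualities unused)."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    return [ReadRecord(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")]


_TRUTH_COLUMNS = ["read_id", "origin", "origin_start", "extent",
                  "emitted_copies", "is_contaminant", "is_fusion_spanning"]


def write_truth(truth: Iterable[TruthRecord], path: str | Path) -> None:
    df = pd.DataFrame([asdict(t) for t in truth], columns=_TRUTH_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [TruthRecord(row.read_id, row.origin, int(row.origin_start),
                        int(row.extent), int(row.emitted_copies),
                        bool(row.is_contaminant), bool(row.is_fusion_spanning))
            for row in df.itertuples(index=False)]
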