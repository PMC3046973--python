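"""End-to-end pipeline: simulate -> align -> quantify -> dedup -> bias -> fusions.

One :class:`RunConfig` drives a reproducible paired-technology run on a toy
transcriptome.  A single global seed fans out to per-stage child seeds by
stage-name hashing, so any stage can be re-run in isolation; rerunning a
config reproduces byte-identical outputs.

The spiked fusion transcript, when enabled, is added to the *simulation*
reference only — the aligner never sees it, so junction-spanning reads fail
to map and must be recovered de novo by the fusion-discovery stage, exactly
as for a real novel fusion.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import align as al
from . import bias, duplicates, fusion, quantify
from . import simulate as sim
from .reference import GeneModel, TranscriptRecord, build_contaminants, gene_lengths, merge_references

logger = logging.getLogger(__name__)


def child_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one (stable, < 2**31)."""
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of one pipeline run."""

    seed: int = 0
    # toy transcriptome
    n_genes: int = 100
    max_isoforms: int = 1
    length_min: int = 500
    length_max: int = 2500
    lognormal_sigma: float = 0.5
    sample_noise_sigma: float = 0.25   # per-sample abundance jitter
    n_samples: int = 1
    homopolymer_length: int = 100
    # library simulation (per technology)
    n_reads: int = 50000
    as_read_length: int = 36
    sms_length_min: int = 25
    sms_length_max: int = 64
    sms_length_mode: int = 33
    bias_exponent: float = 0.5
    duplication_rate: float = sim.DEFAULT_DUPLICATION_RATE
    dark_base_rate: float = 0.05
    error_rate: float = 0.005
    as_contaminant_fraction: float = sim.AS_CONTAMINANT_FRACTION
    sms_contaminant_fraction: float = sim.SMS_CONTAMINANT_FRACTION
    size_selection_min: int = 280
    size_selection_max: int = 320
    # fusion spike
    spike_fusion: bool = False
    fusion_abundance: float = 0.05     # relative weight of the fused transcript
    # analysis parameters
    noise_threshold: float = 0.3
    top_k: int = 500
    recurrence_fraction: float = 0.4
    min_anchor: int = 18
    min_overhang: int = 10
    min_identity: float = 0.9
    flank: int = 100
    min_side_overlap: int = 8
    run_fusions: bool = True
    outdir: str | None = None

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)  # where outputs land must not change what they say
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "RunConfig":
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        unknown = set(mapping) - set(fields)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)  # type: ignore[arg-type]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` config file (or flat YAML)."""
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError("config file must be a flat key-value mapping")
        return cls.from_mapping(data)


@dataclass
class SampleResult:
    """Everything computed for one paired AS/SMS sample."""

    sample_id: str
    as_table: quantify.ExpressionTable
    sms_table: quantify.ExpressionTable
    as_best: list[al.AlignmentRecord]
    sms_best: list[al.AlignmentRecord]
    as_stats: dict
    sms_stats: dict
    dup_summary: dict
    quartiles: pd.Series
    quartile_summary: bias.QuartileSummary
    qq_divergence: float
    qq_pairs: pd.DataFrame
    sweep: bias.DetectionSweepResult
    junctions: list[fusion.FusionJunction]
    as_truth: list[sim.TruthRecord]
    sms_truth: list[sim.TruthRecord]
    sms_nonmapping_ids: set[str] = field(default_factory=set)


@dataclass
class PipelineResult:
    config: RunConfig
    reference: dict[str, TranscriptRecord]
    genes: list[GeneModel]
    samples: list[SampleResult]
    recurrence: bias.RecurrenceResult | None
    fusion_spec: sim.FusionSpec | None
    junction_offset: int | None


def _as_simconfig(cfg: RunConfig, seed: int, tech: str) -> sim.SimConfig:
    common = dict(
        n_reads=cfg.n_reads,
        as_read_length=cfg.as_read_length,
        sms_length_range=(cfg.sms_length_min, cfg.sms_length_max),
        sms_length_mode=cfg.sms_length_mode,
        bias_exponent=cfg.bias_exponent,
        duplication_rate=cfg.duplication_rate,
        dark_base_rate=cfg.dark_base_rate,
        error_rate=cfg.error_rate,
        size_selection_window=(cfg.size_selection_min, cfg.size_selection_max),
        seed=seed,
    )
    frac = cfg.as_contaminant_fraction if tech == "AS" else cfg.sms_contaminant_fraction
    return sim.SimConfig(contaminant_fraction=frac, **common)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full paired-technology pipeline for ``cfg``."""
    reference, genes = sim.make_toy_transcriptome(
        cfg.n_genes, child_seed(cfg.seed, "transcriptome"),
        (cfg.length_min, cfg.length_max), cfg.max_isoforms,
    )
    contaminants = build_contaminants(cfg.homopolymer_length)
    align_reference = merge_references(reference, contaminants)
    index = al.ReferenceIndex(align_reference)

    base_profile = sim.sample_abundances(
        list(reference), cfg.lognormal_sigma, child_seed(cfg.seed, "abundance")
    )

    fusion_spec: sim.FusionSpec | None = None
    junction_offset: int | None = None
    sim_reference = dict(reference)
    junctions_map: dict[str, int] = {}
    if cfg.spike_fusion:
        tids = sorted(reference)
        five, three = tids[0], tids[1]
        fusion_spec = sim.choose_clean_fusion(
            reference, five, three,
            reference[five].length // 2, reference[three].length // 2,
            cfg.fusion_abundance,
        )
        sim_reference, fusion_rec, junction_offset = sim.spike_fusion(reference, fusion_spec)
        junctions_map[fusion_rec.transcript_id] = junction_offset

    samples: list[SampleResult] = []
    for s in range(cfg.n_samples):
        sample_id = f"sample{s + 1}"
        profile = base_profile
        if cfg.n_samples > 1 and cfg.sample_noise_sigma > 0:
            rng = np.random.default_rng(child_seed(cfg.seed, f"sample-noise:{s}"))
            w = base_profile.weights * rng.lognormal(0.0, cfg.sample_noise_sigma,
                                                     base_profile.weights.size)
            profile = sim.AbundanceProfile(base_profile.ids, w / w.sum())
        if fusion_spec is not None:
            profile = sim.with_fusion(
                profile, sim.fusion_id(fusion_spec), cfg.fusion_abundance
            )
        samples.append(_run_sample(
            cfg, sample_id, s, sim_reference, reference, genes, index,
            profile, junctions_map,
        ))

    recurrence = None
    if cfg.n_samples >= 2:
        recurrence = bias.recurrent_overrepresentation(
            [(sr.as_table, sr.sms_table) for sr in samples],
            cfg.top_k, cfg.recurrence_fraction,
        )

    result = PipelineResult(cfg, reference, genes, samples, recurrence,
                            fusion_spec, junction_offset)
    if cfg.outdir:
        write_outputs(result, Path(cfg.outdir))
    return result


def _run_sample(
    cfg: RunConfig,
    sample_id: str,
    s: int,
    sim_reference: Mapping[str, TranscriptRecord],
    reference: Mapping[str, TranscriptRecord],
    genes: Sequence[GeneModel],
    index: al.ReferenceIndex,
    profile: sim.AbundanceProfile,
    junctions_map: Mapping[str, int],
) -> SampleResult:
    as_cfg = _as_simconfig(cfg, child_seed(cfg.seed, f"as-sim:{s}"), "AS")
    sms_cfg = _as_simconfig(cfg, child_seed(cfg.seed, f"sms-sim:{s}"), "SMS")
    as_reads, as_truth = sim.simulate_as_library(sim_reference, profile, as_cfg, junctions_map)
    sms_reads, sms_truth = sim.simulate_sms_library(sim_reference, profile, sms_cfg, junctions_map)

    as_aln, as_log = al.align_reads(as_reads, index, al.bowtie_like())
    sms_aln, sms_log = al.align_reads(sms_reads, index, al.indexdp_like())

    as_best_all = al.single_best(as_aln, child_seed(cfg.seed, f"as-best:{s}"))
    sms_best_all = al.single_best(sms_aln, child_seed(cfg.seed, f"sms-best:{s}"))
    as_best, _ = al.partition_by_contaminant(as_best_all)
    sms_best, _ = al.partition_by_contaminant(sms_best_all)

    as_table = quantify.gene_tables(
        quantify.count_per_transcript(as_best), as_best, genes, reference,
        usable_total=len(as_best), sample_id=sample_id, technology="AS",
    )
    sms_table = quantify.gene_tables(
        quantify.count_per_transcript(sms_best), sms_best, genes, reference,
        usable_total=len(sms_best), sample_id=sample_id, technology="SMS",
    )

    dup_summary = duplicates.duplication_summary(as_best, sms_best)

    universe = bias.gene_universe(as_table, sms_table)
    quartiles = bias.quartile_partition(as_table, universe)
    qsummary = bias.quartile_read_fractions(as_table, sms_table, quartiles)
    qq_pairs, qq_div = bias.qq_compare(as_table, sms_table, universe)
    sweep = bias.detection_sweep(
        as_table, sms_table, gene_lengths(genes, reference)
    )

    nonmapping = fusion.collect_nonmapping(sms_reads, sms_aln, sms_log)
    junctions: list[fusion.FusionJunction] = []
    if cfg.run_fusions:
        junctions = fusion.discover_fusions(
            sms_reads, sms_aln, sms_log, index,
            cfg.min_anchor, 0.15, 0, cfg.min_overhang, cfg.min_identity,
            cfg.flank, cfg.min_side_overlap,
        )

    return SampleResult(
        sample_id, as_table, sms_table, as_best, sms_best,
        al.compute_sample_stats(as_reads, as_aln, as_log),
        al.compute_sample_stats(sms_reads, sms_aln, sms_log),
        dup_summary, quartiles, qsummary, qq_div, qq_pairs, sweep,
        junctions, as_truth, sms_truth,
        {r.read_id for r in nonmapping},
    )


def fusion_recovery(result: PipelineResult, sample: int = 0) -> dict:
    """Score fusion discovery against the generative truth.

    The recoverable denominator is the set of truth junction-spanning SMS
    reads with at least ``min_anchor`` reference bases on one side of the
    junction and at least ``min_side_overlap`` on the other, restricted to
    reads in the non-mapping set: a read whose minor side is short enough
    that its full-length alignment to the major partner still passes the
    NScore filter is mapped by the standard pass and, by construction,
    can never reach a non-mapping-read fusion pipeline.
    """
    cfg = result.config
    sr = result.samples[sample]
    if result.fusion_spec is None or result.junction_offset is None:
        return {"n_junctions": len(sr.junctions), "recovery": float("nan"),
                "n_recoverable": 0, "supporting": 0, "rescued": 0}
    j = result.junction_offset
    recoverable: set[str] = set()
    for t in sr.sms_truth:
        if not t.is_fusion_spanning:
            continue
        if t.read_id not in sr.sms_nonmapping_ids:
            continue
        side5 = j - t.origin_start
        side3 = t.origin_start + t.extent - j
        lo, hi = sorted((side5, side3))
        if hi >= cfg.min_anchor and lo >= cfg.min_side_overlap:
            recoverable.add(t.read_id)
    found: set[str] = set()
    for junc in sr.junctions:
        found |= junc.supporting_read_ids | junc.rescued_read_ids
    n_sup = sum(junc.supporting_reads for junc in sr.junctions)
    n_res = sum(junc.rescued_reads for junc in sr.junctions)
    recovery = (len(found & recoverable) / len(recoverable)) if recoverable else float("nan")
    return {
        "n_junctions": len(sr.junctions),
        "n_recoverable": len(recoverable),
        "supporting": n_sup,
        "rescued": n_res,
        "recovery": recovery,
    }


def pooled_platform_comparison(
    seed: int, n_runs: int = 3, n_reads: int = 50_000
) -> dict:
    """The standard multi-sample platform comparison.

    Runs ``n_runs`` independent paired simulations (fresh transcriptome and
    abundance profile each, emulating distinct biological samples), pools
    per-transcript duplicate counts across all samples for the AS:SMS
    median ratio — the statistic is taken over all transcripts observed in
    all samples — and averages the per-sample quartile fractions and q-q
    divergence.
    """
    as_vals: list[int] = []
    sms_vals: list[int] = []
    reports: list[dict] = []
    removed = {"AS": [], "SMS": []}
    for i in range(n_runs):
        result = run_pipeline(RunConfig(
            seed=child_seed(seed, f"comparison:{i}"), n_reads=n_reads,
            run_fusions=False,
        ))
        sr = result.samples[0]
        as_dup = duplicates.per_transcript_duplicates(sr.as_best, "locus")
        sms_dup = duplicates.per_transcript_duplicates(sr.sms_best, "locus")
        common = set(as_dup) & set(sms_dup)
        as_vals.extend(as_dup[t] for t in common)
        sms_vals.extend(sms_dup[t] for t in common)
        for tech in removed:
            removed[tech].append(sr.dup_summary["pct_reads_removed_locus"][tech])
        reports.append(compare_report(result))
    as_median = float(np.median(as_vals)) if as_vals else 0.0
    sms_median = float(np.median(sms_vals)) if sms_vals else 0.0

    def mean(key: str) -> float:
        return float(np.mean([r[key] for r in reports]))

    return {
        "n_runs": n_runs,
        "n_reads_per_technology": n_runs * n_reads,
        "duplicate_median_ratio": (as_median / sms_median if sms_median > 0
                                   else float("nan")),
        "as_q1_fraction": mean("as_q1_fraction"),
        "sms_q1_fraction": mean("sms_q1_fraction"),
        "as_q34_fraction": mean("as_q34_fraction"),
        "sms_q34_fraction": mean("sms_q34_fraction"),
        "qq_top_decile_divergence": mean("qq_top_decile_divergence"),
        "pct_as_reads_removed_locus": float(np.mean(removed["AS"])),
        "pct_sms_reads_removed_locus": float(np.mean(removed["SMS"])),
    }


def compare_report(result: PipelineResult, sample: int = 0) -> dict:
    """Single-document summary of the paired comparison."""
    sr = result.samples[sample]
    if sr.sms_table.usable_total == 0:
        raise ValueError("empty SMS run: no usable reads")
    if sr.as_table.usable_total == 0:
        raise ValueError("empty AS run: no usable reads")
    qs = sr.quartile_summary
    at = sr.sweep.at(result.config.noise_threshold)
    as_q1 = qs.fraction("AS", [1])
    sms_q1 = qs.fraction("SMS", [1])
    report = {
        "sample_id": sr.sample_id,
        "config_hash": result.config.config_hash(),
        "seed": result.config.seed,
        "as_usable_reads": sr.as_table.usable_total,
        "sms_usable_reads": sr.sms_table.usable_total,
        "quartile_fractions": {
            f"Q{q}": {"AS": qs.fraction("AS", [q]), "SMS": qs.fraction("SMS", [q])}
            for q in (1, 2, 3, 4)
        },
        "as_q1_fraction": as_q1,
        "sms_q1_fraction": sms_q1,
        "as_q34_fraction": qs.fraction("AS", [3, 4]),
        "sms_q34_fraction": qs.fraction("SMS", [3, 4]),
        "qq_top_decile_divergence": sr.qq_divergence,
        "sms_only_at_threshold": int(at["sms_only"]),
        "as_only_at_threshold": int(at["as_only"]),
        "noise_threshold": result.config.noise_threshold,
        "duplicate_median_ratio": sr.dup_summary["as_sms_median_ratio"],
        "recurrent_gene_count": (len(result.recurrence.recurrent)
                                 if result.recurrence else None),
        "n_fusion_junctions": len(sr.junctions),
        "quartile_divergence_flag": (
            "AS over-represents top quartile" if as_q1 - sms_q1 > 0.01
            else "no significant quartile divergence"
        ),
    }
    report.update({f"fusion_{k}": v for k, v in fusion_recovery(result, sample).items()})
    return report


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    """Write all canonical TSV/JSON artifacts for a run."""
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    (outdir / "config.json").write_text(
        json.dumps({**dataclasses.asdict(cfg), **stamp}, indent=2, sort_keys=True) + "\n"
    )
    for sr in result.samples:
        prefix = outdir / sr.sample_id
        prefix.mkdir(exist_ok=True)
        sr.as_table.to_tsv(prefix / "expression_AS.tsv")
        sr.sms_table.to_tsv(prefix / "expression_SMS.tsv")
        duplicates.summary_to_tsv(sr.dup_summary, prefix / "duplication_summary.tsv")
        qdf = sr.quartile_summary.table.copy()
        qdf.to_csv(prefix / "quartile_fractions.tsv", sep="\t", float_format="%.8g")
        sr.qq_pairs.to_csv(prefix / "qq_pairs.csv", index=False, float_format="%.8g")
        sr.sweep.table.to_csv(prefix / "detection_sweep.csv", index=False)
        fusion.junctions_to_tsv(sr.junctions, prefix / "fusions.tsv")
        stats = {"AS": sr.as_stats, "SMS": sr.sms_stats, **stamp}
        (prefix / "sample_stats.json").write_text(json.dumps(stats, indent=2) + "\n")
    report = compare_report(result)
    (outdir / "compare_report.json").write_text(json.dumps(report, indent=2) + "\n")
    if result.recurrence is not None:
        pd.DataFrame({"gene": sorted(result.recurrence.recurrent)}).to_csv(
            outdir / "recurrent_genes.tsv", sep="\t", index=False
        )
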