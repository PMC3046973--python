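# Methods

`xplatseq` simulates and analyses the systematic differences between two
RNA-seq acquisition regimes over one shared ground truth: an
**amplification-based** library (AS; PCR in library preparation and
cluster generation, fixed-length reads, ~300 bp size selection) and a
**single-molecule** library (SMS; amplification-free, variable-length
reads with "dark base" gaps and a higher contaminant load). Everything
downstream — alignment and filtering, gene quantification, duplicate
analysis, bias comparisons, fusion discovery — operates on transcript
sequences, not genomic coordinates.

## Generative model

One abundance profile `w` (relative molar abundances, summing to 1) drives
both libraries.

**Abundances.** `sample_abundances` draws log-normal weights
(`sigma` controls tail heaviness; `sigma = 0` is flat). Real transcriptomes
span many orders of magnitude; the standard comparison study below uses a
milder tail so that per-transcript statistics (in particular the duplicate
medians) are stable at desk-scale depth.

**SMS library.** Per read: transcript `t ~ w`, start uniform, target
length from a discretised triangular distribution on `[25, 64]` bp with
mode 33 (matching the observed range and the ~33 bp read-count-weighted
mean length of single-molecule data; the true length law is not published,
so a two-parameter triangular family is used). Each base is then deleted
independently with probability `dark_base_rate` (default 0.05) — the dark
bases incorporated without detectable fluorescence — and substituted with
probability `error_rate` (default 0.005). No duplication
(`emitted_copies = 1`). A fraction `contaminant_fraction` (default 0.22)
of reads are homopolymer fragments.

**AS library.** Transcripts shorter than the size-selection window's lower
bound (280 bp) are excluded — the gel-excision step. Fragments (280–320 bp,
start uniform) are drawn with selection weight `w**(1 + beta)`; each
emits `1 + K` identical-coordinate copies with
`K ~ Poisson(lambda * w / max(w))`, and one fixed-length 36 bp read is
taken from each copy's 5' end with independent substitution errors.
`beta` (default 0.5) and `lambda` (default 1.5) are the two amplification
knobs: `beta` produces the over-representation of abundant transcripts,
`lambda` the abundance-linked exact-duplicate reads. This is the simplest
model that reproduces both phenomena; it makes no attempt to model
sequence-composition (GC) bias, primer effects, or cluster-density
artefacts. Contaminant fraction defaults to 0.042.

Every read carries a truth record (origin, offset, reference extent,
lineage size, contaminant/fusion-spanning flags), so each downstream claim
is checkable against the generative truth. Generation is byte-deterministic
given the config seed.

**Spiked fusions.** `spike_fusion` appends the chimera
`five'[0:b5] + three'[b3:]` to the *simulation* reference only; the aligner
never sees it, so junction-spanning reads fail to map and must be
recovered de novo. `choose_clean_fusion` builds benchmark breakpoints with
no junction homology: it shifts the 5' break until no gapped `+1/-2`
extension across the junction scores positively in either direction.
Junctions embedded in homologous context are coordinate-ambiguous for any
split-read method; benchmark fixtures avoid them so truth coordinates are
unique.

## Alignment and filtering

One seed-and-extend aligner (exact k-mer seeds, k = 12, sampled every 4
positions; candidate windows merged per transcript; banded
dynamic-programming extension) with two presets:

* `indexdp_like` — gapped extension with unit per-base indel cost, keeps
  alignments with **NScore ≥ 4**, usable read-length window 25–64 bp.
  NScore is `(5·#match − 4·#error) / read_length`, where `#error` counts
  mismatched plus inserted plus deleted bases, one per base (the error
  composition is not published; per-base weighting is assumed). A perfect
  full-length match scores 5 regardless of length.
* `bowtie_like` — ungapped, at most 2 mismatches within the first 32 bases,
  first base trimmed, window 34–64 bp.

Both report at most 25 placements per read; per candidate window only the
best placement is reported, so heavily repetitive targets (homopolymers)
yield one alignment per merged window rather than an exhaustive placement
list. Reverse-complement alignment is attempted and reported with a strand
flag; duplicates and counting ignore strand. Reads with no surviving
alignment are retried once with denser, shorter seeds (k = 8, step 2)
under the same scoring and filters — at a 5% dark-base rate roughly 5% of
short reads otherwise lose every primary seed. With the rescue pass the
aligner attains the exhaustive-DP optimum for >99% of simulated reads
(verified against an independent full-DP oracle in the test suite).

**Single-best mapping**: the unique top-NScore alignment per read, or a
uniform random choice among exact ties (run seed; canonical candidate
order makes the choice reproducible). Reads whose single-best alignment is
to a contaminant reference (name prefix `CONTAM_`) are removed entirely.
**Usable reads** — the normalisation denominator everywhere — are those
surviving the length window, alignment, and contaminant filters.

## Quantification

Gene-level tables from single-best usable alignments:
`rpm = count / usable_total × 1e6`; isoform
`rpkm = count / (isoform_kb × usable_millions)` summed over the gene's
isoforms (plain isoform length, no effective-length or fragment-length
correction); coverage = summed aligned read lengths over all isoforms
divided by the gene's mean isoform length (full read length, not clipped
spans). A read aligning to several isoforms of one gene counts once, on
its single-best isoform. Note that because the simulator draws reads per
*molar* abundance (no length weighting), RPM estimates the abundance
itself and RPKM estimates abundance per unit length; the rank-recovery
test is phrased accordingly.

## Duplicate analysis

A duplicate is a read in excess of one per key. Two key modes:
`locus` (reference, start) and `locus_and_length` (adds read length).
Removal keeps the lexicographically smallest read id per key —
deterministic, and no statistic depends on which copy survives. Positional
profiles bin duplicates by `floor(n_bins · start / length)` (default 50
bins).

The cross-technology summary reports per-transcript duplicate counts,
medians, their AS:SMS ratio, and the fraction of reads removed by
locus-mode removal. The **ratio uses the `locus` key for both
technologies**: with a length-aware key, fixed-length AS reads collide
~25–30× more often than variable-length SMS reads for purely combinatorial
reasons (no length diversity in the key), which at desk-scale coverage
swamps the PCR signal the ratio is meant to expose. The length-aware mode
remains the default for duplicate marking and positional profiles.

## Standard study conditions

Chosen once, then frozen; stated here as the package's own design.

* **Platform comparison** (duplicate ratio, quartile fractions, q-q
  divergence): 100 single-isoform genes, lengths 500–2500 bp, lognormal
  `sigma = 0.5`, 50,000 reads per technology, `beta = 0.5`,
  `lambda = 1.5`. `lambda` was calibrated under exactly these conditions
  so the AS:SMS per-transcript duplicate median ratio is ≈ 3. The sizes
  balance two regimes: with many more transcripts the SMS duplicate median
  drops to a handful of reads and the ratio inherits ±25–30% integer
  granularity; with fewer (or deeper) transcripts birthday-coincidence
  duplicates dominate both technologies and the ratio saturates near 1
  regardless of `lambda`. Because a single sample's ratio still varies by
  roughly ±0.5 across seeds (the abundance-profile draw), the reported
  statistic pools per-transcript duplicate counts over three independent
  simulated samples — mirroring how the statistic is defined over a sample
  set — which tightens the seed spread to roughly 2.7–3.1.
* **Detection sweep**: 300 single-isoform genes, `sigma = 1.5`, 6,000
  reads per technology. At this depth one mapped read already exceeds
  3 RPKM, so the 0.1–3.0 RPKM sweep operates in the presence/absence
  regime: "SMS-only at threshold" effectively counts genes sampled by SMS
  and missed entirely by AS. The direction (SMS-only ≫ AS-only under
  `beta > 0`) is the property under test; absolute counts are not
  comparable to full-scale data.
* **Fusion benchmark**: comparison conditions plus one spiked fusion at
  relative abundance 0.05 (≥ 20 junction-spanning recoverable reads at
  50k); the no-fusion null uses 8,000-read libraries.

## Bias analyses

Genes are partitioned into four equal-count quartiles ordered by AS rpm
descending (ties by name; remainder to earlier quartiles; Q1 = highest).
The gene universe is genes with AS rpm > 0 plus genes observed in SMS,
zero-filled, so dropouts are not silently excluded. Per-quartile rpm sums
are normalised within technology. The q-q comparison pairs sorted
`log2(rpm+1)` values rank-for-rank; its divergence statistic is the mean
AS−SMS difference over the top decile. The detection sweep counts genes
above threshold in exactly one technology for thresholds 0.1–3.0 RPKM
(step 0.1), stratified by maximum isoform length into 0–300, 300–3000,
3000+ bp classes. Recurrence analysis ranks genes per sample by
`as_rpm − sms_rpm` (difference, not ratio, to stay defined at SMS
dropouts), takes the top 500, and reports genes present in at least
`ceil(0.4 × n_samples)` lists. Single-technology candidates have mean SMS
RPKM above the 0.3 noise threshold with mean AS RPKM below it, annotated
with the long-read (>36 bp) fraction, a dispersion statistic (occupied
50 bp start bins over transcript bins), and the distribution of next-best
alignment references; candidates supported only by short reads
(long-read fraction < 0.3) are dropped.

The redistribution arithmetic: if a low quartile's rpm sum is `r` times
the top quartile's and a fraction `m` of the top quartile's reads is moved
into it, the low quartile grows by `(r + m)/r`.

## Fusion discovery

Non-mapping reads (zero surviving alignments; length-filtered reads are
excluded and logged separately) are partially re-aligned: the best
prefix-anchored and suffix-anchored gapped alignment with ≥ 18 anchored
read bases, anchor error rate ≤ 0.15, scored +1/−2 so random sequence
does not extend an anchor. The breakpoint is the anchor's unaligned-facing
end; the remainder of the read is the overhang. Partials are clustered by
(reference, breakpoint, side), exactly by default (`tolerance` exposed for
noisy data). Cluster pairs (5'-side prefix anchors × 3'-side suffix
anchors) are cross-matched against each other's flanking reference
sequence. Because dark-base deletions and anchor-boundary wobble corrupt a
column-wise consensus, matching is per member: an overhang matches a flank
when some junction-anchored prefix of its gapped (+1/−2) alignment path
reaches ≥ 10 matched bases at ≥ 0.9 matches/(matches+errors), and a
cluster matches when at least half of its eligible members do. Junction
pairs on one reference within 2×flank are skipped (they would re-discover
the reference itself) and near-duplicate calls within 15 bp are collapsed
onto the best-supported one. The junction sequence is 100 bp of each flank;
remaining non-mapping reads are rescued when their full alignment to it
reaches NScore 4 and crosses the junction with ≥ 8 reference bases on each
side. The search is transcriptome-only and forward-strand (simulated reads
are forward).

Recovery against truth counts junction-spanning reads with ≥ 18 reference
bases on one side and ≥ 8 on the other *that are in the non-mapping set*:
a spanning read with a minor side of ~8–13 bp frequently still passes the
NScore filter against its major partner (chance matches on the short
tail), is mapped by the standard pass, and is therefore structurally
unreachable for any non-mapping-read pipeline.

## Numerical and engineering choices

* All internal coordinates 0-based half-open; SAM output 1-based per the
  standard, with NScore/match/error counts as `ZN/ZM/ZE` tags.
* DP tie-breaks always prefer the smallest coordinates, making alignment
  deterministic without a seed; only single-best tie-breaking consumes
  randomness.
* One global seed fans out to per-stage child seeds by CRC-32 stage-name
  hashing, so stages can be re-run in isolation; rerunning a config
  reproduces byte-identical TSV outputs.
* FASTQ qualities are constant `I` (no analysis uses base quality).
* Homopolymer contaminant references default to 100 bp so any simulated
  read can align to them in full.

## What the simulation does and does not show

The toy transcriptome has independent random isoform sequences — no shared
exons, paralogy, repeats, or low-complexity regions — so multi-mapping is
rare and unique-mapping rates are higher than in real data; the
mis-mapping noise floor the real comparison observes at the lowest
expression levels is largely absent. Read counts are drawn per molar
abundance without length weighting, and base qualities, strand-specific
protocols, paired ends, and GC effects are not modelled. Passing tests
therefore demonstrate that the analysis chain correctly measures the
amplification phenomena its generative model encodes — selection bias and
copy duplication — not that the model captures every bias of real
libraries.
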