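import logging
import math

import numpy as np
import pytest
from scipy import stats

from xplatseq import simulate as sim
from xplatseq.reference import TranscriptRecord


def flat_config(**kw):
    """A noise-free baseline configuration for targeted assertions."""
    defaults = dict(
        n_reads=1000, dark_base_rate=0.0, error_rate=0.0,
        contaminant_fraction=0.0, bias_exponent=0.0, duplication_rate=0.0,
        seed=0,
    )
    defaults.update(kw)
    return sim.SimConfig(**defaults)


@pytest.fixture
def toy():
    ref, genes = sim.make_toy_transcriptome(20, seed=5, length_range=(400, 1500))
    profile = sim.sample_abundances(list(ref), 1.0, seed=6)
    return ref, genes, profile


class TestSampleAbundances:
    def test_zero_sigma_is_flat(self):
        p = sim.sample_abundances(4, 0.0, seed=1)
        assert np.allclose(p.weights, 0.25)

    def test_deterministic_given_seed(self):
        a = sim.sample_abundances(1000, 2.0, seed=9)
        b = sim.sample_abundances(1000, 2.0, seed=9)
        assert a.ids == b.ids
        assert np.array_equal(a.weights, b.weights)

    def test_heavy_tail_top_decile_dominates(self):
        # at sigma=2 the top decile of transcripts should carry >50% of the
        # weight in at least 95 of 100 seeds
        wins = 0
        for seed in range(100):
            p = sim.sample_abundances(1000, 2.0, seed=seed)
            w = np.sort(p.weights)[::-1]
            wins += w[:100].sum() > 0.5
        assert wins >= 95

    def test_validation(self):
        with pytest.raises(ValueError):
            sim.sample_abundances(0, 1.0, seed=1)
        with pytest.raises(ValueError):
            sim.sample_abundances(5, -1.0, seed=1)


class TestSmsLibrary:
    def test_noise_free_reads_are_exact_substrings(self, toy):
        ref, _, profile = toy
        reads, truth = sim.simulate_sms_library(ref, profile, flat_config())
        assert len(reads) == len(truth) == 1000
        for r, t in zip(reads, truth):
            origin = ref[t.origin].sequence
            assert r.sequence == origin[t.origin_start : t.origin_start + t.extent]
            assert t.emitted_copies == 1

    def test_contaminant_count_binomial(self, toy):
        ref, _, profile = toy
        cfg = flat_config(n_reads=5000, contaminant_fraction=0.2, seed=3)
        _, truth = sim.simulate_sms_library(ref, profile, cfg)
        n_cont = sum(t.is_contaminant for t in truth)
        sd = math.sqrt(5000 * 0.2 * 0.8)
        assert abs(n_cont - 1000) <= 3 * sd

    def test_dark_base_thinning_expectation(self, toy):
        ref, _, profile = toy
        cfg = flat_config(n_reads=10000, dark_base_rate=0.05, seed=4,
                          sms_length_range=(40, 40), sms_length_mode=40)
        reads, _ = sim.simulate_sms_library(ref, profile, cfg)
        lengths = np.array([len(r.sequence) for r in reads])
        # Bernoulli thinning: E[len] = 40 * 0.95, Var = 40 * 0.95 * 0.05
        se = math.sqrt(40 * 0.95 * 0.05 / len(lengths))
        assert abs(lengths.mean() - 38.0) <= 3 * se

    def test_short_transcripts_excluded(self, caplog):
        ref = {
            "T1": TranscriptRecord("T1", "ACGT" * 150),
            "T2": TranscriptRecord("T2", "ACGT" * 5),  # 20 bp < min length
        }
        profile = sim.sample_abundances(["T1", "T2"], 0.0, seed=1)
        with caplog.at_level(logging.WARNING):
            _, truth = sim.simulate_sms_library(ref, profile, flat_config(n_reads=200))
        assert all(t.origin == "T1" for t in truth)
        assert any("excluded" in r.message for r in caplog.records)

    def test_lengths_within_configured_range(self, toy):
        ref, _, profile = toy
        cfg = flat_config(n_reads=3000, seed=8)
        _, truth = sim.simulate_sms_library(ref, profile, cfg)
        lo, hi = cfg.sms_length_range
        assert all(lo <= t.extent <= hi for t in truth)


class TestAsLibrary:
    def test_short_transcript_gets_no_reads(self, caplog):
        ref = {
            "T1": TranscriptRecord("T1", "ACGT" * 150),   # 600 bp
            "T2": TranscriptRecord("T2", "ACGT" * 50),    # 200 bp < 280
        }
        profile = sim.sample_abundances(["T1", "T2"], 0.0, seed=2)
        with caplog.at_level(logging.WARNING):
            _, truth = sim.simulate_as_library(ref, profile, flat_config(n_reads=300))
        assert all(t.origin == "T1" for t in truth)
        assert any("size selection" in r.message for r in caplog.records)

    def test_no_duplication_when_lambda_zero(self, toy):
        ref, _, profile = toy
        _, truth = sim.simulate_as_library(ref, profile, flat_config(n_reads=2000))
        assert all(t.emitted_copies == 1 for t in truth)

    def test_lineage_sizes_recorded(self, toy):
        ref, _, profile = toy
        cfg = flat_config(n_reads=5000, duplication_rate=4.0, seed=5)
        _, truth = sim.simulate_as_library(ref, profile, cfg)
        assert any(t.emitted_copies > 1 for t in truth)
        # reads of one lineage are contiguous and share coordinates
        by_key = {}
        for t in truth:
            by_key.setdefault((t.origin, t.origin_start, t.emitted_copies), 0)
            by_key[(t.origin, t.origin_start, t.emitted_copies)] += 1

    def test_bias_exponent_shifts_reads_to_abundant_transcripts(self, toy):
        ref, _, profile = toy
        top_q = set(np.array(profile.ids)[np.argsort(profile.weights)[::-1][:5]])
        shares = {}
        for beta, lam in ((0.0, 0.0), (1.0, 4.0)):
            cfg = flat_config(n_reads=10000, bias_exponent=beta,
                              duplication_rate=lam, seed=7)
            _, truth = sim.simulate_as_library(ref, profile, cfg)
            shares[beta] = sum(t.origin in top_q for t in truth) / len(truth)
        assert shares[1.0] > shares[0.0]

    def test_locus_duplicates_match_birthday_expectation(self):
        # with no PCR and no bias, per-start-locus collisions are pure
        # birthday coincidences; check the analytic expectation
        L = 3000
        ref = {"T1": TranscriptRecord("T1", "ACGT" * (L // 4))}
        profile = sim.sample_abundances(["T1"], 0.0, seed=3)
        cfg = flat_config(n_reads=10000, seed=9)
        _, truth = sim.simulate_as_library(ref, profile, cfg)
        starts = [t.origin_start for t in truth]
        observed_dup = len(starts) - len(set(starts))
        # fragment length 280-320 -> start positions ~ U[0, L - flen]
        positions = L - 300 + 1
        n = len(starts)
        expected = n - positions * (1 - (1 - 1 / positions) ** n)
        assert abs(observed_dup - expected) <= 4 * math.sqrt(expected)


def test_no_bias_null_as_and_sms_agree():
    # beta=0, lambda=0, no noise, equal depth: per-transcript read counts of
    # the two technologies are draws from the same multinomial
    ref, _ = sim.make_toy_transcriptome(15, seed=21, length_range=(500, 1200),
                                        max_isoforms=1)
    profile = sim.sample_abundances(list(ref), 0.7, seed=22)
    cfg_as = flat_config(n_reads=10000, seed=23)
    cfg_sms = flat_config(n_reads=10000, seed=24)
    _, as_truth = sim.simulate_as_library(ref, profile, cfg_as)
    _, sms_truth = sim.simulate_sms_library(ref, profile, cfg_sms)
    ids = sorted(ref)
    as_counts = [sum(t.origin == i for t in as_truth) for i in ids]
    sms_counts = [sum(t.origin == i for t in sms_truth) for i in ids]
    _, p, _, _ = stats.chi2_contingency([as_counts, sms_counts])
    assert p > 0.01


def test_determinism_byte_identical(tmp_path, toy):
    ref, _, profile = toy
    cfg = sim.default_sms_config(500, seed=42)
    outs = []
    for name in ("a.fastq", "b.fastq"):
        reads, truth = sim.simulate_sms_library(ref, profile, cfg)
        sim.write_fastq(reads, tmp_path / name)
        sim.write_truth(truth, tmp_path / (name + ".tsv"))
        outs.append(((tmp_path / name).read_bytes(),
                     (tmp_path / (name + ".tsv")).read_bytes()))
    assert outs[0] == outs[1]


def test_fastq_and_truth_round_trip(tmp_path, toy):
    ref, _, profile = toy
    reads, truth = sim.simulate_sms_library(ref, profile, flat_config(n_reads=50))
    sim.write_fastq(reads, tmp_path / "r.fastq")
    sim.write_truth(truth, tmp_path / "t.tsv")
    assert sim.read_fastq(tmp_path / "r.fastq") == reads
    assert sim.read_truth(tmp_path / "t.tsv") == truth


class TestFusion:
    def test_fused_length_arithmetic(self):
        ref = {
            "T1": TranscriptRecord("T1", "AC" * 300),   # 600 bp
            "T2": TranscriptRecord("T2", "GT" * 500),   # 1000 bp
        }
        spec = sim.FusionSpec("T1", 250, "T2", 400, 0.05)
        _, rec, joff = sim.spike_fusion(ref, spec)
        assert rec.length == 250 + 600
        assert joff == 250

    def test_degenerate_breaks_rejected(self):
        ref = {
            "T1": TranscriptRecord("T1", "ACGT" * 100),
            "T2": TranscriptRecord("T2", "GGCC" * 100),
        }
        for b5, b3 in ((0, 100), (400, 100), (100, 0), (100, 400)):
            with pytest.raises(ValueError):
                sim.spike_fusion(ref, sim.FusionSpec("T1", b5, "T2", b3, 0.05))

    def test_spanning_flags_match_overlap_rule(self):
        ref, _ = sim.make_toy_transcriptome(4, seed=31, length_range=(600, 1000),
                                            max_isoforms=1)
        tids = sorted(ref)
        spec = sim.choose_clean_fusion(ref, tids[0], tids[1], 300, 400, 0.2)
        aug, rec, joff = sim.spike_fusion(ref, spec)
        profile = sim.with_fusion(
            sim.sample_abundances(tids, 0.0, seed=32), rec.transcript_id, 0.2
        )
        _, truth = sim.simulate_sms_library(
            aug, profile, flat_config(n_reads=2000, seed=33),
            junctions={rec.transcript_id: joff},
        )
        fusion_reads = [t for t in truth if t.origin == rec.transcript_id]
        assert fusion_reads
        for t in fusion_reads:
            expected = t.origin_start < joff < t.origin_start + t.extent
            assert t.is_fusion_spanning == expected
        assert not any(t.is_fusion_spanning for t in truth
                       if t.origin != rec.transcript_id)

    def test_clean_breakpoints_have_no_junction_homology(self):
        ref, _ = sim.make_toy_transcriptome(4, seed=35, length_range=(800, 1200),
                                            max_isoforms=1)
        tids = sorted(ref)
        spec = sim.choose_clean_fusion(ref, tids[0], tids[1], 400, 500, 0.1)
        five = ref[spec.five_prime_id].sequence
        three = ref[spec.three_prime_id].sequence
        assert five[spec.five_prime_break] != three[spec.three_prime_break]
        assert five[spec.five_prime_break - 1] != three[spec.three_prime_break - 1]


def test_simconfig_validation():
    with pytest.raises(ValueError):
        sim.SimConfig(dark_base_rate=1.5)
    with pytest.raises(ValueError):
        sim.SimConfig(n_reads=-1)
    with pytest.raises(ValueError):
        sim.SimConfig(sms_length_range=(30, 20))
    with pytest.raises(ValueError):
        sim.SimConfig(sms_length_mode=10)
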