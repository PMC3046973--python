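import numpy as np
import pandas as pd
import pytest

from xplatseq import bias
from xplatseq.align import AlignmentRecord
from xplatseq.quantify import ExpressionTable
from xplatseq.reference import GeneModel, TranscriptRecord


def make_table(rpm_by_gene, technology="AS", usable_total=10**6, rpkm_by_gene=None):
    genes = sorted(rpm_by_gene)
    df = pd.DataFrame({
        "read_count": [int(rpm_by_gene[g]) for g in genes],
        "rpm": [float(rpm_by_gene[g]) for g in genes],
        "rpkm": [float((rpkm_by_gene or rpm_by_gene)[g]) for g in genes],
        "coverage": 0.0,
    }, index=pd.Index(genes, name="gene"))
    return ExpressionTable(df, "s1", technology, usable_total)


class TestQuartilePartition:
    def test_sort_and_split(self):
        rpm = {f"g{i}": v for i, v in enumerate((80, 70, 60, 50, 40, 30, 20, 10))}
        quart = bias.quartile_partition(make_table(rpm))
        assert set(quart[quart == 1].index) == {"g0", "g1"}
        assert set(quart[quart == 4].index) == {"g6", "g7"}

    def test_remainder_goes_to_earlier_quartiles(self):
        rpm = {f"g{i}": 90 - 10 * i for i in range(9)}
        quart = bias.quartile_partition(make_table(rpm))
        sizes = quart.value_counts().sort_index().tolist()
        assert sizes == [3, 2, 2, 2]

    def test_ties_broken_by_gene_name(self):
        rpm = {"a": 50.0, "b": 50.0, "c": 10.0, "d": 5.0}
        quart = bias.quartile_partition(make_table(rpm))
        assert quart["a"] == 1 and quart["b"] == 2

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            bias.quartile_partition(make_table({"a": 1.0, "b": 2.0, "c": 3.0}))


class TestQuartileFractions:
    def test_normalisation(self):
        rpm = {f"g{i}": v for i, v in
               enumerate((500, 400, 40, 20, 20, 10, 6, 4))}  # Q sums 900/60/30/10
        table = make_table(rpm)
        quart = bias.quartile_partition(table)
        summary = bias.quartile_read_fractions(table, table, quart)
        assert np.allclose(summary.table["as_fraction"],
                           [0.9, 0.06, 0.03, 0.01])
        assert np.allclose(summary.table["as_fraction"],
                           summary.table["sms_fraction"])
        assert summary.table["as_fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_missing_gene_treated_as_zero(self):
        as_table = make_table({"a": 60.0, "b": 30.0, "c": 20.0, "d": 10.0})
        sms_table = make_table({"a": 60.0, "b": 30.0, "c": 20.0}, technology="SMS")
        quart = bias.quartile_partition(as_table)
        summary = bias.quartile_read_fractions(as_table, sms_table, quart)
        assert summary.table.loc["Q4", "sms_rpm"] == 0.0


class TestRedistribution:
    @pytest.mark.parametrize("q_ratio,moved,expected",
                             [(0.004, 0.01, 3.5), (0.5, 0.0, 1.0), (0.01, 0.01, 2.0)])
    def test_fold_change(self, q_ratio, moved, expected):
        assert bias.redistribution_factor(q_ratio, moved) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bias.redistribution_factor(0.0, 0.01)
        with pytest.raises(ValueError):
            bias.redistribution_factor(0.01, -0.1)


class TestQQCompare:
    def test_identical_tables_have_zero_divergence(self):
        table = make_table({f"g{i}": float(i + 1) for i in range(20)})
        pairs, div = bias.qq_compare(table, table)
        assert div == pytest.approx(0.0)
        assert np.allclose(pairs["as_log2_rpm"], pairs["sms_log2_rpm"])

    def test_single_inflated_gene_lifts_top_pair(self):
        rpm = {f"g{i}": float(i + 1) for i in range(20)}
        as_rpm = dict(rpm, g19=rpm["g19"] * 10)
        pairs, div = bias.qq_compare(make_table(as_rpm), make_table(rpm, "SMS"))
        assert pairs["as_log2_rpm"].iloc[-1] > pairs["sms_log2_rpm"].iloc[-1]
        assert div > 0


class TestDetectionSweep:
    LENGTHS = {"a": 200, "b": 500, "c": 1500, "d": 5000}

    def test_threshold_rule(self):
        sms = make_table({"a": 1, "b": 1, "c": 1, "d": 1},
                         rpkm_by_gene={"a": 0.5, "b": 0.4, "c": 0.2, "d": 1.0})
        as_ = make_table({"a": 1, "b": 1, "c": 1, "d": 1},
                         rpkm_by_gene={"a": 0.1, "b": 0.35, "c": 0.25, "d": 1.2})
        sweep = bias.detection_sweep(as_, sms, self.LENGTHS)
        row = sweep.at(0.3)
        assert row["sms_only"] == 1 and row["as_only"] == 0
        assert row["sms_only_0-300"] == 1  # gene "a" is 200 bp

    def test_threshold_above_everything(self):
        t = make_table({"a": 1.0, "b": 2.0}, rpkm_by_gene={"a": 0.1, "b": 0.2})
        sweep = bias.detection_sweep(t, t, self.LENGTHS, thresholds=[5.0])
        assert sweep.table.iloc[0][["sms_only", "as_only"]].tolist() == [0, 0]

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i:04d}" for i in range(1000)]
        as_rpkm = dict(zip(genes, rng.exponential(0.5, 1000)))
        sms_rpkm = dict(zip(genes, rng.exponential(0.5, 1000)))
        lengths = dict(zip(genes, rng.integers(100, 6000, 1000)))
        as_t = make_table({g: 1.0 for g in genes}, rpkm_by_gene=as_rpkm)
        sms_t = make_table({g: 1.0 for g in genes}, "SMS", rpkm_by_gene=sms_rpkm)
        sweep = bias.detection_sweep(as_t, sms_t, lengths)
        for _, row in sweep.table.iterrows():
            t = row["threshold"]
            sms_only = sum(sms_rpkm[g] >= t > as_rpkm[g] for g in genes)
            as_only = sum(as_rpkm[g] >= t > sms_rpkm[g] for g in genes)
            assert row["sms_only"] == sms_only
            assert row["as_only"] == as_only
            for label, lo, hi in (("0-300", 0, 300), ("300-3000", 300, 3000),
                                  ("3000+", 3000, 10**9)):
                expect = sum(sms_rpkm[g] >= t > as_rpkm[g] and lo <= lengths[g] < hi
                             for g in genes)
                assert row[f"sms_only_{label}"] == expect
        # class counts always sum to the total
        for side in ("sms_only", "as_only"):
            class_sum = sum(sweep.table[f"{side}_{label}"]
                            for label in bias.LENGTH_CLASS_LABELS)
            assert (class_sum == sweep.table[side]).all()


class TestRecurrence:
    def _sample(self, diffs):
        as_t = make_table({g: max(d, 0.0) + 1.0 for g, d in diffs.items()})
        sms_t = make_table({g: 1.0 + max(-d, 0.0) for g, d in diffs.items()}, "SMS")
        return as_t, sms_t

    def test_threshold_arithmetic(self):
        # gene "x" is top-2 over-represented in exactly 2 of 3 samples;
        # ceil(0.4 * 3) = 2 -> recurrent
        samples = [
            self._sample({"x": 9.0, "y": 8.0, "z": 0.1, "w": 0.0}),
            self._sample({"x": 9.0, "w": 8.0, "z": 0.1, "y": 0.0}),
            self._sample({"y": 9.0, "w": 8.0, "z": 0.1, "x": 0.0}),
        ]
        result = bias.recurrent_overrepresentation(samples, top_k=2,
                                                   recurrence_fraction=0.4)
        assert result.min_samples == 2
        assert "x" in result.recurrent and "z" not in result.recurrent

    def test_dominant_gene_always_recurrent(self):
        samples = [self._sample({"x": 9.0, "y": 1.0, "z": 0.5}) for _ in range(4)]
        result = bias.recurrent_overrepresentation(samples, top_k=1,
                                                   recurrence_fraction=0.4)
        assert result.recurrent == {"x"}

    def test_full_fraction_is_intersection(self):
        samples = [
            self._sample({"x": 9.0, "y": 8.0, "z": 0.1}),
            self._sample({"x": 9.0, "z": 8.0, "y": 0.1}),
        ]
        result = bias.recurrent_overrepresentation(samples, top_k=2,
                                                   recurrence_fraction=1.0)
        lists = [set(lst) for lst in result.per_sample]
        assert result.recurrent == lists[0] & lists[1]

    def test_sample_order_invariance(self):
        samples = [
            self._sample({"x": 9.0, "y": 8.0, "z": 0.1, "w": 3.0}),
            self._sample({"x": 1.0, "w": 8.0, "z": 5.1, "y": 0.0}),
            self._sample({"y": 9.0, "w": 2.0, "z": 0.1, "x": 4.0}),
        ]
        a = bias.recurrent_overrepresentation(samples, top_k=2)
        b = bias.recurrent_overrepresentation(samples[::-1], top_k=2)
        assert a.recurrent == b.recurrent

    def test_top_k_clamped_with_warning(self, caplog):
        import logging
        samples = [self._sample({"x": 9.0, "y": 8.0})] * 2
        with caplog.at_level(logging.WARNING):
            result = bias.recurrent_overrepresentation(samples, top_k=500)
        assert any("clamped" in r.message for r in caplog.records)
        assert len(result.per_sample[0]) == 2

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            bias.recurrent_overrepresentation([self._sample({"x": 1.0})])


class TestNominateCandidates:
    REF = {
        "TA": TranscriptRecord("TA", "A" * 1000),
        "TB": TranscriptRecord("TB", "C" * 1000),
    }
    GENES = [GeneModel("GA", ("TA",)), GeneModel("GB", ("TB",))]

    def _recs(self, ref_id, n, length):
        return [AlignmentRecord(f"{ref_id}r{i}", ref_id, 50 * i, 50 * i + length,
                                length, 0, length, 5.0, is_single_best=True)
                for i in range(n)]

    def test_threshold_rule_nominates(self):
        sms = [make_table({"GA": 1, "GB": 1}, "SMS", rpkm_by_gene={"GA": 0.6, "GB": 2.0}),
               make_table({"GA": 1, "GB": 1}, "SMS", rpkm_by_gene={"GA": 0.4, "GB": 2.0})]
        as_ = [make_table({"GA": 1, "GB": 1}, rpkm_by_gene={"GA": 0.05, "GB": 2.0}),
               make_table({"GA": 1, "GB": 1}, rpkm_by_gene={"GA": 0.10, "GB": 2.0})]
        recs = self._recs("TA", 10, 40)
        out = bias.nominate_single_tech_candidates(sms, as_, recs, recs,
                                                   self.GENES, self.REF)
        assert out["gene"].tolist() == ["GA"]
        assert out.iloc[0]["long_read_fraction"] == 1.0
        assert out.iloc[0]["dispersion"] == pytest.approx(10 / 20)

    def test_short_read_only_candidates_dropped(self):
        sms = [make_table({"GA": 1, "GB": 1}, "SMS", rpkm_by_gene={"GA": 0.6, "GB": 2.0})]
        as_ = [make_table({"GA": 1, "GB": 1}, rpkm_by_gene={"GA": 0.05, "GB": 2.0})]
        recs = self._recs("TA", 10, 30)  # all 30-mers: long-read fraction 0
        out = bias.nominate_single_tech_candidates(sms, as_, recs, recs,
                                                   self.GENES, self.REF)
        assert out.empty

    def test_next_best_reference_diagnostic(self):
        sms = [make_table({"GA": 1, "GB": 1}, "SMS", rpkm_by_gene={"GA": 0.6, "GB": 2.0})]
        as_ = [make_table({"GA": 1, "GB": 1}, rpkm_by_gene={"GA": 0.05, "GB": 2.0})]
        best = self._recs("TA", 4, 40)
        alts = [AlignmentRecord(r.read_id, "TB", 0, 40, 38, 2, 40, 4.5)
                for r in best]
        out = bias.nominate_single_tech_candidates(sms, as_, best, best + alts,
                                                   self.GENES, self.REF)
        assert out.iloc[0]["next_best_references"].startswith("TB:4")


def test_hard_as_dropout_is_nominated():
    # simulate a transcript absent from the AS library (selection weight 0)
    # but present in SMS: it must surface as a single-technology candidate
    from xplatseq import align as al, quantify as q, simulate as sim
    from xplatseq.reference import build_contaminants, merge_references

    ref, genes = sim.make_toy_transcriptome(12, seed=71, length_range=(600, 1200),
                                            max_isoforms=1)
    tids = sorted(ref)
    dropout = tids[0]
    profile = sim.sample_abundances(tids, 0.5, seed=72)
    as_ids = [t for t in tids if t != dropout]
    w = np.array([profile.as_dict()[t] for t in as_ids])
    as_profile = sim.AbundanceProfile(tuple(as_ids), w / w.sum())
    index = al.ReferenceIndex(merge_references(ref, build_contaminants()))

    def run(profile_, sim_fn, preset, seed):
        cfg = sim.SimConfig(n_reads=4000, contaminant_fraction=0.0, seed=seed)
        reads, _ = sim_fn(ref, profile_, cfg)
        recs, _ = al.align_reads(reads, index, preset)
        best, _ = al.partition_by_contaminant(al.single_best(recs, seed))
        table = q.gene_tables(q.count_per_transcript(best), best, genes, ref,
                              usable_total=len(best))
        return table, best, recs

    as_table, _, _ = run(as_profile, sim.simulate_as_library, al.bowtie_like(), 73)
    sms_table, sms_best, sms_all = run(profile, sim.simulate_sms_library,
                                       al.indexdp_like(), 74)
    out = bias.nominate_single_tech_candidates(
        [sms_table], [as_table], sms_best, sms_all, genes, ref
    )
    gene_of = {t: g.gene_symbol for g in genes for t in g.isoform_ids}
    assert gene_of[dropout] in set(out["gene"])
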