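"""Benchmarking set algebra, commonness stratification, percentage arithmetic."""
import numpy as np
import pytest

from popaf.evaluation import (
    common_fraction,
    compare_to_truth,
    error_reduction,
    model_specific_errors,
    rare_fraction,
    round1,
    stratify_by_commonness,
    zero_frequency_recall,
)
from popaf.matching import annotate_callset
from popaf.model import Callset, GenomicInterval, ReferenceSequence, VariantRecord
from popaf.panel import compute_frequencies
from conftest import make_panel


def _cs(records, label="calls"):
    return Callset(records, sample_ids=("S",), label=label)


def _snp(pos, ref, alt, gt=(0, 1), af=None, contig="chr1"):
    return VariantRecord(contig, pos, ref, (alt,), genotypes=(gt,),
                         per_alt_af=af)


class TestCompareToTruth:
    def test_identical_callsets_have_no_errors(self, tiny_reference):
        seq = tiny_reference.sequence("chr1")
        recs = [_snp(5, seq[5], "G"), _snp(20, seq[20], "T", gt=(1, 1))]
        cmp = compare_to_truth(_cs(recs), _cs(recs, "truth"), tiny_reference)
        assert cmp.n_fp == 0 and cmp.n_fn == 0 and cmp.n_tp == 2

    def test_shifted_indel_representations_count_as_tp(self, tiny_reference):
        """Truth left-shifted vs call right-shifted in the A-run: same
        haplotype, so neither FP nor FN."""
        seq = tiny_reference.sequence("chr1")
        run = seq.index("AAAAAAAA")
        truth = _cs([VariantRecord("chr1", run - 1, seq[run - 1:run + 1],
                                   (seq[run - 1],), genotypes=((0, 1),))], "truth")
        call = _cs([VariantRecord("chr1", run + 3, "AA", ("A",),
                                  genotypes=((0, 1),))])
        cmp = compare_to_truth(call, truth, tiny_reference)
        assert (cmp.n_tp, cmp.n_fp, cmp.n_fn) == (1, 0, 0)

    def test_zygosity_mismatch_counts_as_fp_and_fn(self, tiny_reference):
        seq = tiny_reference.sequence("chr1")
        truth = _cs([_snp(5, seq[5], "G", gt=(1, 1))], "truth")
        call = _cs([_snp(5, seq[5], "G", gt=(0, 1))])
        cmp = compare_to_truth(call, truth, tiny_reference)
        assert (cmp.n_tp, cmp.n_fp, cmp.n_fn) == (0, 1, 1)

    def test_metric_formulas(self, tiny_reference):
        seq = tiny_reference.sequence("chr1")
        truth_recs = [_snp(p, seq[p], "G" if seq[p] != "G" else "C")
                      for p in range(2, 42, 4)]  # 10 truth SNPs
        calls = truth_recs[:9] + [_snp(49, seq[49], "T" if seq[49] != "T" else "A")]
        cmp = compare_to_truth(_cs(calls), _cs(truth_recs, "truth"), tiny_reference)
        assert (cmp.n_tp, cmp.n_fp, cmp.n_fn) == (9, 1, 1)
        assert cmp.precision() == 0.9
        assert cmp.recall() == 0.9
        assert cmp.f1() == pytest.approx(0.9)

    def test_regions_restrict_both_sides(self, tiny_reference):
        seq = tiny_reference.sequence("chr1")
        truth = _cs([_snp(5, seq[5], "G"), _snp(30, seq[30], "T" if seq[30] != "T" else "C")],
                    "truth")
        call = _cs([_snp(5, seq[5], "G")])
        cmp = compare_to_truth(call, truth, tiny_reference,
                               regions=[GenomicInterval("chr1", 0, 10)])
        assert (cmp.n_tp, cmp.n_fp, cmp.n_fn) == (1, 0, 0)

    def test_truth_partition_invariant(self, sim_bundle):
        study = sim_bundle["study"]
        cmp = compare_to_truth(study.calls_a, study.truth, sim_bundle["reference"])
        assert cmp.n_tp + cmp.n_fn >= len(study.truth.records)
        assert cmp.n_fp == study.ledger["fp_a_total"]
        assert cmp.n_fn == study.ledger["fn_a_total"]


class TestStratify:
    def _annotated_comparison(self, tiny_reference):
        seq = tiny_reference.sequence("chr1")
        def alt_at(p, skip=()):
            return next(b for b in "ACGT" if b != seq[p] and b not in skip)
        common = _snp(5, seq[5], alt_at(5), af=[0.02])
        rare = _snp(20, seq[20], alt_at(20), af=[0.01])
        mixed = VariantRecord("chr1", 30, seq[30],
                              tuple({alt_at(30), alt_at(30, skip=alt_at(30))}),
                              genotypes=((1, 2),), per_alt_af=[0.5, 0.001])
        return common, rare, mixed

    def test_boundary_common_above_rare_at_threshold(self, tiny_reference):
        common, rare, _ = self._annotated_comparison(tiny_reference)
        from popaf.evaluation import ComparisonResult
        cmp = ComparisonResult(tp=[common, rare], tp_calls=[common, rare],
                               fp=[], fn=[])
        sm = stratify_by_commonness(cmp)
        assert sm.strata[("common", "SNP")].n_tp == 1
        assert sm.strata[("rare", "SNP")].n_tp == 1

    def test_mixed_multiallelic_excluded_and_counted(self, tiny_reference):
        common, rare, mixed = self._annotated_comparison(tiny_reference)
        from popaf.evaluation import ComparisonResult
        cmp = ComparisonResult(tp=[common], tp_calls=[common],
                               fp=[mixed], fn=[rare])
        sm = stratify_by_commonness(cmp)
        assert sm.excluded_multiallelic == {"tp": 0, "fp": 1, "fn": 0}
        total_fp = sum(m.n_fp for m in sm.strata.values())
        assert total_fp + sm.excluded_multiallelic["fp"] == 1

    def test_partition_identity_on_synthetic_study(self, sim_bundle):
        panel, reference = sim_bundle["panel"], sim_bundle["reference"]
        study = sim_bundle["study"]
        calls = annotate_callset(study.calls_a, panel, reference)
        truth = annotate_callset(study.truth, panel, reference)
        cmp = compare_to_truth(calls, truth, reference)
        sm = stratify_by_commonness(cmp)
        for what, total in (("tp", cmp.n_tp), ("fp", cmp.n_fp), ("fn", cmp.n_fn)):
            binned = sum(getattr(m, f"n_{what}") for m in sm.strata.values())
            assert binned + sm.excluded_multiallelic[what] == total

    def test_planted_stratum_counts_match_ledger(self, sim_bundle):
        panel, reference = sim_bundle["panel"], sim_bundle["reference"]
        study = sim_bundle["study"]
        calls = annotate_callset(study.calls_a, panel, reference)
        truth = annotate_callset(study.truth, panel, reference)
        cmp = compare_to_truth(calls, truth, reference)
        led = study.ledger
        rare_fp = sum(m.n_fp for (s, t), m in
                      stratify_by_commonness(cmp).strata.items() if s == "rare")
        assert rare_fp == led["shared_fp_rare"] + led["a_only_fp_rare"]

    def test_missing_annotation_raises_actionable_error(self, tiny_reference):
        from popaf.evaluation import ComparisonResult
        rec = _snp(5, tiny_reference.sequence("chr1")[5], "G")
        cmp = ComparisonResult(tp=[rec], tp_calls=[rec], fp=[], fn=[])
        with pytest.raises(ValueError, match="annotate_callset"):
            stratify_by_commonness(cmp)


class TestZeroFrequencyRecall:
    def _cmp(self, found, missed, nonzero=0):
        from popaf.evaluation import ComparisonResult
        mk = lambda i, af: _snp(10 + 2 * i, "A", "G", af=[af])
        tp = [mk(i, 0.0) for i in range(found)] + \
             [mk(100 + i, 0.5) for i in range(nonzero)]
        fn = [mk(50 + i, 0.0) for i in range(missed)]
        return ComparisonResult(tp=tp, tp_calls=list(tp), fp=[], fn=fn)

    def test_half_recovered(self):
        assert zero_frequency_recall(self._cmp(2, 2, nonzero=3)) == 0.5

    def test_empty_subset_gives_sentinel_not_one(self):
        assert zero_frequency_recall(self._cmp(0, 0, nonzero=5)) is None

    def test_equals_brute_force_subset_recall(self, sim_bundle):
        panel, reference = sim_bundle["panel"], sim_bundle["reference"]
        study = sim_bundle["study"]
        # plant zero-frequency truth variants: novel SNPs absent from panel
        seq = reference.sequence("chr1")
        extra = []
        for pos in (29_100, 29_200, 29_300, 29_400):
            alt = next(b for b in "ACGT" if b != seq[pos])
            extra.append(VariantRecord("chr1", pos, seq[pos], (alt,),
                                       genotypes=((0, 1),)))
        truth = Callset(study.truth.records + extra, sample_ids=("S",), label="truth")
        calls = Callset(study.calls_a.records + extra[:2], sample_ids=("S",))
        truth_ann = annotate_callset(truth, panel, reference)
        calls_ann = annotate_callset(calls, panel, reference)
        cmp = compare_to_truth(calls_ann, truth_ann, reference)
        zero_truth = [r for r in truth_ann if all(a == 0 for a in r.per_alt_af)]
        found = [r for r in zero_truth if r in set(cmp.tp)]
        assert zero_frequency_recall(cmp) == len(found) / len(zero_truth)
        assert len(zero_truth) >= 4


class TestModelSpecificErrors:
    def test_identical_models_give_empty_sets(self, sim_bundle):
        study = sim_bundle["study"]
        panel, reference = sim_bundle["panel"], sim_bundle["reference"]
        cmp = compare_to_truth(study.calls_a, study.truth, reference)
        mse = model_specific_errors(cmp, cmp, panel, reference)
        assert not mse.a_specific_fp and not mse.a_specific_fn
        assert not mse.b_specific_fp and not mse.b_specific_fn

    def test_constructed_fixture_matches_set_algebra(self, tiny_reference):
        seq = tiny_reference.sequence("chr1")
        def snp(p):
            return _snp(p, seq[p], next(b for b in "ACGT" if b != seq[p]))
        shared, only_a, only_b = snp(5), snp(12), snp(20)
        truth = _cs([snp(30), snp(38)], "truth")
        panel = make_panel([VariantRecord("chr1", 46, seq[46],
                                          (next(b for b in "ACGT" if b != seq[46]),),
                                          genotypes=((0, 1),) * 4)])
        calls_a = _cs([shared, only_a] + truth.records[:1])
        calls_b = _cs([shared, only_b] + truth.records)
        cmp_a = compare_to_truth(calls_a, truth, tiny_reference)
        cmp_b = compare_to_truth(calls_b, truth, tiny_reference)
        mse = model_specific_errors(cmp_a, cmp_b, panel, tiny_reference)
        assert [r.key for r in mse.a_specific_fp] == [only_a.key]
        assert [r.key for r in mse.b_specific_fp] == [only_b.key]
        assert [r.key for r in mse.a_specific_fn] == [truth.records[1].key]
        assert mse.b_specific_fn == []
        assert all(r.per_alt_af is not None for r in mse.a_specific_fp)

    def test_planted_specific_sets_match_ledger(self, sim_bundle):
        study = sim_bundle["study"]
        panel, reference = sim_bundle["panel"], sim_bundle["reference"]
        cmp_a = compare_to_truth(study.calls_a, study.truth, reference)
        cmp_b = compare_to_truth(study.calls_b, study.truth, reference)
        mse = model_specific_errors(cmp_a, cmp_b, panel, reference)
        led = study.ledger
        assert len(mse.a_specific_fp) == led["a_only_fp"]
        assert len(mse.b_specific_fp) == led["b_only_fp"]
        assert len(mse.a_specific_fn) == led["a_only_fn"]
        assert len(mse.b_specific_fn) == led["b_only_fn"]
        # disjointness of the two specific sets
        keys_a = {r.key for r in mse.a_specific_fp}
        keys_b = {r.key for r in mse.b_specific_fp}
        assert not keys_a & keys_b

    def test_differing_truth_sets_rejected(self, sim_bundle):
        study = sim_bundle["study"]
        panel, reference = sim_bundle["panel"], sim_bundle["reference"]
        cmp_a = compare_to_truth(study.calls_a, study.truth, reference)
        other = Callset(study.truth.records[:5], sample_ids=("S",), label="other")
        cmp_o = compare_to_truth(study.calls_b, other, reference)
        with pytest.raises(ValueError, match="truth"):
            model_specific_errors(cmp_a, cmp_o, panel, reference)


class TestPercentageArithmetic:
    """The printed worked-example arithmetic of the headline analyses."""

    @staticmethod
    def _set(n_rare, n_total):
        recs = []
        for i in range(n_total):
            af = 0.001 if i < n_rare else 0.5
            recs.append(VariantRecord("chr1", i, "A", ("G",), per_alt_af=[af]))
        return recs

    @pytest.mark.parametrize("n_rare,n_total,expected", [
        (1125, 2085, 54.0),   # resolved-FP set: just over half rare
        (49, 1952, 2.5),      # induced-FP set: almost none rare
        (0, 10, 0.0),
    ])
    def test_rare_fraction(self, n_rare, n_total, expected):
        assert rare_fraction(self._set(n_rare, n_total)) == expected

    @pytest.mark.parametrize("n_common,n_total,expected", [
        (2207, 2284, 96.6),   # resolved-FN set: almost all common
        (588, 1952, 30.1),    # induced-FN set
    ])
    def test_common_fraction(self, n_common, n_total, expected):
        records = self._set(n_total - n_common, n_total)
        assert common_fraction(records) == expected

    def test_rare_fraction_empty_set_sentinel(self):
        assert rare_fraction([]) is None

    @pytest.mark.parametrize("candidate,baseline,expected", [
        (431, 469, (38, 8.1)),    # exome dataset 1
        (456, 487, (31, 6.4)),    # exome dataset 2
        (469, 469, (0, 0.0)),
    ])
    def test_error_reduction(self, candidate, baseline, expected):
        assert error_reduction(candidate, baseline) == expected

    def test_error_reduction_zero_baseline_sentinel(self):
        assert error_reduction(0, 0) == (None, None)

    def test_error_reduction_accepts_record_sets(self):
        a = self._set(0, 3)
        b = self._set(0, 5)
        assert error_reduction(a, b) == (2, 40.0)

    def test_round1_half_away_from_zero(self):
        assert round1(2.25) == 2.3
        assert round1(2.24) == 2.2
        assert round1(-2.25) == -2.3
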