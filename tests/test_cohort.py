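"""Cohort rare-variant metrics vs brute-force tallies."""
import numpy as np
import pytest

from popaf.cohort import (
    CohortMatrix,
    call_frequency_bins,
    flagged_counts,
    frameshift_counts,
    frequency_bin_stats,
    homozygous_counts,
    is_frameshift,
    titv_by_bin,
    titv_ratio,
)
from popaf.model import Callset, GenomicInterval, ReferenceSequence, VariantRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _cohort(records, samples=("s1", "s2", "s3")):
    return CohortMatrix(Callset(records, sample_ids=samples))


def _site(pos, gts, ref="A", alts=("G",)):
    return VariantRecord("chr1", pos, ref, alts, genotypes=tuple(gts))


def _random_cohort(rng, n_sites=60, n_samples=20, p_indel=0.3):
    samples = tuple(f"s{i}" for i in range(n_samples))
    records = []
    for i in range(n_sites):
        pos = 10 * i
        if rng.random() < p_indel:
            dlen = int(rng.integers(1, 5))
            ref = "A" + "C" * dlen
            alts = ("A",)
        else:
            ref, alts = "A", ("G",)
        gts = tuple(
            tuple(int(a) for a in rng.choice([0, 0, 0, 1], size=2))
            for _ in samples
        )
        records.append(VariantRecord("chr1", pos, ref, alts, genotypes=gts))
    return Callset(records, sample_ids=samples)


class TestCallFrequencyBins:
    def test_singleton_goes_to_bin_one(self):
        cohort = _cohort([_site(10, [(0, 1), (0, 0), (0, 0)])])
        bins = call_frequency_bins(cohort)
        assert len(bins[1]) == 1 and not any(bins[b] for b in range(2, 11))

    def test_frequency_above_k_excluded(self):
        cohort = _cohort([_site(10, [(0, 1), (1, 1), (0, 1)])])
        bins = call_frequency_bins(cohort, k=2)
        assert all(not units for units in bins.values())

    def test_random_cohort_matches_brute_tally(self):
        rng = np.random.default_rng(21)
        cs = _random_cohort(rng)
        cohort = CohortMatrix(cs)
        bins = call_frequency_bins(cohort, k=10)
        for rec in cs:
            n = sum(1 for gt in rec.genotypes if 1 in gt)
            unit = (rec.key, 0)
            if 1 <= n <= 10:
                assert unit in bins[n]
            else:
                assert all(unit not in u for u in bins.values())


class TestHomozygousCounts:
    def test_het_not_counted(self):
        cohort = _cohort([
            _site(10, [(0, 1), (0, 0), (0, 0)]),
            _site(20, [(1, 1), (0, 0), (0, 0)]),
        ])
        table = homozygous_counts(cohort, call_frequency_bins(cohort))
        s1_bin1 = table[(table["bin"] == 1) & (table["sample"] == "s1")]
        assert s1_bin1["count"].item() == 1
        assert table["count"].sum() == 1

    def test_no_hom_calls_all_zero(self):
        cohort = _cohort([_site(10, [(0, 1), (0, 1), (0, 0)])])
        table = homozygous_counts(cohort, call_frequency_bins(cohort))
        assert (table["count"] == 0).all()

    def test_random_cohort_matches_brute_tally(self):
        rng = np.random.default_rng(8)
        cs = _random_cohort(rng)
        cohort = CohortMatrix(cs)
        bins = call_frequency_bins(cohort, k=10)
        table = homozygous_counts(cohort, bins)
        for (b, s), grp in table.groupby(["bin", "sample"]):
            expected = 0
            for rec in cs:
                n_carriers = sum(1 for gt in rec.genotypes if 1 in gt)
                if n_carriers != b:
                    continue
                gt = rec.genotypes[cs.sample_ids.index(s)]
                if gt == (1, 1):
                    expected += 1
            assert grp["count"].item() == expected

    def test_per_bin_totals_sum_to_rare_homozygous_calls(self):
        rng = np.random.default_rng(13)
        cs = _random_cohort(rng)
        cohort = CohortMatrix(cs)
        k = 10
        table = homozygous_counts(cohort, call_frequency_bins(cohort, k))
        for s in cs.sample_ids:
            total = 0
            for rec in cs:
                n_carriers = sum(1 for gt in rec.genotypes if 1 in gt)
                gt = rec.genotypes[cs.sample_ids.index(s)]
                if 1 <= n_carriers <= k and gt == (1, 1):
                    total += 1
            assert table[table["sample"] == s]["count"].sum() == total


class TestFlaggedCounts:
    reference = ReferenceSequence({"chr1": "ACGT" * 200})

    def test_no_overlap_gives_zeros(self):
        cohort = _cohort([_site(10, [(0, 1), (0, 0), (0, 0)], ref="C", alts=("T",))])
        flags = Callset([VariantRecord("chr1", 100, "A", ("G",))])
        table = flagged_counts(cohort, call_frequency_bins(cohort), flags,
                               self.reference)
        assert (table["count"] == 0).all()

    def test_flagged_singleton_counted_for_carrier(self):
        seq = self.reference.sequence("chr1")
        rec = _site(10, [(0, 1), (0, 0), (0, 0)], ref=seq[10], alts=("C",))
        cohort = _cohort([rec])
        flags = Callset([VariantRecord("chr1", 10, seq[10], ("C",))])
        table = flagged_counts(cohort, call_frequency_bins(cohort), flags,
                               self.reference)
        assert table[(table["bin"] == 1) & (table["sample"] == "s1")]["count"].item() == 1
        assert table["count"].sum() == 1

    def test_random_flag_subsets_match_brute_intersection(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        reference = ReferenceSequence({"chr1": seq})
        records = []
        for i in range(40):
            pos = 20 * i + 5
            alt = next(b for b in "ACGT" if b != seq[pos])
            gts = tuple(tuple(int(a) for a in rng.choice([0, 0, 1], size=2))
                        for _ in range(6))
            records.append(VariantRecord("chr1", pos, seq[pos], (alt,),
                                         genotypes=gts))
        samples = tuple(f"s{i}" for i in range(6))
        cs = Callset(records, sample_ids=samples)
        flag_idx = set(rng.choice(40, size=12, replace=False).tolist())
        flags = Callset([VariantRecord(r.contig, r.pos0, r.ref, r.alts)
                         for i, r in enumerate(cs) if i in flag_idx])
        cohort = CohortMatrix(cs)
        bins = call_frequency_bins(cohort, k=6)
        table = flagged_counts(cohort, bins, flags, reference)
        flag_keys = {r.key for r in flags}
        for s in samples:
            expected = 0
            for rec in cs:
                n_carriers = sum(1 for gt in rec.genotypes if 1 in gt)
                gt = rec.genotypes[samples.index(s)]
                if rec.key in flag_keys and 1 in gt and 1 <= n_carriers <= 6:
                    expected += 1
            assert table[table["sample"] == s]["count"].sum() == expected


class TestTiTv:
    def test_worked_example(self):
        assert titv_ratio([("A", "G"), ("C", "T"), ("A", "C")]) == 2.0

    def test_zero_transversions_gives_sentinel(self):
        assert titv_ratio([("A", "G")]) is None

    def test_non_snv_skipped(self):
        recs = [VariantRecord("chr1", 0, "A", ("G",)),
                VariantRecord("chr1", 5, "AT", ("A",)),
                VariantRecord("chr1", 9, "C", ("A",))]
        assert titv_ratio(recs) == 1.0

    def test_random_sets_match_substitution_table(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            pairs = []
            for _ in range(rng.integers(1, 50)):
                ref = str(rng.choice(list("ACGT")))
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                pairs.append((ref, alt))
            ti = sum(1 for r, a in pairs if {r, a} in ({"A", "G"}, {"C", "T"}))
            tv = len(pairs) - ti
            expected = ti / tv if tv else None
            assert titv_ratio(pairs) == expected

    def test_invariant_under_reverse_complement(self):
        rng = np.random.default_rng(23)
        pairs = []
        for _ in range(60):
            ref = str(rng.choice(list("ACGT")))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            pairs.append((ref, alt))
        rc = [(r.translate(_COMPLEMENT), a.translate(_COMPLEMENT))
              for r, a in pairs]
        assert titv_ratio(pairs) == titv_ratio(rc)

    def test_by_bin_pooled_vs_per_sample_modes(self):
        # one hom transition in s1 (singleton), one het transversion in s2
        cohort = _cohort([
            _site(10, [(1, 1), (0, 0), (0, 0)], ref="A", alts=("G",)),
            _site(20, [(0, 0), (0, 1), (0, 0)], ref="A", alts=("C",)),
        ])
        bins = call_frequency_bins(cohort)
        hom = titv_by_bin(cohort, bins, "hom", "pooled")
        het = titv_by_bin(cohort, bins, "het", "pooled")
        assert hom[1] is None          # 1 transition, 0 transversions
        assert het[1] == 0.0           # 0 transitions, 1 transversion


class TestFrameshift:
    regions = [GenomicInterval("chr1", 0, 100)]

    def test_two_bp_deletion_is_frameshift(self):
        cs = Callset([_site(10, [(0, 1)], ref="ACC", alts=("A",))],
                     sample_ids=("s1",))
        assert frameshift_counts(cs, self.regions) == (1, 0)

    def test_three_bp_deletion_in_frame(self):
        cs = Callset([_site(10, [(0, 1)], ref="ACCC", alts=("A",))],
                     sample_ids=("s1",))
        assert frameshift_counts(cs, self.regions) == (0, 0)

    def test_homozygous_subset(self):
        cs = Callset([
            _site(10, [(1, 1)], ref="AC", alts=("A",)),
            _site(30, [(0, 1)], ref="AC", alts=("A",)),
        ], sample_ids=("s1",))
        assert frameshift_counts(cs, self.regions) == (2, 1)

    def test_region_restriction_and_monotonicity(self):
        cs = Callset([
            _site(10, [(0, 1)], ref="AC", alts=("A",)),
            _site(200, [(0, 1)], ref="AC", alts=("A",)),
        ], sample_ids=("s1",))
        small = frameshift_counts(cs, [GenomicInterval("chr1", 0, 100)])
        large = frameshift_counts(cs, [GenomicInterval("chr1", 0, 100),
                                       GenomicInterval("chr1", 150, 300)])
        assert small == (1, 0)
        assert large == (2, 0)
        assert large[0] >= small[0] and large[1] >= small[1]

    def test_empty_regions_rejected(self):
        cs = Callset([_site(10, [(0, 1)])], sample_ids=("s1",))
        with pytest.raises(ValueError):
            frameshift_counts(cs, [])

    def test_random_cohort_matches_mod3_overlap_scan(self):
        rng = np.random.default_rng(31)
        cs = _random_cohort(rng, n_sites=80, p_indel=0.6)
        regions = [GenomicInterval("chr1", 100, 400),
                   GenomicInterval("chr1", 500, 700)]
        expected_pos, expected_hom = set(), set()
        for rec in cs:
            if len(rec.ref) == len(rec.alts[0]):
                continue
            if abs(len(rec.ref) - len(rec.alts[0])) % 3 == 0:
                continue
            if not any(rec.pos0 < iv.end and rec.end0 > iv.start
                       for iv in regions):
                continue
            if any(1 in gt for gt in rec.genotypes):
                expected_pos.add(rec.pos0)
            if any(gt == (1, 1) for gt in rec.genotypes):
                expected_hom.add(rec.pos0)
        assert frameshift_counts(cs, regions) == (len(expected_pos),
                                                  len(expected_hom))

    def test_is_frameshift_table(self):
        assert is_frameshift("AC", "A")        # 1-bp del
        assert is_frameshift("A", "ACC")       # 2-bp ins
        assert not is_frameshift("ACCC", "A")  # 3-bp del
        assert not is_frameshift("A", "G")     # substitution


class TestFrequencyBinStats:
    def test_wrapper_consistent_with_parts(self):
        rng = np.random.default_rng(3)
        cs = _random_cohort(rng, n_sites=40, n_samples=8)
        stats = frequency_bin_stats(cs, k=8)
        cohort = CohortMatrix(cs)
        bins = call_frequency_bins(cohort, k=8)
        assert stats.homozygous.equals(homozygous_counts(cohort, bins))
        assert stats.titv_hom == titv_by_bin(cohort, bins, "hom")
        assert stats.titv_het == titv_by_bin(cohort, bins, "het")
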