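"""Single-sample benchmarking: TP/FP/FN sets, commonness stratification,
model-specific error analysis and the headline percentage arithmetic.

Calls are compared to a truth set by *haplotype identity* — a call and a
truth record match when spliced into the reference over a shared window they
produce the same sequence — so representation differences (shifted indels,
padding) never create spurious errors.  This is a single-allele comparison,
simpler than full diplotype path search (vcfeval/hap.py style): a variant
with the right allele but the wrong zygosity counts as one false positive
plus one false negative.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import Callset, GenomicInterval, ReferenceSequence, VariantRecord
from .matching import annotate_callset, equivalence_probe, haplotype_equivalent
from .panel import ALL, FrequencyPanel

logger = logging.getLogger(__name__)

#: Panel allele frequency above which a variant is "common" (rare otherwise).
COMMON_AF_THRESHOLD = 0.01

#: Sentinel for a metric whose denominator is empty.
UNDEFINED = None


def round1(x: float) -> float:
    """Round half away from zero to one decimal (printed-percentage style)."""
    return math.floor(abs(x) * 10 + 0.5) / 10 * (1 if x >= 0 else -1)


def _zygosity(rec: VariantRecord, alt_index: int) -> Optional[str]:
    """'hom'/'het' for the first sample's genotype, None when absent."""
    if not rec.genotypes:
        return None
    gt = rec.genotypes[0]
    n = sum(1 for a in gt if a == alt_index + 1)
    if n == 2:
        return "hom"
    if n == 1:
        return "het"
    return None


@dataclass
class ComparisonResult:
    """TP/FP/FN record sets for one callset against one truth set.

    ``tp`` holds the truth-side records of matched pairs (so that
    ``|truth in regions| = |tp| + |fn|``); ``tp_calls`` the corresponding
    call-side records.  ``fp``/``fn`` are call-side / truth-side records.
    """

    tp: list[VariantRecord]
    tp_calls: list[VariantRecord]
    fp: list[VariantRecord]
    fn: list[VariantRecord]
    truth_label: str = ""

    @property
    def n_tp(self) -> int:
        return len(self.tp)

    @property
    def n_fp(self) -> int:
        return len(self.fp)

    @property
    def n_fn(self) -> int:
        return len(self.fn)

    @property
    def n_errors(self) -> int:
        return self.n_fp + self.n_fn

    def precision(self) -> Optional[float]:
        d = self.n_tp + self.n_fp
        return self.n_tp / d if d else UNDEFINED

    def recall(self) -> Optional[float]:
        d = self.n_tp + self.n_fn
        return self.n_tp / d if d else UNDEFINED

    def f1(self) -> Optional[float]:
        p, r = self.precision(), self.recall()
        if p is None or r is None or p + r == 0:
            return UNDEFINED
        return 2 * p * r / (p + r)


def compare_to_truth(
    callset: Callset,
    truth: Callset,
    reference: ReferenceSequence,
    regions: Optional[Sequence[GenomicInterval]] = None,
    match_zygosity: bool = True,
) -> ComparisonResult:
    """Benchmark a callset against a truth set by haplotype identity.

    Both sets are restricted to ``regions`` when given.  Each called ALT is
    matched (greedily, in coordinate order) against unconsumed truth ALTs
    whose splice over the shared window is identical.  With
    ``match_zygosity`` a matched allele with differing zygosity contributes
    the record to both FP and FN.
    """
    call_contigs = {r.contig for r in callset}
    truth_contigs = {r.contig for r in truth}
    if call_contigs and truth_contigs and call_contigs != truth_contigs:
        shared = call_contigs & truth_contigs
        logger.warning(
            "contig sets differ (calls %s vs truth %s); using intersection %s",
            sorted(call_contigs), sorted(truth_contigs), sorted(shared),
        )
        callset = Callset([r for r in callset if r.contig in shared],
                          callset.sample_ids, callset.label)
        truth = Callset([r for r in truth if r.contig in shared],
                        truth.sample_ids, truth.label)
    if regions is not None:
        callset = callset.restrict(regions)
        truth = truth.restrict(regions)

    consumed: set[tuple] = set()  # (truth key, alt index)
    tp: list[VariantRecord] = []
    tp_calls: list[VariantRecord] = []
    fp: list[VariantRecord] = []
    fn_extra: list[VariantRecord] = []

    for call in callset:
        call_alts = _called_alt_indices(call)
        rec_matched_all = True
        zyg_mismatch = False
        for ai in call_alts:
            # search nearby truth records for an identical haplotype
            probe = equivalence_probe(call, reference)
            hit = None
            for trec in truth.query(probe):
                for tj in _called_alt_indices(trec):
                    if (trec.key, tj) in consumed:
                        continue
                    if haplotype_equivalent(
                        call, trec, reference,
                        alt_a=call.alts[ai], alt_b=trec.alts[tj],
                    ):
                        hit = (trec, tj)
                        break
                if hit:
                    break
            if hit is None:
                rec_matched_all = False
                continue
            trec, tj = hit
            consumed.add((trec.key, tj))
            if match_zygosity:
                zc, zt = _zygosity(call, ai), _zygosity(trec, tj)
                if zc is not None and zt is not None and zc != zt:
                    zyg_mismatch = True
                    fn_extra.append(trec)
                    continue
            tp.append(trec)
            tp_calls.append(call)
        if not rec_matched_all or zyg_mismatch:
            fp.append(call)

    fn = list(fn_extra)
    for trec in truth:
        for tj in _called_alt_indices(trec):
            if (trec.key, tj) not in consumed:
                fn.append(trec)
                break
    return ComparisonResult(tp=tp, tp_calls=tp_calls, fp=fp, fn=fn,
                            truth_label=truth.label)


def _called_alt_indices(rec: VariantRecord) -> list[int]:
    """ALT indices carried by the record's first sample (all ALTs if no GT)."""
    if not rec.genotypes:
        return list(range(len(rec.alts)))
    gt = rec.genotypes[0]
    idx = sorted({a - 1 for a in gt if a})
    return idx if idx else []


# ---------------------------------------------------------------------------
# Commonness stratification
# ---------------------------------------------------------------------------

@dataclass
class StratumMetrics:
    n_tp: int
    n_fp: int
    n_fn: int

    def precision(self) -> Optional[float]:
        d = self.n_tp + self.n_fp
        return self.n_tp / d if d else UNDEFINED

    def recall(self) -> Optional[float]:
        d = self.n_tp + self.n_fn
        return self.n_tp / d if d else UNDEFINED

    def f1(self) -> Optional[float]:
        p, r = self.precision(), self.recall()
        if p is None or r is None or p + r == 0:
            return UNDEFINED
        return 2 * p * r / (p + r)


@dataclass
class StratifiedMetrics:
    """Per-(stratum, variant-type) metrics plus mixed-multiallelic exclusions."""

    strata: dict[tuple[str, str], StratumMetrics]
    excluded_multiallelic: dict[str, int]  # per TP/FP/FN
    threshold: float = COMMON_AF_THRESHOLD

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for (stratum, vtype), m in sorted(self.strata.items()):
            rows.append(
                {
                    "stratum": stratum, "type": vtype,
                    "tp": m.n_tp, "fp": m.n_fp, "fn": m.n_fn,
                    "precision": m.precision(), "recall": m.recall(),
                    "f1": m.f1(),
                }
            )
        return pd.DataFrame(rows)


def _commonness(rec: VariantRecord, threshold: float) -> str:
    """'common' / 'rare' / 'mixed' from per-ALT panel AF annotations."""
    if rec.per_alt_af is None:
        raise ValueError(
            f"record {rec.contig}:{rec.pos0} lacks AF annotation; run "
            "annotate_callset first"
        )
    flags = {af > threshold for af in rec.per_alt_af}
    if flags == {True}:
        return "common"
    if flags == {False}:
        return "rare"
    return "mixed"


def _vtype(rec: VariantRecord) -> str:
    return "SNP" if rec.is_snv() else "INDEL"


def stratify_by_commonness(
    comparison: ComparisonResult,
    threshold: float = COMMON_AF_THRESHOLD,
) -> StratifiedMetrics:
    """Split TP/FP/FN into common (AF > threshold) and rare (AF <= threshold).

    Multi-allelic records mixing a common and a rare allele are excluded and
    counted.  TP and FN use truth-side annotations, FP call-side.  Counts
    satisfy common + rare + excluded = total for each of TP/FP/FN.
    """
    counts: dict[tuple[str, str], dict[str, int]] = {}
    excluded = {"tp": 0, "fp": 0, "fn": 0}

    def add(records: Iterable[VariantRecord], what: str) -> None:
        for rec in records:
            stratum = _commonness(rec, threshold)
            if stratum == "mixed":
                excluded[what] += 1
                continue
            key = (stratum, _vtype(rec))
            counts.setdefault(key, {"tp": 0, "fp": 0, "fn": 0})[what] += 1

    add(comparison.tp, "tp")
    add(comparison.fp, "fp")
    add(comparison.fn, "fn")
    strata = {
        key: StratumMetrics(c["tp"], c["fp"], c["fn"])
        for key, c in counts.items()
    }
    return StratifiedMetrics(strata=strata, excluded_multiallelic=excluded,
                             threshold=threshold)


def zero_frequency_recall(comparison: ComparisonResult) -> Optional[float]:
    """Recall restricted to truth variants absent from the panel (all-ALT AF 0).

    Returns the sentinel (None) when no truth variant has zero frequency.
    """
    def is_zero(rec: VariantRecord) -> bool:
        if rec.per_alt_af is None:
            raise ValueError("truth records lack AF annotation")
        return all(af == 0.0 for af in rec.per_alt_af)

    found = sum(1 for r in comparison.tp if is_zero(r))
    missed = sum(1 for r in comparison.fn if is_zero(r))
    total = found + missed
    return found / total if total else UNDEFINED


# ---------------------------------------------------------------------------
# Model-specific (population-resolved vs population-induced) errors
# ---------------------------------------------------------------------------

@dataclass
class ModelSpecificErrors:
    """Errors unique to each of two models benchmarked against one truth set.

    For a baseline model A and a frequency-aware model B, ``a_specific_*``
    are A's errors absent from B (population-resolved when B is the aware
    model) and ``b_specific_*`` B's errors absent from A
    (population-induced).  Errors shared by both models are excluded.
    All records carry panel AF; FPs keep their VAF when present.
    """

    a_specific_fp: list[VariantRecord]
    a_specific_fn: list[VariantRecord]
    b_specific_fp: list[VariantRecord]
    b_specific_fn: list[VariantRecord]


def _haplotype_difference(
    xs: Sequence[VariantRecord],
    ys: Sequence[VariantRecord],
    reference: ReferenceSequence,
) -> list[VariantRecord]:
    """Records of xs with no haplotype-identical record in ys."""
    y_set = Callset(list(ys))
    out = []
    for x in xs:
        probe = equivalence_probe(x, reference)
        if not any(haplotype_equivalent(x, y, reference)
                   for y in y_set.query(probe)):
            out.append(x)
    return out


def model_specific_errors(
    comparison_a: ComparisonResult,
    comparison_b: ComparisonResult,
    freq_panel: FrequencyPanel,
    reference: ReferenceSequence,
    grouping_label: str = ALL,
) -> ModelSpecificErrors:
    """Haplotype-identity set differences of two models' FP/FN sets."""
    if comparison_a.truth_label != comparison_b.truth_label:
        raise ValueError(
            "comparisons were made against different truth sets: "
            f"{comparison_a.truth_label!r} vs {comparison_b.truth_label!r}"
        )

    def annotate(records: list[VariantRecord]) -> list[VariantRecord]:
        cs = annotate_callset(
            Callset(records), freq_panel, reference, grouping_label
        )
        return list(cs.records)

    return ModelSpecificErrors(
        a_specific_fp=annotate(
            _haplotype_difference(comparison_a.fp, comparison_b.fp, reference)),
        a_specific_fn=annotate(
            _haplotype_difference(comparison_a.fn, comparison_b.fn, reference)),
        b_specific_fp=annotate(
            _haplotype_difference(comparison_b.fp, comparison_a.fp, reference)),
        b_specific_fn=annotate(
            _haplotype_difference(comparison_b.fn, comparison_a.fn, reference)),
    )


def rare_fraction(
    error_set: Sequence[VariantRecord],
    threshold: float = COMMON_AF_THRESHOLD,
) -> Optional[float]:
    """Percentage of records that are rare (panel AF <= threshold), 1 decimal.

    A multi-allelic record is rare when its most frequent ALT is rare.
    """
    if not error_set:
        return UNDEFINED
    n_rare = 0
    for rec in error_set:
        if rec.per_alt_af is None:
            raise ValueError("error set lacks AF annotation")
        if max(rec.per_alt_af) <= threshold:
            n_rare += 1
    return round1(100.0 * n_rare / len(error_set))


def common_fraction(
    error_set: Sequence[VariantRecord],
    threshold: float = COMMON_AF_THRESHOLD,
) -> Optional[float]:
    """Percentage of records that are common (panel AF > threshold), 1 decimal."""
    rare = rare_fraction(error_set, threshold)
    return UNDEFINED if rare is None else round1(100.0 - rare)


def error_reduction(
    errors_candidate,
    errors_baseline,
) -> tuple[Optional[int], Optional[float]]:
    """(count, percentage) of errors removed relative to a baseline.

    Arguments may be integer counts or record collections.  The percentage is
    ``100 x (baseline - candidate) / baseline`` rounded half away from zero
    to one decimal; a zero baseline yields the sentinel pair (None, None).
    """
    nc = errors_candidate if isinstance(errors_candidate, int) else len(errors_candidate)
    nb = errors_baseline if isinstance(errors_baseline, int) else len(errors_baseline)
    if nb == 0:
        return (UNDEFINED, UNDEFINED)
    count = nb - nc
    return (count, round1(100.0 * count / nb))
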