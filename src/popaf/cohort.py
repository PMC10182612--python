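"""Cohort-level rare-variant metrics for a multi-sample callset.

Calls are stratified by *call frequency*: the number of cohort samples that
carry at least one copy of an allele (1 = singleton), binned from 1 to K
(default 10).  Within each bin the module tallies per-sample homozygous
calls, per-sample calls matching a flagged-site list (e.g. pathogenic
annotations), transition:transversion ratios by zygosity, and frameshift
indel positions restricted to regions of interest.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .model import Callset, GenomicInterval, ReferenceSequence, VariantRecord
from .matching import equivalence_probe, haplotype_equivalent

logger = logging.getLogger(__name__)

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})

#: An allele unit: one ALT allele of one cohort site.
AlleleUnit = tuple[tuple, int]  # (record key, alt index)


class CohortMatrix:
    """Per-allele carrier and homozygote sets over a multi-sample callset."""

    def __init__(self, callset: Callset):
        if not callset.sample_ids:
            raise ValueError("cohort callset has no samples")
        self.callset = callset
        self.samples = callset.sample_ids
        self.records: dict[tuple, VariantRecord] = {r.key: r for r in callset}
        self.carriers: dict[AlleleUnit, set[str]] = {}
        self.homozygotes: dict[AlleleUnit, set[str]] = {}
        for rec in callset:
            if rec.genotypes is None:
                continue
            for ai in range(len(rec.alts)):
                unit = (rec.key, ai)
                carr, hom = set(), set()
                for s, gt in zip(self.samples, rec.genotypes):
                    n = sum(1 for a in gt if a == ai + 1)
                    if n >= 1:
                        carr.add(s)
                    if n == 2:
                        hom.add(s)
                if carr:
                    self.carriers[unit] = carr
                    if hom:
                        self.homozygotes[unit] = hom

    def call_frequency(self, unit: AlleleUnit) -> int:
        """Number of samples carrying >= 1 copy of the allele."""
        return len(self.carriers.get(unit, ()))

    def record(self, unit: AlleleUnit) -> VariantRecord:
        return self.records[unit[0]]

    def alt(self, unit: AlleleUnit) -> str:
        return self.record(unit).alts[unit[1]]


def call_frequency_bins(
    cohort: CohortMatrix, k: int = 10
) -> dict[int, list[AlleleUnit]]:
    """Assign each called allele to bin = its call frequency, for bins 1..K.

    Alleles carried by more than K samples fall outside the rare-call range
    and are excluded.
    """
    bins: dict[int, list[AlleleUnit]] = {b: [] for b in range(1, k + 1)}
    for unit in sorted(cohort.carriers):
        freq = cohort.call_frequency(unit)
        if 1 <= freq <= k:
            bins[freq].append(unit)
    return bins


def homozygous_counts(
    cohort: CohortMatrix, bins: dict[int, list[AlleleUnit]]
) -> pd.DataFrame:
    """Long-format (bin, sample, count) table of homozygous calls per bin."""
    rows = []
    for b, units in sorted(bins.items()):
        per_sample = {s: 0 for s in cohort.samples}
        for unit in units:
            for s in cohort.homozygotes.get(unit, ()):
                per_sample[s] += 1
        for s in cohort.samples:
            rows.append({"bin": b, "sample": s, "count": per_sample[s]})
    return pd.DataFrame(rows, columns=["bin", "sample", "count"])


def flagged_counts(
    cohort: CohortMatrix,
    bins: dict[int, list[AlleleUnit]],
    flag_sites: Callset,
    reference: ReferenceSequence,
) -> pd.DataFrame:
    """Per-sample, per-bin counts of calls matching a flagged-site callset.

    Flag matching is by haplotype identity, so a flagged variant recorded in
    a different representation still counts.
    """
    rows = []
    for b, units in sorted(bins.items()):
        per_sample = {s: 0 for s in cohort.samples}
        for unit in units:
            rec = cohort.record(unit)
            probe = equivalence_probe(rec, reference)
            flagged = any(
                haplotype_equivalent(rec, f, reference, alt_a=cohort.alt(unit))
                for f in flag_sites.query(probe)
            )
            if not flagged:
                continue
            for s in cohort.carriers[unit]:
                per_sample[s] += 1
        for s in cohort.samples:
            rows.append({"bin": b, "sample": s, "count": per_sample[s]})
    return pd.DataFrame(rows, columns=["bin", "sample", "count"])


def titv_ratio(
    snvs: Sequence[tuple[str, str]] | Sequence[VariantRecord],
) -> Optional[float]:
    """Transitions / transversions over (ref, alt) base pairs or SNV records.

    Non-SNV inputs are skipped with a log message; zero transversions yield
    the sentinel (None).
    """
    ti = tv = 0
    n_skipped = 0
    for item in snvs:
        if isinstance(item, VariantRecord):
            if not item.is_snv():
                n_skipped += 1
                continue
            pairs = [(item.ref, a) for a in item.alts]
        else:
            pairs = [item]
        for ref, alt in pairs:
            if len(ref) != 1 or len(alt) != 1:
                n_skipped += 1
                continue
            if (ref, alt) in TRANSITIONS:
                ti += 1
            else:
                tv += 1
    if n_skipped:
        logger.debug("titv_ratio skipped %d non-SNV allele(s)", n_skipped)
    return ti / tv if tv else None


def titv_by_bin(
    cohort: CohortMatrix,
    bins: dict[int, list[AlleleUnit]],
    zygosity: str = "hom",
    mode: str = "per_sample_mean",
) -> dict[int, Optional[float]]:
    """Ti:Tv per bin for homozygous or heterozygous SNV calls.

    ``per_sample_mean`` (default) computes a ratio per sample then averages
    over samples with a defined ratio; ``pooled`` aggregates all calls in
    the bin.
    """
    if zygosity not in ("hom", "het"):
        raise ValueError("zygosity must be 'hom' or 'het'")
    if mode not in ("per_sample_mean", "pooled"):
        raise ValueError("mode must be 'per_sample_mean' or 'pooled'")
    out: dict[int, Optional[float]] = {}
    for b, units in sorted(bins.items()):
        snv_units = [
            u for u in units
            if cohort.record(u).is_snv(cohort.alt(u))
        ]

        def unit_samples(u: AlleleUnit) -> set[str]:
            hom = cohort.homozygotes.get(u, set())
            return hom if zygosity == "hom" else cohort.carriers[u] - hom

        if mode == "pooled":
            pairs = []
            for u in snv_units:
                rec = cohort.record(u)
                pairs.extend((rec.ref, cohort.alt(u)) for _ in unit_samples(u))
            out[b] = titv_ratio(pairs)
        else:
            ratios = []
            for s in cohort.samples:
                pairs = [
                    (cohort.record(u).ref, cohort.alt(u))
                    for u in snv_units if s in unit_samples(u)
                ]
                r = titv_ratio(pairs)
                if r is not None:
                    ratios.append(r)
            out[b] = sum(ratios) / len(ratios) if ratios else None
    return out


@dataclass
class FrequencyBinStats:
    """All Fig-5-style per-bin statistics for one cohort callset."""

    k: int
    bins: dict[int, list[AlleleUnit]]
    homozygous: pd.DataFrame           # (bin, sample, count)
    flagged: Optional[pd.DataFrame]    # (bin, sample, count) or None
    titv_hom: dict[int, Optional[float]]
    titv_het: dict[int, Optional[float]]


def frequency_bin_stats(
    callset: Callset,
    k: int = 10,
    flag_sites: Optional[Callset] = None,
    reference: Optional[ReferenceSequence] = None,
    titv_mode: str = "per_sample_mean",
) -> FrequencyBinStats:
    """One-call convenience wrapper computing every per-bin statistic."""
    cohort = CohortMatrix(callset)
    bins = call_frequency_bins(cohort, k)
    flagged = None
    if flag_sites is not None:
        if reference is None:
            raise ValueError("flag matching requires a reference")
        flagged = flagged_counts(cohort, bins, flag_sites, reference)
    return FrequencyBinStats(
        k=k,
        bins=bins,
        homozygous=homozygous_counts(cohort, bins),
        flagged=flagged,
        titv_hom=titv_by_bin(cohort, bins, "hom", titv_mode),
        titv_het=titv_by_bin(cohort, bins, "het", titv_mode),
    )


def is_frameshift(ref: str, alt: str) -> bool:
    """An indel shifts the reading frame iff its length change is not a
    multiple of 3 (length-preserving alleles are not indels)."""
    d = abs(len(ref) - len(alt))
    return d % 3 != 0


def frameshift_counts(
    callset: Callset,
    regions: Sequence[GenomicInterval],
) -> tuple[int, int]:
    """(positions with a frameshift indel call, homozygous subset).

    Positions are distinct (contig, pos0) whose reference span intersects the
    regions and where at least one called frameshift allele exists; the
    homozygous subset counts positions where some sample is homozygous for
    such an allele.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    cohort = CohortMatrix(callset)
    positions: set[tuple[str, int]] = set()
    hom_positions: set[tuple[str, int]] = set()
    for unit, carriers in cohort.carriers.items():
        rec = cohort.record(unit)
        alt = cohort.alt(unit)
        if not is_frameshift(rec.ref, alt):
            continue
        if not any(rec.span.overlaps(iv) for iv in regions):
            continue
        positions.add((rec.contig, rec.pos0))
        if cohort.homozygotes.get(unit):
            hom_positions.add((rec.contig, rec.pos0))
    return len(positions), len(hom_positions)
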