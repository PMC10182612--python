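"""Population-stratified allele frequencies from a multi-sample panel.

The panel plays the role of a population reference callset (1000Genomes-style):
per-site, per-population alternate-allele frequencies computed from genotypes
with every missing genotype filled as homozygous reference, so that all sites
share the same denominator ``ploidy x n_members`` (the missing2ref convention).
Counts are kept as exact rationals; floats are derived views.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence, Union

from .model import Callset, GenomicInterval, SampleMetadata, VariantRecord

logger = logging.getLogger(__name__)

#: Grouping label covering every panel sample.
ALL = "ALL"


@dataclass(frozen=True)
class PopulationGrouping:
    """A named subset of panel samples (e.g. one superpopulation)."""

    label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"grouping {self.label!r} has no members")


class FrequencyPanel:
    """Interval-queryable panel with per-grouping allele counts/frequencies."""

    def __init__(
        self,
        callset: Callset,
        counts: Mapping[tuple, Mapping[str, tuple[int, ...]]],
        denominators: Mapping[str, int],
        ploidy: int = 2,
    ):
        self.callset = callset
        self._counts = {k: dict(v) for k, v in counts.items()}
        self.denominators = dict(denominators)
        self.ploidy = ploidy
        self.n_samples = len(callset.sample_ids)

    @property
    def grouping_labels(self) -> tuple[str, ...]:
        return tuple(self.denominators)

    def query_overlapping(self, interval: GenomicInterval) -> list[VariantRecord]:
        """Panel records whose reference span overlaps the half-open interval.

        Insertions occupy their single anchor base.  Unknown contigs yield an
        empty result (logged), not an error.
        """
        hits = self.callset.query(interval)
        if not hits and interval.contig not in {r.contig for r in self.callset}:
            logger.debug("no panel records on contig %s", interval.contig)
        return hits

    def alt_counts(self, record: VariantRecord, label: str = ALL) -> tuple[int, ...]:
        return self._counts[record.key][label]

    def af_fractions(self, record: VariantRecord, label: str = ALL) -> tuple[Fraction, ...]:
        denom = self.denominators[label]
        return tuple(Fraction(c, denom) for c in self.alt_counts(record, label))

    def af(self, record: VariantRecord, label: str = ALL) -> list[float]:
        return [float(f) for f in self.af_fractions(record, label)]

    def ref_frequency(self, record: VariantRecord, label: str = ALL) -> Fraction:
        return 1 - sum(self.af_fractions(record, label), Fraction(0))


def _tally(
    record: VariantRecord,
    sample_index: Mapping[str, int],
    members: Iterable[str],
) -> tuple[int, ...]:
    """Alternate-allele tallies over members, missing alleles counted as REF."""
    counts = [0] * len(record.alts)
    gts = record.genotypes
    for s in members:
        gt = gts[sample_index[s]]
        for a in gt:
            if a:  # None (missing -> ref) and 0 both contribute to REF
                counts[a - 1] += 1
    return tuple(counts)


def compute_frequencies(
    panel_callset: Callset,
    groupings: Union[None, Mapping[str, Iterable[str]], Sequence[PopulationGrouping]] = None,
    sample_map: Optional[SampleMetadata] = None,
    ploidy: int = 2,
    af_tag_tolerance: float = 1e-6,
) -> FrequencyPanel:
    """Compute per-grouping allele frequencies with missing genotypes as reference.

    ``AF(alt) = alt count among members / (ploidy x n_members)`` so every site
    in a grouping shares one denominator.  The ``ALL`` grouping over every
    panel sample is always present.  When ``sample_map`` is given, one
    grouping per superpopulation label is added.  Records that carry AF INFO
    tags but no genotypes are accepted for the ``ALL`` grouping only; when
    both are present genotypes win and discrepancies above
    ``af_tag_tolerance`` are logged.
    """
    if ploidy != 2:
        raise ValueError("ploidy is fixed at 2; non-diploid panels are not supported")
    samples = panel_callset.sample_ids
    has_genotypes = bool(samples) and any(
        r.genotypes is not None for r in panel_callset
    )

    if not has_genotypes:
        # AF-tag-only panel: frequencies are taken at face value for ALL.
        counts: dict[tuple, dict[str, tuple[int, ...]]] = {}
        denom = 10 ** 8  # synthetic denominator for rational bookkeeping
        for rec in panel_callset:
            if rec.per_alt_af is None:
                raise ValueError(
                    f"panel record {rec.contig}:{rec.pos0} has neither genotypes "
                    "nor AF INFO"
                )
            counts[rec.key] = {ALL: tuple(round(a * denom) for a in rec.per_alt_af)}
        return FrequencyPanel(panel_callset, counts, {ALL: denom}, ploidy=ploidy)

    group_map: dict[str, set[str]] = {ALL: set(samples)}
    if groupings is not None:
        if isinstance(groupings, Mapping):
            items = [(lab, set(mem)) for lab, mem in groupings.items()]
        else:
            items = [(g.label, set(g.members)) for g in groupings]
        for lab, mem in items:
            missing = sorted(mem - set(samples))
            if missing:
                raise KeyError(
                    f"grouping {lab!r} members absent from panel: {missing}"
                )
            group_map[lab] = mem
    if sample_map is not None:
        missing = sorted(set(samples) - set(sample_map.samples))
        if missing:
            raise KeyError(f"panel samples absent from sample map: {missing}")
        for lab in sample_map.labels("superpopulation"):
            mem = sample_map.members(lab) & set(samples)
            if mem:
                group_map.setdefault(lab, mem)

    sample_index = {s: i for i, s in enumerate(samples)}
    denominators = {lab: ploidy * len(mem) for lab, mem in group_map.items()}
    counts = {}
    for rec in panel_callset:
        if rec.genotypes is None:
            raise ValueError(
                f"panel record {rec.contig}:{rec.pos0} lacks genotypes"
            )
        per_label = {
            lab: _tally(rec, sample_index, mem) for lab, mem in group_map.items()
        }
        counts[rec.key] = per_label
        if rec.per_alt_af is not None:
            computed = [c / denominators[ALL] for c in per_label[ALL]]
            for tag, got in zip(rec.per_alt_af, computed):
                if abs(tag - got) > af_tag_tolerance:
                    logger.warning(
                        "AF tag %.6g disagrees with genotype-derived %.6g at %s:%d",
                        tag, got, rec.contig, rec.pos0,
                    )
    return FrequencyPanel(panel_callset, counts, denominators, ploidy=ploidy)


def exclude_samples(
    panel_callset: Callset,
    exclude: Union[str, Iterable[str]],
    sample_map: Optional[SampleMetadata] = None,
    level: str = "population",
) -> Callset:
    """Drop samples (by id, or by population label via ``sample_map``).

    Returns a new panel callset; recomputing frequencies on it shrinks every
    denominator by ``ploidy x n_removed`` for the affected groupings.
    """
    samples = set(panel_callset.sample_ids)
    if isinstance(exclude, str):
        if exclude in samples:
            drop = {exclude}
        elif sample_map is not None:
            drop = sample_map.members(exclude, level=level) & samples
            if not drop:
                drop = sample_map.members(exclude, level="superpopulation") & samples
            if not drop:
                raise KeyError(f"no panel samples match label {exclude!r}")
        else:
            raise KeyError(f"unknown sample or label {exclude!r}")
    else:
        drop = set(exclude)
        unknown = sorted(drop - samples)
        if unknown:
            raise KeyError(f"samples not in panel: {unknown}")
    keep = [s for s in panel_callset.sample_ids if s not in drop]
    if not keep:
        raise ValueError("cannot exclude every panel sample")
    return panel_callset.subset_samples(keep)
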