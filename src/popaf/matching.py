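"""Haplotype-based allele matching against a population panel.

A candidate variant and a panel variant may describe the same sequence change
with different literal VCF records (shifted within a repeat run, padded with
shared bases, MNP vs padded SNP).  Normalisers such as left-alignment do not
resolve every such case, so matching here is done on spliced local
haplotypes: both alleles are substituted into the reference over a shared
window and compared as raw strings.

The procedure for one candidate ``v``:

1. query all panel variants overlapping the candidate's repeat-homology
   span (its span ``[v_start, v_end)`` widened across the repeat context
   its indel alleles can shift over) — this is the cohort set ``V_C``;
2. form ``V = {v} | V_C`` and extend the window once to
   ``[min start over V, max end over V)``;
3. splice each candidate ALT and each cohort ALT into the reference over the
   extended window; an exact string match transfers the cohort allele's
   frequency to the candidate ALT.

Unmatched candidate ALTs get frequency 0.0.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .model import (
    AlignedRead,
    Callset,
    GenomicInterval,
    ReferenceSequence,
    VariantRecord,
)
from .panel import ALL, FrequencyPanel

logger = logging.getLogger(__name__)


@dataclass
class CandidateContext:
    """A candidate variant with its queried cohort set and extended window."""

    candidate: VariantRecord
    cohort: tuple[VariantRecord, ...]
    initial_window: GenomicInterval
    extended_window: GenomicInterval

    @property
    def variants(self) -> tuple[VariantRecord, ...]:
        return (self.candidate, *self.cohort)


@dataclass(frozen=True)
class HaplotypeSeq:
    """A window and the sequence obtained by splicing one allele into it."""

    window: GenomicInterval
    sequence: str


class AlleleFrequencyDict(dict):
    """candidate ALT allele -> matched panel frequency (0.0 when unmatched)."""

    def __init__(self, candidate: VariantRecord, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.candidate = candidate
        for alt in candidate.alts:
            self.setdefault(alt, 0.0)


def extend_window(
    candidate: VariantRecord,
    cohort_variants: Sequence[VariantRecord],
) -> GenomicInterval:
    """Single-pass window extension over ``V = {candidate} | cohort``.

    Returns [min start, max end) over all spans in V; with an empty cohort
    this is the candidate's own span.  No re-query is performed after the
    extension.
    """
    starts = [candidate.pos0] + [u.pos0 for u in cohort_variants]
    ends = [candidate.end0] + [u.end0 for u in cohort_variants]
    return GenomicInterval(candidate.contig, min(starts), max(ends))


def homology_span(
    variant: VariantRecord,
    reference: ReferenceSequence,
    max_shift: int = 64,
) -> GenomicInterval:
    """The candidate span extended over the variant's repeat-homology range.

    An indel inside a repeat run admits several literal records at shifted
    anchor positions that all splice to the same haplotype.  This walks the
    anchor one base at a time in each direction, keeping a step only when
    the shifted record is splice-identical, and returns the union of spans.
    For variants with no shiftable representation (SNVs, indels out of
    repeat context) this is exactly the variant's own span.
    """
    lo, hi = variant.pos0, variant.end0
    contig_len = reference.length(variant.contig)
    seq = reference.sequence(variant.contig)
    for alt in variant.alts:
        if len(alt) == len(variant.ref):
            continue
        for direction in (-1, +1):
            pos = variant.pos0
            for _ in range(max_shift):
                new_pos = pos + direction
                if new_pos < 0 or new_pos + len(variant.ref) > contig_len:
                    break
                new_ref = seq[new_pos:new_pos + len(variant.ref)]
                if len(alt) < len(variant.ref):
                    new_alt = new_ref[:len(alt)]
                else:
                    new_alt = new_ref + alt[len(variant.ref):]
                if new_alt == new_ref:
                    break
                shifted = VariantRecord(variant.contig, new_pos, new_ref, (new_alt,))
                if not haplotype_equivalent(variant, shifted, reference,
                                            alt_a=alt, alt_b=new_alt):
                    break
                pos = new_pos
                lo = min(lo, new_pos)
                hi = max(hi, new_pos + len(variant.ref))
    return GenomicInterval(variant.contig, lo, hi)


def equivalence_probe(
    variant: VariantRecord,
    reference: ReferenceSequence,
) -> GenomicInterval:
    """Interval guaranteed to overlap every record splice-equivalent to
    ``variant``: its repeat-homology span padded by one base each side."""
    span = homology_span(variant, reference)
    return GenomicInterval(
        variant.contig,
        max(0, span.start - 1),
        min(reference.length(variant.contig), span.end + 1),
    )


def build_context(
    candidate: VariantRecord,
    freq_panel: FrequencyPanel,
    reference: Optional[ReferenceSequence] = None,
    iterative: bool = False,
    max_rounds: int = 8,
) -> CandidateContext:
    """Query the cohort set for a candidate and extend the window.

    The query interval is the candidate's repeat-homology span (see
    :func:`homology_span`) when a reference is given, so that panel records
    holding a shifted representation of the same indel are found; for
    left-normalised inputs this equals the candidate's own span.  The
    procedure is single-pass by default: query once, extend once.
    ``iterative=True`` re-queries over the extended window until a fixed
    point (variants newly dragged into an extended window then also
    participate).
    """
    initial = (homology_span(candidate, reference)
               if reference is not None else candidate.span)
    cohort = tuple(freq_panel.query_overlapping(initial))
    window = extend_window(candidate, cohort)
    if iterative:
        for _ in range(max_rounds):
            more = tuple(freq_panel.query_overlapping(window))
            new_window = extend_window(candidate, more)
            if new_window == window and len(more) == len(cohort):
                break
            cohort, window = more, new_window
    return CandidateContext(candidate, cohort, initial, window)


def build_haplotype(
    reference: ReferenceSequence,
    window: GenomicInterval,
    variant: VariantRecord,
    allele: str,
) -> HaplotypeSeq:
    """Splice one allele of one variant into the reference over a window.

    sequence = ref[window.start : pos0] + allele + ref[variant end : window.end]
    """
    if variant.contig != window.contig:
        raise ValueError("variant and window are on different contigs")
    if not window.contains(variant.span):
        raise ValueError(
            f"variant span {variant.span} exceeds window {window}; "
            "extend the window first"
        )
    if allele != variant.ref and allele not in variant.alts:
        raise ValueError(f"allele {allele!r} is not an allele of the variant")
    left = reference.fetch(GenomicInterval(window.contig, window.start, variant.pos0))
    right = reference.fetch(GenomicInterval(window.contig, variant.end0, window.end))
    return HaplotypeSeq(window, left + allele + right)


def match_alleles(
    candidate: VariantRecord,
    freq_panel: FrequencyPanel,
    reference: ReferenceSequence,
    grouping_label: str = ALL,
    iterative: bool = False,
) -> AlleleFrequencyDict:
    """Match each candidate ALT to panel alleles by exact haplotype identity.

    Haplotypes are built one variant-allele at a time (no combined
    multi-variant haplotypes).  When several cohort alleles match one
    candidate ALT, the maximum frequency is kept and the collision is logged
    — the duplicates describe one physical haplotype, so frequencies are not
    summed.
    """
    ctx = build_context(candidate, freq_panel, reference, iterative=iterative)
    window = ctx.extended_window
    result = AlleleFrequencyDict(candidate)
    if not ctx.cohort:
        return result
    cohort_haps: list[tuple[str, float]] = []
    for cv in ctx.cohort:
        freqs = freq_panel.af(cv, grouping_label)
        for alt, af in zip(cv.alts, freqs):
            hap = build_haplotype(reference, window, cv, alt)
            cohort_haps.append((hap.sequence, af))
    for alt in candidate.alts:
        hap = build_haplotype(reference, window, candidate, alt)
        matches = [af for seq, af in cohort_haps if seq == hap.sequence]
        if not matches:
            continue
        if len(matches) > 1:
            logger.info(
                "%d cohort alleles share one haplotype at %s:%d; keeping max AF",
                len(matches), candidate.contig, candidate.pos0,
            )
        result[alt] = max(matches)
    return result


def supported_allele(read: AlignedRead, candidate: VariantRecord) -> Optional[str]:
    """The allele string a read carries over the candidate's reference span.

    ``None`` when the read does not fully cover the span.
    """
    if read.contig != candidate.contig:
        return None
    return read.query_segment(candidate.pos0, candidate.end0)


def annotate_reads(
    reads: Sequence[AlignedRead],
    candidate: VariantRecord,
    af_dict: AlleleFrequencyDict,
) -> dict[str, float]:
    """Per-read allele frequency at the candidate site.

    A read carrying a matched ALT gets that ALT's dictionary frequency; a
    reference-supporting read gets ``max(0, 1 - sum of matched ALT AFs)``;
    a read carrying any other allele gets 0.0.  Reads that do not overlap
    the candidate span are skipped (logged).
    """
    ref_freq = max(0.0, 1.0 - sum(af_dict[a] for a in candidate.alts))
    out: dict[str, float] = {}
    for read in reads:
        allele = supported_allele(read, candidate)
        if allele is None:
            logger.debug("read %s does not cover candidate %s:%d; skipped",
                         read.name, candidate.contig, candidate.pos0)
            continue
        if allele == candidate.ref:
            out[read.name] = ref_freq
        elif allele in af_dict:
            out[read.name] = af_dict[allele]
        else:
            out[read.name] = 0.0
    return out


def annotate_callset(
    callset: Callset,
    freq_panel: FrequencyPanel,
    reference: ReferenceSequence,
    grouping_label: str = ALL,
    iterative: bool = False,
) -> Callset:
    """Fill ``per_alt_af`` on every record via :func:`match_alleles`."""
    n_matched = n_zero = 0
    records = []
    for rec in callset:
        af_dict = match_alleles(
            rec, freq_panel, reference,
            grouping_label=grouping_label, iterative=iterative,
        )
        afs = [af_dict[a] for a in rec.alts]
        if any(a > 0 for a in afs):
            n_matched += 1
        else:
            n_zero += 1
        records.append(
            VariantRecord(
                rec.contig, rec.pos0, rec.ref, rec.alts,
                genotypes=rec.genotypes, qual=rec.qual,
                per_alt_af=afs,
                per_alt_vaf=list(rec.per_alt_vaf) if rec.per_alt_vaf else None,
            )
        )
    logger.info(
        "annotated %d records (%d with a panel match, %d all-zero) [%s]",
        len(records), n_matched, n_zero, grouping_label,
    )
    return Callset(records, sample_ids=callset.sample_ids, label=callset.label)


def haplotype_equivalent(
    a: VariantRecord,
    b: VariantRecord,
    reference: ReferenceSequence,
    alt_a: Optional[str] = None,
    alt_b: Optional[str] = None,
) -> bool:
    """Do two records (or two specific ALTs) describe the same sequence change?

    Both alleles are spliced into the reference over the union window padded
    by one base on each side and compared as strings.
    """
    if a.contig != b.contig:
        return False
    start = max(0, min(a.pos0, b.pos0) - 1)
    end = min(reference.length(a.contig), max(a.end0, b.end0) + 1)
    window = GenomicInterval(a.contig, start, end)
    alts_a = (alt_a,) if alt_a is not None else a.alts
    alts_b = (alt_b,) if alt_b is not None else b.alts
    for aa in alts_a:
        hap_a = build_haplotype(reference, window, a, aa).sequence
        if any(
            build_haplotype(reference, window, b, bb).sequence == hap_a
            for bb in alts_b
        ):
            return True
    return False
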