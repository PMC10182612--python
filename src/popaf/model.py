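"""Core domain types: intervals, variants, reads, references, callsets.

All coordinates inside the package are 0-based half-open. Conversion to and
from VCF's 1-based convention happens only in :mod:`popaf.vcfio`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_DNA = frozenset("ACGT")

#: Continental-level superpopulation labels used for panel stratification.
SUPERPOPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic window [start, end) on one contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not (0 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "need 0 <= start <= end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap test; intervals sharing only a boundary do not overlap."""
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )


def _check_allele(allele: str, what: str) -> str:
    if not allele:
        raise ValueError(f"{what} allele must be non-empty")
    up = allele.upper()
    if not set(up) <= _DNA:
        raise ValueError(f"{what} allele {allele!r} contains non-ACGT characters")
    return up


#: A diploid genotype: two allele indices, ``None`` marking a missing allele.
Genotype = tuple[Optional[int], Optional[int]]


@dataclass
class VariantRecord:
    """One variant site: a reference allele and one or more alternates.

    ``pos0`` is the 0-based start of the reference allele; the record's
    reference span is ``[pos0, pos0 + len(ref))``.  Insertions therefore
    occupy the single base that anchors them.  ``genotypes`` holds one
    diploid allele-index pair per sample (``None`` = missing allele);
    ``per_alt_af`` / ``per_alt_vaf`` carry one value per alternate allele.
    """

    contig: str
    pos0: int
    ref: str
    alts: tuple[str, ...]
    genotypes: Optional[tuple[Genotype, ...]] = None
    qual: Optional[float] = None
    per_alt_af: Optional[list[float]] = None
    per_alt_vaf: Optional[list[float]] = None

    def __post_init__(self) -> None:
        if self.pos0 < 0:
            raise ValueError("pos0 must be >= 0")
        self.ref = _check_allele(self.ref, "REF")
        alts = tuple(_check_allele(a, "ALT") for a in self.alts)
        if any(a == self.ref for a in alts):
            raise ValueError(f"ALT equal to REF at {self.contig}:{self.pos0}")
        if len(set(alts)) != len(alts):
            raise ValueError(f"duplicate ALT alleles at {self.contig}:{self.pos0}")
        self.alts = alts
        for name, vals in (("per_alt_af", self.per_alt_af),
                           ("per_alt_vaf", self.per_alt_vaf)):
            if vals is not None:
                if len(vals) != len(alts):
                    raise ValueError(f"{name} needs one entry per ALT")
                if any(not (0.0 <= v <= 1.0) for v in vals):
                    raise ValueError(f"{name} values must lie in [0, 1]")
        if self.genotypes is not None:
            self.genotypes = tuple(tuple(gt) for gt in self.genotypes)
            for gt in self.genotypes:
                if len(gt) != 2:
                    raise ValueError("only diploid genotypes are supported")
                for a in gt:
                    if a is not None and not (0 <= a <= len(alts)):
                        raise ValueError(f"allele index {a} out of range")

    # Identity used for set algebra: the literal site representation.
    # Haplotype-aware (representation-insensitive) comparison lives in
    # popaf.matching and popaf.evaluation.
    @property
    def key(self) -> tuple[str, int, str, tuple[str, ...]]:
        return (self.contig, self.pos0, self.ref, self.alts)

    def __hash__(self) -> int:
        return hash(self.key)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantRecord):
            return NotImplemented
        return self.key == other.key

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.pos0, self.pos0 + len(self.ref))

    @property
    def end0(self) -> int:
        return self.pos0 + len(self.ref)

    def is_snv(self, alt: Optional[str] = None) -> bool:
        alts = (alt,) if alt is not None else self.alts
        return len(self.ref) == 1 and all(len(a) == 1 for a in alts)

    def is_indel(self, alt: Optional[str] = None) -> bool:
        alts = (alt,) if alt is not None else self.alts
        return any(len(a) != len(self.ref) for a in alts)

    def allele(self, index: int) -> str:
        """Allele sequence by genotype index (0 = REF, 1.. = ALTs)."""
        return self.ref if index == 0 else self.alts[index - 1]


class ReferenceSequence:
    """In-memory reference genome: contig name -> uppercase sequence."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for contig, seq in sequences.items():
            up = seq.upper()
            if not set(up) <= _DNA | {"N"}:
                raise ValueError(f"contig {contig} contains non-ACGTN characters")
            self._seqs[contig] = up

    @classmethod
    def from_fasta(cls, path) -> "ReferenceSequence":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def contigs(self) -> tuple[str, ...]:
        return tuple(self._seqs)

    def length(self, contig: str) -> int:
        return len(self._seqs[contig])

    def sequence(self, contig: str) -> str:
        return self._seqs[contig]

    def fetch(self, interval: GenomicInterval) -> str:
        seq = self._seqs.get(interval.contig)
        if seq is None:
            raise KeyError(f"unknown contig {interval.contig!r}")
        if interval.end > len(seq):
            raise ValueError(
                f"fetch {interval.contig}:{interval.start}-{interval.end} "
                f"beyond contig end {len(seq)}"
            )
        return seq[interval.start:interval.end]


#: Alignment ops: M consumes reference and query, I query only, D reference only.
CigarOp = tuple[str, int]


@dataclass
class AlignedRead:
    """A gapless-or-simply-gapped aligned read (M/I/D runs only)."""

    name: str
    contig: str
    start0: int
    ops: tuple[CigarOp, ...]
    bases: str
    base_quals: tuple[int, ...]
    mapq: int = 60
    strand: str = "+"

    def __post_init__(self) -> None:
        self.ops = tuple((op, int(n)) for op, n in self.ops)
        for op, n in self.ops:
            if op not in "MID" or n <= 0:
                raise ValueError(f"bad alignment op {(op, n)!r}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        self.bases = self.bases.upper()
        self.base_quals = tuple(self.base_quals)
        qlen = sum(n for op, n in self.ops if op in "MI")
        if qlen != len(self.bases):
            raise ValueError(
                f"ops consume {qlen} query bases but read has {len(self.bases)}"
            )
        if len(self.base_quals) != len(self.bases):
            raise ValueError("one base quality per base required")

    @property
    def reference_length(self) -> int:
        return sum(n for op, n in self.ops if op in "MD")

    @property
    def end0(self) -> int:
        return self.start0 + self.reference_length

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.start0, self.end0)

    def query_segment(self, start: int, end: int) -> Optional[str]:
        """Read bases aligned to reference window [start, end).

        Includes insertions anchored strictly inside the window (an ``I`` op
        following reference position ``p`` is included iff start <= p < end),
        so the segment of a read carrying an insertion/deletion reproduces the
        alternate allele string.  Returns ``None`` when the read does not
        fully cover the window.
        """
        if start < self.start0 or end > self.end0 or start >= end:
            return None
        out: list[str] = []
        rpos = self.start0
        qpos = 0
        for op, n in self.ops:
            if op == "M":
                lo, hi = max(rpos, start), min(rpos + n, end)
                if lo < hi:
                    out.append(self.bases[qpos + (lo - rpos):qpos + (hi - rpos)])
                rpos += n
                qpos += n
            elif op == "I":
                # inserted between reference positions rpos-1 and rpos;
                # keep it iff that gap lies inside [start, end)
                if rpos - 1 >= start and rpos <= end:
                    out.append(self.bases[qpos:qpos + n])
                qpos += n
            else:  # D
                rpos += n
        return "".join(out)


@dataclass(frozen=True)
class SampleMetadata:
    """sample id -> (population, superpopulation) assignments."""

    populations: Mapping[str, str]
    superpopulations: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.populations) != set(self.superpopulations):
            raise ValueError("population and superpopulation maps must share samples")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.populations)

    def members(self, label: str, level: str = "superpopulation") -> set[str]:
        table = self.superpopulations if level == "superpopulation" else self.populations
        return {s for s, lab in table.items() if lab == label}

    def labels(self, level: str = "superpopulation") -> tuple[str, ...]:
        table = self.superpopulations if level == "superpopulation" else self.populations
        return tuple(dict.fromkeys(table.values()))


class Callset:
    """An interval-queryable, sorted collection of variant records."""

    def __init__(
        self,
        records: Iterable[VariantRecord],
        sample_ids: Sequence[str] = (),
        label: str = "",
    ):
        self.records: list[VariantRecord] = sorted(
            records, key=lambda r: (r.contig, r.pos0, r.ref, r.alts)
        )
        self.sample_ids: tuple[str, ...] = tuple(sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.label = label
        for rec in self.records:
            if rec.genotypes is not None and self.sample_ids and \
                    len(rec.genotypes) != len(self.sample_ids):
                raise ValueError(
                    f"record {rec.contig}:{rec.pos0} has {len(rec.genotypes)} "
                    f"genotypes for {len(self.sample_ids)} samples"
                )
        self._trees: Optional[dict[str, IntervalTree]] = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def _index(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for i, rec in enumerate(self.records):
                trees.setdefault(rec.contig, IntervalTree()).addi(
                    rec.pos0, rec.end0, i
                )
            self._trees = trees
        return self._trees

    def query(self, interval: GenomicInterval) -> list[VariantRecord]:
        """Records whose reference span overlaps [start, end), in sorted order."""
        tree = self._index().get(interval.contig)
        if tree is None:
            logger.debug("query on unknown contig %s", interval.contig)
            return []
        hits = sorted(iv.data for iv in tree.overlap(interval.start, interval.end))
        return [self.records[i] for i in hits]

    def subset_samples(self, keep: Sequence[str]) -> "Callset":
        keep = list(keep)
        missing = [s for s in keep if s not in self.sample_ids]
        if missing:
            raise KeyError(f"samples not in callset: {missing}")
        idx = [self.sample_ids.index(s) for s in keep]
        recs = []
        for rec in self.records:
            gts = None
            if rec.genotypes is not None:
                gts = tuple(rec.genotypes[i] for i in idx)
            recs.append(
                VariantRecord(
                    rec.contig, rec.pos0, rec.ref, rec.alts,
                    genotypes=gts, qual=rec.qual,
                    per_alt_af=list(rec.per_alt_af) if rec.per_alt_af else None,
                    per_alt_vaf=list(rec.per_alt_vaf) if rec.per_alt_vaf else None,
                )
            )
        return Callset(recs, sample_ids=keep, label=self.label)

    def restrict(self, regions: Sequence[GenomicInterval]) -> "Callset":
        """Records whose span overlaps any of the given intervals."""
        keep = []
        for rec in self.records:
            if any(rec.span.overlaps(iv) for iv in regions):
                keep.append(rec)
        return Callset(keep, sample_ids=self.sample_ids, label=self.label)
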