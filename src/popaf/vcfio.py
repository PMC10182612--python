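"""Readers and writers for VCF, BED3, FASTA, SAM and the sample-map TSV.

VCF parsing and writing go through :mod:`pysam`; POS is converted between
VCF's 1-based convention and the package's 0-based half-open coordinates
here and nowhere else.  Symbolic and breakend ALT alleles carry no literal
sequence and are skipped at ingestion (with a logged count), since haplotype
splicing requires concrete alleles.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import pysam

from .model import (
    AlignedRead,
    Callset,
    GenomicInterval,
    ReferenceSequence,
    SampleMetadata,
    VariantRecord,
)

logger = logging.getLogger(__name__)

_LITERAL = frozenset("ACGT")


def _is_literal(allele: Optional[str]) -> bool:
    return bool(allele) and set(allele.upper()) <= _LITERAL


def read_vcf(path, region: Optional[GenomicInterval] = None) -> Callset:
    """Read a VCF into a :class:`Callset`.

    Multi-allelic records are kept as single records.  Records whose ALT
    alleles are all symbolic/breakend are skipped and counted; a literal
    subset of a partly-symbolic record is kept (AF entries subset to match).
    Phase is discarded (``|`` treated as ``/``).
    """
    path = str(path)
    records: list[VariantRecord] = []
    n_symbolic = 0
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF header of {path}: {exc}") from exc
    samples = list(vcf.header.samples)
    for i, rec in enumerate(vcf, start=1):
        try:
            alts = rec.alts or ()
            keep = [j for j, a in enumerate(alts) if _is_literal(a)]
            if not keep or not _is_literal(rec.ref):
                n_symbolic += 1
                continue
            if len(keep) < len(alts):
                n_symbolic += 1  # partly symbolic: symbolic alleles dropped
            kept_alts = tuple(alts[j].upper() for j in keep)

            def _per_alt(key: str) -> Optional[list[float]]:
                if key not in rec.info:
                    return None
                vals = rec.info[key]
                if not isinstance(vals, tuple):
                    vals = (vals,)
                return [float(vals[j]) for j in keep]

            gts = None
            if samples:
                remap = {0: 0}
                remap.update({j + 1: k + 1 for k, j in enumerate(keep)})
                gts = []
                for s in samples:
                    raw = rec.samples[s].get("GT", (None, None))
                    if raw is None:
                        raw = (None, None)
                    if len(raw) == 1:
                        if raw[0] is None:  # "." missing call
                            raw = (None, None)
                        else:
                            raise ValueError(
                                f"non-diploid genotype for sample {s}; ploidy is fixed at 2"
                            )
                    gts.append(tuple(
                        None if a is None else remap.get(a) for a in raw
                    ))
                gts = tuple(gts)
            vr = VariantRecord(
                contig=rec.contig,
                pos0=rec.start,
                ref=rec.ref.upper(),
                alts=kept_alts,
                genotypes=gts,
                qual=rec.qual,
                per_alt_af=_per_alt("AF"),
                per_alt_vaf=_per_alt("VAF"),
            )
        except Exception as exc:
            raise ValueError(f"malformed VCF record #{i} in {path}: {exc}") from exc
        if region is not None and not vr.span.overlaps(region):
            continue
        records.append(vr)
    if n_symbolic:
        logger.info("skipped %d symbolic/structural allele record(s) in %s",
                    n_symbolic, path)
    cs = Callset(records, sample_ids=samples, label=Path(path).stem)
    cs.n_symbolic_skipped = n_symbolic  # type: ignore[attr-defined]
    return cs


def write_vcf(
    callset: Callset,
    path,
    reference: Optional[ReferenceSequence] = None,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write a callset as VCF 4.2 with per-ALT AF/VAF INFO fields."""
    lengths: dict[str, int] = dict(contig_lengths or {})
    if reference is not None:
        for c in reference.contigs:
            lengths.setdefault(c, reference.length(c))
    for rec in callset.records:
        need = rec.end0
        if lengths.get(rec.contig, 0) < need:
            lengths[rec.contig] = need

    header = pysam.VariantHeader()
    for contig, length in lengths.items():
        header.contigs.add(contig, length=length)
    header.info.add("AF", "A", "Float", "Panel allele frequency per ALT allele")
    header.info.add("VAF", "A", "Float",
                    "Variant allele fraction (supporting-read fraction) per ALT")
    if callset.sample_ids:
        header.formats.add("GT", 1, "String", "Genotype")
        for s in callset.sample_ids:
            header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in callset.records:
            vrec = out.new_record(
                contig=rec.contig,
                start=rec.pos0,
                alleles=(rec.ref, *rec.alts),
            )
            if rec.qual is not None:
                vrec.qual = rec.qual
            if rec.per_alt_af is not None:
                vrec.info["AF"] = tuple(rec.per_alt_af)
            if rec.per_alt_vaf is not None:
                vrec.info["VAF"] = tuple(rec.per_alt_vaf)
            if callset.sample_ids:
                gts = rec.genotypes or tuple(
                    (None, None) for _ in callset.sample_ids
                )
                for s, gt in zip(callset.sample_ids, gts):
                    vrec.samples[s]["GT"] = gt
                    vrec.samples[s].phased = False
            out.write(vrec)


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ intervals, preserving the 0-based half-open convention.

    Overlapping intervals are returned as-is (no merging).
    """
    rows: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
            rows.append(iv)
    return rows


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    pd.DataFrame(
        [(iv.contig, iv.start, iv.end) for iv in intervals]
    ).to_csv(path, sep="\t", header=False, index=False)


def read_sample_map(path) -> SampleMetadata:
    """Read a TSV with columns sample, population, superpopulation."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "population", "superpopulation"}
    if not required <= set(df.columns):
        raise ValueError(f"sample map needs columns {sorted(required)}")
    if df["sample"].duplicated().any():
        dups = df["sample"][df["sample"].duplicated()].tolist()
        raise ValueError(f"duplicate sample ids in map: {dups}")
    return SampleMetadata(
        populations=dict(zip(df["sample"], df["population"])),
        superpopulations=dict(zip(df["sample"], df["superpopulation"])),
    )


def write_sample_map(meta: SampleMetadata, path) -> None:
    pd.DataFrame(
        {
            "sample": list(meta.samples),
            "population": [meta.populations[s] for s in meta.samples],
            "superpopulation": [meta.superpopulations[s] for s in meta.samples],
        }
    ).to_csv(path, sep="\t", index=False)


def write_fasta(reference: ReferenceSequence, path, width: int = 60) -> None:
    """Write a reference as FASTA and build its .fai index."""
    with open(path, "w") as fh:
        for contig in reference.contigs:
            fh.write(f">{contig}\n")
            seq = reference.sequence(contig)
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    pysam.faidx(str(path))


_CIGAR_OPS = {0: "M", 1: "I", 2: "D", 7: "M", 8: "M"}


def read_sam(path) -> list[AlignedRead]:
    """Read aligned reads from SAM/BAM (M/I/D/=/X ops only)."""
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            ops = []
            for code, n in aln.cigartuples:
                if code not in _CIGAR_OPS:
                    raise ValueError(
                        f"unsupported CIGAR op code {code} in read {aln.query_name}"
                    )
                ops.append((_CIGAR_OPS[code], n))
            reads.append(
                AlignedRead(
                    name=aln.query_name,
                    contig=aln.reference_name,
                    start0=aln.reference_start,
                    ops=tuple(ops),
                    bases=aln.query_sequence,
                    base_quals=tuple(aln.query_qualities or [30] * len(aln.query_sequence)),
                    mapq=aln.mapping_quality,
                    strand="-" if aln.is_reverse else "+",
                )
            )
    return reads


def write_sam(reads: Sequence[AlignedRead], path,
              contig_lengths: dict[str, int]) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in contig_lengths.items()],
    }
    op_code = {"M": 0, "I": 1, "D": 2}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in sorted(reads, key=lambda r: (r.contig, r.start0, r.name)):
            aln = pysam.AlignedSegment(out.header)
            aln.query_name = read.name
            aln.query_sequence = read.bases
            aln.reference_name = read.contig
            aln.reference_start = read.start0
            aln.mapping_quality = read.mapq
            aln.cigartuples = [(op_code[op], n) for op, n in read.ops]
            aln.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in read.base_quals)
            )
            aln.flag = 16 if read.strand == "-" else 0
            out.write(aln)
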