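"""Seeded generators for every input the toolkit consumes.

The generators stand in for the real-data inputs of a population-aware
variant-calling study: a reference genome, a multi-sample diploid reference
panel with population structure and known per-population allele counts,
binomially sampled reads at a given variant allele fraction,
representation-perturbed copies of panel variants (for haplotype-matching
tests), and truth/call-set triples with planted false positives and false
negatives.  Every generator is deterministic under its seed and emits a
ground-truth ledger that downstream tests treat as the oracle.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matching import haplotype_equivalent
from .model import (
    AlignedRead,
    Callset,
    GenomicInterval,
    Genotype,
    ReferenceSequence,
    SampleMetadata,
    VariantRecord,
)

_BASES = np.array(list("ACGT"))

#: 1000Genomes-like superpopulation proportions (AFR is the largest group).
DEFAULT_POPULATIONS = {
    "AFR": 0.26, "AMR": 0.14, "EAS": 0.20, "EUR": 0.20, "SAS": 0.20,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a desk-scale slice of a 1000Genomes-style panel and a
    35x Illumina short-read experiment: five superpopulations at roughly
    1000Genomes proportions, a rare-skewed Beta(0.3, 1.5) site-frequency
    spectrum, 101-bp reads at depth 35 with a 1e-3 substitution error rate.
    """

    seed: int = 0
    genome_length: int = 50_000
    n_contigs: int = 1
    n_samples: int = 100
    populations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POPULATIONS))
    sites_per_kb: float = 5.0
    af_beta: tuple[float, float] = (0.3, 1.5)
    indel_fraction: float = 0.2
    multiallelic_fraction: float = 0.05
    missing_fraction: float = 0.02
    repeat_runs_per_kb: float = 1.0
    read_depth: int = 35
    read_length: int = 101
    base_error_rate: float = 1e-3
    ploidy: int = 2

    def __post_init__(self) -> None:
        if abs(sum(self.populations.values()) - 1.0) > 1e-9:
            raise ValueError("population proportions must sum to 1")
        for name in ("indel_fraction", "multiallelic_fraction",
                     "missing_fraction", "base_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.ploidy != 2:
            raise ValueError("only diploid simulation is supported")


def _rng(config_or_seed) -> np.random.Generator:
    seed = (config_or_seed.seed if isinstance(config_or_seed, SimConfig)
            else config_or_seed)
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

@dataclass
class SyntheticReference:
    reference: ReferenceSequence
    #: planted homopolymer / tandem-repeat runs (the generator's own ledger)
    repeat_runs: list[GenomicInterval]


def gen_reference(config: SimConfig,
                  rng: Optional[np.random.Generator] = None) -> SyntheticReference:
    """Random reference with planted repeat runs at the configured density.

    Runs (homopolymers of length 8-14 or dinucleotide repeats of 4-7 units)
    are planted non-overlapping, one per evenly spaced segment, and recorded
    in the returned ledger; they provide the repeat context needed for
    representation-shift fixtures.
    """
    rng = rng or _rng(config)
    seqs: dict[str, str] = {}
    runs: list[GenomicInterval] = []
    for ci in range(config.n_contigs):
        contig = f"chr{ci + 1}"
        length = config.genome_length
        seq = rng.choice(_BASES, size=length)
        n_runs = int(round(config.repeat_runs_per_kb * length / 1000))
        if n_runs:
            seg = length // n_runs
            for k in range(n_runs):
                unit = "".join(rng.choice(_BASES, size=rng.integers(1, 3)))
                n_copies = (int(rng.integers(8, 15)) if len(unit) == 1
                            else int(rng.integers(4, 8)))
                run_len = len(unit) * n_copies
                lo, hi = k * seg + 5, (k + 1) * seg - run_len - 5
                if hi <= lo:
                    continue
                start = int(rng.integers(lo, hi))
                tile = (unit * n_copies)
                seq[start:start + run_len] = list(tile)
                # break the run at both flanks so its length is exact
                flank = [b for b in "ACGT" if b != tile[0] and b != tile[-1]]
                seq[start - 1] = flank[0]
                if start + run_len < length:
                    seq[start + run_len] = flank[-1]
                runs.append(GenomicInterval(contig, start, start + run_len))
        seqs[contig] = "".join(seq)
    return SyntheticReference(ReferenceSequence(seqs), runs)


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPanel:
    callset: Callset
    sample_map: SampleMetadata
    #: per (contig, pos0, ref, alt, grouping): alt count and denominator,
    #: tallied from the emitted genotypes with missing filled as reference
    af_ledger: pd.DataFrame


def _population_sizes(config: SimConfig) -> dict[str, int]:
    """Largest-remainder apportionment of samples to populations."""
    labels = list(config.populations)
    exact = {p: config.populations[p] * config.n_samples for p in labels}
    sizes = {p: max(1, int(exact[p])) for p in labels}
    while sum(sizes.values()) < config.n_samples:
        p = max(labels, key=lambda q: exact[q] - sizes[q])
        sizes[p] += 1
    while sum(sizes.values()) > config.n_samples:
        p = min((q for q in labels if sizes[q] > 1),
                key=lambda q: exact[q] - sizes[q])
        sizes[p] -= 1
    return sizes


def _draw_site(
    config: SimConfig,
    reference: ReferenceSequence,
    contig: str,
    pos: int,
    in_run: Optional[GenomicInterval],
    rng: np.random.Generator,
) -> Optional[VariantRecord]:
    seq = reference.sequence(contig)
    if in_run is not None:
        # run-unit deletion or insertion: shiftable by construction
        unit_len = 1
        ref = seq[pos:pos + 1 + unit_len]
        if len(ref) < 2 or pos + 2 > in_run.end:
            return None
        if rng.random() < 0.5:
            return VariantRecord(contig, pos, ref, (ref[0],))
        return VariantRecord(contig, pos, ref[0], (ref,))
    if rng.random() < config.indel_fraction:
        ilen = int(rng.integers(1, 4))
        if rng.random() < 0.5 and pos + 1 + ilen < len(seq):
            ref = seq[pos:pos + 1 + ilen]
            return VariantRecord(contig, pos, ref, (ref[0],))
        ins = "".join(rng.choice(_BASES, size=ilen))
        ref = seq[pos]
        alt = ref + ins
        return VariantRecord(contig, pos, ref, (alt,))
    ref = seq[pos]
    others = [b for b in "ACGT" if b != ref]
    if rng.random() < config.multiallelic_fraction:
        alts = tuple(rng.choice(others, size=2, replace=False))
    else:
        alts = (str(rng.choice(others)),)
    return VariantRecord(contig, pos, ref, alts)


def gen_panel(
    config: SimConfig,
    synth_ref: SyntheticReference,
    rng: Optional[np.random.Generator] = None,
) -> SyntheticPanel:
    """A diploid panel with population-structured allele frequencies.

    Per site and population, a target frequency is drawn from the Beta
    spectrum with a population-specific multiplicative jitter; the planted
    alt count ``k_p = round(f_p x 2 N_p)`` alleles are placed on randomly
    chosen haplotypes.  A configurable fraction of genotypes is then masked
    as missing, and the ledger records the post-masking tallies (missing
    counted as reference) — exactly what frequency computation should
    recover.
    """
    rng = rng or _rng(config)
    reference = synth_ref.reference
    sizes = _population_sizes(config)
    samples: list[str] = []
    sample_pop: dict[str, str] = {}
    for pop, n in sizes.items():
        for i in range(n):
            sid = f"{pop}{i:04d}"
            samples.append(sid)
            sample_pop[sid] = pop
    sample_map = SampleMetadata(populations=dict(sample_pop),
                                superpopulations=dict(sample_pop))

    run_by_contig: dict[str, list[GenomicInterval]] = {}
    for run in synth_ref.repeat_runs:
        run_by_contig.setdefault(run.contig, []).append(run)

    records: list[VariantRecord] = []
    for contig in reference.contigs:
        length = reference.length(contig)
        n_sites = int(round(config.sites_per_kb * length / 1000))
        runs = run_by_contig.get(contig, [])
        # dedicate ~15% of sites to run-context indels (shiftable fixtures)
        n_run_sites = min(len(runs), max(1, n_sites * 15 // 100)) if runs else 0
        chosen_runs = list(rng.choice(len(runs), size=n_run_sites,
                                      replace=False)) if n_run_sites else []
        used: set[int] = set()
        sites: list[tuple[int, Optional[GenomicInterval]]] = []
        for ri in chosen_runs:
            run = runs[int(ri)]
            pos = int(rng.integers(run.start, run.end - 1))
            if pos in used:
                continue
            used.update(range(pos - 5, pos + 6))
            sites.append((pos, run))
        margin = config.read_length + 5
        while len(sites) < n_sites:
            pos = int(rng.integers(margin, length - margin))
            if any(p in used for p in range(pos - 5, pos + 6)):
                continue
            used.update(range(pos - 5, pos + 6))
            sites.append((pos, None))
        for pos, run in sorted(sites):
            rec = _draw_site(config, reference, contig, pos, run, rng)
            if rec is not None:
                records.append(rec)

    # genotypes with planted per-population counts
    pop_slices: dict[str, list[int]] = {}
    offset = 0
    for pop, n in sizes.items():
        pop_slices[pop] = list(range(offset, offset + n))
        offset += n

    a, b = config.af_beta
    final_records: list[VariantRecord] = []
    for rec in records:
        hap = np.zeros((config.n_samples, 2), dtype=np.int64)
        base_f = float(rng.beta(a, b))
        for pop, idx in pop_slices.items():
            n_haps = 2 * len(idx)
            f_pop = float(np.clip(base_f * np.exp(rng.normal(0.0, 0.5)), 0, 1))
            for ai in range(len(rec.alts)):
                share = f_pop if ai == 0 else f_pop * 0.3
                k = int(round(share * n_haps))
                free = [(s, h) for s in idx for h in (0, 1) if hap[s, h] == 0]
                k = min(k, len(free))
                if k:
                    for j in rng.choice(len(free), size=k, replace=False):
                        s, h = free[int(j)]
                        hap[s, h] = ai + 1
        if not hap.any():
            s = int(rng.integers(0, config.n_samples))
            hap[s, int(rng.integers(0, 2))] = 1
        gts: list[Genotype] = [tuple(int(x) for x in hap[s]) for s in range(config.n_samples)]
        if config.missing_fraction:
            mask = rng.random(config.n_samples) < config.missing_fraction
            gts = [(None, None) if m else gt for gt, m in zip(gts, mask)]
        counts_all = [0] * len(rec.alts)
        for gt in gts:
            for al in gt:
                if al:
                    counts_all[al - 1] += 1
        denom = 2 * config.n_samples
        final_records.append(
            VariantRecord(
                rec.contig, rec.pos0, rec.ref, rec.alts,
                genotypes=tuple(gts),
                per_alt_af=[c / denom for c in counts_all],
            )
        )

    callset = Callset(final_records, sample_ids=samples, label="panel")

    # ledger: post-masking tallies per grouping
    rows = []
    groupings = {"ALL": list(range(config.n_samples))}
    groupings.update(pop_slices)
    for rec in callset:
        for label, idx in groupings.items():
            denom = 2 * len(idx)
            counts = [0] * len(rec.alts)
            for s in idx:
                for al in rec.genotypes[s]:
                    if al:
                        counts[al - 1] += 1
            for ai, alt in enumerate(rec.alts):
                rows.append(
                    {
                        "contig": rec.contig, "pos0": rec.pos0,
                        "ref": rec.ref, "alt": alt, "grouping": label,
                        "count": counts[ai], "denominator": denom,
                        "af": counts[ai] / denom,
                    }
                )
    return SyntheticPanel(callset, sample_map, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Representation perturbation
# ---------------------------------------------------------------------------

PERTURB_MODES = ("shift", "pad", "mnp")


def perturb_representation(
    variant: VariantRecord,
    reference: ReferenceSequence,
    mode: str,
) -> Optional[VariantRecord]:
    """A different literal record describing the same sequence change.

    Modes: ``shift`` moves an indel by one base within its repeat context;
    ``pad`` prepends the preceding reference base to REF and every ALT;
    ``mnp`` appends the following reference base (turning a SNP into an
    MNP-shaped record).  The perturbed record is verified by full-window
    splice equality before being returned; a variant that is not perturbable
    in the requested mode yields ``None`` (explicit no-op signal).
    """
    if mode not in PERTURB_MODES:
        raise ValueError(f"unknown perturbation mode {mode!r}")
    seq = reference.sequence(variant.contig)

    candidate: Optional[VariantRecord] = None
    if mode == "shift":
        if len(variant.alts) != 1 or not variant.is_indel():
            return None
        alt = variant.alts[0]
        for new_pos in (variant.pos0 - 1, variant.pos0 + 1):
            if new_pos < 0 or new_pos + len(variant.ref) > len(seq):
                continue
            new_ref = seq[new_pos:new_pos + len(variant.ref)]
            if len(alt) < len(variant.ref):      # deletion
                new_alt = new_ref[:len(alt)]
            elif len(alt) > len(variant.ref):    # insertion
                new_alt = new_ref + alt[len(variant.ref):]
            else:
                return None
            try:
                cand = VariantRecord(variant.contig, new_pos, new_ref, (new_alt,),
                                     genotypes=variant.genotypes)
            except ValueError:
                continue
            if cand.key != variant.key and _verified(variant, cand, reference):
                return cand
        return None

    if mode == "pad":
        if variant.pos0 < 1:
            return None
        pad = seq[variant.pos0 - 1]
        candidate = VariantRecord(
            variant.contig, variant.pos0 - 1,
            pad + variant.ref, tuple(pad + a for a in variant.alts),
            genotypes=variant.genotypes,
        )
    else:  # mnp
        if variant.end0 >= len(seq):
            return None
        nxt = seq[variant.end0]
        candidate = VariantRecord(
            variant.contig, variant.pos0,
            variant.ref + nxt, tuple(a + nxt for a in variant.alts),
            genotypes=variant.genotypes,
        )
    return candidate if _verified(variant, candidate, reference) else None


def _verified(orig: VariantRecord, cand: VariantRecord,
              reference: ReferenceSequence) -> bool:
    """Allele-wise splice-equality check (the generator's own acceptance)."""
    return all(
        haplotype_equivalent(orig, cand, reference, alt_a=oa, alt_b=ca)
        for oa, ca in zip(orig.alts, cand.alts)
    )


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def gen_reads(
    config: SimConfig,
    reference: ReferenceSequence,
    genotype: Genotype,
    site: VariantRecord,
    rng: Optional[np.random.Generator] = None,
    sample_name: str = "S0",
) -> list[AlignedRead]:
    """Depth reads over one site for one diploid genotype.

    Each read draws its allele from the genotype (heterozygous sites give
    each read a fair coin per haplotype, i.e. expected VAF 0.5), carries the
    corresponding local haplotype with simple M/I/D alignment ops, and
    receives substitution errors at the configured rate.
    """
    rng = rng or _rng(config)
    L = config.read_length
    seq = reference.sequence(site.contig)
    span = len(site.ref)
    reads: list[AlignedRead] = []
    alleles = [0 if a is None else a for a in genotype]
    for i in range(config.read_depth):
        allele_idx = int(alleles[int(rng.integers(0, 2))])
        allele = site.allele(allele_idx)
        max_off = L - max(span, len(allele)) - 1
        off = int(rng.integers(1, max(2, max_off)))
        start = max(0, site.pos0 - off)
        pre = site.pos0 - start
        if allele_idx == 0:
            bases = seq[start:start + L]
            ops: list[tuple[str, int]] = [("M", len(bases))]
        else:
            tail_needed = L - pre - len(allele)
            tail = seq[site.end0:site.end0 + max(0, tail_needed)]
            bases = seq[start:site.pos0] + allele + tail
            ops = [("M", pre)] if pre else []
            d = len(allele) - span
            if d == 0:
                ops = [("M", len(bases))]
            elif d < 0:  # deletion: shared anchor prefix of length len(allele)
                ops.append(("M", len(allele)))
                ops.append(("D", -d))
                if tail:
                    ops.append(("M", len(tail)))
                ops = _merge_ops(ops)
            else:  # insertion after the shared anchor
                ops.append(("M", span))
                ops.append(("I", d))
                if tail:
                    ops.append(("M", len(tail)))
                ops = _merge_ops(ops)
        if config.base_error_rate:
            arr = list(bases)
            errs = np.nonzero(rng.random(len(arr)) < config.base_error_rate)[0]
            for p in errs:
                arr[p] = str(rng.choice([b for b in "ACGT" if b != arr[p]]))
            bases = "".join(arr)
        quals = tuple(int(q) for q in rng.integers(25, 41, size=len(bases)))
        reads.append(
            AlignedRead(
                name=f"{sample_name}_r{i:04d}",
                contig=site.contig,
                start0=start,
                ops=tuple(ops),
                bases=bases,
                base_quals=quals,
                mapq=60,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    return reads


def _merge_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if n <= 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return merged


# ---------------------------------------------------------------------------
# Truth and call sets with planted errors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorPlant:
    """Planted confusion counts for a pair of call sets A and B.

    ``*_fp_rare`` false positives are novel variants (panel AF 0, hence
    rare); ``*_fp_common`` are common panel variants the sampled individual
    does not carry.  False negatives remove truth variants of the stated
    commonness.  ``shared_*`` errors are planted in both call sets (they
    must be excluded by model-specific analysis).
    """

    a_only_fp_rare: int = 5
    a_only_fp_common: int = 3
    b_only_fp_rare: int = 1
    b_only_fp_common: int = 5
    shared_fp: int = 4
    a_only_fn_rare: int = 1
    a_only_fn_common: int = 5
    b_only_fn_rare: int = 4
    b_only_fn_common: int = 2
    shared_fn: int = 3


@dataclass
class SyntheticStudy:
    truth: Callset
    calls_a: Callset
    calls_b: Callset
    #: realized planted counts (categories may fall short of the request
    #: when the panel lacks enough sites of the wanted commonness)
    ledger: dict[str, int]


def gen_truth_and_calls(
    config: SimConfig,
    panel: SyntheticPanel,
    reference: ReferenceSequence,
    rng: Optional[np.random.Generator] = None,
    plant: ErrorPlant = ErrorPlant(),
    common_threshold: float = 0.01,
) -> SyntheticStudy:
    """Sample a proband from panel frequencies and plant call-set errors."""
    rng = rng or _rng(config)
    denom = 2 * config.n_samples

    truth_records: list[VariantRecord] = []
    for rec in panel.callset:
        afs = rec.per_alt_af or [0.0] * len(rec.alts)
        gt = []
        for _ in range(2):
            u = rng.random()
            acc = 0.0
            allele = 0
            for ai, af in enumerate(afs):
                acc += af
                if u < acc:
                    allele = ai + 1
                    break
            gt.append(allele)
        if any(gt):
            called = sorted({a for a in gt if a})
            vafs = [0.0] * len(rec.alts)
            for a in called:
                n = gt.count(a)
                vafs[a - 1] = 1.0 if n == 2 else 0.5
            truth_records.append(
                VariantRecord(rec.contig, rec.pos0, rec.ref, rec.alts,
                              genotypes=((gt[0], gt[1]),),
                              per_alt_vaf=vafs)
            )
    truth = Callset(truth_records, sample_ids=("PROBAND",), label="truth")

    truth_keys = {r.key for r in truth_records}
    af_by_key = {r.key: (r.per_alt_af or [0.0]) for r in panel.callset}

    def commonness_of(key) -> str:
        return "common" if max(af_by_key[key]) > common_threshold else "rare"

    # pools for planted FPs
    non_carried = [r for r in panel.callset if r.key not in truth_keys]
    common_pool = [r for r in non_carried if commonness_of(r.key) == "common"]
    rng.shuffle(common_pool)
    used_pos = {(r.contig, r.pos0) for r in panel.callset}

    def novel_variant() -> VariantRecord:
        while True:
            contig = reference.contigs[int(rng.integers(0, len(reference.contigs)))]
            length = reference.length(contig)
            pos = int(rng.integers(config.read_length,
                                   length - config.read_length))
            if any((contig, p) in used_pos for p in range(pos - 5, pos + 6)):
                continue
            used_pos.add((contig, pos))
            ref = reference.sequence(contig)[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            return VariantRecord(contig, pos, ref, (alt,))

    def make_fp() -> VariantRecord:
        rec = novel_variant()
        return VariantRecord(rec.contig, rec.pos0, rec.ref, rec.alts,
                             genotypes=((0, 1),),
                             per_alt_vaf=[float(rng.uniform(0.15, 0.6))])

    def take_common_fp() -> Optional[VariantRecord]:
        if not common_pool:
            return None
        rec = common_pool.pop()
        return VariantRecord(rec.contig, rec.pos0, rec.ref, rec.alts,
                             genotypes=((0, 1),),
                             per_alt_vaf=[float(rng.uniform(0.2, 0.6))] +
                                         [0.0] * (len(rec.alts) - 1))

    ledger: dict[str, int] = {}

    def plant_fps(n_rare: int, n_common: int, tag: str) -> list[VariantRecord]:
        out = [make_fp() for _ in range(n_rare)]
        got_common = 0
        for _ in range(n_common):
            rec = take_common_fp()
            if rec is not None:
                out.append(rec)
                got_common += 1
        ledger[f"{tag}_rare"] = n_rare
        ledger[f"{tag}_common"] = got_common
        return out

    fp_shared = plant_fps(plant.shared_fp, 0, "shared_fp")
    ledger["shared_fp"] = len(fp_shared)
    fp_a = plant_fps(plant.a_only_fp_rare, plant.a_only_fp_common, "a_only_fp")
    fp_b = plant_fps(plant.b_only_fp_rare, plant.b_only_fp_common, "b_only_fp")
    ledger["a_only_fp"] = len(fp_a)
    ledger["b_only_fp"] = len(fp_b)

    # pools for planted FNs, drawn from truth by commonness
    truth_common = [r for r in truth_records if commonness_of(r.key) == "common"]
    truth_rare = [r for r in truth_records if commonness_of(r.key) == "rare"]
    rng.shuffle(truth_common)
    rng.shuffle(truth_rare)

    def take_fns(n_rare: int, n_common: int, tag: str) -> set:
        keys = set()
        got_r = got_c = 0
        for _ in range(n_rare):
            if truth_rare:
                keys.add(truth_rare.pop().key)
                got_r += 1
        for _ in range(n_common):
            if truth_common:
                keys.add(truth_common.pop().key)
                got_c += 1
        ledger[f"{tag}_rare"] = got_r
        ledger[f"{tag}_common"] = got_c
        return keys

    fn_shared = take_fns(plant.shared_fn, 0, "shared_fn")
    ledger["shared_fn"] = len(fn_shared)
    fn_a = take_fns(plant.a_only_fn_rare, plant.a_only_fn_common, "a_only_fn")
    fn_b = take_fns(plant.b_only_fn_rare, plant.b_only_fn_common, "b_only_fn")
    ledger["a_only_fn"] = len(fn_a)
    ledger["b_only_fn"] = len(fn_b)

    def build_calls(fn_keys: set, fps: list[VariantRecord], label: str) -> Callset:
        recs = [r for r in truth_records if r.key not in fn_keys]
        recs.extend(fps)
        return Callset(recs, sample_ids=("PROBAND",), label=label)

    calls_a = build_calls(fn_shared | fn_a, fp_shared + fp_a, "calls_a")
    calls_b = build_calls(fn_shared | fn_b, fp_shared + fp_b, "calls_b")
    ledger["n_truth"] = len(truth_records)
    ledger["fp_a_total"] = len(fp_shared) + len(fp_a)
    ledger["fp_b_total"] = len(fp_shared) + len(fp_b)
    ledger["fn_a_total"] = len(fn_shared) + len(fn_a)
    ledger["fn_b_total"] = len(fn_shared) + len(fn_b)
    return SyntheticStudy(truth, calls_a, calls_b, ledger)
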