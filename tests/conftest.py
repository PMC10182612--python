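"""Shared fixtures and independent oracles for the test suite.

The oracle helpers here deliberately avoid the library's windowing and
matching code paths: equivalence is decided by splicing alleles into the
*full contig* sequence and comparing raw strings, and tallies/overlaps are
computed by linear scans.
"""
from __future__ import annotations

import numpy as np
import pytest

from popaf.model import Callset, GenomicInterval, ReferenceSequence, VariantRecord
from popaf.panel import compute_frequencies
from popaf.synthetic import SimConfig, gen_panel, gen_reference, gen_truth_and_calls


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def splice_full(seq: str, pos0: int, ref: str, allele: str) -> str:
    """Whole-contig sequence after substituting one allele (the oracle splice)."""
    assert seq[pos0:pos0 + len(ref)] == ref, "record REF disagrees with contig"
    return seq[:pos0] + allele + seq[pos0 + len(ref):]


def oracle_equivalent(seq: str, a: VariantRecord, alt_a: str,
                      b: VariantRecord, alt_b: str) -> bool:
    """Full-contig splice equality for two (record, alt) pairs."""
    return splice_full(seq, a.pos0, a.ref, alt_a) == \
        splice_full(seq, b.pos0, b.ref, alt_b)


def oracle_match(seq: str, candidate: VariantRecord, panel_records,
                 panel_afs, near: int = 50):
    """Brute-force allele-frequency dictionary by exhaustive splice comparison.

    panel_afs: record key -> list of per-alt frequencies.  Only panel records
    within ``near`` bp are compared (equivalent representations of short
    variants cannot lie farther apart); duplicates keep the max frequency.
    Returns (af_dict, n_pairs_compared).
    """
    out = {alt: 0.0 for alt in candidate.alts}
    n_pairs = 0
    for prec in panel_records:
        if prec.contig != candidate.contig:
            continue
        if prec.end0 < candidate.pos0 - near or prec.pos0 > candidate.end0 + near:
            continue
        for j, palt in enumerate(prec.alts):
            for calt in candidate.alts:
                n_pairs += 1
                if oracle_equivalent(seq, candidate, calt, prec, palt):
                    out[calt] = max(out[calt], panel_afs[prec.key][j])
    return out, n_pairs


def brute_overlap(records, interval: GenomicInterval):
    """Linear-scan half-open overlap filter."""
    return [
        r for r in records
        if r.contig == interval.contig
        and r.pos0 < interval.end and r.end0 > interval.start
    ]


def brute_af(record: VariantRecord, sample_ids, members, ploidy: int = 2):
    """Allele tally / fixed denominator with missing counted as reference."""
    idx = {s: i for i, s in enumerate(sample_ids)}
    counts = [0] * len(record.alts)
    for s in members:
        for a in record.genotypes[idx[s]]:
            if a:
                counts[a - 1] += 1
    denom = ploidy * len(members)
    return [c / denom for c in counts]


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def sim_bundle():
    """One fully generated synthetic study shared across tests (seed 11)."""
    cfg = SimConfig(seed=11, genome_length=30_000, n_samples=40,
                    base_error_rate=0.0)
    rng = np.random.default_rng(cfg.seed)
    synth_ref = gen_reference(cfg, rng)
    panel_sim = gen_panel(cfg, synth_ref, rng)
    panel = compute_frequencies(panel_sim.callset,
                                sample_map=panel_sim.sample_map)
    study = gen_truth_and_calls(cfg, panel_sim, synth_ref.reference, rng)
    return {
        "config": cfg,
        "reference": synth_ref.reference,
        "runs": synth_ref.repeat_runs,
        "panel_sim": panel_sim,
        "panel": panel,
        "study": study,
    }


@pytest.fixture
def tiny_reference():
    """A 60-bp single-contig reference with a central A-homopolymer run."""
    seq = "ACGTACGTGC" + "TTGCA" + "AAAAAAAA" + "GCTTACGATC" + "ACGTACGTGC" * 2 + "CGTACGA"
    return ReferenceSequence({"chr1": seq})


def make_panel(records, sample_ids=("s1", "s2", "s3", "s4"), groupings=None):
    """Small genotyped panel -> FrequencyPanel, for hand-built fixtures."""
    cs = Callset(records, sample_ids=sample_ids, label="panel")
    return compute_frequencies(cs, groupings=groupings)
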