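"""Cohort-level rare-variant metrics on a multi-sample callset.

Treats the synthetic panel as a called cohort: stratifies alleles by the
number of carrier samples (1 = singleton .. K = 10), then reports per-bin
homozygote counts, transition:transversion ratios by zygosity, and
frameshift-indel positions restricted to a region list.
"""
import numpy as np

from popaf import (
    GenomicInterval,
    SimConfig,
    compute_frequencies,
    frameshift_counts,
    frequency_bin_stats,
    gen_panel,
    gen_reference,
)

config = SimConfig(seed=42, genome_length=20_000, n_samples=20)
rng = np.random.default_rng(config.seed)
synth_ref = gen_reference(config, rng)
panel_sim = gen_panel(config, synth_ref, rng)
cohort_calls = panel_sim.callset

stats = frequency_bin_stats(cohort_calls, k=10)
singletons = len(stats.bins[1])
print(f"cohort: {len(cohort_calls)} sites x {len(cohort_calls.sample_ids)} samples")
print(f"singleton alleles (1 carrier): {singletons}; "
      f"alleles in bins 1..10: {sum(len(u) for u in stats.bins.values())}")

hom_per_bin = stats.homozygous.groupby("bin")["count"].sum()
print("\nhomozygous calls per bin (cohort total):")
print(hom_per_bin.to_string())

print("\nTi:Tv by bin (per-sample mean; None = no transversions observed):")
for b in sorted(stats.titv_hom):
    print(f"  bin {b:>2}: hom {stats.titv_hom[b]}  het {stats.titv_het[b]}")

regions = [GenomicInterval("chr1", 0, 10_000)]
n_pos, n_hom = frameshift_counts(cohort_calls, regions)
print(f"\nframeshift indel positions in chr1:0-10000: {n_pos} "
      f"({n_hom} with a homozygous call)")
print("(an indel is frameshift when its length change is not a multiple of 3)")
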