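"""Render the allele-frequency pileup channel for one candidate site.

Simulates reads for a heterozygous carrier, matches the candidate against
the panel, and renders the 7-channel pileup tensor.  In the AF channel each
read is coloured by the log-transformed frequency of the allele it carries:
reference-supporting and alternate-supporting reads get different, uniform
row intensities; alleles absent from the panel render as 0.
"""
import numpy as np

from popaf import (
    GenomicInterval,
    SimConfig,
    TransformParams,
    compute_frequencies,
    gen_panel,
    gen_reads,
    gen_reference,
    match_alleles,
    render_pileup,
    transform_af,
)

config = SimConfig(seed=42, genome_length=20_000, n_samples=100,
                   read_depth=12, base_error_rate=0.0)
rng = np.random.default_rng(config.seed)
synth_ref = gen_reference(config, rng)
panel_sim = gen_panel(config, synth_ref, rng)
panel = compute_frequencies(panel_sim.callset)

site = next(r for r in panel_sim.callset if r.is_snv() and len(r.alts) == 1)
af_dict = match_alleles(site, panel, synth_ref.reference)
af = af_dict[site.alts[0]]
print(f"candidate {site.contig}:{site.pos0} {site.ref}>{site.alts[0]}, "
      f"panel AF {af:.4f}")

params = TransformParams()  # af_floor 1e-4 -> 0, AF 1 -> 254
print(f"transform: AF {af:.4f} -> intensity {transform_af(af, params)}; "
      f"ref allele {1 - af:.4f} -> {transform_af(1 - af, params)}; "
      f"midpoint AF 0.01 -> {transform_af(0.01, params)}")

reads = gen_reads(config, synth_ref.reference, (0, 1), site, rng)
window = GenomicInterval(site.contig, site.pos0 - 8, site.end0 + 8)
tensor = render_pileup(reads, synth_ref.reference, site, window, af_dict, params)
print(f"\npileup tensor: {tensor.data.shape[0]} reads x "
      f"{tensor.data.shape[1]} positions x {tensor.data.shape[2]} channels")

af_channel = tensor.channel("allele_frequency")
rows = sorted({int(v) for row in af_channel for v in set(row.tolist()) if v})
print(f"distinct nonzero AF-channel intensities: {rows}")
print("(one value per allele class: alt-supporting vs ref-supporting reads;\n"
      " every read row is uniformly coloured)")
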