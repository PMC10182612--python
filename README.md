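# popaf

Population allele-frequency machinery for variant calling: haplotype-based
matching of candidate alleles to a reference panel, population-stratified
allele frequencies, a log-transformed allele-frequency (AF) pileup channel,
and single-sample / cohort-level evaluation of call sets stratified by
variant commonness.

## Who this is for

Developers and evaluators of population-aware variant callers. Large panels
such as the 1000 Genomes Project record how often each alternate allele
occurs in a population; feeding that signal into calling (rather than
post-hoc filtering) can improve both precision and recall, especially for
rare variants. The hard part is bookkeeping: the *same* sequence change can
be written as different VCF records (an indel shifted inside a repeat run,
padded with shared bases, a SNV written as an MNP), so naive position/allele
lookup misannotates exactly the variants that matter. `popaf` implements
the haplotype-comparison machinery that makes frequency annotation robust to
representation, plus the downstream analyses that quantify what population
information changes.

## What it computes

**Allele matching.** For a candidate variant *v* with span
[v_start, v_end), all panel (cohort) variants V_C overlapping the
candidate's repeat-homology span are queried and the window is extended once
to [min start, max end) over V = {v} ∪ V_C. Every candidate ALT and every
cohort ALT is spliced one-at-a-time into the reference over that shared
window; an exact string match transfers the cohort allele's frequency into
an allele-frequency dictionary keyed by the candidate ALT (unmatched → 0).

**Panel frequencies.** AF(alt) = alt-allele count / (2 × N members), with
every missing genotype filled as homozygous reference so all sites share
one denominator (the missing2ref convention). Groupings: `ALL` plus one per
superpopulation (AFR, AMR, EAS, EUR, SAS) from a sample map; arbitrary
subsets and sample exclusions are supported. Counts are exact rationals.

**AF channel.** Reads in a candidate's pileup are coloured by their allele's
frequency through

    intensity(af) = round(max_intensity · max(0, 1 − log10(af) / log10(af_floor)))

with `af_floor = 1e-4`, `max_intensity = 254`: AF 1 → 254, AF ≤ 1e-4 → 0,
monotone in between, resolution concentrated at low frequency. Channels 0–5
are simplified stand-ins for the usual read channels (bases, base quality,
mapping quality, strand, supports-variant, differs-from-reference).

**Evaluation.** TP/FP/FN by haplotype identity (representation shifts never
create spurious errors), precision/recall/F1 stratified into common
(AF > 0.01) vs rare (AF ≤ 0.01) variants with mixed multi-allelic records
excluded, recall over zero-frequency truth variants, model-specific error
sets (errors unique to each of two models, shared errors excluded) with AF
and VAF annotations, rare/common fractions and error-reduction percentages.

**Cohort metrics.** Alleles binned by call frequency (number of carrier
samples, 1 = singleton .. K = 10): per-sample homozygote counts, flagged-site
counts (e.g. pathogenic-annotated), Ti:Tv ratios by zygosity, and
frameshift-indel positions restricted to BED regions.

**Synthetic data.** Seeded generators for every input — reference with
planted repeat runs, a diploid panel with known per-population allele
counts, representation-perturbed variant copies, binomially sampled reads,
and truth/call-set pairs with planted error ledgers — so the whole toolkit
is testable offline with exact ground truth.

## Worked example

```bash
python examples/01_annotate_frequencies.py
```

```
panel: 100 sites, 100 samples, groupings ('ALL', 'AFR', 'AMR', 'EAS', 'EUR', 'SAS')

candidate chr1:705 GG>G
   ALL frequency: 0.6750
   AFR frequency: 0.3462
   EUR frequency: 0.8750
shifted representation 704 GG>G -> same ALL frequency: 0.6750

exact value: 27/40 of 200 haplotypes (missing genotypes counted as reference)
```

The candidate 1-bp deletion is annotated with its panel frequency overall
(0.675) and per superpopulation; the same deletion written one base to the
left matches the identical spliced haplotype and receives the identical
frequency. The exact value is a count over the fixed 200-haplotype
denominator. The other examples render the AF pileup channel
(`02_af_channel.py`), benchmark two call sets with commonness stratification
and model-specific error analysis (`03_benchmark_stratified.py`), and
compute cohort rare-variant metrics (`04_cohort_metrics.py`).

A thin CLI mirrors the library (`popaf simulate|frequencies|annotate|
channels|stratify|errors|cohort`); every run writes a `manifest.json` with
its inputs, parameters and seed.

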