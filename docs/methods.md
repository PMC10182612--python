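# Methods

This note documents the models and procedures implemented in `popaf`, the
choices made where the design was genuinely open, and what the synthetic
data does and does not establish.

## Coordinates and representation

All internal coordinates are 0-based half-open; conversion to VCF's 1-based
positions happens only at VCF read/write. A variant's reference span is
`[pos0, pos0 + len(REF))`, so an insertion occupies the single base that
anchors it. Symbolic and breakend ALT alleles are excluded at ingestion
(with a logged count) because haplotype splicing requires literal sequence.
Genotype phase is discarded — frequency computation needs only allele
counts. All alleles are uppercased on ingestion.

## Panel allele frequencies

For a grouping G of panel samples,

    AF(alt) = (alt-allele count among G, missing alleles counted as REF)
              / (2 · |G|)

Filling missing genotypes as reference gives every site the same
denominator, so frequencies from different sites are directly comparable;
the alternative (per-site called-allele denominators) makes sparsely
genotyped sites look artificially common. Counts are kept as exact
rationals (`fractions.Fraction`) and converted to float only at the edge,
so the invariant ref + Σ alt = 1 holds exactly and tests can assert
equality rather than tolerance. Ploidy is fixed at 2 and non-diploid
genotypes are rejected; sex-chromosome special ploidy is out of scope.
Panels carrying AF INFO tags but no genotypes are accepted for the `ALL`
grouping only; when both are present, genotypes win and discrepancies
beyond 1e-6 are logged. One independent test cross-checks the `ALL`
frequencies against `bcftools +missing2ref | +fill-tags`.

## Allele matching

A candidate ALT and a panel ALT are the same sequence change iff splicing
each into the reference over a common window yields identical strings.
The procedure: query panel variants overlapping the candidate, form
V = {candidate} ∪ V_C, extend the window once to [min start, max end) over
V, splice every allele of V over that window, and compare strings exactly.
Haplotypes are built one variant-allele at a time: no combinatorial
phasing of co-located panel variants, and no diplotype path search.

**Query interval.** The initial query uses the candidate's
*repeat-homology span*: the union of anchor positions over which the
candidate's indel alleles can shift while splicing to the same haplotype,
found by stepping the anchor one base at a time with splice verification.
For left-normalised input this collapses to the candidate's own span.
The wider query is necessary because a panel insertion anchored one repeat
unit away has a 1-bp span that does not overlap the candidate's span at
all; without it, representation invariance — the property the haplotype
comparison exists to provide — fails for shifted insertions. Window
extension itself remains single-pass (query once, extend once); an
optional fixed-point mode (`iterative=True`) re-queries over the extended
window until stable, off by default.

**Duplicate matches.** When several panel alleles splice to the same
haplotype (duplicated panel records in different representations), the
maximum frequency is kept and the collision is logged. The duplicates
describe one physical haplotype, so summing would double-count it.

**Per-read frequencies.** A read is assigned the frequency of the allele it
carries over the candidate span (insertions anchored strictly inside the
span included): a matched ALT gets its dictionary frequency, a
reference-supporting read gets `max(0, 1 − Σ matched alt AFs)` (the floor
guards panels whose duplicated records make the alt sum exceed 1), and an
unlisted allele gets 0. Reads not fully covering the span are skipped.

## AF channel

The transform is

    intensity(af) = round(max_intensity · max(0, 1 − log10(af)/log10(af_floor)))

with rounding half away from zero. Defaults: `af_floor = 1e-4` (below one
allele in a ~5,000-haplotype panel, so any observed panel allele renders
above 0) and `max_intensity = 254`. The map sends [af_floor, 1] onto
[0, max] monotonically with resolution concentrated at low frequency,
where the signal of interest (rare vs absent) lives; the exact constants
are a documented choice of this package and are configurable. Channels 0–5
use documented linear scalings (base identity at fixed intensities, base
quality capped at Q40, mapping quality capped at 60, strand at two fixed
levels, supports-variant and differs-from-reference as binary masks); they
are deliberately simplified stand-ins — faithful re-rendering of a
production caller's channels belongs to that caller. Rows are ordered by
(start, name) for reproducibility; row order is otherwise arbitrary.

## Evaluation

Calls are compared to truth by single-allele haplotype identity, reusing
the matching machinery, restricted to confident regions when given.
Matching is greedy in coordinate order; each truth ALT is consumed at most
once. A matched allele with the wrong zygosity counts as one FP plus one
FN — the strict set framing, chosen over partial credit. This is simpler
than diplotype-path benchmarking engines (vcfeval / hap.py): compound
heterozygous representations that only match as a pair of haplotypes are
scored as errors here, a documented divergence.

Stratification: a record is common when every ALT has panel AF > 0.01,
rare when every ALT is ≤ 0.01; multi-allelic records mixing both are
excluded and counted, so common + rare + excluded = total holds per error
class. Zero-frequency recall is computed over truth records whose ALTs all
have AF = 0; an empty subset yields an undefined sentinel (None), never
1.0. Model-specific error sets are haplotype-identity set differences of
two models' FP/FN sets against one truth set; errors shared by both models
are excluded. All printed percentages round half away from zero to one
decimal.

## Cohort metrics

Call frequency counts *samples carrying ≥ 1 copy* of an allele, not allele
copies — the singleton of interest is "present in exactly one sample".
Multi-allelic sites contribute each ALT independently. Alleles with call
frequency above K (default 10) fall outside the rare-call range and are
excluded from bins. Ti:Tv uses the transition set {A↔G, C↔T}; zero
transversions yield the sentinel. Two aggregation modes are provided:
per-sample mean (default; a ratio per sample, averaged over samples with a
defined ratio) and pooled. A frameshift indel changes length by a
non-multiple of 3; frameshift counting reports distinct positions whose
span intersects the region list, with the homozygous subset counted
separately. Per-sample tables are emitted in long format (bin, sample,
count) so any plotting layer can reproduce dot-plot figures.

## Synthetic data

The generator emulates, at desk scale, the inputs of a population-aware
calling study: a random reference with planted homopolymer/dinucleotide
runs (the repeat context that makes representation ambiguity real), a
diploid panel of 100 samples across five superpopulations at roughly
1000-Genomes-like proportions (AFR 0.26, AMR 0.14, EAS/EUR/SAS 0.20), a
rare-skewed Beta(0.3, 1.5) site-frequency spectrum with multiplicative
per-population jitter (log-normal, σ = 0.5), 5 sites/kb with a 0.2 indel
and 0.05 multi-allelic fraction, 2% missing genotypes, and 101-bp reads at
depth 35 with a 1e-3 substitution error rate — values chosen once as
representative of a 35× Illumina short-read experiment and configurable in
`SimConfig`. Planted alt counts are placed on explicit haplotypes, and the
emitted ledger records post-masking tallies, which is exactly what
missing-as-reference frequency computation must recover. Perturbed variant
copies (repeat shift, shared-base padding, MNP-padding) are verified
splice-equal before being emitted. Truth sets are sampled from panel
frequencies; call sets add planted FP/FN errors (shared and model-specific,
rare and common) with a realized-count ledger.

What the generator does *not* model: linkage disequilibrium and haplotype
blocks, realistic error profiles (indel errors, quality decay), split or
soft-clipped reads, structural variants, and sex chromosomes. Passing
tests therefore establish the correctness of the bookkeeping — matching,
counting, set algebra, binning — under known ground truth, not calling
accuracy on real data.

## Numerical and degenerate-input conventions

Frequencies are exact fractions; equality assertions in tests are exact.
Undefined ratios (empty denominators, zero transversions, empty error
sets, zero baselines) return None rather than a numeric placeholder.
Rounding of printed percentages and intensities is half away from zero.
Reads are processed deterministically in (start, name) order; generator
outputs are byte-identical under a fixed seed. Problem sizes in the test
and acceptance runs (20–30 kb genomes, 20–200 samples, ≥ 1,000
perturbation fixtures, ≥ 10,000 oracle pairs) were chosen as the smallest
scales at which every planted structure (all five populations, both error
commonness classes, shiftable indels in runs) appears with margin.

## Known limitations

- Single-allele haplotype comparison cannot credit multi-variant
  rewrites (e.g. one MNP vs two SNVs whose combination matches).
- The greedy truth matching can in principle differ from an optimal
  bipartite assignment when several nearby records are mutually
  equivalent; with consumed-allele bookkeeping this did not occur in any
  tested fixture.
- The AF transform's constants are this package's own; a caller trained
  on differently scaled channels would need its own values.
- Autosomal diploid genotypes only.
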