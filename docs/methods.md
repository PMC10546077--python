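# Methods

This note documents the statistical definitions used by the analysis
modules and the model behind the synthetic data generator, including
parameter defaults, their rationale, and what the generator does and
does not emulate.

## Analysis definitions

### K-mer binning (`kmerbin`)

K-mers (k ≤ 31) are 2-bit encoded and collapsed to canonical form (the
numerically smaller of a k-mer and its reverse complement); windows
containing non-ACGT characters are skipped. Parent-unique sets are the
set difference of the two parental databases, with count bounds applied
to the retaining parent (defaults `[0.3c, 3c]` for coverage `c`, to
drop sequencing-error singletons and repeat-inflated counts; when the
database is built directly from an assembled genome rather than reads,
`min_count=1` is appropriate). A read with `sa` hits against parent A's
unique set and `sb` against B's is labelled `A` if `sa ≥ s` and
`sb = 0` (symmetrically `B`), `ambiguous` if both reach the support
threshold, and `common` otherwise; long reads need `s = 2` supporting
k-mers, short reads 1. `common` reads go to **both** bins; `ambiguous`
reads are resolved by majority support, ties going to both bins.

### Divergence decomposition (`alnmetrics`)

All rates use gap-uncompressed alignment columns as denominator.
`ide1 = matches / columns`; `ide2 = matches / (matches + mismatches +
gap_opens)` (each indel run charged once), so `ide2 ≥ ide1` always.
Indel runs of ≥ 50 bp are "large" (structural); the decomposition
reports mismatch, small-indel, large-indel and total uncompressed
rates. When the decomposition is built from printed aggregates, the
components must reconcile with the total within a relative tolerance of
1e-3 (printed values are rounded). Only extended CIGARs (`=`/`X`/`I`/`D`)
are accepted; the ambiguous `M` op is rejected.

### NG86 Ka/Ks (`ng86`)

Per-codon synonymous site counts are the per-position fractions of
single-base changes that preserve the amino acid (changes to stop count
as nonsynonymous sites). Differences between codons average over all
minimal substitution paths, excluding paths that pass through an
intermediate stop codon (if every path does, all are kept). Proportions
are corrected with Jukes–Cantor, `d = −(3/4) ln(1 − 4p/3)`, undefined
(reported `None`) at saturation. A 2×2 Fisher exact test on rounded
(Sd, S−Sd; Nd, N−Nd) gives the p-value. Codons with ambiguous bases are
skipped; an internal stop raises an error; a terminal stop codon is
skipped.

### Ortholog comparison (`orthocomp`)

Global alignment uses match +2, mismatch −3, and affine gaps costing
`5 + 2g` for a gap of length g. Regions compared: spliced CDS, peptide,
introns, and 2 kb upstream/downstream flanks (strand-aware; windows
truncated at contig edges are flagged). A pair is "highly conserved"
when both CDS and peptide identity exceed 0.90; "same structure" means
equal CDS segment counts. The indel census counts each pair at most
once per region × threshold cell with strict thresholds (>10 bp,
>50 bp). Flank identity trends use the Mann–Kendall test with
tie-corrected variance and continuity correction. Identity between
co-optimal alignments need not be unique; substitution-only pairs are
symmetric, gapped ones may differ slightly between aligners.

### Domain expansion (`domexp`)

A domain counts as expanded in a species when all four hold strictly:
(i) that species has the unique maximum gene count; (ii) max/second
> 1.2; (iii) max − second > 3; (iv) max / mean(of the other species) > 1.5. Criterion (iii) is deliberately not scale-invariant: it
suppresses calls on small counts (6 vs 3 fails; 60 vs 30 passes). A
focal-species variant tests one species against all non-focal species,
allowing two related focal species to qualify on the same domain.

### Population statistics (`popstats`)

SNPs kept are biallelic with MAF strictly > 0.01 and missing rate
strictly < 0.05. Classification uses |Δp| > 0.75 (enriched) and > 0.95
(specific), both strict. Per-site diversity is `2c(n−c)/(n(n−1))` over
called haplotypes (NaN below 4); window π sums sites and divides by the
full window length (invariant sites count as zero). Fst is
Weir–Cockerham (1984), windowed as a ratio of sums Σa/Σ(a+b+c);
negative estimates are reported as-is. The selection scan thresholds
are empirical nearest-rank quantiles (rank ⌈qn⌉ of the sorted finite
values), comparisons strict; a candidate window exceeds the Fst
quantile AND sits in a π-ratio tail, and overlapping genes are
collected once each. LD decay bins squared Pearson correlation of
dosages by pair distance into `(0, w], (w, 2w] …`; zero-distance pairs
and monomorphic sites are skipped (expected r² for unlinked sites is
≈ 1/(n−1) from sampling alone).

### Assembly statistics (`asmstats`)

Nx is the length at which the cumulative sorted-descending sum first
reaches ≥ x% of the total; Lx its 1-based rank. Gene length is the
gene-feature span (introns included); CDS length sums CDS segments;
genes bin by CDS segment count into {1, 2–10, 11–20, >20}. FASTQ
quality summaries count bases at or above phred 20/30 (offset 33).

## The synthetic generator (`synthio`)

### Model

An ancestor sequence is drawn uniformly over ACGT. Two lineages evolve
independently from it, each with:

- substitutions at `substitution_rate` per bp (default 0.01 per
  lineage, i.e. ~2% pairwise divergence between the derived genomes);
- small indels at `small_indel_rate = 1e-2` events/bp, lengths
  geometric(p = 0.3) clipped to [1, 49] (mean ≈ 3.3 bp);
- large indels at `large_indel_rate = 2e-4` events/bp, lengths
  lognormal(μ = ln 150, σ = 1.0) clipped to [50, 10000].

These defaults were chosen once, from the divergence composition the
tool is meant to study (per-lineage mismatch ~1%, small-indel bp a few
percent, large-indel bp the dominant component), and were not adjusted
after observing test outcomes. Every event is recorded in a truth set,
and an exact alignment of each derived genome to the ancestor is
emitted as an extended CIGAR (`=`/`X`/`I`/`D`), so downstream metrics
can be validated against planted truth without running an aligner.

Within-species heterozygosity (default 0.025, substitutions only)
turns each derived genome into a diploid parent; the offspring inherits
one haplotype from each parent. Long reads are error-free-by-default
substrings with lognormal lengths (mean 16,032 bp, σlog 0.2, minimum
100 bp) and a per-base error rate of 1e-3 (HiFi-like ~Q30); short
reads are 150 bp.

Optionally, `protected_intervals` (typically CDS segments) model
purifying selection: indels are rejected inside them, because
frame-shifts would otherwise destroy most simulated genes at the
default rates. `sanitize_orfs` rewrites internal stop codons in
simulated gene models (TAA→TTA, TAG→TTG, TGA→TGG, strand-aware) so
annotations translate cleanly.

Population genotypes are drawn binomially per individual from per-site
allele frequencies shared between two populations, except for a planted
fraction of differentiated sites with near-fixed frequencies
(p ~ U(0.99, 1) in one population, U(0, 0.01) in the other). Near-fixed
planting reflects what species-diagnostic SNPs are: a frequency
difference barely above the 0.95 threshold could not be recovered
reliably from finite samples, a fixed-vs-absent difference can.

### Numerical choices

- Indel lengths are clipped, not resampled, at the truncation bounds
  (bias is negligible: the geometric tail beyond 49 has mass ~3e-8;
  the lognormal mass outside [50, 10000] is counted at the bounds).
- K-mers use 2-bit encoding in uint64 with numeric-min canonicalization,
  so databases of tens of millions of k-mers fit comfortably in memory.
- Genotypes are int8 dosages (−1 missing, −2 multiallelic placeholder).
- Empirical quantiles are nearest-rank (no interpolation), so scan
  thresholds are always observed values and strict comparisons have
  unambiguous semantics.

### What the generator does not emulate

- No sequencing-coverage noise model beyond uniform read start
  positions, and no chimeric or adapter artifacts.
- Repeat content: the ancestor is i.i.d. uniform, so k-mer uniqueness
  is much higher than in a real molluscan genome; binning accuracy on
  simulated data is an upper bound.
- Later indel events whose position falls inside an earlier deletion
  are skipped (at default rates about 4% of events), so realized indel
  rates sit slightly below nominal; recovery tests use a 15% relative
  tolerance that absorbs this along with the columns-vs-ancestor-bp
  denominator difference.
- Population sites are unlinked (independent draws), so LD decay on
  simulated genotypes reflects only the sampling floor.
- No gene gain/loss, no inversions or translocations, no selection
  beyond the indel-protection intervals.

## Limitations

Thresholds (0.75/0.95 allele-frequency classes, 50 bp SV boundary,
four-criterion expansion margins, quantile tails) are fixed conventions
exposed as parameters; they are not estimated from data. The Fisher and
chi-square tests treat sites/pairs as independent. Identity from a
single optimal alignment is reported even when co-optimal alignments
exist. All performance statements in this repository are about
simulated data with planted truth, not about any real genome.
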