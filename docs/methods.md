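# Methods

## Model and assumptions

The unit of inference is a biallelic heterozygous SNV covered by
quantitative short-read data. Under the null, each quality-passing,
independently sampled read covering the site carries either allele with
probability 0.5; allelic imbalance is a departure from that symmetry.
The pipeline's job is to make the observed allele counts a fair sample
before testing: mapping must not prefer one allele (allele-aware
alignment + the allele-swap mappability filter), counts must not be
inflated by PCR resampling (duplicate collapse), and miscalled bases
must not leak in (strict Phred > 30 gate).

Only SNVs are modelled. Indels, structural variants, multiallelic sites
and phasing are out of scope; multiallelic/indel records in input VCFs
are skipped and counted. All in-memory coordinates are 0-based
half-open; files use the 1-based conventions of their formats, with
conversion only at I/O boundaries.

## Reference construction

Three deterministic stages, all SNV substitutions (contig lengths are
invariant):

1. *Population stage*: at every common variant (folded minor allele
   frequency strictly > 0.05), the genome carries the population major
   allele and the sidecar the minor allele. The stored per-variant
   frequency is the ALT-allele frequency (VCF INFO/AF); "major" means
   frequency > 0.5, with an exact 0.5 tie keeping the original
   reference base, so the operation is deterministic.
2. *Sample stage*: genotyped sites overwrite stage 1. Homozygous sites
   fix the genome base and clear any sidecar entry; heterozygous sites
   keep the pre-existing genome base when it is one of the two sample
   alleles and sidecar the other. Keeping the incumbent base (rather
   than always the VCF REF) makes complete-, partial- and
   common-variant runs maximally comparable, since they share genome
   orientation wherever they share information.
3. *Predicted-site updates* (before a second round): a predicted site
   whose alleles conflict with an existing sidecar entry keeps the
   existing entry and warns — catalogued information outranks
   read-derived prediction.

The *complement reference* exchanges genome and sidecar alleles at every
sidecar site. It is an involution and is used as a symmetry check: an
unbiased aligner must produce identical unique placements and identical
imbalance calls against either orientation.

## Alignment

The micro-aligner does ungapped, both-strand placement with a mismatch
budget (default 1, indels never allowed). At sidecar sites a read base
matches if it equals the genome base or, in allele-aware mode, the
sidecar base; reads spanning several sidecar sites match any
combination of alleles independently, with no cap on the number of such
sites. Status is `unique` when exactly one placement attains the
minimum mismatch count within budget, `multimapped` when several do,
`unmapped` otherwise.

Candidates come from pigeonhole k-mer seeding (a read with ≤ m
mismatches split into m+1 chunks must match one chunk exactly; index
k-mers overlapping sidecar sites are expanded to both alleles), so the
search is provably exhaustive; reads too short to seed fall back to a
full scan. A property test asserts exact agreement with an independent
brute-force scan on random genomes. Throughput on mammalian genomes is
a non-goal: externally aligned SAM (e.g. from a production allele-aware
aligner) is ingested instead, with secondary/supplementary records
treated as multimapped and CIGAR indels/clips handled by dropping
observations at deleted positions.

Duplicate removal keys on (contig, strand-aware 5' position, strand)
and keeps the read with the highest base-quality sum, ties broken by
smallest read id — the tie-break is not semantically meaningful, only
deterministic.

The mappability filter swaps each variant-covering read's base at one
site at a time to the other allele (k swapped versions for k sites, not
2^k combinations) and re-aligns allele-aware; the read survives only if
every swapped version is unique at the same locus. Swapped bases
inherit the original base quality, which cannot affect placement.

## Statistics

**Exact binomial test.** Two-sided tail at p = 0.5 by distance from
n/2: P(|X − n/2| ≥ |a1 − n/2|), equivalently double the smaller
one-sided tail capped at 1. Computed with exact integer arithmetic up
to n = 1000 and by scipy binomial tails above (both paths are
cross-checked in the tests). n counts only the two catalogued alleles;
third-allele reads are tallied separately and excluded from testing.

**Beta-binomial Z.** With site counts mixing over p ~ Beta(α, α), the
variance of the allele proportion at depth N is (2α + N)/(4N(2α + 1)),
giving Z = (P̂ − 0.5)/sqrt((2α + N)/(4N(2α + 1))) and a two-sided
normal-tail p-value; as α → ∞ this reduces to the binomial z-score
2·√N·(P̂ − 0.5). The normal tail (rather than an exact beta-binomial
tail sum) is the package's choice; the Z construction itself is the
documented statistic.

**α estimation.** Method of moments: solve
mean_i[(2α + N_i)/(4N_i(2α + 1))] = mean_i[(p̂_i − 0.5)²] by bracketed
root finding (the left side decreases monotonically from 1/4 to the
binomial floor mean[1/(4N_i)]). The genome (allele-1) orientation
defines p̂. Method of moments was chosen over maximum likelihood for
its closed-form moment equation and directly testable recovery; MLE
would satisfy the same contract. **No-overdispersion sentinel:** the
moment estimate v̂ sits within sampling noise of the binomial floor on
genuinely binomial data, so a literal at-or-below-floor rule would flip
a coin there. The estimator returns α = ∞ when v̂ ≤ floor + 3·SE(v̂),
with SE the empirical standard error of the squared centered
proportions — a one-sided three-sigma moment test. At the recovery
condition used in the tests (α = 5, depth 50) v̂ is ~10× the floor and
the sentinel margin is never the binding constraint.

**Calling.** A site is tested when both alleles have ≥ 5 reads
(`min_reads_per_allele`); optionally, known-het/common sites with one
allele entirely absent but ≥ 10 total reads can be tested too
("complete imbalance", off by default since at common-variant sites a
homozygous sample is indistinguishable from complete imbalance without
external evidence). Significance is an uncorrected p < 0.01; equal
counts are never flagged. Benjamini–Hochberg FDR control is available
behind a flag but off by default. All tested sites are reported, in
three confidence tiers: all calls, calls at known/common variants
(higher confidence), calls at predicted variants (lower confidence).

**Het-site prediction.** An uncatalogued position is predicted
heterozygous when ≥ 5 quality-passing reads carry the genome base and
≥ 5 carry one single specific other base (the most frequent non-genome
base; alphabetical tie-break). The Rsq filter (strictly > 0.3) is
applied to imputed catalogs before reference construction, i.e. as an
inclusion requirement during alignment.

## Evaluation framework

Calls from a reduced-information run are scored against the
complete-genotype run by site position (direction agreement optional):
TP both imbalanced, FP evaluated-run only, FN truth only; sensitivity
TP/(TP+FN), precision TP/(TP+FP). Strata: all sites; known/common
sites; predicted sites; and a restricted-truth stratum whose truth set
is intersected with the sites the evaluated run tested, separating
"tested but missed" from "never saw the site".

## Synthetic data

The generator emulates a diploid sample sequenced at regulatory sites:
a uniform-random genome (optionally with copied segments to create
multi-mapping), SNVs with ALT frequencies ~ U(0.05, 0.95), two
consistent haplotypes, and Poisson(depth) reads per het site whose
start is uniform over covering positions and whose haplotype of origin
is Bernoulli(per-site ratio). Substitution errors occur per base at the
configured rate and are emitted at Q20 — under the Q > 30 counting gate,
so errors stress alignment but not the counts; a configurable fraction
of reads is duplicated exactly. Everything is a pure function of the
config seed (one NumPy generator, per-stage substreams); determinism is
promised within this implementation, not across languages.

Default study conditions (chosen once): 20 kb single contig, 10
variants/kb with het fraction 1.0 (200 het sites), depth 60, 50 bp
reads, 1% error rate, 10% duplicates, 30% of sites imbalanced at ratio
0.8 with random direction, partial-catalog coverage 80% with
Rsq ~ U(0.4, 1), no repeats. Variants are kept a read length away from
contig ends and repeat copies. Desk-scale sizes keep the full test
suite and the acceptance script in seconds while leaving per-site
counts (~35–45 after duplicate collapse) in the regime where the ≥ 5
reads/allele and p < 0.01 rules are meaningfully exercised.

What the generator does *not* model — and passing tests therefore do
not demonstrate: fragment-size and peak-shape structure of real
ChIP-seq signal, non-uniform coverage, indels, correlated base errors,
mapping quality miscalibration of external aligners, and copy-number
variation (CNV regions can be supplied as a blacklist but are not
simulated). Two fixture artifacts are worth knowing: nearby het sites
share reads, so a balanced site adjacent to an imbalanced one inherits
real skew through haplotype structure (this is faithful linkage, but it
means truth-table comparisons of *balanced* pooled fractions are done
over truth-balanced sites only); and duplicate-collapse keying by
(position, strand) removes some genuinely distinct templates at high
per-site depth, lowering effective depth — as the real deduplication it
mirrors also does.

## Numerical and degenerate-input choices

- Strict inequalities throughout where thresholds are stated strictly:
  MAF > 0.05, Rsq > 0.3, base quality > 30.
- `N` bases: never match anything in alignment; excluded from allele
  tallies; variant evidence overrides an `N` genome base during
  reference construction.
- Equal allele counts: favored allele undefined, never flagged
  imbalanced regardless of p.
- α root finding brackets [1e-9, 1e12]; dispersion at or above the
  α→0 ceiling of 1/4 returns the lower bracket edge.
- Zero-depth sites are reported in count tables but excluded from α
  estimation and never tested.
- Empty inputs (no reads, empty catalogs, empty predicted sets) are
  identities or empty outputs, not errors; a configuration yielding
  zero variants is an error.

## Known limitations

- The micro-aligner is exact but quadratic-ish in genome size for
  unseedable reads; it is a correctness instrument, not a production
  aligner.
- Beta-binomial p-values use the normal tail of Z, which is
  anticonservative at very low depth (N ≲ 10) where the Z distribution
  is discrete.
- Evaluation matches sites by position only; allele identity is carried
  in the tables but not required to agree unless strict-direction mode
  is on.
- Single-sample, autosomal-style analysis only; no phasing, no
  multi-sample VCFs.
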