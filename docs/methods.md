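# Methods

`svpopgen` implements a desk-scale version of a hybrid structural-variant
(SV) population-genomics workflow for two populations: ensemble merging of
per-caller SV callsets from short-read (SR) and long-read (LR) platforms,
genotype quality control, differentiation statistics, outlier/candidate
detection, and gene-proximity GO enrichment, all exercised against a
synthetic-data generator with known truth.

## Ensemble merging

Each caller's calls are points in (start position, length) space, typed as
DEL/DUP/INS/INV. Two calls on the same chromosome with compatible types may
describe the same SV when their Euclidean distance in that space is at most

    max(min_dist_floor, max_dist_linear * min(len_a, len_b))

with `max_dist_linear = 0.25` and `min_dist_floor = 30` bp by default. Using
the *smaller* variant's length makes the rule mutual: both variants'
constraints hold. The floor keeps the threshold from collapsing for tiny
SVs and is configurable. The distance metric itself (Euclidean over
position and length) is our choice; the procedure it feeds is the standard
minimum-spanning-forest construction used by graph-based SV mergers:
all admissible pairs are sorted by ascending distance (ties broken on the
calls' own coordinates so the result is independent of input order) and
joined by union-find, refusing joins between components that already share
a caller (or a sample, unless intra-sample merging is enabled). An optional
strict mode additionally requires every cross-component pair to satisfy the
criterion. Cluster representatives are medoids (minimum summed distance;
ties broken by position then caller name).

The union callset is filtered for clusters supported by at least two
distinct callers ("tools", not caller-sample pairs) and a representative
length of at least 50 bp - anything shorter is a small indel by the usual
SV definition. The cross-platform step re-runs the same procedure on the
two filtered platform sets with type normalization on (DUP matches INS,
since the platforms report the same event under different types), treating
each platform as one pseudo-caller so two same-platform clusters never
merge; outputs carry SR / LR / SR+LR provenance.

## Genotype QC

Per-sample genotypes are masked to missing when DP < 4, GQ < 5, DP >= 80
(five times the nominal 16X coverage) or GQ equals a caller-specific
sentinel (127 for the SNP/indel caller, 256 for the graph genotyper). The
two published phrasings of the depth cap ("more than five times" vs
"DP = 80") are unified as the single monotone rule DP >= 80 for both
sources. Population-level filters then keep variants with alt-allele
frequency in [0.05, 0.95] (equivalent to minor-allele frequency >= 0.05)
and missing fraction <= 0.5, boundaries inclusive; removal reasons are
tallied and conserve the input count.

Genotyped SVs are matched back to putative merged SVs by position
(|dpos| <= 50 bp) and relative allele-length difference (<= 0.25 of the
longer length), greedily by ascending (position, length) distance with
each record used at most once. These tolerances are defaults, not
published values, and are configurable. Genotype concordance compares the
modal genotype of >= 3 caller tables (consensus requires two agreeing
non-missing votes; two disagreeing votes or three-way disagreement give no
consensus) against the graph genotype; records with a missing graph
genotype are not evaluable, and the summary rate is concordant over
concordant plus discordant.

## Differentiation statistics

Per-variant FST uses the Weir & Cockerham (1984) two-allele,
two-population variance components a (among populations), b (among
individuals) and c (within individuals), computed from per-population
sample sizes, allele frequencies and observed heterozygosities with
missing individuals excluded per variant. Any aggregate - window,
chromosome, genome - is the weighted ratio of sums sum(a)/sum(a+b+c);
a mean-of-ratios alternative is deliberately not the default. The
estimator is undefined where a population has fewer than two non-missing
genotypes and reported as 0 (flagged) for monomorphic sites. Slightly
negative estimates are kept internally and only clamped at reporting.

FST windows are 100 kb sliding with 10-kb steps; variant density and
base-pairs-covered tracks use non-overlapping 100-kb windows (whether the
original density track was sliding is unstated; disjoint was chosen).
Span variants contribute their footprint intersection with each window;
insertions contribute their inserted length wholly to the window
containing the insertion point (capped at the window size) - the
assignment is our choice. Overlapping same-class footprints are summed by
default, with an opt-in union mode.

PCA mean-imputes missing dosages per variant, centers and scales columns
by sqrt(p(1-p)), eigendecomposes the individual-by-individual covariance,
and fixes signs so each eigenvector's first nonzero entry is positive.
LD decay bins squared genotype correlations of same-chromosome pairs by
physical distance.

## Outliers and candidates

The "upper 97% quantile" outlier rule is interpreted as FST at or above
the type-7 (linear interpolation) 97th percentile, i.e. the top 3%,
computed separately per variant class. Fisher exact tests are two-sided
on 2x2 allelic counts (two alleles per non-missing genotyped individual);
Benjamini-Hochberg q-values below 0.01 define Fisher outliers, and the
intersection of both flags is the outlier-of-differentiation set.

RDA regresses the imputed, column-centered genotype matrix on the
centered two-level population indicator; the single constrained axis is
extracted by SVD of the fitted values and candidates are variants whose
loading deviates from the mean loading by more than three standard
deviations. Mean imputation for RDA and the mean +/- 3 SD centering are
our choices where the procedure is usually cited without detail.

## Annotation

Genes and variants are "near" when their 1-based closed spans overlap or
sit within 10 kb (a variant ending at e and a gene starting at s match
when s - e <= 10,000, matching `bedtools window -w 10000` semantics). The
full reference span is used for DEL/DUP/INV and the anchor point for
insertions and SNPs - the published rule names "start or end positions"
without resolving large-SV spans, and the full span was chosen. GO
enrichment is a one-sided hypergeometric over-representation test per
term with >= 1 study gene, BH-corrected across tested terms; a term is
significant below corrected p = 0.1 within the biological_process
namespace. No DAG ancestor propagation is applied by default; an optional
pass over a child-to-parent table is available.

## Synthetic data

The generator emulates the study conditions rather than sequencing reads:

* **Cohort**: 29 "RO" + 31 "PU" diploid individuals.
* **Divergence**: Balding-Nichols per-population frequencies around a
  uniform(0.05, 0.95) ancestral frequency, parameterized directly by the
  target FST (`theta_fst`, default 0.05 - the moderate-differentiation
  regime). A planted fraction (default 2%) of loci is set to a fixed
  strong contrast (0.9 vs 0.1) to emulate divergent selection; the
  default fraction is kept below the 3% outlier-quantile mass so planted
  loci can all be flagged.
* **Genotypes**: Hardy-Weinberg binomial draws; DP ~ Poisson(16) after
  the nominal short-read coverage; GQ ~ clipped normal(60, 20); genotypes
  missing at rate 0.1 independently of correctness (QC only needs the
  fields, not a realistic error coupling).
* **Callsets**: six caller profiles (three per platform) named after the
  tools they imitate, with qualitative fidelity: short-read callers are
  deletion-biased and weak or blind on insertions, long-read callers are
  sensitive across types with larger breakpoint jitter (SD 8 bp vs 3 bp).
  Emission is Bernoulli per (caller, svtype); breakpoints and lengths get
  normal jitter; false positives are placed uniformly with caller-specific
  type mixes. The SV type mix defaults to the union-callset composition
  (59.1% DEL, 38.3% INS, 2.2% DUP, 0.4% INV) with lognormal lengths
  (median ~200 bp, clipped to [50 bp, 10 kb]).
* **Scale**: default 20,000 SNPs, 2,000 indels, 1,000 SVs on four 5-Mb
  chromosomes; recovery statistics in the acceptance suite use 20,000
  loci and 20 seeds per condition, which keeps every run in seconds while
  leaving Monte-Carlo error well inside the stated tolerances.

Loci are independent (no linkage), which keeps the truth analytic; LD
decay is exercised instead by a separate AR(1) haplotype generator whose
latent Gaussian correlation decays exponentially with distance. The
generator therefore does not reproduce linked selection, coalescent
ancestry, reference bias or read-level artefacts - passing recovery tests
shows the estimators are correct under the model, not that the model
captures everything in real data.

The RDA null check uses the strictly exchangeable configuration (theta ->
0, all ancestral frequencies 0.5), under which loadings are homoscedastic
and approximately Gaussian so the three-SD rule flags ~2*Phi(-3) = 0.27%
of loci. With heterogeneous ancestral frequencies the loading
distribution becomes a scale mixture and the null exceedance roughly
doubles - worth remembering when interpreting candidate counts on real
data.

## Numerical choices and edge cases

* Internal coordinates are 0-based half-open; VCF values convert at the
  I/O boundary; insertions occupy a single anchor base (end = pos).
* BND records are dropped (with a count) rather than converted to
  inversions; symbolic alleles are preserved, not sequence-resolved.
* Fisher tables with an empty margin give p = 1 with no error; BH
  q-values are clipped at 1; quantiles are type-7 throughout.
* Merging tie-breaks (edge ordering, medoid choice) are fixed and
  deterministic; all generator randomness descends from a single seed and
  outputs are byte-identical across re-runs.
* Equal-length multi-nucleotide substitutions do not fit the
  SNP/indel/SV partition and are rejected at classification.

## Known limitations

Exact reproduction of the study's real-data counts and FST values is out
of scope: those require the original sequencing data, the upstream caller
stack, and a genotype-likelihood FST estimator (the published analysis
used an SFS-based estimator; this package substitutes the genotype-based
Weir-Cockerham estimator that it cites, so the real-data genome-wide
values are not comparison targets). Breakpoint refinement, genome-graph
construction, repeat/synteny discovery and semantic clustering of GO
terms are likewise replaced by their downstream interfaces (emulated
callsets, genotyped VCFs, generic feature tracks, raw term lists).
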