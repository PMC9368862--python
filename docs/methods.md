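# Methods

This note documents the models, defaults and numerical choices behind
`bsamap`, and what the synthetic experiments do and do not establish.

## The pooled-mapping model

The scan targets a bulked-segregant design for an induced mutation: a
plant heterozygous at a single causal locus (and at many background
mutagen-induced SNPs) is selfed; from the segregating progeny, two pools
of extreme-phenotype individuals are sequenced. Under a semi-dominant
trait the two homozygous classes are phenotypically distinguishable, so
the mutant pool is homozygous mutant at the causal locus and the wild-type
pool homozygous wild. At a marker at recombination fraction *r* from the
causal locus the expected pooled allele frequencies are 1−r and r, giving

E[ED] = √2·(1 − 2r)

in the error-free, infinite-depth limit. The acceptance suite verifies
this closed form by simulation at r ∈ {0, 0.1, 0.25} (200 replicates,
3-SE agreement). At r = 0.5 the linkage signal is zero but the *measured*
mean ED is not: with 2N = 40 pooled chromosomes and finite depth, ED at an
unlinked site has a sampling-noise floor E[√2·|Δf̂|] ≈ 0.14 (pools of 20,
depth 200). The suite therefore compares the r = 0.5 mean against an
independent Monte-Carlo oracle of that floor (binomial pool composition
plus binomial read sampling, no linkage machinery) rather than against 0.

## Per-site statistic and QC

ED is computed over the full 4-base frequency vectors, so sequencing
errors to third bases contribute; for biallelic sites it reduces to
√2·|Δf_alt| (property-tested to 1e-12). Sites with total depth below
`min_reads` (default 4) in *either* pool are removed before the scan; the
boundary (= 4) is retained. A configurable power exponent on ED is exposed
(some pipelines use ED⁴ to sharpen peaks) but defaults to 1.

## Smoothing

Raw ED values are fitted with a tricube-weighted local mean over a
physical window (default `window_bp` = 1 Mb): for site *i*, weights
w(u) = (1 − |u|³)³ with u = distance/(window/2) over sites within half a
window. This is the standard LOESS kernel without iterative robustness
steps — adequate because ED is bounded and the causal signal spans many
sites. Fitted values are convex combinations of raw values, hence lie
within the raw range of the window; fitting is per chromosome with no
cross-chromosome smoothing. The weight matrix is assembled sparsely so
that hundreds of permutation profiles can be fitted in one pass.

## Threshold

Three methods are exposed:

- `fixed` — a user-supplied cutoff (e.g. the literature-style 0.05).
- `median_plus_k_sd` — median + k·SD of the fitted values (default k = 3).
- `quantile_permutation` (default) — the 0.995 quantile of fitted null
  profiles (default 200 replicates). The null at each site removes any
  true frequency difference while keeping the observed depths. When the
  pool size N is known (default 20), each pool's allele composition is
  redrawn as Binomial(2N, f₀)/2N from the combined frequency f₀ before
  read sampling, so the null reproduces the finite-pool noise of a truly
  unlinked segregating site. With `pool_size=None` the null degrades to a
  multivariate-hypergeometric re-split of the pooled reads, which reflects
  read sampling only and sits below the unlinked-site ED floor — kept for
  data where the pool size is unknown. (A naive "swap the pool labels per
  site" permutation is degenerate: ED is symmetric under pool exchange.)

One genome-wide threshold is computed from all chromosomes' fitted values.

## Interval and peak calling

Candidate intervals are maximal runs of consecutive sites with fitted ED
strictly above the threshold; runs whose facing boundary sites are within
`merge_gap_bp` (default 0) are merged. The peak is the member site with
the largest fitted value, leftmost on ties; a gene belongs to an interval
iff its CDS span overlaps it by ≥ 1 bp. Coordinates are 1-based inclusive
internally (the VCF/GFF3 convention) and converted to 0-based half-open
only when writing BED.

A genome-extent caveat: on the default synthetic genome — a single 10 Mb
chromosome at 4 cM/Mb, i.e. 0.4 Morgans — *every* site is within ~28 cM of
the causal locus, so fitted ED exceeds the unlinked-null threshold
chromosome-wide and the called interval legitimately spans the chromosome.
Peak localisation is the informative output at that genome size (the peak
falls within 500 kb of the planted SNP in ≥ 90% of seeded runs); distinct
intervals appear once the genome contains regions genuinely unlinked to
the causal locus (multiple chromosomes or lower cM/Mb).

## Variant annotation

Effects are predicted against gene models with ordered CDS segments using
the standard nuclear codon table: coding position by summing segment
lengths in coding order (minus-strand genes reverse-complemented),
codon = ⌈coding_pos/3⌉, and classification in the order synonymous →
nonsense (new stop) → stop_loss → start_loss (codon 1 loses ATG) →
missense. UTRs are not modelled (gene span = CDS extent; genic non-CDS
positions are "intronic"), splice sites are not classified, and
overlapping genes yield one record each. The implementation is verified
exhaustively against a brute-force mutate-and-translate oracle over all
64 codons × 3 positions × 3 alternate bases × both strands. Motif checking
translates the full protein and reports whether the affected residue falls
inside an exact motif occurrence (e.g. the first proline of the Aux/IAA
degron GWPPV), with its 1-based offset.

## Segregation testing

Pearson's chi-square goodness of fit against fixed ratios, df = k − 1,
p-values from scipy's chi-square distribution; no Yates correction by
default (a flag enables it). Inheritance-mode classification tests the
applicable candidate ratios (3:1, 15:1, 13:3, 9:7 for two classes; 1:2:1
for three) and returns the non-rejected ratio with the largest p-value.
Note that equal two-class counts such as 100:100, while rejecting 3:1
decisively (χ² = 33.3), are *not* rejected by 9:7 at α = 0.05
(χ² ≈ 3.17) — ratio sets with near-balanced members are weakly
discriminated at moderate sample sizes.

## Fine mapping

Phenotype-to-genotype compatibility sets (semi-dominant: WT→{A}, INT→{H},
MUT→{B}; dominant: MUT→{H,B}; recessive: WT→{A,H}) define per-individual
marker discordance; missing genotypes are non-informative. A discordant
marker excludes the causal locus *at* that marker but says nothing beyond
it, so each individual's feasible region is the union of open intervals
around its runs of concordant markers, bounded by the nearest discordant
marker on each side (or the chromosome end). The reported interval is the
intersection of these regions across individuals — open at the bounding
markers, monotonically non-widening as individuals are added. Two
degenerate outcomes are distinguished: an empty intersection raises an
inconsistency error (phenotyping/genotyping error or wrong mode), and
disjoint surviving regions separated by a positive-length infeasible gap
raise an ambiguity error. Regions that merely abut at a single excluded
marker position (an individual with a double crossover tightly around one
marker) are merged: the exclusion there has zero width. An optional
`min_discordant` (default 1) treats markers discordant in fewer
individuals as genotyping noise.

The default simulated cross mirrors a two-stage linkage design: 185 F2
plants from two opposite homozygous parents, 13 markers over ~1.83 Mb (two
outer anchors plus 11 interior markers) with the causal locus inside a
91 kb gap between markers 7 and 8; the layout shrinks proportionally on
short test chromosomes. In 100 error-free seeded cohorts the returned open
interval contains the true causal position every time (median width
~200 kb).

## Synthetic data

The generator is a model of the study design, not of a full genome:

- **Genome/genes** — uniform-composition random sequence; 2–6-segment
  non-overlapping gene models (100–400 codons) encoding clean ORFs, one of
  which carries the configured protein motif (default GWPPV).
- **Variants** — background SNPs with EMS bias: C→T/G→A transitions with
  probability `ems_bias` (default 0.98; the alternative branch excludes
  the canonical transition partner so the realised transition fraction is
  exactly the bias in expectation). Exactly one causal SNP: a
  coding-strand C→T at the second base of a proline codon (CCx→CTx,
  Pro→Leu) at the motif's first proline.
- **Meiosis** — Haldane model: Poisson crossover counts (chromosome length
  in Morgans, default 4 cM/Mb) with uniform positions and no interference;
  r = (1 − e^(−2d))/2 is verified by simulation. The selfed-heterozygote
  design keeps all mutant alleles in coupling (one mutagenised genome),
  which is both realistic and the worst case for background noise;
  segregating (rather than fixed) background SNPs are the default.
- **Pools/reads** — `pool_size` (default 20) individuals per extreme
  phenotype class; per site and pool, depth ~ Poisson(38) and base counts
  multinomial with P(alt) = f(1−e) + (1−f)e/3, symmetric substitution
  errors (default e = 0.005). Zero-depth sites are emitted and left to QC.
- **Cohorts** — selfed-heterozygote cohort of 200 (needs ≥ 20 per
  homozygous class; 200 gives 50 in expectation under 1:2:1); biparental
  fine-mapping cohort of 185.

What the generator does *not* emulate: mapping/alignment bias, indels and
structural variants, depth heterogeneity beyond Poisson, variant-calling
artefacts, polygenic or incompletely penetrant traits, and segregation
distortion. Passing tests therefore demonstrate the statistical machinery
under the stated design, not robustness to those real-data effects.

## Determinism and problem sizes

All stochastic stages are driven by numpy Generators derived from a single
seed via `SeedSequence.spawn`, and pipeline outputs are byte-identical
across reruns with the same seed. The shipped verification runs use sizes
chosen to exercise the design at desk scale: 2000 SNPs on 10 Mb for the
scan (50 seeded runs for recovery rates), 200 replicates for the
closed-form checks, and 100 cohorts for fine-mapping coverage;
`scripts/acceptance.py` reports rates over 25 scan runs and 50 cohorts.
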