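# Methods

This note documents the models, algorithms, defaults and design choices
behind `lcwgs`, and what the synthetic benchmark does and does not show
about real sequencing data.

## Synthetic cohort

**Pedigree.** `generate_pedigree` builds a closed multi-generation
pedigree: founders form generation 1 with alternating sexes; each later
generation pairs the previous generation's males and females at random
and draws children per couple from a zero-truncated Poisson (rate
`mean_offspring`, default 2.2–2.5) so no lineage dies out at desk scale.
With probability `second_union_prob` (default 0.3) a leftover individual
forms a second union with an already-paired partner, which creates
half-sib and avuncular structure. A fraction `admixture_fraction`
(default 0.25) of founders is labelled population B. The defaults target
a cohort of roughly 100–140 individuals over three generations — the
pedigree complexity of real family studies is not published in a usable
form, so these are configurable conventions, not claims of fidelity.

**Haplotypes and LD.** Founder haplotypes are mosaics of a small panel of
seed haplotypes: each haplotype starts on a uniformly chosen seed and
switches to a fresh uniform seed between adjacent sites with probability
`switch_rate` (default 0.02), then each allele is flipped with
`mutation_rate` (default 0.003, the source of rare variants). This gives
tunable, distance-decaying r² with far less machinery than a coalescent
simulator — all the haplotype-copying caller needs. Per-site seed
frequencies are drawn from a rare-skewed Beta(0.5, 1.5); populations A and
B use independent seed panels whose frequencies differ by Laplace(0, 0.1)
noise, producing the wide-tailed cross-population frequency differences
seen when comparing an admixed cohort with an external reference
population. A bounded rejection step (redraw of the mutation layer, with
a forced single-haplotype toggle as last resort) guarantees every site is
polymorphic among founders when `min_minor_count ≥ 1`. Positions are
1-based on a single synthetic chromosome with ~1 kb spacing.

**Gene dropping.** Children receive one recombinant gamete per parent
(template switching between the parent's two haplotypes at `recomb_rate`
per interval, default 0.01); founder haplotypes pass through unchanged and
no mutation occurs during the drop. Note the conserved quantity is the
*contribution-weighted* founder frequency: the expected frequency of an
individual is the mean of its parents', so founders with more descendants
weigh more. The property test checks against this exact expectation.

**Sequencing.** Read totals per sample-site are Poisson with the sample's
mean depth; per-sample depths are uniform on [1, 15] by default, mirroring
a cohort whose central mass sits between ~3× and ~12×. Each read reports
the allele of a uniformly chosen haplotype, flipped with `base_error`
(default 0.005). Pileup counts are the atomic evidence — no reads,
alignment or base-quality structure.

**Chip.** Array genotypes are truth at a marker subset plus symmetric
genotyping error (0.001), missingness (0.005), a Bernoulli(0.005) set of
A/B-flipped markers (g → 2−g, the artifact that drives concordance to ~0
at homozygous genotypes), and `n_duplicates` (default 5) independently
re-genotyped duplicate samples.

## Callers

All callers start from the same per-read independent binomial likelihood
with symmetric error; PL encoding follows VCF convention (phred, min 0,
cap 255). Genotype argmax ties break toward the lower dosage, biasing to
the reference as production callers do. No caller ever receives pedigree
information.

**Single-sample** calls the flat-prior maximum-likelihood genotype; call
quality is the phred gap between best and second-best genotype, and calls
under `min_call_quality` (default 4) or at zero depth are missing. This
flat-prior quality is deliberately literal: it makes the single-sample
caller *permissive* as a site discoverer (a 1-ref/1-alt pileup yields a
17-phred heterozygote), which is worth keeping in mind when comparing
discovery fractions.

**Multi-sample** estimates the per-site allele frequency by EM on the
genotype-likelihood mixture under Hardy–Weinberg proportions (monotone in
the observed-data likelihood; flat-likelihood sites return the
initialization), flags a site when the phred likelihood ratio of q̂
against q=0 reaches `min_site_quality` (default 4), and assigns
posterior-mode genotypes under the HWE(q̂) prior — zero-depth samples
thereby get the prior mode. A flagged site whose posterior modes are all
hom-ref would contradict the call-set invariant that a variant flag
implies a carrier, so the sample with the strongest non-reference
posterior is promoted to its best alternate genotype.

**LD-aware** mirrors the production pipeline shape: a multi-sample
likelihood-ratio pre-pass defines the candidate variant sites (everything
else is a reference call for every sample — which is why this caller
trades singleton discovery for genotype accuracy), then iterative
refinement runs on those sites. Haplotypes initialize from single-sample
MAP genotypes with random phase; each round updates samples in random
order by running the diploid Li–Stephens copying HMM (ordered template
pairs; per-interval switch probability `recomb_switch` = 0.01 to a uniform
template; copied alleles flipped with `template_error` = 0.01; emissions
sum the genotype likelihood over the latent genotype) against up to
`n_templates` = 40 haplotypes from the other samples, then backward-samples
a state path and redraws the allele pair per site. Final genotypes are the
posterior mode averaged over the last half of `n_rounds` = 20 rounds.
The forward–backward recursions exploit the factorized transition for
O(H²) updates and are exact — verified against brute-force path
enumeration to 10⁻⁹ — with inner loops compiled by numba.
Rounds/templates are free parameters surfaced in the config; no fidelity
to any production tool's internals is claimed beyond the qualitative
caller-class ordering.

## Evaluation

Concordance counts only surviving, chip-polymorphic markers; `N_{S,v}` is
the number of chip genotypes for sample S with ≥1 alternate allele
(chip-missing excluded), `N_{S,m}` those matched exactly by the caller
with missing read as hom-ref. The false-positive rate divides a sample's
chip-hom-ref calls by its non-reference calls over surviving markers; it
is reported both including chip-monomorphic markers (headline) and
restricted to polymorphic ones, since the convention is genuinely
ambiguous. Samples with empty denominators report NaN, never 0.

Site finding bins chip-variant sites by chip minor-allele frequency with
dedicated MAC=1 and MAC=2 bins below the continuous bins; empty bins are
NaN. The discovery model fits `p` by bounded scalar maximum likelihood on
independent Bernoulli(1−(1−p)^f) observations, with `f` = number of
carrier samples by default (an allele-count alternative is a switch, as
the definition of `f` is ambiguous in the source material).

**Marker QC** applies, in order: duplicate-discordance removal (> 3 of
the duplicate pairs discordant), the exact HWE test (`p < 10⁻¹⁰`, computed
on a configured unrelated subset — default the greedy pedigree-kinship
< 0.1 subset), then the flip filter (per-marker concordance < 2%,
computed like C_S but transposed). The flip filter additionally requires
≥ `flip_min_carriers` (default 5) chip-alt samples at the marker: at desk
scale a rare variant missed by the caller would otherwise be removed on
the evidence of a single carrier, censoring exactly the not-found sites
out of the lowest frequency bin. The HWE test uses exact rational
arithmetic (Fraction), so its p-values are exactly reproducible and the
enumeration comparison in the tests is meaningful at machine precision.

## Identity matching

`log₁₀ M` sums `−PL(GT_chip)/10 + log₁₀ f_GT` over markers with a
non-missing chip genotype; `f_GT` is the chip genotype-class frequency
(not an HWE-derived allele frequency), floored at 10⁻⁴ so empty classes
do not contribute −∞. Scores are normalized per marker used for cross-pair
comparison (different WGS samples have informative PLs at different
markers); raw sums are reported alongside. Ties in the argmax are
reported, not broken. Flags are diagnostic only — no automatic
adjudication against the pedigree.

## Kinship and BLUE frequencies

Pedigree kinship uses the standard generation-order recursion (founders
non-inbred; φ(i,j) = ½[φ(f,j)+φ(m,j)], φ(i,i) = ½(1+φ(f,m))); results are
exact dyadic rationals in floating point. Empirical kinship is the
centered-dosage moment estimator with pairwise-complete missing handling
and a MAF floor (default 0.01) because low-frequency sites destabilize the
2q(1−q) denominator; it serves the descriptive Figure-style histograms and
subset selection, not relationship hypothesis testing. The BLUE weights
each site's non-missing samples by Φ⁻¹1 (weights cached per missingness
pattern; singular submatrices are logged and reported NaN; estimates are
clipped to [0, 1] with a clip counter). With every sample genotyped in a
non-inbred pedigree the BLUE reproduces the realized founder allele
frequency exactly, which is the cleanest statement of what the correction
does: it undoes the over-weighting of large sibships. By default the BLUE
consumes pedigree kinship; empirical kinship can be passed instead.

## Problem sizes and numerical choices

The benchmark cohort is 100 sequenced samples × 1000 SNPs with depths
uniform on [1, 15] and base error 0.005 — large enough for the depth
stratification and frequency bins to be populated, small enough to run in
about a minute. Replicate studies use 200 gene drops (BLUE) and 10
cohorts of 20 samples × 2000 markers (swap detection). EM tolerance is
10⁻⁸ on q with 200 iterations; HMM lattices are renormalized per site;
the discovery-model likelihood clips p to [10⁻¹², 1−10⁻¹²]. One master
seed derives per-stage seeds by CRC32 stage-name hashing, so any stage can
be re-run in isolation and full runs are byte-identical.

## What the benchmark does and does not show

The simulation reproduces the *mechanisms* — depth-dependent concordance,
the caller-information ordering, the singleton cost of LD refinement,
flip/duplicate/HWE artifacts, IBD-inflated naive frequencies — but not
the numbers of any real cohort: real genomes have structured error (which
inflates false positives beyond the binomial model), megabase-scale LD,
far more markers, and deeper cryptic relatedness. Median concordances and
site-finding fractions here are therefore expected to be more optimistic
than published values from hundreds-of-samples cohorts, and nothing about
Affymetrix chemistry or alignment pipelines is modelled. The LD caller is
an iterative-resampling approximation; it has no convergence diagnostics
beyond round-averaging, and very small cohorts (< ~10 samples) give it
little to copy from. Indels and non-autosomal chromosomes are out of
scope throughout.
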