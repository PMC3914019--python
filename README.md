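# lcwgs

Evaluation of low-coverage whole-genome-sequencing (WGS) variant calling on
simulated pedigree cohorts.

Low-coverage WGS (~1–15× mean depth) is a genotype-sampling strategy that
sits between fixed-content SNP arrays and deep sequencing: per-site read
evidence is weak, so calling quality depends heavily on how much cohort
information the caller uses.  This package re-creates that comparison at
desk scale for anyone studying caller behaviour, designing a sequencing
experiment, or teaching statistical genetics: it simulates a
multi-generation pedigree cohort with admixture and linkage disequilibrium
(LD), sequences it *in silico* at configurable depth, genotypes it on a
synthetic exome-chip complete with real-world artifacts (A/B allele flips,
duplicate samples, missingness), and then measures every statistic used to
compare callers against chip genotypes.

## What is implemented

**Three caller classes** (each sees only read pileups — never the pedigree):

1. *single-sample*: per sample-site maximum-likelihood genotype from the
   binomial read model, `L(D|hom-ref) = C(n,a) e^a (1-e)^r`,
   `L(D|het) = C(n,a) 0.5^n`, `L(D|hom-alt) = C(n,a) (1-e)^a e^r`, with a
   phred quality threshold;
2. *multi-sample*: per-site allele frequency `q̂` by EM over genotype
   likelihoods, a phred likelihood-ratio site test against `q = 0`, and
   posterior-mode genotypes under a Hardy–Weinberg prior;
3. *LD-aware*: MaCH/Thunder-style iterative refinement — each sample's
   haplotype pair is repeatedly resampled from the exact forward–backward
   posterior of a Li–Stephens diploid copying HMM over the other samples'
   current haplotypes, restricted to candidate sites from a multi-sample
   discovery pre-pass.

**Evaluation statistics**: per-sample concordance
`C_S = N_{S,m}/N_{S,v}` over chip genotypes carrying a non-reference
allele (missing calls count as hom-ref), per-sample false-positive rate,
frequency-binned site finding ("found" = any sample called with an
alternate allele, regardless of genotype agreement), and the single-sample
discovery model `P(found) = 1-(1-p)^f` for a site with `f` carriers.

**Marker QC**: duplicate-pair discordance (> 3 discordant pairs), an exact
conditional Hardy–Weinberg test (rational arithmetic; removal at
`p < 10⁻¹⁰` on an unrelated subset), and the allele-flip filter
(per-marker concordance < 2%).

**Sample-identity matching**: the statistic
`log₁₀ M = Σ_markers [−PL(GT_chip)/10 + log₁₀ f_GT]`, maximized when a
WGS sample and a chip sample are the same individual; used to detect and
resolve sample swaps.

**Kinship and corrected allele frequencies**: the exact pedigree kinship
recursion, a centered-dosage moment estimator from genotypes, greedy
unrelated-subset selection, and the best linear unbiased estimate (BLUE)
of allele frequencies, `q̂ = (1ᵀΦ⁻¹x)/(1ᵀΦ⁻¹1)` with `Φ` the kinship
matrix and `x` the half-dosages — removing the upward bias that identical-
by-descent allele copies give the naive prevalence.

## Worked example

```python
from lcwgs import RunConfig, run_experiment

result = run_experiment(RunConfig(seed=1, out_dir="lcwgs_run"))
for m in ("single", "multi", "ld"):
    print(m, round(100 * result.summary[f"median_concordance_{m}"], 1),
          round(result.summary[f"median_fpr_{m}"], 4))
```

prints (100 samples, 1000 SNPs, depths uniform on 1–15×):

```
single 91.3 0.0152
multi 93.9 0.0135
ld 95.8 0.0099
```

Read: the median sample agrees with its chip genotypes at 91.3% of
chip-variant sites under single-sample calling, 93.9% with the cohort
frequency prior, and 95.8% with LD-aware refinement, while the fraction of
called non-reference genotypes that the chip says are hom-ref drops from
~1.5% to ~1% — the caller-information ordering that makes low-coverage
sequencing viable.  The gap concentrates at low depth: below 5× the
LD-aware caller leads the multi-sample caller by ~12 percentage points.
The same run writes per-sample concordance tables, site-finding curves,
marker-QC reports, the identity-match matrix and kinship/BLUE frequency
tables to `lcwgs_run/`.

The `lcwgs` command exposes the same pipeline as subcommands
(`simulate`, `call`, `evaluate`, `match`, `kinship`, `freq`, `run`).

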