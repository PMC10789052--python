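# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic-data generators do and do not emulate,
and the numerical conventions a maintainer needs to know.

## Coordinates and region windows

All coordinates are 0-based half-open (BED convention); GTF input is
converted on read.  Windows are defined as offsets from the TSS and TES in
transcription orientation and then mapped to genome coordinates, so the
promoter (TSS − 400 bp to TSS + 100 bp) is exactly 500 bp and the TES
region (TES − 100 bp to TES + 2000 bp) exactly 2,100 bp on either strand.
A gene shorter than 200 bp has an empty gene body; this is flagged, not an
error.  Windows clipped at chromosome bounds are flagged `clipped`.

Peak-to-feature annotation assigns the peak midpoint to exactly one
category with priority promoter > 5′UTR > 3′UTR > exon > intron >
TES/downstream > enhancer > intergenic; when several genes claim a
midpoint at the same priority the nearest TSS wins.  The category list is
standard; the priority order and the nearest-TSS tie-break are this
package's choices, since multi-feature overlaps need *some* total rule.

## ChIP occupancy

Fragments are assigned to a window iff their midpoint falls inside it, and
the same fragment may count toward different window types of one gene —
each window is analyzed independently.  Counting is a per-chromosome
binary search over sorted midpoints, exact for arbitrary (even
overlapping) windows.

FPKM = count · 10⁹ / (length · library size).  The pausing index is
implemented verbatim as (FPKM_promoter/L1)/(FPKM_body/L2).  Because FPKM
is already length-normalized, this divides by length twice; under equal
promoter and body densities it returns L2/L1 rather than 1.  The formula
is kept as printed because it is the study definition; `mode="density"`
(the plain FPKM quotient) is provided for callers who want the
conventional density ratio, and the synthetic-recovery tests use that mode
since the generator plants densities.  PI is undefined exactly when body
signal is zero; undefined entries are NaN-flagged and excluded from
downstream tests rather than propagated.

Metagene profiles use 20 × 100-bp bins per 2-kb flank and a gene body
rescaled to 60 equal fractional bins (100 bins total); per-gene, per-bin
counts are converted to FPKM and averaged across genes with a standard
error.  The TSS-centered peak profile uses 51 bins of 400 bp with the
center bin straddling the TSS; note 51 × 400 bp = 20.4 kb, slightly wider
than the nominal ±10 kb span — the center-bin convention was adopted
because the text's span and bin grid cannot both hold exactly.  Browser
tracks are scaled to read count per bp per 10 million mapped reads.

### Differential occupancy

Genes without signal in the KO group — a zero count in any KO replicate
for the tested window — are removed first (the KO accumulates Pol II, so a
gene dark in KO is taken as dark everywhere).  Counts are then normalized
with a faithful reimplementation of TMM (trimmed mean of M-values): the
reference is the sample whose 75th count percentile is closest to the
across-sample mean, M-values are trimmed 30% per tail and A-values 5%, the
surviving M-values are combined with inverse-variance (delta-method)
weights, and factors are rescaled to geometric mean 1.  The
implementation agrees with edgeR's `calcNormFactors` to ~1e-6 on test
matrices (checked by an Rscript cross-check in the suite).  Log2 CPM uses
a 0.5-count offset against factor-adjusted library sizes.

The per-gene test is a **moderated paired t-test**: per-gene variances of
the paired log2-CPM differences are shrunk toward an empirical-Bayes prior
fitted by moment matching on log variances (the limma `squeezeVar`
scheme), and the t statistic is referred to n − 1 plus the prior degrees
of freedom.  With three replicate pairs a plain paired t has only two
degrees of freedom and essentially no genome-wide power; variance pooling
across genes is what makes the few-replicate design testable and matches
standard practice for this assay.  When fewer than two genes have positive
variance (degenerate input) the test falls back to the plain paired t with
the usual zero-variance conventions (p = 1 at zero difference).
Significance is BH FDR < 0.1 by default, direction by the sign of the mean
KO − WT log2 difference.  The pausing-index comparison (`compare_pausing`)
keeps the plain paired t per gene, as its study design prescribes.

## Anchored differential expression

Transcripts with mean CPM across all samples below 1 are removed
("less than one count per million"); the threshold is inclusive — CPM
exactly 1 is retained.  The filter scope (mean across samples rather than
per-sample) keeps one transcript set for both groups; the anchor is exempt
from removal but must itself pass, else normalization is impossible.

The anchor factor is the **ratio of log2 CPMs** exactly as specified —
f_s = log2CPM_s(anchor) / mean(log2CPM(anchor)) — not the (perhaps
intended) log of a CPM ratio.  The printed form is only well defined for
anchor CPM > 1, and the implementation refuses lower anchor abundance
rather than guessing.  Factors act through effective library sizes
(library × factor), so a sample with more anchor signal is deflated.

Per-transcript testing is a negative-binomial likelihood-ratio test with
Var = μ + φμ².  φ is a per-transcript method-of-moments estimate on
counts scaled to a common library, floored at zero and shrunk 50/50 toward
the across-transcript median — a fully specified, deliberately simple
estimator (the empirical-Bayes machinery of dedicated DE packages is out
of scope).  Group means are fitted by vectorized Newton iteration of the
one-intercept NB score equation with a log effective-library offset
(verified against statsmodels GLM to 1e-5); the deviance difference is
referred to χ²(1).  An all-zero group sits at the boundary (log-mean
−∞, log-likelihood 0).  Under the generator's null the raw p-values are
approximately uniform with a modest inflation (type-I fraction ≈ 0.075 at
n = 3 vs 3) attributable to the plug-in dispersion; planted log2 fold
changes of 2 are recovered with bias < 0.15.

Gene summaries roll significant transcripts up to unique up/down/both gene
sets; percentages of up/down transcripts are reported to one decimal.

## Variant prioritization

Site filter: VQSR PASS **and** (MQ > 20 **or** inbreeding coefficient
< −0.3).  The disjunction is implemented exactly as specified even though
a conjunction may have been intended; missing annotations fail the clause
they belong to.  Genotype filter (all strict): alt-allele fraction > 25%
for carrier calls, depth > 10, genotype quality > 20.  AC/AN/AF are then
recalculated per population from passing genotypes only (AN = 2 × passing
subjects).

Classification against a control allele-count table: any control locus
with coverage < 30X is discarded as poor quality (the coverage gate is
applied to every record, not only candidate-novel ones); control AC = 0
at adequate coverage ⇒ novel; control AF < 0.01 ⇒ rare; else common.  A
(variant, population) pair with no control record at all is discarded as
coverage-unknowable — gnomAD-style "absent" sites come with locus
coverage and are represented as AC = 0 records.

C-score: phred = −10·log10(rank fraction), bijective on (0, 1];
deleteriousness selection is strictly greater-than the threshold.
Association builds either an allele-count table ([AC, AN−AC] against the
control) or a carrier table (carriers vs non-carrier subjects, with
control carriers approximated by control AC over AN/2 subjects, the
rare-variant approximation forced by allele-count-only control data).
Both modes and both sidednesses are available because the study text does
not pin down the unit, and its printed association p-values are not
reproducible from the printed allele counts under either obvious
convention; the default is the one-sided carrier test of case enrichment.
The odds ratio is ad/bc with an explicit infinity flag when a control cell
is zero, alongside a Haldane (+0.5) corrected value.  Raw p-values are
reported by default (the study treats its tightly linked variants as one
signal); a BH switch exists for callers who want it.

## Incidence accounting

Mendelian expectations are exact cross fractions.  Lethality is
(expected − observed)/expected; an observed fraction above expected warns
and goes through unclamped.  The observed KO fraction can be computed with
two denominators: the literal survivor share at weaning (which is
renormalized by the missing pups and understates the loss) and the
conceived-offspring denominator, (wt + het)/(1 − expected) — the default,
which makes lethality ∘ census recover the planted loss and reproduces
"10% observed vs 25% expected ⇒ 60% lethality" arithmetic.  The combined
incidence is prenatal rate + survivor rate × (1 − lethality), exact before
rounding; the printed convention (components to one decimal percent,
combined to a whole percent, summed after rounding) is the default and
configurable.  Chi-square tests are Pearson without continuity correction
by default (Yates behind a flag), df = k − 1.

## AP-MS scoring

Pipeline order is fixed: keep → impute → bait-normalize → test.  Preys
quantified (nonzero) in at least 3 of 4 runs of either condition are kept.
Zeros are replaced by draws from Normal(mean, sd) of the lowest-20%
nonzero spectral counts, truncated at zero by rejection — counts cannot be
negative, so the imputed mean sits slightly above the pool mean (the
truncated-normal mean; tests check against that value).  Every run is
divided by its bait count.  High-confidence interactors versus the
empty-vector control require two-tailed t p < 0.05 AND a mean
spectral-count ratio > 1.5.  Differential interaction between bait
variants is tested on log2-normalized counts with an additive stabilizer
s₀ = 0.1 in the t denominator (a Perseus-style "0-correction"; the exact
published form is not specified, so the constant and its placement are
configurable), BH-adjusted, significant at FDR < 0.05 with geometric-mean
fold beyond ±2.

## Synthetic data

One root seed spawns independent per-generator streams, so outputs are
bit-identical under the same config and adding a generator never perturbs
another.  Defaults are the study conditions: 3 biological replicate pairs,
1e6 fragments per ChIP library, planted 2× occupancy inflation on 5% of
genes, 5% differentially expressed transcripts at |log2FC| = 2, NB
dispersion 0.1, 60% homozygous-null lethality, 27.7% survivor phenotype
penetrance with a 3.7% wild-type background, four AP-MS runs per
condition with 15% dropout.

* **Annotation**: non-overlapping genes of 2.5–8 kb with clear 10-kb
  flanks on one synthetic chromosome, random strands (both always
  represented), a simple 3-exon structure and interior CDS.
* **ChIP**: fragment midpoints drawn from a mixture of a uniform component
  over TSS − 400 … TES + 2000 and an extra promoter component whose share
  is pausing_level·500/(span + pausing_level·500), so promoter density is
  (1 + pausing_level) × body density; fixed 200-bp fragments; a uniform
  intergenic background holds 10% of the library in WT, and in KO the
  planted genes' extra mass is taken from that background so planted
  expected counts are exactly fold × WT at constant depth.  Fragment
  counts per sample sum exactly to the library size (multinomial
  allocation).
* **RNA-seq**: NB counts with lognormal baseline means, a common
  dispersion, an anchor transcript with identical means in both groups,
  and signed planted effects; every 20th transcript shares a gene with its
  neighbor so gene-level rollups are exercised.
* **Cohort**: diploid genotypes under per-site allele frequencies with
  realistic AD/DP/GQ, ~5% of calls degraded to fail one genotype clause,
  one non-PASS site and one low-coverage control locus; planted causal
  sites have case AF = causal_af and control AC = 0 at 45X.
* **Litters**: 1:2:1 genotypes in litters of 8, KO pups removed before
  census with the lethality probability, phenotypes among survivors by
  genotype-specific penetrance.
* **AP-MS**: Poisson spectral counts with 4× enrichment for planted
  interactors, half of which lose the enrichment in the mutant-bait
  condition; dropout zeros; bait counts of comparable magnitude in every
  run (each purification is anchored by its own bait recovery).

What the generators do **not** emulate: read-level sequences, mapping or
GC bias, fragment-length variation, overdispersion in ChIP counts beyond
multinomial sampling, linkage between cohort sites, population structure
beyond two labels, litter random effects, and intensity-dependent AP-MS
missingness.  Passing recovery tests therefore demonstrates estimator
correctness under the declared model, not robustness to those real-data
artifacts.

## Numerical conventions

BH is a direct step-up with enforced monotonicity, cross-checked against a
brute-force oracle and statsmodels.  Fisher exact tests delegate to
scipy and are cross-checked against exhaustive rational-arithmetic
hypergeometric enumeration.  NB likelihoods use gammaln throughout; the
Newton fits clip steps at ±5 and converge to 1e-10.  Dispersions are
floored at 1e-8 (the Poisson limit).  The trigamma inverse used by the
variance-shrinkage prior follows the standard Newton recursion.  Problem
sizes in the simulation-based tests (2,000 genes/transcripts, 10 seeds,
1e6-fragment libraries) were chosen to make planted-truth recovery
measurable while keeping the default suite fast.

## Known limitations

The printed-PI mode double-normalizes by length by construction; use the
density mode for biological interpretation.  The anchor-ratio
normalization is scale-sensitive (a ratio of logarithms); it is faithful
to its specification but statistically unusual.  The cohort association
in carrier mode approximates control carrier counts from allele counts.
The moment dispersion estimator mildly inflates NB-LRT type-I error at
n = 3; callers needing exact calibration should increase replication.
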