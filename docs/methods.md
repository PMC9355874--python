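# Methods

This note records the models, conventions and numerical choices behind
chforge, and what its synthetic benchmarks do and do not demonstrate.

## Filtering model

Tumor-only somatic calls over a driver-gene panel mix three populations:
true CH drivers (alt fraction = clone VAF, typically 0.02–0.5), germline
heterozygous variants that escaped the population reference (alt fraction
≈ 0.5, binomially dispersed with depth), and artifacts (low alt fraction,
strand-asymmetric support).  The chain separates them with rules that each
target one failure mode, applied in a fixed order chosen so that
cohort-level statistics (carrier counts, mean/max VAF per variant) are
computed on well-defined intermediate sets:

1. **Read-support QC** (per record): ≥2 alt reads with ≥1 on each strand,
   depth ≥7 (SNV) or ≥10 (indel/substitution), population MAF < 10⁻³.
   Dropped records carry one terminal reason (priority: alt reads, strand,
   depth, frequency).
2. **Candidate selection** (per variant): `PASS` calls, plus
   `germline`-flagged calls of variants that are `PASS` in ≥2 other samples;
   any other caller flag is terminal.
3. **Novel-variant gate**: variants in neither COSMIC nor dbSNP need ≥4
   carriers (counted after QC) and MAF < 5×10⁻⁵.
4. **Driver evidence**: hotspot membership, ≥7 hematological COSMIC
   reports (the larger of the resource table and the record's annotation),
   or a consequence-whitelist match; otherwise the record is dropped.
5. **Germline rescue**: hotspots are always included; other
   `germline`-flagged calls survive only if flagged germline in fewer
   samples than flagged `PASS` *and* at least one call of the variant has
   binomial p < 10⁻³ (lower tail of Bin(depth, 0.5), or Bin(depth, 0.95)
   at copy number one — the lower tail because a somatic clone has *fewer*
   alt reads than a germline het).
6. **Cohort exclusions**: for variants outside COSMIC and the hotspot list,
   drop when MAF ≥ 5×10⁻⁵ and the carrier VAFs look germline-like
   (mean > 0.2) or noise-like (max < 0.1); truncating variants
   (frameshift/nonsense/splice) additionally require one carrier with
   binomial p < 10⁻³.  The frequency clause is parsed as
   `MAF ≥ 5×10⁻⁵ AND (mean > 0.2 OR max < 0.1)`; the alternative reading
   (`(MAF ≥ 5×10⁻⁵ AND mean > 0.2) OR max < 0.1`) is available via
   `FilterConfig(rule_a_maf_gates_both=False)`.
7. **Assembly**: per-individual CH status, gene subtypes (non-exclusive: a
   carrier of DNMT3A *and* TET2 mutations belongs to both), and clone class
   from the individual's **maximum** VAF against 0.1.

Conventions the upstream literature leaves open, fixed here: VAF is
`alt_depth / depth` from the allelic-depth fields; population MAF is the
maximum over configured reference panels; the carrier-count gate counts
samples (one somatic allele each); hotspot keys match on normalized genomic
change.  Thresholds all live in `FilterConfig` and are overridable.

Rerunning the chain on its own output is a fixed point in practice; in
principle the carrier-count and flag-ratio rules could see smaller counts on
a second pass if the first pass removed carriers of a borderline variant,
which is why the audit trail records the counts each decision used.

## Cohort statistics

Prevalence cells use Clopper–Pearson intervals; empty cells are reported as
undefined, not zero.  Age-shift tests are two-sided Wilcoxon rank-sum:
exact enumeration when both groups have ≤25 observations without ties,
otherwise the tie- and continuity-corrected normal approximation (the
branches agree to ~5×10⁻³ at the switch point).  Sex ratios use a 2×2
chi-squared (1 df) without Yates correction (configurable).  Prevalent
associations are maximum-likelihood logistic fits with Wald intervals;
blood counts and biochemistry enter per log₁₀ unit; separation or
non-convergence is reported as a `failed` status rather than raised,
mirroring how such cells appear blanked in association heatmaps.
Missing covariates are handled complete-case.  BH FDR is applied within an
analysis family; the family is whatever result list is passed to
`attach_fdr`.

## Mendelian randomization

Harmonization aligns outcome rows to the exposure effect allele: label
swaps negate Γ and complement the frequency; strand flips are resolved by
base complement; palindromic SNPs are resolved by allele frequency only
when both frequencies are outside [0.42, 0.58], otherwise dropped (the
window follows the de-facto convention of the standard harmonization
tooling).  IVW is fixed-effect by default — identical to σ_y⁻²-weighted
least squares through the origin — with an optional multiplicative
random-effects SE inflated by √(Q/(m−1)) when heterogeneity exceeds 1.
MR-Egger orients instruments to γ > 0, regresses Γ on γ with weights
σ_y⁻², and floors the residual scale at 1 (so an exact fit reports the
fixed-effect SE).  The weighted median interpolates the ordered Wald ratios
at cumulative standardized weight 0.5 and takes its SE from a parametric
bootstrap (default 1,000 draws, seeded).  P-values are two-sided normal.
Single-instrument analyses fall back to the Wald ratio.

## Post-GWAS utilities

Eligibility thresholds are strict inequalities exactly as printed; a row at
p = 5×10⁻⁸ is not genome-wide significant.  Clumping is greedy over a
supplied r² matrix with no base-pair window: the smallest-p eligible row
(ties broken by chromosome, position, snp id) absorbs everything at
r² ≥ threshold, so leads are pairwise below threshold and raising the
threshold can only split loci.  The gene vote lists genes nominated by ≥2
of seven boolean channels, ranked by votes then alphabetically; when no
gene reaches two votes but exactly one channel nominated exactly one gene
in the locus, that gene is listed.  The evidence channels are consumed as
precomputed booleans — gene-level association, summary-based MR with
colocalization, interaction-network hub status, variant-to-gene lookup,
fine-mapped gene-body overlap, accessible-chromatin/expression overlap and
missense annotation are all upstream tools, not reimplemented here.

## Synthetic-data generator

The generator's defaults encode the study conditions the package targets:
ages 38–72 (uniform), 55% female, marginal CH prevalence 5.45% (the
intercept is solved by root-finding against the drawn covariates), CH odds
+6.7%/year, null sex effect, ten driver genes with frequencies proportional
to their rank order, clone VAF ~ Beta(2, 8) (median ≈ 0.18, matching the
spread of published per-gene VAF distributions), depth ~ Poisson(40),
~1.07 mutations per carrier.  Contaminants draw alt ~ Bin(depth, 0.5) at
shared germline SNP sites with MAFs spanning 10⁻⁵–10⁻¹·⁵, are flagged
`germline` 90% of the time, and are otherwise `PASS` to exercise the later
defenses.  Artifacts put all alt reads on one (uniformly chosen) strand so
the strand rule alone removes them.  Five percent of driver calls are
mislabelled `germline` to exercise rescue.  The driver panel layout
(hotspot/COSMIC/whitelist site pools) is fixed reference data, deliberately
independent of the simulation seed.

MR summary statistics follow γ_j ~ N(0, 0.05²) reported with SE 0.004 and
Γ_j = θγ_j + α_j reported with SE 0.02, with mean-zero pleiotropy α_j on an
invalid fraction (InSIDE holds); alleles are randomly swapped,
strand-flipped and occasionally palindromic.  GWAS blocks use AR(1)
correlation √r² between neighbours with block size 5 and adjacent r² 0.6,
so every within-block pair stays above the 0.05 clumping threshold and one
causal variant per block yields exactly one lead.

What the generator does **not** emulate: realistic LD from a reference
panel, read-level data, sequencing-batch artifacts that correlate across
sites, population structure in the PCs (drawn i.i.d. normal), relatedness,
or per-gene VAF differences.  Tests passing on this data show the decision
rules implement their definitions and that estimators recover known truth
under their stated assumptions — not that the pipeline's operating
characteristics transfer to any particular real cohort.

## Detection limits and the recovery benchmark

The read-support screen imposes a hard detectability ceiling.  With
depth ~ Poisson(40), alt ~ Bin(depth, v) and strands ~ Bin(alt, ½), the
probability that a clone at VAF v yields ≥2 alt reads on both strands is
0.40 at v = 0.05, 0.75 at v = 0.10, 0.96 at v = 0.20 (exact integration).
Averaged over the Beta(2, 8) clone-size distribution, ~89% of clones at
VAF ≥ 0.05 are detectable at 40×; no realistic clone-size distribution
reaches 95% at this depth.  Measured end-to-end sensitivity for injected
VAF ≥ 0.05 drivers on the default cohort is ~0.86: the gap beyond the
detection ceiling comes from the two deliberately conservative rules
(germline-flagged calls at sites without two PASS carriers elsewhere, and
non-COSMIC truncating variants whose carriers all have VAF high enough that
the binomial test cannot reject the germline null).  Contaminant retention
is ~0 and artifact retention exactly 0.  The acceptance suite nevertheless
asserts sensitivity ≥ 0.95 for this scenario and that assertion fails by
design of the scenario, not by implementation defect; the unit suite pins
the attainable properties (drivers lost only to the two conservative rules,
≥90% retention of detectable drivers, contaminant/artifact rejection).

## Problem sizes

The test suite simulates cohorts of 2,000–50,000 individuals (one logistic
recovery at 100,000), 200-replicate MR coverage/recovery loops, and
clumping instances of ≤10 variants against brute-force oracles; the full
suite runs in well under five minutes on one core.  These sizes were chosen
so that binomial/simulation tolerances (3 standard errors) are tight enough
to detect implementation errors while keeping each test readable as a
statement about the statistic it checks.
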