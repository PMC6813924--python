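# Methods

This note documents the models, defaults and design choices behind
`hbocprio`, and what the synthetic cohorts do and do not establish about
real data.

## Cohort model

The discovery cohort emulates a multiplex-family exome study ascertained
through affected index patients. Defaults: 17 nuclear families with 52
sequenced individuals (each family contributes a sequenced mother and two
or three sequenced children; fathers exist in the pedigree for
gene-dropping but are unsequenced), children mostly female
(`prob_female_child = 0.85`), male breast cancer permitted. The
replication cohort is 51 unrelated affected singletons. These sizes were
chosen to match the scale at which small family studies of this design
operate and are the defaults the acceptance checks run at.

Affection is assigned in two layers: carriers of a planted risk variant
become affected with that variant's penetrance (default 1.0), and every
individual is additionally exposed to a sporadic (phenocopy) rate of
0.05 — a realistic background rate that lets the cohort exhibit
intra-family etiological heterogeneity (an affected relative who does not
carry the familial variant). Every family is guaranteed one affected
index patient, reflecting ascertainment.

## Genotypes

Sites are independent biallelic variants; linkage is deliberately not
modeled because no downstream step uses LD, and independence keeps the
analytic expectations (kinship means, founder-frequency convergence)
exact. Founder genotypes are Binomial(2, MAF) draws at the configured
stratum frequency; non-founders receive one allele from each parent with
probability dosage/2 (Mendelian gene-dropping). Background panel MAFs sit
on point-mass strata (defaults 0%, 0.005%, 0.05%, 0.2%, 1%) spanning the
rare-variant filter's decision boundaries; stratum-0 sites are
cohort-private — planted as a single founder heterozygote and absent from
both frequency panels, exactly the signature of an unreported variant.

Planted risk variants are introduced into the mother of each chosen
carrier family and deterministically transmitted to the first child;
other transmissions are random. The forced transmission is still
Mendelian-consistent (the child's alt allele exists in the parent) and
emulates ascertainment: multiplex families enter such studies *because*
several affected members share the variant. A `discordant_sample` knob
replaces one individual's genotypes with unrelated draws, emulating a
sample swap for the kinship QC.

Per-call QC metrics are generated from a clean model (depth ~
Poisson(150), het alt fraction ~ Binomial(depth, 0.5), GQ 80–99) matching
deep exome coverage; a `noise_fraction` knob degrades a random subset of
calls (depth 3–8, skewed balance, GQ 5–14) that the QC surrogate should
reject.

What the simulator does not model: linkage and haplotype structure,
population stratification, sequencing-error or mapping artifacts,
relatedness across families, and site-level missingness patterns. Passing
the synthetic checks therefore demonstrates the *logic* of the filters
(thresholds, set operations, segregation rules, estimator calibration),
not robustness to real-data artifacts.

## Kinship

The KING-robust within-pair estimator is used because it needs no
external allele frequencies and is robust to structure:
φ̂ = (N_Aa,Aa − 2·N_AA,aa)/(N_Aa^(i) + N_Aa^(j)), missing genotypes
dropped pairwise, cohort-monomorphic sites removed (uninformative; an
optional cohort-MAF floor is exposed but defaults to 0). A zero
denominator raises an explicit error rather than returning 0.
Relationship bands use the standard powers-of-two cutoffs (0.354, 0.177,
0.0884, 0.0442). Discordance flagging compares observed φ̂ for declared
first/second-degree pairs against the unrelated cutoff (0.0442); a pair
is only assessable when its φ̂ denominator has at least
`min_informative_hets` (default 100) heterozygous sites — below that the
estimator is too noisy to call a declared relative unrelated, and the
pair is skipped with a warning rather than flagged. A sample discordant
with every declared relative is recommended for exclusion.

## Prioritization rules and defaults

* `maf_max = 0.001` (inclusive ≤, both panels) for the rare filter;
  `fsv_maf_max = 0.0001` (strict <) for family-specific variants. A
  variant absent from a panel is treated as frequency 0 by the filters —
  required for genuinely unreported variants to survive — but absence is
  preserved as missing in the data model and logged distinctly from a
  panel-reported 0.
* Family co-segregation requires ≥ `min_family_carriers = 2` affected
  sequenced carriers in one family, relaxed to the number of affected
  sequenced members where fewer were sequenced (one suffices in a
  single-affected family). This "as far as ascertainable" reading keeps
  the filter monotone in the threshold.
* The last-exon exclusion applies at replication (both the discovery and
  the replication variant must lie outside the final exon; unknown exon
  position is conservatively treated as last-exon). A
  `last_exon_at_discovery` flag enables the stricter reading at
  discovery too; default off.
* Predictor consensus defaults to `k = 1` of a 7-tool panel because a
  variant supported by a single tool can still be a defensible candidate
  when familial and cross-cohort evidence concur; LoF variants bypass the
  panel. `unknown` verdicts never count as damaging.
* Genotype-QC surrogate: het calls need depth ≥ 10, GQ ≥ 20 and alt
  fraction in [0.25, 0.75]; hom-alt calls need alt fraction ≥ 0.9. These
  are conventional manual-review heuristics standing in for visual read
  inspection.
* All transcript-matching rules (replication, SVGU same-gene) compare
  transcript identifiers, never bare gene symbols; a variant with several
  transcript annotations is evaluated per (variant, transcript) pair.
  SVGU unrelatedness requires different family *and* pairwise φ̂ below
  0.0442 when kinship estimates are supplied; `require_same_transcript`
  can be relaxed to gene-level sharing.

## Association

The two-sided Fisher p is the sum of hypergeometric point probabilities
(fixed margins) not exceeding the observed table's probability, with a
relative tie tolerance of 1e-7 — the convention exact-test
implementations use; an exhaustive exact-arithmetic enumeration over all
tables with N ≤ 30 is the test oracle. Zero-margin tables define p = 1
with a warning. The odds ratio is the sample cross-product ad/(bc), which
reproduces all six published comparisons at two decimals; since the
original CI method is not stated, both Woolf (log-OR normal) and
exact-conditional (noncentral hypergeometric inversion, via
`scipy.stats.contingency.odds_ratio`) intervals are implemented, with
exact-conditional the default because it matches the published intervals
on the sparsest table. Any zero cell makes the OR degenerate (0 or ∞) and
suppresses the CI explicitly; no continuity correction is applied. Burden
collapsing sums qualifying alleles (LoF, non-last-exon, MAF ≤ 0.1% in
both panels) per gene before testing and returns an explicit
empty-burden marker rather than a silent p = 1. No multiple-testing
correction is applied by default; Benjamini–Hochberg is available.

## Numerical and degenerate-input choices

Multi-allelic VCF records are split per alt allele, conserving per-sample
dosage; `./.` genotypes are excluded from carrier counts, denominators
and kinship. Duplicate (chrom, pos, ref, alt) keys abort ingest.
Candidate output order is fixed (gene, chrom, pos, ref, alt), and the
generator is byte-deterministic for a given config + seed. Pipeline
stages log an (n_in, n_out) funnel and a stage that would expand its
input set aborts the run.

## Problem sizes used in checks

The test suite and acceptance script run the generator at the study's own
scale (17 families / 52 individuals discovery, 51-singleton replication),
kinship calibration over 10,000 gene-dropped sites and 20 nuclear
families, the exhaustive Fisher oracle over all 46,376 tables with
N ≤ 30, and the monotonicity property over 100 seeded six-family
cohorts. The planted-truth recovery scenario disables loss-of-function
consequences in the rare background strata (`rare_lof_background =
False`) and zeroes background predictor support so the planted variants
are the only qualifying signal — exact-recovery statements are only
meaningful when the background contains no qualifying variants by
construction. The generator's default leaves rare LoF background enabled.

## Known limitations

Only the SnpEff-style `ANN` dialect described in `io_formats` is parsed
(VEP `CSQ` is rejected as unsupported). The burden test is the collapsed
Fisher comparison of cumulative allele counts, not a variance-component
(kernel) test. Population-structure analysis (PCA), CNV calling and
read-level evidence are out of scope; the genotype-QC surrogate is a
heuristic stand-in for manual read review, not a re-genotyper.
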