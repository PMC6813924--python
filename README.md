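# hbocprio

Family-based rare-variant prioritization for hereditary breast/ovarian
cancer (HBOC) cohorts.

Roughly half of HBOC families carry no identifiable pathogenic variant in
the established risk genes (*BRCA1*, *BRCA2*, *PALB2*, ...). A standard
discovery design for such families is exome sequencing of small multiplex
pedigrees followed by aggressive filtering: keep rare loss-of-function
(LoF) variants that co-segregate with cancer inside a family, then demand
independent support from an unrelated patient cohort. `hbocprio`
implements that full analysis as a reusable, tested pipeline — from
annotated VCF + pedigree ingest through kinship QC, gene- and
variant-based shortlisting, cross-cohort replication, and case–control
allele-count association — together with a synthetic cohort generator
(pedigree gene-dropping with planted risk alleles) so the whole workflow
can be exercised and scored without access-controlled patient data.

## What it computes

**Kinship QC.** Pairwise kinship from genotype dosages with the
KING-robust within-pair estimator

φ̂ = (N_Aa,Aa − 2·N_AA,aa) / (N_Aa^(i) + N_Aa^(j)),

where N_Aa,Aa counts shared-heterozygous sites and N_AA,aa opposite
homozygotes. Expected values: 0.5 duplicates, 0.25 first-degree, ~0
unrelated. Declared close relatives with φ̂ below the standard unrelated
cutoff (0.0442) are flagged; a sample discordant with *all* its declared
relatives is recommended for exclusion (a sample-swap / misattributed
relationship check).

**Gene-based discovery.** A variant is shortlisted iff it is LoF
(stop-gain, frameshift, essential ±2 bp splice) on some transcript, has
MAF ≤ 0.1% in both reference panels (absence from a panel counts as 0),
and is carried by ≥ 2 affected sequenced patients of one family — one
carrier suffices where only one affected member was sequenced. Carrier
genotypes must pass a genotype-QC surrogate (depth ≥ 10, GQ ≥ 20, het
allele balance in [0.25, 0.75]).

**Replication.** A discovery gene replicates iff an unrelated patient of
a second cohort carries *any* rare LoF on the *same transcript*, with
both variants outside the transcript's last exon (late truncations often
escape nonsense-mediated decay).

**Variant-based discovery.** Three tagging strategies over an expanded
universe (LoF + missense + in-frame indels + stop-loss): CGV (gene on a
cancer-gene list), SVGU (identical variant — or distinct same-transcript
variants — in genetically unrelated patients), FSV (ultra-rare MAF <
0.01%, private to one family). Tagged variants must additionally be rare,
LoF or called damaging by ≥ k of 7 in-silico predictors (default k = 1),
and present in all affected sequenced relatives of each carrier family.

**Association.** Two-sided Fisher's exact test on 2×2 alt/ref allele
tables (cases vs controls), odds ratio OR = ad/(bc) with Woolf or
exact-conditional 95% CI, and per-gene burden collapsing of qualifying
rare LoF allele counts.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (each is a thin driver over the library):

```bash
python analysis/01_simulate_cohort.py --seed 1   # 17 families / 52 individuals + 51 singletons
python analysis/02_kinship_qc.py
python analysis/03_gene_discovery.py
python analysis/05_association.py
```

which prints (seed 1):

```
discordant: F05_C1 vs F05_C2 (expected phi 0.250, observed -0.016)
discordant: F05_C1 vs F05_MO (expected phi 0.250, observed -0.053)
recommended exclusions: ['F05_C1']
discovery shortlist: ['RISK1', 'RISK2', 'RISK3'] (planted: ['RISK1', 'RISK2', 'RISK3'])
replicated genes: ['RISK1', 'RISK3']
recovery: 3/3 planted genes, 0 false positives
SETBP1:c.4129G>C   NFE-TCGA               OR=1.25 (1.05-1.49) p=0.0114
C7orf34:c.248C>T   NFE-TCGA               OR=1.46 (1.02-2.07) p=0.0325
```

The generator planted three fully penetrant LoF variants and one
deliberate sample swap (`F05_C1`): kinship QC excludes exactly that
sample, discovery recovers exactly the planted genes, and replication
keeps exactly the two genes given a second same-transcript LoF. The
association lines recompute the published cohort allele-count comparisons
from the counts table bundled with the package
(`hbocprio/data/published_counts.tsv`): for the two prioritized missense
variants, cancer patients vs cancer-free individuals give OR 1.25
(1.05–1.49, p = 0.0114) and 1.46 (1.02–2.07, p = 0.0325) in the
TCGA-vs-ExAC pairing.

The same steps are available as a CLI (`hbocprio simulate / kinship /
shortlist-genes / shortlist-variants / replicate / assoc / run-all`), and
`hbocprio.pipeline.run_pipeline` drives everything from one YAML config.

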