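"""Synthetic multi-family HBOC cohort generator.

Produces complete study inputs — pedigrees, genotypes, annotations,
population-frequency panels and a truth manifest — so every downstream
stage of the pipeline can be exercised and scored without any real data.

The generator emulates the statistical structure the discovery filters
assume:

* **Families.** Nuclear families ascertained through an affected index
  patient. Each family has an (unsequenced) father, a sequenced mother and
  sequenced children; the default layout is 17 families totalling 52
  sequenced individuals (one 4-member and sixteen 3-member sequenced sets),
  matching a small multiplex-family exome study. Children are mostly
  female (a breast/ovarian cancer study ascertains few males), and male
  breast cancer is allowed.
* **Background variation.** Independent biallelic sites whose panel MAFs
  sit on configurable strata (default 0%, 0.005%, 0.05%, 0.2% and 1%).
  Founder genotypes are drawn binomially from the stratum frequency;
  stratum-0 sites are cohort-private (planted as a single founder
  heterozygote and absent from both panels). Non-founders receive alleles
  by Mendelian gene-dropping. Sites are independent (no linkage): the
  pipeline never uses LD, and independence keeps analytic checks exact.
* **Planted risk variants.** Each planted variant is introduced into the
  mother of each chosen carrier family and transmitted to the first child
  (a deterministic Mendelian transmission emulating ascertainment of
  multiplex families; all other transmissions are random). Affection is
  assigned by penetrance for carriers, plus a background sporadic
  (phenocopy) rate — default 0.05 — so tests can exercise intra-family
  etiological heterogeneity.
* **Replication cohort.** Unrelated affected singletons; configurable
  plants put a *different* rare LoF in a chosen candidate gene on the same
  transcript (outside the last exon unless requested otherwise), or copy
  an identical discovery variant for presence lookups.

Identical config + seed give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation import DEFAULT_PREDICTOR_TOOLS, LOF_TERMS, ConsequenceAnnotation, PredictorPanel
from .io_formats import (
    GenotypeCall,
    Pedigree,
    PedigreeCollection,
    PedigreeIndividual,
    PopulationFrequencies,
    VariantKey,
    VariantRecord,
    write_frequency_table,
    write_ped,
    write_vcf,
)

_BASES = "ACGT"

_BACKGROUND_CONSEQUENCES = (
    ("missense_variant", 0.50),
    ("synonymous_variant", 0.22),
    ("stop_gained", 0.06),
    ("frameshift_variant", 0.04),
    ("splice_donor_variant", 0.02),
    ("splice_acceptor_variant", 0.02),
    ("inframe_deletion", 0.05),
    ("inframe_insertion", 0.03),
    ("stop_lost", 0.02),
    ("intron_variant", 0.04),
)

_NONLOF_CONSEQUENCES = tuple(
    (term, w) for term, w in _BACKGROUND_CONSEQUENCES if term not in LOF_TERMS
)


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass
class PlantedVariant:
    """Specification of one risk variant to plant in the discovery cohort."""

    gene: str
    consequence: str = "stop_gained"
    n_carrier_families: int = 1
    penetrance: float = 1.0
    absent_from_panels: bool = True
    maf_panel: float = 0.0
    last_exon: bool = False
    transcript_id: Optional[str] = None
    damaging_tools: int = 7  # predictor verdicts for non-LoF plants

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ConfigError(f"penetrance {self.penetrance} outside [0, 1]")
        if self.absent_from_panels and self.maf_panel > 0:
            raise ConfigError(
                f"planted variant in {self.gene}: maf_panel {self.maf_panel} "
                "inconsistent with absent_from_panels"
            )
        if self.transcript_id is None:
            self.transcript_id = f"TR_{self.gene}"


@dataclass
class SimulationConfig:
    """Discovery-cohort generator settings.

    Defaults reproduce the scale of the study design: 17 nuclear families,
    52 sequenced individuals, a 5% sporadic affection rate, ~150x mean
    depth, a 7-tool predictor panel.
    """

    n_families: int = 17
    family_children: Optional[List[int]] = None  # sequenced children per family
    n_background_variants: int = 400
    background_maf_strata: Tuple[Tuple[float, float], ...] = (
        (0.0, 0.2),
        (5e-5, 0.2),
        (5e-4, 0.2),
        (2e-3, 0.2),
        (1e-2, 0.2),
    )
    rare_lof_background: bool = True
    background_damaging_rate: float = 0.3
    planted_risk: List[PlantedVariant] = field(default_factory=list)
    sporadic_rate: float = 0.05
    predictor_tools: Tuple[str, ...] = DEFAULT_PREDICTOR_TOOLS
    mean_depth: float = 150.0
    noise_fraction: float = 0.0  # fraction of calls given QC-failing metrics
    prob_female_child: float = 0.85
    discordant_sample: Optional[str] = None  # emulate a sample swap: genotypes redrawn as unrelated
    random_seed: int = 0

    def __post_init__(self) -> None:
        self.planted_risk = [
            p if isinstance(p, PlantedVariant) else PlantedVariant(**p)
            for p in self.planted_risk
        ]
        self.background_maf_strata = tuple(
            (float(m), float(w)) for m, w in self.background_maf_strata
        )
        if self.family_children is None:
            # one 4-member and (n-1) 3-member sequenced sets: mother + children
            self.family_children = [3] + [2] * (self.n_families - 1)
        if len(self.family_children) != self.n_families:
            raise ConfigError("family_children length must equal n_families")
        if not 0.0 <= self.sporadic_rate <= 1.0:
            raise ConfigError("sporadic_rate outside [0, 1]")
        total = sum(w for _, w in self.background_maf_strata)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError("background MAF stratum weights must sum to 1")


@dataclass
class CohortBundle:
    records: List[VariantRecord]
    samples: List[str]
    pedigrees: PedigreeCollection
    frequencies: PopulationFrequencies
    truth: dict


# ---------------------------------------------------------------------------
# pedigree construction and gene-dropping
# ---------------------------------------------------------------------------


def build_nuclear_families(
    n_families: int, children_per_family: Sequence[int], rng: np.random.Generator, prob_female_child: float = 0.85
) -> PedigreeCollection:
    """Father + mother + children per family; father marked unsequenced later."""
    coll = PedigreeCollection()
    for f in range(n_families):
        fid = f"F{f + 1:02d}"
        ped = Pedigree(fid)
        ped.add(PedigreeIndividual(f"{fid}_FA", fid, None, None, "male"))
        ped.add(PedigreeIndividual(f"{fid}_MO", fid, None, None, "female"))
        for c in range(children_per_family[f]):
            sex = "female" if rng.random() < prob_female_child else "male"
            ped.add(
                PedigreeIndividual(
                    f"{fid}_C{c + 1}", fid, f"{fid}_FA", f"{fid}_MO", sex
                )
            )
        coll.families[fid] = ped
    return coll


def _drop_order(ped: Pedigree) -> List[str]:
    """Members in an order where parents precede children."""
    order: List[str] = []
    placed: set[str] = set()
    pending = sorted(ped.members)
    while pending:
        progressed = False
        for sid in list(pending):
            ind = ped.members[sid]
            if all(p is None or p in placed for p in (ind.father_id, ind.mother_id)):
                order.append(sid)
                placed.add(sid)
                pending.remove(sid)
                progressed = True
        if not progressed:  # pragma: no cover - validate() rejects cycles
            raise ValueError(f"unresolvable pedigree {ped.family_id}")
    return order


def gene_drop(
    pedigrees: PedigreeCollection,
    founder_freqs: np.ndarray,
    rng: np.random.Generator,
    forced: Optional[Dict[int, Dict[str, int]]] = None,
) -> Dict[str, np.ndarray]:
    """Mendelian gene-dropping over independent sites.

    ``founder_freqs`` holds one allele frequency per site; founder dosages
    are Binomial(2, freq) and every non-founder allele is drawn from a
    parent's two alleles. ``forced`` maps site index -> {sample: dosage}
    to override specific genotypes (founder plants and deterministic
    transmissions); a forced child dosage of 1 takes the alt allele from
    the carrier parent, which keeps transmissions Mendelian-consistent.
    """
    m = len(founder_freqs)
    forced = forced or {}
    dosage: Dict[str, np.ndarray] = {}
    for fid in sorted(pedigrees.families):
        ped = pedigrees.families[fid]
        for sid in _drop_order(ped):
            ind = ped.members[sid]
            if ind.is_founder:
                g = rng.binomial(2, founder_freqs)
            else:
                pat = dosage[ind.father_id]
                mat = dosage[ind.mother_id]
                # transmitted allele is alt with probability dosage/2
                g = (rng.random(m) < pat / 2.0).astype(np.int64) + (
                    rng.random(m) < mat / 2.0
                ).astype(np.int64)
            dosage[sid] = g
    for j, overrides in forced.items():
        for sid, g in overrides.items():
            pedigrees.individual(sid)  # KeyError if unknown
            dosage[sid][j] = g
    return dosage


# ---------------------------------------------------------------------------
# site synthesis
# ---------------------------------------------------------------------------


@dataclass
class _Site:
    chrom: str
    pos: int
    ref: str
    alt: str
    annotation: ConsequenceAnnotation
    panel: Optional[PredictorPanel]
    maf_a: Optional[float]
    maf_b: Optional[float]
    founder_freq: float
    planted: Optional[PlantedVariant] = None


def _random_alleles(rng: np.random.Generator) -> Tuple[str, str]:
    i = int(rng.integers(0, 4))
    j = (i + 1 + int(rng.integers(0, 3))) % 4
    return _BASES[i], _BASES[j]


def _choose_weighted(rng: np.random.Generator, options: Sequence[Tuple[str, float]]) -> str:
    terms = [t for t, _ in options]
    w = np.array([x for _, x in options])
    return terms[int(rng.choice(len(terms), p=w / w.sum()))]


def _predictor_panel(
    rng: np.random.Generator,
    tools: Sequence[str],
    consequence: str,
    damaging_rate: float,
    forced_damaging: Optional[int] = None,
) -> PredictorPanel:
    verdicts = {}
    if forced_damaging is not None:
        for k, tool in enumerate(tools):
            verdicts[tool] = "damaging" if k < forced_damaging else "tolerated"
    else:
        base = 0.9 if consequence in LOF_TERMS else damaging_rate
        for tool in tools:
            r = rng.random()
            verdicts[tool] = "damaging" if r < base else ("unknown" if r > 0.97 else "tolerated")
    return PredictorPanel.from_strings(verdicts)


def _qc_metrics(
    rng: np.random.Generator, dosage: int, mean_depth: float, noisy: bool
) -> GenotypeCall:
    if noisy:
        depth = int(rng.integers(3, 9))
    else:
        depth = max(1, int(rng.poisson(mean_depth)))
    if dosage == 1:
        p_alt = 0.12 if noisy else 0.5
    elif dosage == 2:
        p_alt = 0.98
    else:
        p_alt = 0.005
    alt_depth = int(rng.binomial(depth, p_alt))
    gq = int(rng.integers(5, 15)) if noisy else int(rng.integers(80, 100))
    return GenotypeCall(dosage, depth, alt_depth, gq)


# ---------------------------------------------------------------------------
# discovery cohort
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate the full discovery-cohort bundle from one seeded config."""
    rng = np.random.default_rng(config.random_seed)
    pedigrees = build_nuclear_families(
        config.n_families, config.family_children, rng, config.prob_female_child
    )
    family_ids = sorted(pedigrees.families)
    sequenced = [
        ind.sample_id
        for fid in family_ids
        for ind in pedigrees.families[fid].members.values()
        if not ind.sample_id.endswith("_FA")
    ]
    pedigrees.mark_sequenced(sequenced)
    founders = [
        ind.sample_id for fid in family_ids for ind in pedigrees.families[fid].members.values() if ind.is_founder
    ]

    # --- background sites ------------------------------------------------
    sites: List[_Site] = []
    strata = config.background_maf_strata
    stratum_mafs = [m for m, _ in strata]
    stratum_w = np.array([w for _, w in strata])
    pos_counter = 10_000
    for i in range(config.n_background_variants):
        chrom = f"chr{(i % 22) + 1}"
        pos_counter += int(rng.integers(50, 5000))
        maf = stratum_mafs[int(rng.choice(len(stratum_mafs), p=stratum_w / stratum_w.sum()))]
        rare = maf <= 1e-3
        if rare and not config.rare_lof_background:
            term = _choose_weighted(rng, _NONLOF_CONSEQUENCES)
        else:
            term = _choose_weighted(rng, _BACKGROUND_CONSEQUENCES)
        ref, alt = _random_alleles(rng)
        gene = f"BG{i:04d}"
        exon_total = int(rng.integers(2, 16))
        exon_rank = int(rng.integers(1, exon_total + 1))
        ann = ConsequenceAnnotation(
            gene=gene,
            transcript_id=f"TR_{gene}",
            consequence_term=term,
            exon_rank=exon_rank,
            exon_total=exon_total,
            cdna_change=f"c.{exon_rank * 100}{ref}>{alt}",
        )
        panel = _predictor_panel(rng, config.predictor_tools, term, config.background_damaging_rate)
        sites.append(
            _Site(
                chrom=chrom,
                pos=pos_counter,
                ref=ref,
                alt=alt,
                annotation=ann,
                panel=panel,
                maf_a=None if maf == 0.0 else maf,
                maf_b=None if maf == 0.0 else maf,
                founder_freq=maf,
            )
        )

    # --- planted sites ----------------------------------------------------
    forced: Dict[int, Dict[str, int]] = {}
    planted_families: Dict[int, List[str]] = {}
    available_families = list(family_ids)
    for plant in config.planted_risk:
        if plant.n_carrier_families > len(available_families):
            raise ConfigError(f"not enough families left to plant {plant.gene}")
        chosen = [
            available_families.pop(int(rng.integers(0, len(available_families))))
            for _ in range(plant.n_carrier_families)
        ]
        ref, alt = _random_alleles(rng)
        pos_counter += int(rng.integers(50, 5000))
        exon_total = 10
        exon_rank = exon_total if plant.last_exon else int(rng.integers(1, exon_total))
        ann = ConsequenceAnnotation(
            gene=plant.gene,
            transcript_id=plant.transcript_id,
            consequence_term=plant.consequence,
            exon_rank=exon_rank,
            exon_total=exon_total,
            protein_change="p.Trp100*" if plant.consequence == "stop_gained" else None,
            cdna_change=f"c.{exon_rank * 120}{ref}>{alt}",
        )
        panel = _predictor_panel(
            rng,
            config.predictor_tools,
            plant.consequence,
            config.background_damaging_rate,
            forced_damaging=None if plant.consequence in LOF_TERMS else plant.damaging_tools,
        )
        j = len(sites)
        sites.append(
            _Site(
                chrom=f"chr{(j % 22) + 1}",
                pos=pos_counter,
                ref=ref,
                alt=alt,
                annotation=ann,
                panel=panel,
                maf_a=None if plant.absent_from_panels else plant.maf_panel,
                maf_b=None if plant.absent_from_panels else plant.maf_panel,
                founder_freq=0.0,
                planted=plant,
            )
        )
        forced[j] = {}
        for fid in chosen:
            forced[j][f"{fid}_MO"] = 1  # founder plant
            forced[j][f"{fid}_C1"] = 1  # deterministic transmission to first child
        planted_families[j] = chosen

    # cohort-private background sites: one random founder heterozygote
    for j, site in enumerate(sites):
        if site.planted is None and site.founder_freq == 0.0:
            forced[j] = {founders[int(rng.integers(0, len(founders)))]: 1}

    founder_freqs = np.array([s.founder_freq for s in sites])
    dosage = gene_drop(pedigrees, founder_freqs, rng, forced)
    if config.discordant_sample is not None:
        # sample swap: this individual's DNA is from an unrelated person
        pedigrees.individual(config.discordant_sample)  # KeyError if unknown
        dosage[config.discordant_sample] = rng.binomial(2, founder_freqs)

    # --- affection assignment --------------------------------------------
    planted_site_idx = [j for j, s in enumerate(sites) if s.planted is not None]
    for fid in family_ids:
        ped = pedigrees.families[fid]
        for sid in sorted(ped.members):
            ind = ped.members[sid]
            carrier_pen = 0.0
            for j in planted_site_idx:
                if dosage[sid][j] >= 1:
                    carrier_pen = max(carrier_pen, sites[j].planted.penetrance)
            r = rng.random()
            affected = r < carrier_pen or rng.random() < config.sporadic_rate
            if affected:
                if ind.sex == "female":
                    cat = ["breast_cancer", "ovarian_cancer", "other_cancer"][
                        int(rng.choice(3, p=[0.8, 0.12, 0.08]))
                    ]
                else:
                    cat = ["breast_cancer", "other_cancer"][int(rng.choice(2, p=[0.5, 0.5]))]
                ind.affection = cat
                ind.age_at_diagnosis = float(np.round(rng.normal(48, 8), 0))
        # ascertainment: every family entered the study through an affected index
        affected_children = [
            s for s in sorted(ped.members) if ped.members[s].is_affected and not ped.members[s].is_founder
        ]
        if affected_children:
            ped.members[affected_children[0]].is_index = True
        else:
            first_child = sorted(
                s for s in ped.members if not ped.members[s].is_founder
            )[0]
            ped.members[first_child].affection = "breast_cancer"
            ped.members[first_child].age_at_diagnosis = float(np.round(rng.normal(42, 6), 0))
            ped.members[first_child].is_index = True

    # --- materialize records ----------------------------------------------
    records: List[VariantRecord] = []
    freqs = PopulationFrequencies()
    truth_planted = []
    for j, site in enumerate(sites):
        genotypes: Dict[str, GenotypeCall] = {}
        any_alt = False
        for sid in sequenced:
            g = int(dosage[sid][j])
            noisy = config.noise_fraction > 0 and rng.random() < config.noise_fraction
            genotypes[sid] = _qc_metrics(rng, g, config.mean_depth, noisy)
            any_alt = any_alt or g > 0
        if not any_alt and site.planted is None:
            continue  # monomorphic in the sequenced cohort: not a called variant
        rec = VariantRecord(
            chrom=site.chrom,
            pos=site.pos,
            ref=site.ref,
            alt=site.alt,
            variant_id=None,
            site_quality=float(np.round(rng.uniform(200, 5000), 1)),
            genotypes=genotypes,
            annotations=[site.annotation],
            predictors=site.panel,
            maf_panel_a=site.maf_a,
            maf_panel_b=site.maf_b,
        )
        records.append(rec)
        if site.maf_a is not None:
            freqs.panel_a[rec.key] = site.maf_a
        if site.maf_b is not None:
            freqs.panel_b[rec.key] = site.maf_b
        if site.planted is not None:
            carriers = [s for s in sequenced if dosage[s][j] >= 1]
            truth_planted.append(
                {
                    "key": list(rec.key),
                    "gene": site.planted.gene,
                    "transcript_id": site.planted.transcript_id,
                    "consequence": site.planted.consequence,
                    "penetrance": site.planted.penetrance,
                    "carrier_samples": carriers,
                    "carrier_families": sorted({s.split("_")[0] for s in carriers}),
                    "last_exon": site.planted.last_exon,
                    "absent_from_panels": site.planted.absent_from_panels,
                }
            )

    truth = {
        "planted": truth_planted,
        "n_families": config.n_families,
        "n_sequenced": len(sequenced),
        "seed": config.random_seed,
    }
    return CohortBundle(records, sequenced, pedigrees, freqs, truth)


# ---------------------------------------------------------------------------
# replication cohort
# ---------------------------------------------------------------------------


@dataclass
class ReplicationPlant:
    """A distinct LoF to plant in a candidate gene in the replication cohort."""

    gene: str
    transcript_id: Optional[str] = None  # None: reuse the discovery transcript
    consequence: str = "frameshift_variant"
    n_carriers: int = 1
    last_exon: bool = False
    absent_from_panels: bool = True
    maf_panel: float = 0.0

    def __post_init__(self) -> None:
        if self.absent_from_panels and self.maf_panel > 0:
            raise ConfigError(
                f"replication plant in {self.gene}: maf_panel inconsistent with absent_from_panels"
            )


@dataclass
class ReplicationConfig:
    n_patients: int = 51
    n_background_variants: int = 150
    background_maf_strata: Tuple[Tuple[float, float], ...] = (
        (0.0, 0.2),
        (5e-5, 0.2),
        (5e-4, 0.2),
        (2e-3, 0.2),
        (1e-2, 0.2),
    )
    rare_lof_background: bool = True
    background_damaging_rate: float = 0.3
    plants: List[ReplicationPlant] = field(default_factory=list)
    identical_variants: List[VariantKey] = field(default_factory=list)
    predictor_tools: Tuple[str, ...] = DEFAULT_PREDICTOR_TOOLS
    mean_depth: float = 150.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        self.plants = [
            p if isinstance(p, ReplicationPlant) else ReplicationPlant(**p)
            for p in self.plants
        ]
        self.identical_variants = [tuple(k) for k in self.identical_variants]
        self.background_maf_strata = tuple(
            (float(m), float(w)) for m, w in self.background_maf_strata
        )


def simulate_replication_cohort(
    config: ReplicationConfig, candidate_records: Sequence[VariantRecord] = ()
) -> CohortBundle:
    """Generate a cohort of unrelated affected singleton patients.

    ``candidate_records`` are discovery-cohort records used two ways: a
    :class:`ReplicationPlant` without an explicit transcript inherits the
    discovery transcript (and exon count) of its gene, and keys listed in
    ``config.identical_variants`` are re-planted identically (same
    chrom/pos/ref/alt) in one patient for presence lookups.
    """
    rng = np.random.default_rng(config.random_seed)
    coll = PedigreeCollection()
    samples = []
    for p in range(config.n_patients):
        fid = f"R{p + 1:03d}"
        sid = f"{fid}_P"
        ped = Pedigree(fid)
        ped.add(
            PedigreeIndividual(
                sid,
                fid,
                None,
                None,
                "female" if rng.random() < 0.95 else "male",
                affection="breast_cancer",
                age_at_diagnosis=float(np.round(rng.normal(45, 9), 0)),
                is_index=True,
            )
        )
        coll.families[fid] = ped
        samples.append(sid)
    coll.mark_sequenced(samples)

    by_key = {rec.key: rec for rec in candidate_records}
    by_gene: Dict[str, VariantRecord] = {}
    for rec in candidate_records:
        for ann in rec.annotations:
            by_gene.setdefault(ann.gene, rec)

    sites: List[_Site] = []
    carriers_per_site: Dict[int, List[str]] = {}
    pos_counter = 5_000_000
    for i in range(config.n_background_variants):
        chrom = f"chr{(i % 22) + 1}"
        pos_counter += int(rng.integers(50, 5000))
        mafs = [m for m, _ in config.background_maf_strata]
        w = np.array([x for _, x in config.background_maf_strata])
        maf = mafs[int(rng.choice(len(mafs), p=w / w.sum()))]
        rare = maf <= 1e-3
        if rare and not config.rare_lof_background:
            term = _choose_weighted(rng, _NONLOF_CONSEQUENCES)
        else:
            term = _choose_weighted(rng, _BACKGROUND_CONSEQUENCES)
        ref, alt = _random_alleles(rng)
        gene = f"RB{i:04d}"
        exon_total = int(rng.integers(2, 16))
        ann = ConsequenceAnnotation(
            gene=gene,
            transcript_id=f"TR_{gene}",
            consequence_term=term,
            exon_rank=int(rng.integers(1, exon_total + 1)),
            exon_total=exon_total,
        )
        sites.append(
            _Site(
                chrom,
                pos_counter,
                ref,
                alt,
                ann,
                _predictor_panel(rng, config.predictor_tools, term, config.background_damaging_rate),
                None if maf == 0.0 else maf,
                None if maf == 0.0 else maf,
                maf,
            )
        )

    truth_planted = []
    for plant in config.plants:
        template = by_gene.get(plant.gene)
        if plant.transcript_id is None:
            if template is None:
                raise ConfigError(
                    f"replication plant for {plant.gene} has no discovery record to copy a transcript from"
                )
            transcript = template.annotations[0].transcript_id
            exon_total = template.annotations[0].exon_total or 10
        else:
            transcript = plant.transcript_id
            exon_total = 10
        exon_rank = exon_total if plant.last_exon else max(1, int(rng.integers(1, exon_total)))
        ref, alt = _random_alleles(rng)
        pos_counter += int(rng.integers(50, 5000))
        chrom = template.chrom if template is not None else f"chr{int(rng.integers(1, 23))}"
        ann = ConsequenceAnnotation(
            gene=plant.gene,
            transcript_id=transcript,
            consequence_term=plant.consequence,
            exon_rank=exon_rank,
            exon_total=exon_total,
            protein_change="p.Arg32fs" if plant.consequence == "frameshift_variant" else None,
        )
        j = len(sites)
        sites.append(
            _Site(
                chrom,
                pos_counter,
                ref,
                alt,
                ann,
                _predictor_panel(rng, config.predictor_tools, plant.consequence, 0.3),
                None if plant.absent_from_panels else plant.maf_panel,
                None if plant.absent_from_panels else plant.maf_panel,
                0.0,
            )
        )
        chosen = list(rng.choice(samples, size=plant.n_carriers, replace=False))
        carriers_per_site[j] = [str(s) for s in chosen]
        truth_planted.append(
            {
                "key": [chrom, pos_counter, ref, alt],
                "gene": plant.gene,
                "transcript_id": transcript,
                "consequence": plant.consequence,
                "carrier_samples": sorted(str(s) for s in chosen),
                "last_exon": plant.last_exon,
                "kind": "distinct_lof",
            }
        )

    identical_truth = []
    for key in config.identical_variants:
        template = by_key.get(tuple(key))
        if template is None:
            raise ConfigError(f"identical variant {key} not among candidate records")
        j = len(sites)
        sites.append(
            _Site(
                template.chrom,
                template.pos,
                template.ref,
                template.alt,
                template.annotations[0],
                template.predictors,
                template.maf_panel_a,
                template.maf_panel_b,
                0.0,
            )
        )
        carrier = str(rng.choice(samples))
        carriers_per_site[j] = [carrier]
        identical_truth.append({"key": list(template.key), "carrier_samples": [carrier]})

    # singleton genotypes: founders only, so draw directly
    records: List[VariantRecord] = []
    freqs = PopulationFrequencies()
    for j, site in enumerate(sites):
        genotypes: Dict[str, GenotypeCall] = {}
        planted_carriers = set(carriers_per_site.get(j, []))
        any_alt = False
        for sid in samples:
            if sid in planted_carriers:
                g = 1
            elif site.founder_freq > 0:
                g = int(rng.binomial(2, site.founder_freq))
            else:
                g = 0
            genotypes[sid] = _qc_metrics(rng, g, config.mean_depth, noisy=False)
            any_alt = any_alt or g > 0
        if not any_alt:
            continue
        rec = VariantRecord(
            chrom=site.chrom,
            pos=site.pos,
            ref=site.ref,
            alt=site.alt,
            site_quality=float(np.round(rng.uniform(200, 5000), 1)),
            genotypes=genotypes,
            annotations=[site.annotation],
            predictors=site.panel,
            maf_panel_a=site.maf_a,
            maf_panel_b=site.maf_b,
        )
        records.append(rec)
        if site.maf_a is not None:
            freqs.panel_a[rec.key] = site.maf_a
        if site.maf_b is not None:
            freqs.panel_b[rec.key] = site.maf_b

    truth = {
        "planted": truth_planted,
        "identical": identical_truth,
        "n_patients": config.n_patients,
        "seed": config.random_seed,
    }
    return CohortBundle(records, samples, coll, freqs, truth)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_bundle(bundle: CohortBundle, outdir: str | Path, prefix: str = "cohort") -> Dict[str, Path]:
    """Write VCF + PED + frequency panels + truth manifest; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / f"{prefix}.vcf",
        "ped": outdir / f"{prefix}.ped",
        "panel_a": outdir / f"{prefix}.panel_a.tsv",
        "panel_b": outdir / f"{prefix}.panel_b.tsv",
        "truth": outdir / f"{prefix}.truth.json",
    }
    write_vcf(bundle.records, bundle.samples, paths["vcf"])
    write_ped(bundle.pedigrees, paths["ped"])
    write_frequency_table(bundle.frequencies.panel_a, paths["panel_a"])
    write_frequency_table(bundle.frequencies.panel_b, paths["panel_b"])
    paths["truth"].write_text(json.dumps(bundle.truth, indent=2, sort_keys=True) + "\n")
    return paths
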