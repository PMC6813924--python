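"""Generator contracts: determinism, Mendelian consistency, penetrance, plants."""

import numpy as np
import pytest

from conftest import PLANTED_GENES, clean_discovery_config
from hbocprio import gene_prioritization as gp
from hbocprio.synthetic_data import (
    ConfigError,
    PlantedVariant,
    ReplicationConfig,
    ReplicationPlant,
    SimulationConfig,
    build_nuclear_families,
    gene_drop,
    simulate_cohort,
    simulate_replication_cohort,
    write_bundle,
)


def test_identical_config_and_seed_give_identical_bytes(tmp_path):
    cfg = dict(n_background_variants=150, planted_risk=[PlantedVariant(gene="G1")], random_seed=9)
    p1 = write_bundle(simulate_cohort(SimulationConfig(**cfg)), tmp_path / "a")
    p2 = write_bundle(simulate_cohort(SimulationConfig(**cfg)), tmp_path / "b")
    for name in ("vcf", "ped", "panel_a", "panel_b", "truth"):
        assert p1[name].read_bytes() == p2[name].read_bytes()


def test_default_layout_matches_study_scale(clean_bundle):
    assert len(clean_bundle.pedigrees.families) == 17
    assert len(clean_bundle.samples) == 52
    sexes = [clean_bundle.pedigrees.individual(s).sex for s in clean_bundle.samples]
    assert sexes.count("male") >= 1  # male breast cancer is allowed
    for ped in clean_bundle.pedigrees.families.values():
        index = [m for m in ped.members.values() if m.is_index]
        assert len(index) == 1 and index[0].is_affected


def test_fully_penetrant_plant_in_mother_daughter_pair():
    cfg = SimulationConfig(
        n_families=1,
        family_children=[1],
        n_background_variants=20,
        planted_risk=[PlantedVariant(gene="G1", penetrance=1.0)],
        random_seed=3,
    )
    bundle = simulate_cohort(cfg)
    (entry,) = bundle.truth["planted"]
    assert set(entry["carrier_samples"]) >= {"F01_MO", "F01_C1"}
    for s in entry["carrier_samples"]:
        assert bundle.pedigrees.individual(s).is_affected


def test_mendelian_consistency_across_seeds():
    """Every non-founder allele is traceable to a parent, all sites."""
    for seed in range(3):
        rng = np.random.default_rng(seed)
        coll = build_nuclear_families(5, [3, 2, 2, 4, 2], rng)
        freqs = rng.uniform(0.0, 0.5, size=300)
        dosage = gene_drop(coll, freqs, rng)
        for ped in coll.families.values():
            for ind in ped.members.values():
                if ind.is_founder:
                    continue
                pat, mat, g = dosage[ind.father_id], dosage[ind.mother_id], dosage[ind.sample_id]
                lower = (pat == 2).astype(int) + (mat == 2).astype(int)
                upper = (pat >= 1).astype(int) + (mat >= 1).astype(int)
                assert np.all(g >= lower) and np.all(g <= upper)


def test_forced_transmission_is_mendelian_consistent():
    bundle = simulate_cohort(clean_discovery_config(seed=17))
    planted_keys = {tuple(t["key"]) for t in bundle.truth["planted"]}
    by_key = {r.key: r for r in bundle.records}
    for t in bundle.truth["planted"]:
        rec = by_key[tuple(t["key"])]
        for fam in t["carrier_families"]:
            mother = rec.genotypes[f"{fam}_MO"].allele_count
            child = rec.genotypes[f"{fam}_C1"].allele_count
            assert mother >= 1 and child >= 1  # child's alt allele exists in the mother


def test_realized_founder_frequency_converges():
    rng = np.random.default_rng(1)
    coll = build_nuclear_families(400, [2] * 400, rng)
    target = 0.07
    dosage = gene_drop(coll, np.full(200, target), rng)
    founders = [i.sample_id for i in coll.all_individuals() if i.is_founder]
    realized = np.mean([dosage[s] for s in founders]) / 2.0
    se = np.sqrt(target * (1 - target) / (2 * len(founders) * 200))
    assert abs(realized - target) < 4 * se


def test_recovery_sensitivity_degrades_with_penetrance():
    def sensitivity(penetrance, seed):
        cfg = clean_discovery_config(
            seed=seed,
            planted_risk=[PlantedVariant(gene=g, penetrance=penetrance) for g in PLANTED_GENES],
        )
        bundle = simulate_cohort(cfg)
        found = {c.gene for c in gp.shortlist_genes_discovery(bundle.records, bundle.pedigrees)}
        return len(found & set(PLANTED_GENES)) / len(PLANTED_GENES)

    full = np.mean([sensitivity(1.0, s) for s in range(6)])
    low = np.mean([sensitivity(0.2, s) for s in range(6)])
    assert full == 1.0
    assert low <= full


def test_planted_maf_inconsistent_with_absence_rejected():
    with pytest.raises(ConfigError, match="inconsistent"):
        PlantedVariant(gene="G", absent_from_panels=True, maf_panel=0.001)
    with pytest.raises(ConfigError, match="penetrance"):
        PlantedVariant(gene="G", penetrance=1.5)
    with pytest.raises(ConfigError, match="sum to 1"):
        SimulationConfig(background_maf_strata=((0.0, 0.5), (0.01, 0.2)))


def test_replication_plant_recovers_candidate_gene(clean_bundle):
    cands = gp.shortlist_genes_discovery(clean_bundle.records, clean_bundle.pedigrees)

    def replicate_with(**plant_kw):
        cfg = ReplicationConfig(
            rare_lof_background=False,
            plants=[ReplicationPlant(gene="RISK2", **plant_kw)],
            random_seed=31,
        )
        rep = simulate_replication_cohort(cfg, clean_bundle.records)
        return {c.gene for c in gp.replicate_genes(cands, rep.records)}

    # a second, distinct LoF on the discovery transcript in 1 of 51 singletons
    assert replicate_with() == {"RISK2"}
    # forced into the last exon: excluded
    assert replicate_with(last_exon=True) == set()
    # on a different transcript of the same gene: excluded
    assert replicate_with(transcript_id="TR_OTHER") == set()


def test_replication_cohort_is_unrelated_singletons(replication_bundle):
    assert len(replication_bundle.samples) == 51
    assert len(replication_bundle.pedigrees.families) == 51
    for s in replication_bundle.samples:
        assert replication_bundle.pedigrees.individual(s).is_affected
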