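"""CGV / SVGU / FSV tagging and the combined variant-based shortlist."""

import pytest

from conftest import clean_discovery_config
from helpers import call, family, pedigrees, record
from hbocprio.gene_prioritization import shortlist_genes_discovery
from hbocprio.synthetic_data import (
    PlantedVariant,
    ReplicationConfig,
    simulate_cohort,
    simulate_replication_cohort,
)
from hbocprio.variant_prioritization import (
    CGV,
    FSV,
    GeneListError,
    SVGU_IDENTICAL,
    SVGU_SAME_GENE,
    cgv_select,
    cross_cohort_presence,
    fsv_select,
    merge_tags,
    shortlist_variants,
    svgu_select,
)


def two_family_setting():
    return pedigrees(
        family("F1", [("C1", "breast_cancer")], mother_affection="breast_cancer"),
        family("F2", [("C1", "breast_cancer")]),
    )


# --- CGV -------------------------------------------------------------------


def test_cgv_tags_by_gene_list_membership():
    recs = [
        record(pos=100, gene="SETBP1", consequence="missense_variant", carriers=("F1_C1",)),
        record(pos=200, gene="NOVEL", consequence="stop_gained", carriers=("F1_C1",)),
    ]
    tags = cgv_select(recs, ["setbp1", "BRCA1"])
    assert tags == {recs[0].key: {CGV}}  # LoF in an unlisted gene stays untagged


def test_cgv_set_membership_is_exact():
    recs = [
        record(pos=100 + i, gene=f"G{i}", consequence="missense_variant", carriers=("F1_C1",))
        for i in range(200)
    ]
    listed = [f"G{i}" for i in range(0, 200, 20)]  # 10 of 200
    tags = cgv_select(recs, listed)
    assert len(tags) == 10
    assert {k for k in tags} == {recs[i].key for i in range(0, 200, 20)}


def test_empty_gene_list_is_a_configuration_error():
    with pytest.raises(GeneListError):
        cgv_select([record()], [])


# --- SVGU ------------------------------------------------------------------


def test_identical_variant_in_unrelated_patients_tagged():
    peds = two_family_setting()
    rec = record(gene="C7ORF34", consequence="missense_variant",
                 carriers=("F1_MO", "F1_C1", "F2_C1"))
    tags = svgu_select([rec], peds)
    assert tags[rec.key] == {SVGU_IDENTICAL}


def test_identical_variant_within_one_family_untagged():
    peds = two_family_setting()
    rec = record(gene="G", consequence="missense_variant", carriers=("F1_MO", "F1_C1"))
    assert svgu_select([rec], peds) == {}


def test_kinship_overrides_family_labels():
    # same declared families, but the pair is genetically related (phi 0.25):
    # cryptic relatedness suppresses the SVGU tag
    peds = two_family_setting()
    rec = record(gene="G", consequence="missense_variant", carriers=("F1_C1", "F2_C1"))
    phi = {("F1_C1", "F2_C1"): 0.25}
    assert svgu_select([rec], peds, kinship_phi=phi) == {}
    phi = {("F1_C1", "F2_C1"): -0.01}
    assert svgu_select([rec], peds, kinship_phi=phi)[rec.key] == {SVGU_IDENTICAL}


def test_distinct_variants_same_transcript_in_unrelated_tagged():
    peds = two_family_setting()
    r1 = record(pos=100, gene="G", consequence="missense_variant", carriers=("F1_C1",))
    r2 = record(pos=200, gene="G", consequence="inframe_deletion", carriers=("F2_C1",))
    tags = svgu_select([r1, r2], peds)
    assert tags[r1.key] == {SVGU_SAME_GENE} and tags[r2.key] == {SVGU_SAME_GENE}


def test_distinct_variants_different_transcripts_untagged_by_default():
    peds = two_family_setting()
    r1 = record(pos=100, gene="G", transcript="TR_G1", consequence="missense_variant",
                carriers=("F1_C1",))
    r2 = record(pos=200, gene="G", transcript="TR_G2", consequence="missense_variant",
                carriers=("F2_C1",))
    assert svgu_select([r1, r2], peds) == {}
    relaxed = svgu_select([r1, r2], peds, require_same_transcript=False)
    assert relaxed[r1.key] == {SVGU_SAME_GENE}


# --- FSV -------------------------------------------------------------------


def test_fsv_requires_ultra_rare_and_single_family():
    peds = two_family_setting()
    private = record(pos=100, gene="G1", consequence="missense_variant",
                     carriers=("F1_MO", "F1_C1"))
    too_common = record(pos=200, gene="G2", consequence="missense_variant",
                        carriers=("F1_C1",), maf_b=0.0005)  # 0.05%
    two_fams = record(pos=300, gene="G3", consequence="missense_variant",
                      carriers=("F1_C1", "F2_C1"))
    tags = fsv_select([private, too_common, two_fams], peds)
    assert tags == {private.key: {FSV}}


def test_fsv_threshold_is_strict():
    peds = two_family_setting()
    at_limit = record(gene="G", carriers=("F1_C1",), maf_a=0.0001, maf_b=0.0001)
    assert fsv_select([at_limit], peds) == {}


def test_fsv_and_svgu_identical_are_mutually_exclusive():
    with pytest.raises(AssertionError):
        merge_tags({("chr1", 1, "A", "C"): {FSV}}, {("chr1", 1, "A", "C"): {SVGU_IDENTICAL}})


# --- combined shortlist ----------------------------------------------------


def test_tagged_missense_with_single_damaging_tool_shortlisted():
    # two affected sisters carrying a CGV+SVGU missense damaging in 1/7 tools
    peds = pedigrees(
        family("F1", [("C1", "breast_cancer"), ("C2", "breast_cancer")]),
        family("F2", [("C1", "breast_cancer")]),
    )
    rec = record(gene="SETBP1", consequence="missense_variant",
                 carriers=("F1_C1", "F1_C2", "F2_C1"), noncarriers=("F1_MO", "F1_FA"),
                 damaging=1)
    tags = merge_tags(cgv_select([rec], ["SETBP1"]), svgu_select([rec], peds))
    assert tags[rec.key] == {CGV, SVGU_IDENTICAL}
    (cand,) = shortlist_variants([rec], tags, peds, consensus_k=1)
    assert cand.strategy_tags == {CGV, SVGU_IDENTICAL}
    assert cand.n_carrier_patients == 3


def test_zero_damaging_votes_fails_consensus_unless_lof():
    peds = two_family_setting()
    rec = record(gene="SETBP1", consequence="missense_variant",
                 carriers=("F1_MO", "F1_C1", "F2_C1"), damaging=0)
    tags = svgu_select([rec], peds)
    assert shortlist_variants([rec], tags, peds, consensus_k=1) == []
    lof = record(pos=999, gene="SETBP1", consequence="stop_gained",
                 carriers=("F1_MO", "F1_C1", "F2_C1"), damaging=0)
    tags = svgu_select([lof], peds)
    assert len(shortlist_variants([lof], tags, peds, consensus_k=1)) == 1


def test_variant_absent_from_an_affected_relative_dropped():
    peds = pedigrees(
        family("F1", [("C1", "breast_cancer"), ("C2", "breast_cancer")]),
        family("F2", [("C1", "breast_cancer")]),
    )
    rec = record(gene="G", consequence="missense_variant",
                 carriers=("F1_C1", "F2_C1"), noncarriers=("F1_C2", "F1_MO", "F1_FA"),
                 damaging=4)
    tags = svgu_select([rec], peds)
    assert tags  # tagged, but the second affected sister does not carry it
    assert shortlist_variants([rec], tags, peds) == []


def test_rare_maf_filter_applies_to_shortlist():
    peds = two_family_setting()
    rec = record(gene="G", consequence="missense_variant",
                 carriers=("F1_C1", "F2_C1"), damaging=4, maf_b=0.002)
    tags = svgu_select([rec], peds)
    assert shortlist_variants([rec], tags, peds) == []


def test_shortlist_is_subset_of_tagged_set(clean_bundle):
    peds, records = clean_bundle.pedigrees, clean_bundle.records
    tags = merge_tags(
        svgu_select(records, peds),
        fsv_select(records, peds),
    )
    cands = shortlist_variants(records, tags, peds)
    assert {c.key for c in cands} <= set(tags)


def test_variant_truth_manifest_recovered_exactly():
    """With sterile background, the shortlist equals the planted qualifying set."""
    cfg = clean_discovery_config(
        seed=29,
        sporadic_rate=0.0,
        planted_risk=[
            PlantedVariant(gene="CANC1", consequence="missense_variant",
                           damaging_tools=4),  # CGV (listed below) + FSV
            PlantedVariant(gene="SHARED1", consequence="missense_variant",
                           n_carrier_families=2, damaging_tools=1),  # SVGU identical
            PlantedVariant(gene="LOFG1"),  # FSV stop-gain
        ],
    )
    bundle = simulate_cohort(cfg)
    records, peds = bundle.records, bundle.pedigrees
    tags = merge_tags(
        cgv_select(records, ["CANC1"]),
        svgu_select(records, peds),
        fsv_select(records, peds),
    )
    cands = shortlist_variants(records, tags, peds)
    assert {c.key for c in cands} == {tuple(t["key"]) for t in bundle.truth["planted"]}


def test_cross_cohort_presence_flags_identical_keys(clean_bundle, replication_bundle):
    cands = shortlist_genes_discovery(clean_bundle.records, clean_bundle.pedigrees)
    presence = cross_cohort_presence(cands, replication_bundle.records)
    expected_present = {tuple(e["key"]) for e in replication_bundle.truth["identical"]}
    flagged = {k for k, v in presence.items() if v}
    assert flagged == expected_present & {c.key for c in cands}
    assert flagged  # the planted identical overlap is found
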