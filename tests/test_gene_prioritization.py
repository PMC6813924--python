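"""Gene-based discovery shortlist, QC surrogate, and replication rules."""

import numpy as np
import pytest

from conftest import PLANTED_GENES, clean_discovery_config
from helpers import call, family, pedigrees, record
from hbocprio.gene_prioritization import (
    QCThresholds,
    SegregationError,
    qc_surrogate,
    replicate_genes,
    shortlist_genes_discovery,
)
from hbocprio.synthetic_data import SimulationConfig, _qc_metrics, simulate_cohort


# --- QC surrogate ----------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs,expected",
    [
        (dict(depth=60, alt_depth=29, genotype_quality=99), True),  # clean het
        (dict(depth=60, alt_depth=5, genotype_quality=99), False),  # balance 0.08
        (dict(depth=5, alt_depth=3, genotype_quality=99), False),  # shallow
        (dict(depth=60, alt_depth=29, genotype_quality=10), False),  # low GQ
        (dict(depth=None, alt_depth=None, genotype_quality=None), False),  # no metrics
    ],
)
def test_het_qc_surrogate(kwargs, expected):
    from hbocprio.io_formats import GenotypeCall

    assert qc_surrogate(GenotypeCall(1, **kwargs)) is expected


def test_hom_alt_requires_high_alt_fraction():
    from hbocprio.io_formats import GenotypeCall

    assert qc_surrogate(GenotypeCall(2, depth=50, alt_depth=49, genotype_quality=90))
    assert not qc_surrogate(GenotypeCall(2, depth=50, alt_depth=30, genotype_quality=90))


def test_qc_rejects_simulated_noisy_carrier_calls():
    """Calls drawn from the generator's degraded-quality model never pass."""
    rng = np.random.default_rng(0)
    noisy = [_qc_metrics(rng, 1, 150.0, noisy=True) for _ in range(200)]
    clean = [_qc_metrics(rng, 1, 150.0, noisy=False) for _ in range(200)]
    assert sum(qc_surrogate(c) for c in noisy) == 0
    assert np.mean([qc_surrogate(c) for c in clean]) > 0.95


# --- discovery rule --------------------------------------------------------


def mother_daughter_setting():
    peds = pedigrees(
        family("F25", [("C1", "breast_cancer")], mother_affection="breast_cancer")
    )
    rec = record(
        gene="MDM1",
        consequence="stop_gained",
        carriers=("F25_MO", "F25_C1"),
        noncarriers=("F25_FA",),
    )
    return peds, rec


def test_planted_stopgain_in_affected_pair_shortlisted():
    peds, rec = mother_daughter_setting()
    (cand,) = shortlist_genes_discovery([rec], peds)
    assert cand.gene == "MDM1" and cand.n_carrier_patients == 2
    assert cand.carrier_families == ["F25"]


def test_maf_above_threshold_in_one_panel_excludes():
    peds, rec = mother_daughter_setting()
    rec.maf_panel_b = 0.002  # 0.2% in the gnomAD-like panel
    assert shortlist_genes_discovery([rec], peds) == []
    rec.maf_panel_b = 0.001  # threshold is inclusive
    assert len(shortlist_genes_discovery([rec], peds)) == 1


def test_single_affected_family_needs_only_one_carrier():
    peds = pedigrees(family("F1", [("C1", "breast_cancer")]))
    rec = record(gene="G1", carriers=("F1_C1",), noncarriers=("F1_MO", "F1_FA"))
    (cand,) = shortlist_genes_discovery([rec], peds)
    assert cand.n_carrier_patients == 1


def test_multi_affected_family_requires_two_carriers():
    peds = pedigrees(
        family("F1", [("C1", "breast_cancer"), ("C2", "ovarian_cancer")])
    )
    rec = record(gene="G1", carriers=("F1_C1",), noncarriers=("F1_C2", "F1_MO", "F1_FA"))
    assert shortlist_genes_discovery([rec], peds) == []
    rec2 = record(gene="G1", carriers=("F1_C1", "F1_C2"), noncarriers=("F1_MO", "F1_FA"))
    (cand,) = shortlist_genes_discovery([rec2], peds)
    assert cand.n_carrier_patients == 2


def test_non_lof_variants_never_shortlisted():
    peds, _ = mother_daughter_setting()
    rec = record(gene="G", consequence="missense_variant", carriers=("F25_MO", "F25_C1"))
    assert shortlist_genes_discovery([rec], peds) == []


def test_unaffected_carriers_reported_but_not_counted():
    peds = pedigrees(
        family("F1", [("C1", "breast_cancer"), ("C2", "unaffected")],
               mother_affection="breast_cancer")
    )
    rec = record(gene="G1", carriers=("F1_MO", "F1_C1", "F1_C2"), noncarriers=("F1_FA",))
    (cand,) = shortlist_genes_discovery([rec], peds)
    assert cand.n_carrier_patients == 2
    assert cand.unaffected_carriers == ["F1_C2"]


def test_carrier_without_pedigree_is_a_hard_error():
    peds = pedigrees(family("F1", [("C1", "breast_cancer")]))
    rec = record(gene="G1", carriers=("F1_C1", "ORPHAN"))
    with pytest.raises(SegregationError, match="ORPHAN"):
        shortlist_genes_discovery([rec], peds)


def test_qc_failing_carrier_not_counted():
    peds = pedigrees(
        family("F1", [("C1", "breast_cancer"), ("C2", "breast_cancer")])
    )
    rec = record(gene="G1", carriers=("F1_C1",), noncarriers=("F1_MO", "F1_FA"))
    rec.genotypes["F1_C2"] = call(1, depth=5, alt_depth=3)  # carrier, fails QC
    assert shortlist_genes_discovery([rec], peds) == []


def test_excluded_sample_removed_from_counting():
    peds, rec = mother_daughter_setting()
    # the mother's sample is kinship-excluded: the daughter alone qualifies,
    # because she is then the family's only countable affected member
    (cand,) = shortlist_genes_discovery([rec], peds, excluded_samples=frozenset({"F25_MO"}))
    assert cand.carrier_samples == ["F25_C1"]


def test_truth_manifest_recovered_exactly(clean_bundle):
    cands = shortlist_genes_discovery(clean_bundle.records, clean_bundle.pedigrees)
    assert {c.gene for c in cands} == set(PLANTED_GENES)
    assert {c.key for c in cands} == {tuple(t["key"]) for t in clean_bundle.truth["planted"]}


def test_null_cohort_with_common_background_yields_empty_shortlist():
    cfg = SimulationConfig(
        n_families=8,
        family_children=[2] * 8,
        n_background_variants=300,
        background_maf_strata=((2e-3, 0.5), (1e-2, 0.5)),
        planted_risk=[],
        random_seed=13,
    )
    bundle = simulate_cohort(cfg)
    assert shortlist_genes_discovery(bundle.records, bundle.pedigrees) == []


def test_thresholds_are_monotone(clean_bundle):
    records, peds = clean_bundle.records, clean_bundle.pedigrees
    base = {c.key for c in shortlist_genes_discovery(records, peds, maf_max=0.001)}
    tighter = {c.key for c in shortlist_genes_discovery(records, peds, maf_max=0.0001)}
    stricter = {c.key for c in shortlist_genes_discovery(records, peds, min_family_carriers=3)}
    assert tighter <= base and stricter <= base


# --- replication -----------------------------------------------------------


def discovery_candidate(exon=(2, 9)):
    peds, _ = mother_daughter_setting()
    rec = record(gene="MDM1", transcript="TR_MDM1", exon=exon,
                 carriers=("F25_MO", "F25_C1"), noncarriers=("F25_FA",))
    return shortlist_genes_discovery([rec], peds)


def test_distinct_lof_same_transcript_replicates():
    cands = discovery_candidate()
    rep = record(pos=5000, ref="A", alt="T", gene="MDM1", transcript="TR_MDM1",
                 consequence="frameshift_variant", exon=(2, 9), carriers=("R001_P",))
    (out,) = replicate_genes(cands, [rep])
    assert out.stages == ["discovery", "replicated"]
    assert out.replication_variants == [rep.key]


def test_replication_requires_same_transcript():
    cands = discovery_candidate()
    rep = record(pos=5000, gene="MDM1", transcript="TR_MDM1_alt",
                 consequence="frameshift_variant", exon=(2, 9), carriers=("R001_P",))
    assert replicate_genes(cands, [rep]) == []


def test_replication_excludes_last_exon_on_either_side():
    rep_ok = record(pos=5000, gene="MDM1", transcript="TR_MDM1",
                    consequence="frameshift_variant", exon=(2, 9), carriers=("R001_P",))
    rep_last = record(pos=5000, gene="MDM1", transcript="TR_MDM1",
                      consequence="frameshift_variant", exon=(9, 9), carriers=("R001_P",))
    assert replicate_genes(discovery_candidate(), [rep_last]) == []
    assert replicate_genes(discovery_candidate(exon=(9, 9)), [rep_ok]) == []
    assert replicate_genes(discovery_candidate(exon=(None, None)), [rep_ok]) == []


def test_replication_respects_maf_filter():
    cands = discovery_candidate()
    rep = record(pos=5000, gene="MDM1", transcript="TR_MDM1",
                 consequence="frameshift_variant", exon=(2, 9), carriers=("R001_P",),
                 maf_b=0.002)
    assert replicate_genes(cands, [rep]) == []


def test_replicated_genes_are_subset_of_discovery(clean_bundle, replication_bundle):
    cands = shortlist_genes_discovery(clean_bundle.records, clean_bundle.pedigrees)
    replicated = replicate_genes(cands, replication_bundle.records)
    assert {c.gene for c in replicated} <= {c.gene for c in cands}
    assert {c.gene for c in replicated} == {"RISK1", "RISK3"}
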