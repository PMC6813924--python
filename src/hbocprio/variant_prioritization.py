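"""Variant-based prioritization: three strategies over an expanded universe.

Beyond LoF, the variant-based universe also admits in-frame indels,
missense and stop-loss variants. Three tagging strategies run over it:

* **CGV** — cancer gene variants: the variant's gene is on a curated
  cancer-gene list.
* **SVGU** — shared variants/genes in unrelated patients: either the
  identical variant is carried by genetically unrelated patients
  (different family *and* pairwise kinship below the unrelated cutoff), or
  two distinct admitted variants on the same transcript of one gene are
  carried by unrelated patients.
* **FSV** — family-specific variants: ultra-rare (MAF < 0.01%, strict)
  variants whose carriers all belong to a single family or patient.

A tagged variant is shortlisted if it additionally passes the rare-MAF
filter in both panels, is LoF or called damaging by at least ``k`` panel
predictors, is present in all affected sequenced relatives of each carrier
family, and its counted carrier genotypes pass the QC surrogate.

FSV and SVGU-identical are mutually exclusive by construction
(single-family versus shared-across-unrelated); this is asserted on every
tagging run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

from .annotation import classify_lof, in_variant_universe, predictor_consensus
from .gene_prioritization import (
    CandidateRecord,
    QCThresholds,
    SegregationError,
    passes_maf_filter,
    qc_surrogate,
)
from .io_formats import PedigreeCollection, VariantKey, VariantRecord
from .kinship import UNRELATED_CUTOFF

logger = logging.getLogger(__name__)

DEFAULT_FSV_MAF_MAX = 0.0001  # strict (<)


@dataclass(frozen=True)
class StrategyTag:
    strategy: str  # CGV / SVGU / FSV
    sub_reason: Optional[str] = None  # SVGU: identical_variant_shared / same_gene_distinct_variants

    def __str__(self) -> str:
        return self.strategy if self.sub_reason is None else f"{self.strategy}:{self.sub_reason}"


CGV = StrategyTag("CGV")
SVGU_IDENTICAL = StrategyTag("SVGU", "identical_variant_shared")
SVGU_SAME_GENE = StrategyTag("SVGU", "same_gene_distinct_variants")
FSV = StrategyTag("FSV")

TagMap = Dict[VariantKey, Set[StrategyTag]]


class GeneListError(ValueError):
    """Empty or unusable cancer-gene list."""


def _affected_carriers(
    rec: VariantRecord, pedigrees: PedigreeCollection, excluded: FrozenSet[str]
) -> List[str]:
    out = []
    for s in rec.carriers():
        if s in excluded or s not in pedigrees:
            continue
        ind = pedigrees.individual(s)
        if ind.is_sequenced and ind.is_affected:
            out.append(s)
    return sorted(out)


def cgv_select(records: Sequence[VariantRecord], cancer_genes: Sequence[str]) -> TagMap:
    """Tag variants whose gene symbol is on the cancer-gene list."""
    if not cancer_genes:
        raise GeneListError("cancer-gene list is empty")
    listed = {g.upper() for g in cancer_genes}
    tags: TagMap = {}
    for rec in records:
        if any(ann.gene.upper() in listed for ann in rec.annotations):
            tags.setdefault(rec.key, set()).add(CGV)
    return tags


def _pairwise_unrelated(
    s1: str,
    s2: str,
    pedigrees: PedigreeCollection,
    phi: Optional[Mapping[Tuple[str, str], float]],
    cutoff: float,
) -> bool:
    if pedigrees.family_of(s1) == pedigrees.family_of(s2):
        return False
    if phi is None:
        return True
    value = phi.get((s1, s2), phi.get((s2, s1)))
    return value is not None and value < cutoff


def svgu_select(
    records: Sequence[VariantRecord],
    pedigrees: PedigreeCollection,
    kinship_phi: Optional[Mapping[Tuple[str, str], float]] = None,
    unrelated_cutoff: float = UNRELATED_CUTOFF,
    require_same_transcript: bool = True,
    excluded_samples: FrozenSet[str] = frozenset(),
) -> TagMap:
    """Tag variants shared across unrelated patients, by identity or by gene.

    ``kinship_phi`` maps unordered sample pairs to estimated phi; when
    omitted, unrelatedness falls back to family membership alone.
    """
    tags: TagMap = {}
    carriers_by_key = {
        rec.key: _affected_carriers(rec, pedigrees, excluded_samples) for rec in records
    }

    def has_unrelated_pair(samples_a: Sequence[str], samples_b: Sequence[str]) -> bool:
        return any(
            _pairwise_unrelated(a, b, pedigrees, kinship_phi, unrelated_cutoff)
            for a in samples_a
            for b in samples_b
        )

    # identical variant in unrelated patients
    for rec in records:
        carriers = carriers_by_key[rec.key]
        if len(carriers) >= 2 and has_unrelated_pair(carriers, carriers):
            tags.setdefault(rec.key, set()).add(SVGU_IDENTICAL)

    # distinct admitted variants on the same gene (same transcript by default)
    by_unit: Dict[str, List[VariantRecord]] = {}
    for rec in records:
        for ann in rec.annotations:
            if not in_variant_universe(ann, "variant_based"):
                continue
            unit = ann.transcript_id if require_same_transcript else ann.gene
            group = by_unit.setdefault(unit, [])
            if rec not in group:
                group.append(rec)
    for unit in sorted(by_unit):
        group = by_unit[unit]
        if len(group) < 2:
            continue
        for i, rec_i in enumerate(group):
            for rec_j in group[i + 1 :]:
                if rec_i.key == rec_j.key:
                    continue
                if has_unrelated_pair(carriers_by_key[rec_i.key], carriers_by_key[rec_j.key]):
                    tags.setdefault(rec_i.key, set()).add(SVGU_SAME_GENE)
                    tags.setdefault(rec_j.key, set()).add(SVGU_SAME_GENE)
    return tags


def fsv_select(
    records: Sequence[VariantRecord],
    pedigrees: PedigreeCollection,
    fsv_maf_max: float = DEFAULT_FSV_MAF_MAX,
    excluded_samples: FrozenSet[str] = frozenset(),
) -> TagMap:
    """Tag ultra-rare variants private to one family (or one patient)."""
    tags: TagMap = {}
    for rec in records:
        if not passes_maf_filter(rec, fsv_maf_max, strict=True):
            continue
        carriers = [s for s in rec.carriers() if s not in excluded_samples]
        if not carriers:
            continue
        families = {pedigrees.family_of(s) for s in carriers if s in pedigrees}
        if len(families) == 1:
            tags.setdefault(rec.key, set()).add(FSV)
    return tags


def merge_tags(*tag_maps: TagMap) -> TagMap:
    merged: TagMap = {}
    for tm in tag_maps:
        for key, tags in tm.items():
            merged.setdefault(key, set()).update(tags)
    for key, tags in merged.items():
        assert not (FSV in tags and SVGU_IDENTICAL in tags), (
            f"variant {key} tagged both FSV and SVGU-identical; "
            "single-family and shared-across-unrelated are mutually exclusive"
        )
    return merged


def shortlist_variants(
    records: Sequence[VariantRecord],
    tags: TagMap,
    pedigrees: PedigreeCollection,
    maf_max: float = 0.001,
    consensus_k: int = 1,
    qc: QCThresholds = QCThresholds(),
    excluded_samples: FrozenSet[str] = frozenset(),
) -> List[CandidateRecord]:
    """Filter tagged variants on MAF, pathogenicity, segregation and QC."""
    out: List[CandidateRecord] = []
    for rec in records:
        rec_tags = tags.get(rec.key)
        if not rec_tags:
            continue
        if not passes_maf_filter(rec, maf_max):
            continue
        is_lof = any(classify_lof(a) for a in rec.annotations)
        if not predictor_consensus(rec.predictors, consensus_k, is_lof=is_lof):
            continue
        admitted = [a for a in rec.annotations if in_variant_universe(a, "variant_based")]
        if not admitted:
            continue
        carriers = []
        for s in rec.carriers():
            if s in excluded_samples:
                continue
            if s not in pedigrees:
                raise SegregationError(
                    f"carrier {s} of {rec.chrom}:{rec.pos} has no pedigree entry"
                )
            if pedigrees.individual(s).is_sequenced:
                carriers.append(s)
        affected_carriers = [
            s
            for s in carriers
            if pedigrees.individual(s).is_affected and qc_surrogate(rec.genotypes[s], qc)
        ]
        if not affected_carriers:
            continue
        # presence in affected relatives: every affected sequenced member of
        # each carrier family must carry the variant (and pass QC)
        carrier_families = sorted({pedigrees.family_of(s) for s in carriers})
        segregates = True
        for fid in carrier_families:
            for member in pedigrees.families[fid].affected_sequenced():
                if member.sample_id in excluded_samples:
                    continue
                call = rec.genotypes.get(member.sample_id)
                if (
                    call is None
                    or not call.allele_count
                    or not qc_surrogate(call, qc)
                ):
                    segregates = False
                    break
            if not segregates:
                break
        if not segregates:
            continue
        unaffected = sorted(
            s for s in carriers if not pedigrees.individual(s).is_affected
        )
        ann = admitted[0]
        out.append(
            CandidateRecord(
                key=rec.key,
                gene=ann.gene,
                transcript_id=ann.transcript_id,
                annotation=ann,
                carrier_samples=sorted(affected_carriers),
                carrier_families=carrier_families,
                n_carrier_patients=len(affected_carriers),
                unaffected_carriers=unaffected,
                maf_panel_a=rec.maf_panel_a,
                maf_panel_b=rec.maf_panel_b,
                qc_pass=True,
                stages=["discovery"],
                strategy_tags=set(rec_tags),
            )
        )
    out.sort(key=lambda c: (c.gene, c.key[0], c.key[1], c.key[2], c.key[3]))
    return out


def cross_cohort_presence(
    candidates: Sequence[CandidateRecord],
    replication_records: Sequence[VariantRecord],
) -> Dict[VariantKey, List[str]]:
    """Carriers of each candidate's identical variant in the replication cohort.

    Returns a map candidate key -> replication carrier samples (empty list
    when absent); candidates found in >= 1 patient also gain the
    ``replication_presence`` stage label in place.
    """
    by_key: Dict[VariantKey, VariantRecord] = {r.key: r for r in replication_records}
    presence: Dict[VariantKey, List[str]] = {}
    for cand in candidates:
        rec = by_key.get(cand.key)
        carriers = sorted(rec.carriers()) if rec is not None else []
        presence[cand.key] = carriers
        if carriers and "replication_presence" not in cand.stages:
            cand.stages.append("replication_presence")
    return presence
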