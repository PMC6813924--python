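"""Gene-based discovery shortlisting and cross-cohort replication.

Discovery rule (applied to the family cohort): a variant is shortlisted
iff it is loss-of-function on at least one transcript, has MAF <= 0.1%
(inclusive) in both reference panels — a variant absent from a panel is
treated as MAF 0 there, logged separately from a panel-reported 0 — and,
within at least one family, is carried by at least two affected sequenced
patients. In families where co-segregation cannot be ascertained because
fewer affected members were sequenced, the requirement drops to the number
that could be ascertained (one carrier suffices in a single-affected
family). Every counted carrier genotype must pass the genotype-QC
surrogate, a programmatic stand-in for visual read inspection.

Replication rule: a discovery gene replicates iff at least one patient of
the independent replication cohort carries *any* rare LoF on the same
transcript as the discovery variant, with both variants outside the
transcript's last exon (truncations there often escape nonsense-mediated
decay). An unknown exon position is conservatively treated as last-exon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .annotation import ConsequenceAnnotation, classify_lof, is_last_exon
from .io_formats import (
    GenotypeCall,
    PedigreeCollection,
    VariantKey,
    VariantRecord,
)

logger = logging.getLogger(__name__)

DEFAULT_MAF_MAX = 0.001  # inclusive


class SegregationError(ValueError):
    """A carrier sample has no pedigree entry; segregation unascertainable."""


@dataclass(frozen=True)
class QCThresholds:
    """Genotype-level QC surrogate thresholds."""

    min_depth: int = 10
    min_gq: int = 20
    het_balance: Tuple[float, float] = (0.25, 0.75)
    hom_min_fraction: float = 0.9


@dataclass
class CandidateRecord:
    """A variant (on one transcript) surviving a prioritization workflow."""

    key: VariantKey
    gene: str
    transcript_id: str
    annotation: ConsequenceAnnotation
    carrier_samples: List[str]
    carrier_families: List[str]
    n_carrier_patients: int  # affected, sequenced, QC-passing carriers
    unaffected_carriers: List[str] = field(default_factory=list)
    maf_panel_a: Optional[float] = None
    maf_panel_b: Optional[float] = None
    qc_pass: bool = True
    stages: List[str] = field(default_factory=lambda: ["discovery"])
    strategy_tags: Set = field(default_factory=set)
    replication_variants: List[VariantKey] = field(default_factory=list)


def qc_surrogate(
    call: GenotypeCall, thresholds: QCThresholds = QCThresholds()
) -> bool:
    """Pass/fail a carrier genotype on depth, GQ and allele balance.

    Heterozygous calls need depth >= min_depth, GQ >= min_gq and an
    alt-read fraction inside the het balance band; homozygous-alt calls
    need an alt fraction >= hom_min_fraction. Missing metrics fail.
    """
    if call.allele_count in (None, 0):
        return False
    if call.depth is None or call.genotype_quality is None or call.alt_depth is None:
        return False
    if call.depth < thresholds.min_depth or call.genotype_quality < thresholds.min_gq:
        return False
    balance = call.alt_depth / call.depth if call.depth else 0.0
    if call.allele_count == 1:
        lo, hi = thresholds.het_balance
        return lo <= balance <= hi
    return balance >= thresholds.hom_min_fraction


def passes_maf_filter(
    rec: VariantRecord, maf_max: float, *, strict: bool = False
) -> bool:
    """Rare in both panels; absence from a panel counts as 0 (logged)."""
    for panel, maf in (("panel_a", rec.maf_panel_a), ("panel_b", rec.maf_panel_b)):
        if maf is None:
            logger.debug(
                "%s:%d %s>%s absent from %s; treated as MAF 0",
                rec.chrom,
                rec.pos,
                rec.ref,
                rec.alt,
                panel,
            )
            continue
        if (maf >= maf_max) if strict else (maf > maf_max):
            return False
    return True


def _family_carrier_counts(
    rec: VariantRecord,
    pedigrees: PedigreeCollection,
    thresholds: QCThresholds,
    excluded_samples: FrozenSet[str],
) -> Tuple[Dict[str, List[str]], List[str]]:
    """QC-passing affected carriers per family, plus unaffected carriers.

    Raises :class:`SegregationError` for a carrier with no pedigree entry.
    """
    by_family: Dict[str, List[str]] = {}
    unaffected: List[str] = []
    for sample in rec.carriers():
        if sample in excluded_samples:
            continue
        if sample not in pedigrees:
            raise SegregationError(
                f"carrier {sample} of {rec.chrom}:{rec.pos} {rec.ref}>{rec.alt} "
                "has no pedigree entry"
            )
        ind = pedigrees.individual(sample)
        if not ind.is_sequenced:
            continue
        if not ind.is_affected:
            unaffected.append(sample)
            continue
        if not qc_surrogate(rec.genotypes[sample], thresholds):
            continue
        by_family.setdefault(ind.family_id, []).append(sample)
    return by_family, unaffected


def shortlist_genes_discovery(
    records: Sequence[VariantRecord],
    pedigrees: PedigreeCollection,
    maf_max: float = DEFAULT_MAF_MAX,
    min_family_carriers: int = 2,
    qc: QCThresholds = QCThresholds(),
    excluded_samples: FrozenSet[str] = frozenset(),
    last_exon_at_discovery: bool = False,
) -> List[CandidateRecord]:
    """Apply the gene-based discovery workflow; output sorted by (gene, chrom, pos).

    One candidate is emitted per (variant, LoF transcript) pair, so the
    same-transcript replication rule can be applied downstream.
    """
    n_affected_seq: Dict[str, int] = {
        fid: len([m for m in ped.affected_sequenced() if m.sample_id not in excluded_samples])
        for fid, ped in pedigrees.families.items()
    }
    out: List[CandidateRecord] = []
    for rec in records:
        lof_anns = [a for a in rec.annotations if classify_lof(a)]
        if last_exon_at_discovery:
            lof_anns = [a for a in lof_anns if is_last_exon(a) is False]
        if not lof_anns:
            continue
        if not passes_maf_filter(rec, maf_max):
            continue
        by_family, unaffected = _family_carrier_counts(rec, pedigrees, qc, excluded_samples)
        qualifying_families = []
        for fid, carriers in by_family.items():
            # co-segregation is required only as far as it can be ascertained:
            # a family with fewer affected sequenced members than the carrier
            # requirement qualifies with all of them carrying
            required = min(min_family_carriers, max(1, n_affected_seq.get(fid, 0)))
            if len(carriers) >= required:
                qualifying_families.append(fid)
        if not qualifying_families:
            continue
        all_carriers = sorted(s for fams in by_family.values() for s in fams)
        for ann in lof_anns:
            out.append(
                CandidateRecord(
                    key=rec.key,
                    gene=ann.gene,
                    transcript_id=ann.transcript_id,
                    annotation=ann,
                    carrier_samples=all_carriers,
                    carrier_families=sorted(qualifying_families),
                    n_carrier_patients=len(all_carriers),
                    unaffected_carriers=sorted(unaffected),
                    maf_panel_a=rec.maf_panel_a,
                    maf_panel_b=rec.maf_panel_b,
                    qc_pass=True,
                    stages=["discovery"],
                )
            )
    out.sort(key=lambda c: (c.gene, c.key[0], c.key[1], c.key[2], c.key[3]))
    return out


def replicate_genes(
    candidates: Sequence[CandidateRecord],
    replication_records: Sequence[VariantRecord],
    maf_max: float = DEFAULT_MAF_MAX,
    qc: QCThresholds = QCThresholds(),
) -> List[CandidateRecord]:
    """Cross-cohort replication of discovery genes (same transcript, no last exon)."""
    out: List[CandidateRecord] = []
    for cand in candidates:
        if is_last_exon(cand.annotation) is not False:
            continue  # unknown exon position is conservatively excluded
        hits: List[VariantKey] = []
        for rec in replication_records:
            if not passes_maf_filter(rec, maf_max):
                continue
            carriers = [s for s in rec.carriers() if qc_surrogate(rec.genotypes[s], qc)]
            if not carriers:
                continue
            for ann in rec.annotations:
                if (
                    ann.transcript_id == cand.transcript_id
                    and classify_lof(ann)
                    and is_last_exon(ann) is False
                ):
                    hits.append(rec.key)
                    break
        if hits:
            replicated = CandidateRecord(
                key=cand.key,
                gene=cand.gene,
                transcript_id=cand.transcript_id,
                annotation=cand.annotation,
                carrier_samples=list(cand.carrier_samples),
                carrier_families=list(cand.carrier_families),
                n_carrier_patients=cand.n_carrier_patients,
                unaffected_carriers=list(cand.unaffected_carriers),
                maf_panel_a=cand.maf_panel_a,
                maf_panel_b=cand.maf_panel_b,
                qc_pass=cand.qc_pass,
                stages=list(cand.stages) + ["replicated"],
                strategy_tags=set(cand.strategy_tags),
                replication_variants=sorted(set(hits)),
            )
            out.append(replicated)
    out.sort(key=lambda c: (c.gene, c.key[0], c.key[1]))
    return out
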