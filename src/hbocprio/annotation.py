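"""Functional consequence handling for prioritization filters.

Variants enter the pipeline with one annotation per transcript. All rules
here operate on a single (variant, transcript) pair: a variant is
loss-of-function (LoF) if it is LoF on at least one transcript, and
transcript-matching rules (replication, same-gene sharing) always compare
transcript identifiers, never bare gene symbols.

LoF is the classical truncating set: stop-gain, frameshift, and the
essential (+/-2 bp) splice donor/acceptor sites. Truncating variants in a
transcript's final exon frequently escape nonsense-mediated decay, so the
last-exon rule excludes them from cross-cohort LoF matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

logger = logging.getLogger(__name__)

#: Sequence Ontology terms treated as loss-of-function.
LOF_TERMS = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
    }
)

#: Additional terms admitted by the variant-based (but not gene-based) universe.
VARIANT_MODE_EXTRA_TERMS = frozenset(
    {
        "inframe_insertion",
        "inframe_deletion",
        "missense_variant",
        "stop_lost",
    }
)

#: Default in-silico predictor panel (seven tools).
DEFAULT_PREDICTOR_TOOLS = (
    "SIFT",
    "POLYPHEN",
    "MUTATIONTASTER",
    "CADD",
    "LRT",
    "FATHMM",
    "PROVEAN",
)


class Verdict(str, Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ConsequenceAnnotation:
    """Per-transcript functional annotation of one variant."""

    gene: str
    transcript_id: str
    consequence_term: str
    exon_rank: Optional[int] = None
    exon_total: Optional[int] = None
    protein_change: Optional[str] = None
    cdna_change: Optional[str] = None

    def __post_init__(self) -> None:
        if (
            self.exon_rank is not None
            and self.exon_total is not None
            and self.exon_rank > self.exon_total
        ):
            raise ValueError(
                f"exon_rank {self.exon_rank} > exon_total {self.exon_total} "
                f"({self.gene}/{self.transcript_id})"
            )


@dataclass
class PredictorPanel:
    """Verdicts from a panel of in-silico pathogenicity predictors.

    ``unknown`` never counts toward the damaging tally.
    """

    verdicts: Mapping[str, Verdict] = field(default_factory=dict)

    @classmethod
    def from_strings(cls, verdicts: Mapping[str, str]) -> "PredictorPanel":
        norm = {}
        for tool, v in verdicts.items():
            try:
                norm[tool] = Verdict(str(v).strip().lower())
            except ValueError:
                norm[tool] = Verdict.UNKNOWN
        return cls(norm)

    @property
    def damaging_count(self) -> int:
        return sum(1 for v in self.verdicts.values() if v is Verdict.DAMAGING)


def classify_lof(annotation: ConsequenceAnnotation) -> bool:
    """True iff the annotation's consequence term is loss-of-function.

    Unrecognized terms (not in the LoF set nor in the known non-LoF
    vocabulary) are logged and classified non-LoF.
    """
    term = annotation.consequence_term
    if term in LOF_TERMS:
        return True
    if term not in _KNOWN_NON_LOF:
        logger.warning("unrecognized consequence term %r; classified non-LoF", term)
    return False


_KNOWN_NON_LOF = VARIANT_MODE_EXTRA_TERMS | {
    "synonymous_variant",
    "intron_variant",
    "splice_region_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "start_lost",
    "intergenic_variant",
}


def in_variant_universe(annotation: ConsequenceAnnotation, mode: str) -> bool:
    """Whether the annotation is admitted by the given prioritization mode.

    ``gene_based`` admits only LoF; ``variant_based`` additionally admits
    in-frame indels, missense and stop-loss variants.
    """
    if mode not in ("gene_based", "variant_based"):
        raise ValueError(f"unknown mode {mode!r}")
    if classify_lof(annotation):
        return True
    if mode == "variant_based":
        return annotation.consequence_term in VARIANT_MODE_EXTRA_TERMS
    return False


def is_last_exon(annotation: ConsequenceAnnotation) -> Optional[bool]:
    """True iff the variant falls in the transcript's final exon.

    Returns ``None`` (unknown) when exon rank/total are missing; callers
    applying the last-exon exclusion must treat unknown conservatively
    (excluded from replication matching).
    """
    if annotation.exon_rank is None or annotation.exon_total is None:
        return None
    return annotation.exon_rank == annotation.exon_total


def predictor_consensus(
    panel: Optional[PredictorPanel], k: int, *, is_lof: bool = False
) -> bool:
    """True iff at least ``k`` panel tools call the variant damaging.

    LoF variants bypass the predictor check entirely. With ``k = 0`` every
    variant passes. A missing panel is a damaging count of zero.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if is_lof:
        return True
    count = panel.damaging_count if panel is not None else 0
    return count >= k
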