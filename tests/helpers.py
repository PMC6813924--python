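"""Shared builders for compact in-memory test objects."""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import Dict, Optional, Sequence, Tuple

from hbocprio.annotation import ConsequenceAnnotation, PredictorPanel
from hbocprio.io_formats import (
    GenotypeCall,
    Pedigree,
    PedigreeCollection,
    PedigreeIndividual,
    VariantRecord,
)

GOOD_CALL = dict(depth=60, alt_depth=29, genotype_quality=99)


def call(count: Optional[int], **kw) -> GenotypeCall:
    base = dict(GOOD_CALL)
    if count == 0:
        base.update(alt_depth=0)
    elif count == 2:
        base.update(alt_depth=58)
    base.update(kw)
    return GenotypeCall(count, **base)


def record(
    chrom: str = "chr1",
    pos: int = 1000,
    ref: str = "G",
    alt: str = "T",
    gene: str = "GENE1",
    transcript: Optional[str] = None,
    consequence: str = "stop_gained",
    exon: Tuple[int, int] = (2, 10),
    carriers: Sequence[str] = (),
    noncarriers: Sequence[str] = (),
    maf_a: Optional[float] = None,
    maf_b: Optional[float] = None,
    damaging: Optional[int] = None,
    tools: int = 7,
) -> VariantRecord:
    genotypes: Dict[str, GenotypeCall] = {}
    for s in carriers:
        genotypes[s] = call(1)
    for s in noncarriers:
        genotypes[s] = call(0)
    panel = None
    if damaging is not None:
        panel = PredictorPanel.from_strings(
            {f"TOOL{i}": "damaging" if i < damaging else "tolerated" for i in range(tools)}
        )
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        genotypes=genotypes,
        annotations=[
            ConsequenceAnnotation(
                gene=gene,
                transcript_id=transcript or f"TR_{gene}",
                consequence_term=consequence,
                exon_rank=exon[0] if exon else None,
                exon_total=exon[1] if exon else None,
            )
        ],
        predictors=panel,
        maf_panel_a=maf_a,
        maf_panel_b=maf_b,
    )


def family(
    fid: str,
    children: Sequence[Tuple[str, str]],  # (suffix, affection)
    mother_affection: str = "unaffected",
    father_affection: str = "unaffected",
) -> Pedigree:
    ped = Pedigree(fid)
    ped.add(PedigreeIndividual(f"{fid}_FA", fid, None, None, "male", father_affection, is_sequenced=True))
    ped.add(PedigreeIndividual(f"{fid}_MO", fid, None, None, "female", mother_affection, is_sequenced=True))
    for suffix, affection in children:
        ped.add(
            PedigreeIndividual(
                f"{fid}_{suffix}", fid, f"{fid}_FA", f"{fid}_MO", "female", affection, is_sequenced=True
            )
        )
    return ped


def pedigrees(*peds: Pedigree) -> PedigreeCollection:
    return PedigreeCollection({p.family_id: p for p in peds})


def fisher_exact_bruteforce(a: int, b: int, c: int, d: int) -> float:
    """Exact-arithmetic two-sided Fisher p: enumerate the hypergeometric support.

    Point probabilities share the denominator C(n, c1), so tables are
    compared via integer numerators; the tie tolerance 1e-7 enters as the
    exact rational (10^7 + 1)/10^7.
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    nums = {k: comb(r1, k) * comb(n - r1, c1 - k) for k in range(lo, hi + 1)}
    obs = nums[a]
    total = sum(v for v in nums.values() if v * 10**7 <= obs * (10**7 + 1))
    return float(min(Fraction(total, comb(n, c1)), Fraction(1)))
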