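"""Readers and writers for every on-disk format the pipeline touches.

The pipeline consumes an annotated multi-sample VCF (v4.2), pedigree files
in a PED dialect extended with cancer phenotype columns, tab-separated
population allele-frequency tables for two reference panels, a cancer-gene
list (one symbol per line), and tab-separated cohort allele-count tables.

Annotation dialect (the only one supported; VEP CSQ is not): a SnpEff-style
``ANN`` INFO field with comma-separated per-transcript entries of the form

    Allele|Consequence|Gene|Transcript|ExonRank/ExonTotal|HGVSc|HGVSp

where the exon and HGVS fields may be empty. In-silico predictor verdicts
ride along as paired site-level INFO keys ``<TOOL>_call`` (damaging /
tolerated / unknown) and ``<TOOL>_score`` (float), one pair per panel tool.

PED dialect: the six standard columns (family, individual, father, mother,
sex, phenotype) followed by three extension columns: affection category
(``unaffected`` / ``breast_cancer`` / ``ovarian_cancer`` / ``other_cancer``),
age at diagnosis in years (``.`` if not applicable), and an index-patient
flag (0/1). Whether an individual was sequenced is not stored in the PED;
it is derived from membership in the VCF sample list.

Coordinates are 1-based fully closed as in VCF. Multi-allelic records are
split into one :class:`VariantRecord` per alternate allele on ingest.
Genotypes encoded ``./.`` carry a missing allele count and are excluded
from carrier counting, allele-number denominators and kinship.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from cyvcf2 import VCF

from .annotation import ConsequenceAnnotation, PredictorPanel, DEFAULT_PREDICTOR_TOOLS

logger = logging.getLogger(__name__)

AFFECTION_CATEGORIES = ("unaffected", "breast_cancer", "ovarian_cancer", "other_cancer")
AFFECTED_CATEGORIES = frozenset({"breast_cancer", "ovarian_cancer", "other_cancer"})

VariantKey = Tuple[str, int, str, str]


class VcfFormatError(ValueError):
    """Malformed VCF header or body."""


class AnnotationDialectError(ValueError):
    """ANN entry does not follow the declared dialect."""


class IngestError(ValueError):
    """Content-level problem in an otherwise well-formed file."""


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycles, unknown parents)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one split alt allele.

    ``allele_count`` is the number of copies of *this* alt allele
    (0, 1, 2) or ``None`` for a missing genotype.
    """

    allele_count: Optional[int]
    depth: Optional[int] = None
    alt_depth: Optional[int] = None
    genotype_quality: Optional[int] = None

    def __post_init__(self) -> None:
        if (
            self.depth is not None
            and self.alt_depth is not None
            and not (0 <= self.alt_depth <= self.depth)
        ):
            raise ValueError(f"alt_depth {self.alt_depth} outside [0, depth={self.depth}]")

    @property
    def is_missing(self) -> bool:
        return self.allele_count is None


@dataclass
class VariantRecord:
    """One alternate allele at one site, with per-sample genotypes."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_id: Optional[str] = None
    site_quality: Optional[float] = None
    genotypes: Dict[str, GenotypeCall] = field(default_factory=dict)
    annotations: List[ConsequenceAnnotation] = field(default_factory=list)
    predictors: Optional[PredictorPanel] = None
    maf_panel_a: Optional[float] = None  # None = absent from panel
    maf_panel_b: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos {self.pos} must be >= 1")
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or set(allele) - set("ACGT"):
                raise ValueError(f"{name} allele {allele!r} must be non-empty over ACGT")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def genes(self) -> List[str]:
        seen: List[str] = []
        for ann in self.annotations:
            if ann.gene not in seen:
                seen.append(ann.gene)
        return seen

    def carriers(self, samples: Optional[Iterable[str]] = None) -> List[str]:
        """Samples carrying >= 1 copy of the alt allele (missing excluded)."""
        pool = self.genotypes if samples is None else {
            s: self.genotypes[s] for s in samples if s in self.genotypes
        }
        return [s for s, g in pool.items() if g.allele_count is not None and g.allele_count >= 1]


@dataclass
class PedigreeIndividual:
    sample_id: str
    family_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str  # "male" / "female" / "unknown"
    affection: str = "unaffected"
    age_at_diagnosis: Optional[float] = None
    is_index: bool = False
    is_sequenced: bool = False

    def __post_init__(self) -> None:
        if self.affection not in AFFECTION_CATEGORIES:
            raise ValueError(f"unknown affection category {self.affection!r}")
        if self.is_index and not self.is_affected:
            raise ValueError(f"index individual {self.sample_id} must be affected")

    @property
    def is_affected(self) -> bool:
        return self.affection in AFFECTED_CATEGORIES

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """One family: members keyed by sample id, parent links resolved."""

    family_id: str
    members: Dict[str, PedigreeIndividual] = field(default_factory=dict)

    def add(self, ind: PedigreeIndividual) -> None:
        self.members[ind.sample_id] = ind

    def validate(self) -> None:
        for ind in self.members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self.members:
                    raise PedigreeError(
                        f"{ind.sample_id} lists unknown parent {pid} in family {self.family_id}"
                    )
        # cycle check: no individual may appear among its own ancestors
        for start, ind in self.members.items():
            stack = [p for p in (ind.father_id, ind.mother_id) if p is not None]
            seen: set[str] = set()
            while stack:
                sid = stack.pop()
                if sid == start:
                    raise PedigreeError(
                        f"{start} is its own ancestor in family {self.family_id}"
                    )
                if sid in seen:
                    continue
                seen.add(sid)
                anc = self.members[sid]
                stack.extend(p for p in (anc.father_id, anc.mother_id) if p is not None)

    def affected_sequenced(self) -> List[PedigreeIndividual]:
        return [m for m in self.members.values() if m.is_affected and m.is_sequenced]


@dataclass
class PedigreeCollection:
    families: Dict[str, Pedigree] = field(default_factory=dict)

    def individual(self, sample_id: str) -> PedigreeIndividual:
        for ped in self.families.values():
            if sample_id in ped.members:
                return ped.members[sample_id]
        raise KeyError(sample_id)

    def __contains__(self, sample_id: str) -> bool:
        return any(sample_id in ped.members for ped in self.families.values())

    def family_of(self, sample_id: str) -> str:
        return self.individual(sample_id).family_id

    def all_individuals(self) -> List[PedigreeIndividual]:
        return [m for ped in self.families.values() for m in ped.members.values()]

    def mark_sequenced(self, samples: Iterable[str]) -> None:
        sset = set(samples)
        for ind in self.all_individuals():
            ind.is_sequenced = ind.sample_id in sset


@dataclass
class PopulationFrequencies:
    """Global minor-allele frequencies from two reference panels.

    Panel A stands in for a 1000-Genomes-like panel and panel B for a
    gnomAD-like panel. A variant may be absent from either panel; absence
    is preserved as ``None`` here (never silently zero-filled) and only the
    rare-variant filters decide, with logging, to treat absence as MAF 0.
    """

    panel_a: Dict[VariantKey, float] = field(default_factory=dict)
    panel_b: Dict[VariantKey, float] = field(default_factory=dict)

    def lookup(self, key: VariantKey) -> Tuple[Optional[float], Optional[float]]:
        return self.panel_a.get(key), self.panel_b.get(key)


@dataclass(frozen=True)
class CohortAlleleCounts:
    group: str
    alt_alleles: int
    total_alleles: int

    def __post_init__(self) -> None:
        if self.total_alleles <= 0:
            raise IngestError(f"total_alleles must be positive ({self.group})")
        if not 0 <= self.alt_alleles <= self.total_alleles:
            raise IngestError(
                f"alt_alleles {self.alt_alleles} outside [0, {self.total_alleles}] ({self.group})"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_ANN_N_FIELDS = 7


def _parse_ann_entry(entry: str) -> Tuple[str, ConsequenceAnnotation]:
    parts = entry.split("|")
    if len(parts) != _ANN_N_FIELDS:
        raise AnnotationDialectError(
            f"ANN entry has {len(parts)} fields, expected {_ANN_N_FIELDS}: {entry!r}"
        )
    allele, term, gene, transcript, exon, hgvs_c, hgvs_p = (p.strip() for p in parts)
    exon_rank = exon_total = None
    if exon:
        try:
            rank_s, total_s = exon.split("/")
            exon_rank, exon_total = int(rank_s), int(total_s)
        except ValueError as exc:
            raise AnnotationDialectError(f"bad exon field {exon!r} in ANN entry") from exc
    return allele, ConsequenceAnnotation(
        gene=gene,
        transcript_id=transcript,
        consequence_term=term,
        exon_rank=exon_rank,
        exon_total=exon_total,
        protein_change=hgvs_p or None,
        cdna_change=hgvs_c or None,
    )


def _format_ann_entry(alt: str, ann: ConsequenceAnnotation) -> str:
    exon = (
        f"{ann.exon_rank}/{ann.exon_total}"
        if ann.exon_rank is not None and ann.exon_total is not None
        else ""
    )
    return "|".join(
        [alt, ann.consequence_term, ann.gene, ann.transcript_id, exon, ann.cdna_change or "", ann.protein_change or ""]
    )


def read_vcf(
    path: str | Path,
    frequencies: Optional[PopulationFrequencies] = None,
    predictor_tools: Sequence[str] = DEFAULT_PREDICTOR_TOOLS,
) -> Tuple[List[VariantRecord], List[str]]:
    """Read an annotated VCF into split, annotated variant records.

    Returns ``(records, sample_ids)``. Multi-allelic sites yield one record
    per alt allele with per-allele dosages; ANN entries attach to the record
    whose alt matches the entry's allele. When ``frequencies`` is given the
    two panel MAFs are joined by (chrom, pos, ref, alt) as a left join:
    every record survives, with panel-absent entries kept as ``None``.

    Raises :class:`VcfFormatError` for an unreadable header,
    :class:`AnnotationDialectError` for an ANN entry that does not follow
    the declared dialect, and :class:`IngestError` for duplicated
    (chrom, pos, ref, alt) keys.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad headers
        raise VcfFormatError(f"cannot parse VCF header of {path}: {exc}") from exc
    samples = list(vcf.samples)
    records: List[VariantRecord] = []
    seen: set[VariantKey] = set()
    for line_no, v in enumerate(vcf, start=1):
        ann_raw = v.INFO.get("ANN")
        ann_by_allele: Dict[str, List[ConsequenceAnnotation]] = {}
        if ann_raw:
            for entry in str(ann_raw).split(","):
                allele, ann = _parse_ann_entry(entry)
                ann_by_allele.setdefault(allele, []).append(ann)
        verdicts = {}
        for tool in predictor_tools:
            call = v.INFO.get(f"{tool}_call")
            if call is not None:
                verdicts[tool] = str(call)
        panel = PredictorPanel.from_strings(verdicts) if verdicts else None

        gts = v.genotypes  # [[a0, a1, phased], ...]
        depths = v.format("DP")
        gqs = v.format("GQ")
        ads = v.format("AD")
        for alt_idx, alt in enumerate(v.ALT, start=1):
            key = (v.CHROM, v.POS, v.REF, alt)
            if key in seen:
                raise IngestError(
                    f"duplicated variant {v.CHROM}:{v.POS} {v.REF}>{alt} (record {line_no})"
                )
            seen.add(key)
            genotypes: Dict[str, GenotypeCall] = {}
            for si, sample in enumerate(samples):
                alleles = gts[si][:-1]
                if any(a < 0 for a in alleles):
                    count: Optional[int] = None
                else:
                    count = sum(1 for a in alleles if a == alt_idx)
                depth = int(depths[si][0]) if depths is not None and depths[si][0] >= 0 else None
                gq = int(gqs[si][0]) if gqs is not None and gqs[si][0] >= 0 else None
                alt_depth = None
                if ads is not None and len(ads[si]) > alt_idx and ads[si][alt_idx] >= 0:
                    alt_depth = int(ads[si][alt_idx])
                    if depth is None:
                        depth = int(sum(x for x in ads[si] if x >= 0))
                genotypes[sample] = GenotypeCall(count, depth, alt_depth, gq)
            rec = VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=alt,
                variant_id=v.ID,
                site_quality=round(v.QUAL, 1) if v.QUAL is not None else None,
                genotypes=genotypes,
                annotations=ann_by_allele.get(alt, []),
                predictors=panel,
            )
            if frequencies is not None:
                rec.maf_panel_a, rec.maf_panel_b = frequencies.lookup(key)
            records.append(rec)
    return records, samples


def write_vcf(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    predictor_tools: Sequence[str] = DEFAULT_PREDICTOR_TOOLS,
) -> None:
    """Write biallelic records as a VCF v4.2 text file (deterministic bytes)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
        "'Allele|Consequence|Gene|Transcript|ExonRank/ExonTotal|HGVSc|HGVSp'\">",
    ]
    for tool in predictor_tools:
        lines.append(
            f'##INFO=<ID={tool}_call,Number=1,Type=String,Description="{tool} verdict">'
        )
        lines.append(
            f'##INFO=<ID={tool}_score,Number=1,Type=Float,Description="{tool} score">'
        )
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    ]
    contigs = []
    for rec in records:
        if rec.chrom not in contigs:
            contigs.append(rec.chrom)
    for chrom in contigs:
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for rec in sorted(records, key=lambda r: (contigs.index(r.chrom), r.pos, r.ref, r.alt)):
        info_parts = []
        if rec.annotations:
            info_parts.append(
                "ANN=" + ",".join(_format_ann_entry(rec.alt, a) for a in rec.annotations)
            )
        if rec.predictors is not None:
            for tool in predictor_tools:
                if tool in rec.predictors.verdicts:
                    info_parts.append(f"{tool}_call={rec.predictors.verdicts[tool].value}")
        info = ";".join(info_parts) if info_parts else "."
        qual = f"{rec.site_quality:.1f}" if rec.site_quality is not None else "."
        cols = [
            rec.chrom,
            str(rec.pos),
            rec.variant_id or ".",
            rec.ref,
            rec.alt,
            qual,
            "PASS",
            info,
            "GT:DP:AD:GQ",
        ]
        for sample in samples:
            g = rec.genotypes.get(sample, GenotypeCall(None))
            if g.allele_count is None:
                gt = "./."
            else:
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[g.allele_count]
            dp = str(g.depth) if g.depth is not None else "."
            if g.depth is not None and g.alt_depth is not None:
                ad = f"{g.depth - g.alt_depth},{g.alt_depth}"
            else:
                ad = "."
            gq = str(g.genotype_quality) if g.genotype_quality is not None else "."
            cols.append(f"{gt}:{dp}:{ad}:{gq}")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}


def read_ped(path: str | Path) -> PedigreeCollection:
    """Read the extended PED dialect into validated per-family pedigrees."""
    coll = PedigreeCollection()
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) != 9:
            raise IngestError(f"PED line {ln}: expected 9 columns, got {len(cols)}")
        fid, iid, fat, mot, sex, _pheno, affection, age, index = cols
        ind = PedigreeIndividual(
            sample_id=iid,
            family_id=fid,
            father_id=None if fat in ("0", ".") else fat,
            mother_id=None if mot in ("0", ".") else mot,
            sex=_SEX_CODES.get(sex, "unknown"),
            affection=affection,
            age_at_diagnosis=None if age in (".", "NA", "") else float(age),
            is_index=index == "1",
        )
        coll.families.setdefault(fid, Pedigree(fid)).add(ind)
    for ped in coll.families.values():
        ped.validate()
    return coll


def write_ped(coll: PedigreeCollection, path: str | Path) -> None:
    lines = []
    for fid in coll.families:
        for ind in coll.families[fid].members.values():
            age = f"{ind.age_at_diagnosis:g}" if ind.age_at_diagnosis is not None else "."
            lines.append(
                "\t".join(
                    [
                        ind.family_id,
                        ind.sample_id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_OUT[ind.sex],
                        "2" if ind.is_affected else "1",
                        ind.affection,
                        age,
                        "1" if ind.is_index else "0",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# frequency / count / gene-list tables
# ---------------------------------------------------------------------------


def read_frequency_table(path: str | Path) -> Dict[VariantKey, float]:
    """TSV with header chrom/pos/ref/alt/maf -> {key: maf}."""
    table: Dict[VariantKey, float] = {}
    lines = Path(path).read_text().splitlines()
    for ln, raw in enumerate(lines, start=1):
        if ln == 1 and raw.lower().startswith("chrom"):
            continue
        if not raw.strip():
            continue
        chrom, pos, ref, alt, maf = raw.split("\t")
        maf_f = float(maf)
        if not 0.0 <= maf_f <= 0.5:
            raise IngestError(f"{path} line {ln}: MAF {maf_f} outside [0, 0.5]")
        table[(chrom, int(pos), ref, alt)] = maf_f
    return table


def read_frequency_panels(path_a: str | Path, path_b: str | Path) -> PopulationFrequencies:
    return PopulationFrequencies(
        panel_a=read_frequency_table(path_a), panel_b=read_frequency_table(path_b)
    )


def write_frequency_table(table: Dict[VariantKey, float], path: str | Path) -> None:
    lines = ["chrom\tpos\tref\talt\tmaf"]
    for (chrom, pos, ref, alt), maf in sorted(table.items()):
        lines.append(f"{chrom}\t{pos}\t{ref}\t{alt}\t{maf:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_counts_table(path: str | Path) -> List[Tuple[str, str, CohortAlleleCounts]]:
    """TSV with header variant/group/alt/total -> validated allele counts."""
    out: List[Tuple[str, str, CohortAlleleCounts]] = []
    lines = Path(path).read_text().splitlines()
    for ln, raw in enumerate(lines, start=1):
        if ln == 1 and raw.lower().startswith("variant"):
            continue
        if not raw.strip():
            continue
        cols = raw.split("\t")
        if len(cols) != 4:
            raise IngestError(f"{path} line {ln}: expected 4 columns")
        variant, group, alt, total = cols
        out.append((variant, group, CohortAlleleCounts(group, int(alt), int(total))))
    return out


def read_gene_list(path: str | Path) -> List[str]:
    """One gene symbol per line; symbols are uppercased for matching."""
    genes = [
        line.strip().upper()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return genes
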