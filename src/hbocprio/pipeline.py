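"""End-to-end orchestration: simulate -> kinship QC -> shortlists -> replication -> association.

Every stage logs its input and output record counts to a filter funnel
(n_out <= n_in always), the run configuration is echoed verbatim into the
output directory, and reports are written as stable-schema TSV/JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import association as assoc_mod
from . import gene_prioritization as gp
from . import variant_prioritization as vp
from .io_formats import (
    CohortAlleleCounts,
    PedigreeCollection,
    PopulationFrequencies,
    read_counts_table,
    read_frequency_panels,
    read_gene_list,
    read_ped,
    read_vcf,
    VariantRecord,
)
from .kinship import flag_pedigree_discordance, kinship_table
from .synthetic_data import (
    CohortBundle,
    ReplicationConfig,
    SimulationConfig,
    simulate_cohort,
    simulate_replication_cohort,
    write_bundle,
)

logger = logging.getLogger(__name__)

#: Default case/control group pairings for the association stage.
DEFAULT_ASSOCIATION_PAIRS = (
    ("NFE-TCGA", "NFE-ExAC-nonTCGA"),
    ("EUR-UKB-cancer", "EUR-UKB-cancerfree"),
    ("EUR-UKB-femaleBC", "EUR-UKB-female-cancerfree"),
)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class FunnelEntry:
    stage: str
    n_in: int
    n_out: int


class Funnel:
    """Filter-funnel log: every stage must be non-expanding."""

    def __init__(self) -> None:
        self.entries: List[FunnelEntry] = []

    def record(self, stage: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise StageFailure(stage, f"funnel expanded: {n_in} -> {n_out}")
        logger.info("stage %s: %d -> %d records", stage, n_in, n_out)
        self.entries.append(FunnelEntry(stage, n_in, n_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(e) for e in self.entries])


@dataclass
class PipelineConfig:
    """Fully serializable run configuration (echoed into the output directory)."""

    # inputs; either explicit paths or an embedded simulation
    vcf: Optional[str] = None
    ped: Optional[str] = None
    panel_a: Optional[str] = None
    panel_b: Optional[str] = None
    gene_list: Optional[str] = None
    replication_vcf: Optional[str] = None
    replication_ped: Optional[str] = None
    counts_table: Optional[str] = None
    simulate: Optional[dict] = None  # SimulationConfig fields
    simulate_replication: Optional[dict] = None  # ReplicationConfig fields
    # thresholds
    maf_max: float = 0.001
    fsv_maf_max: float = 0.0001
    min_family_carriers: int = 2
    consensus_k: int = 1
    qc_depth: int = 10
    qc_gq: int = 20
    qc_balance: Tuple[float, float] = (0.25, 0.75)
    kinship_unrelated_cutoff: float = 0.0442
    kinship_maf_floor: float = 0.0
    kinship_min_informative_hets: int = 100
    last_exon_at_discovery: bool = False
    ci_method: str = "exact_conditional"
    association_pairs: Sequence[Tuple[str, str]] = DEFAULT_ASSOCIATION_PAIRS
    random_seed: int = 0
    out_dir: str = "hbocprio_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.qc_balance = tuple(cfg.qc_balance)
        cfg.association_pairs = [tuple(p) for p in cfg.association_pairs]
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["qc_balance"] = list(self.qc_balance)
        data["association_pairs"] = [list(p) for p in self.association_pairs]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @property
    def qc(self) -> gp.QCThresholds:
        return gp.QCThresholds(
            min_depth=self.qc_depth, min_gq=self.qc_gq, het_balance=self.qc_balance
        )


def candidates_to_frame(candidates: Sequence[gp.CandidateRecord]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "chrom": c.key[0],
                "pos": c.key[1],
                "ref": c.key[2],
                "alt": c.key[3],
                "gene": c.gene,
                "transcript": c.transcript_id,
                "consequence": c.annotation.consequence_term,
                "n_carrier_patients": c.n_carrier_patients,
                "carrier_samples": ",".join(c.carrier_samples),
                "carrier_families": ",".join(c.carrier_families),
                "carriers_in_unaffected": ",".join(c.unaffected_carriers),
                "maf_panel_a": "." if c.maf_panel_a is None else f"{c.maf_panel_a:g}",
                "maf_panel_b": "." if c.maf_panel_b is None else f"{c.maf_panel_b:g}",
                "stages": ",".join(c.stages),
                "strategies": ";".join(sorted(str(t) for t in c.strategy_tags)),
                "replication_variants": ";".join(
                    f"{k[0]}:{k[1]}:{k[2]}:{k[3]}" for k in c.replication_variants
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "gene",
            "transcript",
            "consequence",
            "n_carrier_patients",
            "carrier_samples",
            "carrier_families",
            "carriers_in_unaffected",
            "maf_panel_a",
            "maf_panel_b",
            "stages",
            "strategies",
            "replication_variants",
        ],
    )


def association_from_counts(
    counts: Sequence[Tuple[str, str, CohortAlleleCounts]],
    pairs: Sequence[Tuple[str, str]] = DEFAULT_ASSOCIATION_PAIRS,
    method: str = "exact_conditional",
) -> pd.DataFrame:
    """Per-variant two-group Fisher comparisons from a cohort counts table."""
    by_variant: Dict[str, Dict[str, CohortAlleleCounts]] = {}
    order: List[str] = []
    for variant, group, cc in counts:
        if variant not in by_variant:
            order.append(variant)
        by_variant.setdefault(variant, {})[group] = cc
    rows = []
    for variant in order:
        groups = by_variant[variant]
        for case_group, control_group in pairs:
            if case_group not in groups or control_group not in groups:
                continue
            case, control = groups[case_group], groups[control_group]
            table = assoc_mod.TwoByTwoTable.from_counts(
                case.alt_alleles, case.total_alleles, control.alt_alleles, control.total_alleles
            )
            res = assoc_mod.odds_ratio_ci(table, method=method)
            rows.append(
                {
                    "variant": variant,
                    "case_group": case_group,
                    "control_group": control_group,
                    "case_alt": table.a,
                    "case_ref": table.b,
                    "control_alt": table.c,
                    "control_ref": table.d,
                    "p_two_sided": res.p_two_sided,
                    "odds_ratio": res.odds_ratio,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    kinship: pd.DataFrame
    exclusions: List[str]
    gene_candidates: List[gp.CandidateRecord]
    replicated: List[gp.CandidateRecord]
    variant_candidates: List[gp.CandidateRecord]
    presence: Dict
    association: Optional[pd.DataFrame]
    funnel: Funnel
    out_dir: Optional[Path] = None


def run_pipeline(config: PipelineConfig, write_reports: bool = True) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    With ``config.simulate`` set, synthetic inputs are generated first,
    written under ``out_dir/inputs`` and read back through the standard
    readers so the run exercises the same IO path as a real-data run.
    """
    out_dir = Path(config.out_dir)
    if write_reports:
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")
    funnel = Funnel()

    # --- inputs ---------------------------------------------------------
    if config.simulate is not None:
        sim_cfg = SimulationConfig(**{**config.simulate, "random_seed": config.random_seed})
        bundle = simulate_cohort(sim_cfg)
        inputs = out_dir / "inputs"
        paths = write_bundle(bundle, inputs, prefix="discovery")
        config.vcf, config.ped = str(paths["vcf"]), str(paths["ped"])
        config.panel_a, config.panel_b = str(paths["panel_a"]), str(paths["panel_b"])
        if config.simulate_replication is not None:
            rep_cfg = ReplicationConfig(
                **{**config.simulate_replication, "random_seed": config.random_seed + 1}
            )
            rep_bundle = simulate_replication_cohort(rep_cfg, bundle.records)
            rep_paths = write_bundle(rep_bundle, inputs, prefix="replication")
            config.replication_vcf = str(rep_paths["vcf"])
            config.replication_ped = str(rep_paths["ped"])
            # panels must cover both cohorts
            merged = PopulationFrequencies(
                panel_a={**bundle.frequencies.panel_a, **rep_bundle.frequencies.panel_a},
                panel_b={**bundle.frequencies.panel_b, **rep_bundle.frequencies.panel_b},
            )
            from .io_formats import write_frequency_table

            write_frequency_table(merged.panel_a, paths["panel_a"])
            write_frequency_table(merged.panel_b, paths["panel_b"])
    if config.vcf is None or config.ped is None:
        raise StageFailure("inputs", "no VCF/PED provided and no simulation configured")

    try:
        frequencies = (
            read_frequency_panels(config.panel_a, config.panel_b)
            if config.panel_a and config.panel_b
            else PopulationFrequencies()
        )
        records, samples = read_vcf(config.vcf, frequencies)
        pedigrees = read_ped(config.ped)
        pedigrees.mark_sequenced(samples)
    except Exception as exc:
        raise StageFailure("ingest", str(exc)) from exc
    funnel.record("ingest", len(records), len(records))

    # --- kinship QC ------------------------------------------------------
    kin = kinship_table(records, samples, maf_floor=config.kinship_maf_floor)
    report = flag_pedigree_discordance(
        kin,
        pedigrees,
        unrelated_cutoff=config.kinship_unrelated_cutoff,
        min_informative_hets=config.kinship_min_informative_hets,
    )
    exclusions = report.exclusions
    excluded = frozenset(exclusions)
    funnel.record("kinship_exclusion", len(samples), len(samples) - len(exclusions))

    # --- gene-based discovery --------------------------------------------
    try:
        gene_candidates = gp.shortlist_genes_discovery(
            records,
            pedigrees,
            maf_max=config.maf_max,
            min_family_carriers=config.min_family_carriers,
            qc=config.qc,
            excluded_samples=excluded,
            last_exon_at_discovery=config.last_exon_at_discovery,
        )
    except gp.SegregationError as exc:
        raise StageFailure("gene_discovery", str(exc)) from exc
    funnel.record("gene_discovery", len(records), len(gene_candidates))

    # --- replication ------------------------------------------------------
    replicated: List[gp.CandidateRecord] = []
    rep_records: List[VariantRecord] = []
    if config.replication_vcf:
        rep_records, _rep_samples = read_vcf(config.replication_vcf, frequencies)
        replicated = gp.replicate_genes(
            gene_candidates, rep_records, maf_max=config.maf_max, qc=config.qc
        )
        funnel.record("gene_replication", len(gene_candidates), len(replicated))

    # --- variant-based discovery -----------------------------------------
    phi_map = {
        (r.sample_i, r.sample_j): r.phi for r in kin.itertuples(index=False)
    }
    tag_maps = []
    if config.gene_list:
        tag_maps.append(vp.cgv_select(records, read_gene_list(config.gene_list)))
    tag_maps.append(
        vp.svgu_select(
            records,
            pedigrees,
            kinship_phi=phi_map,
            unrelated_cutoff=config.kinship_unrelated_cutoff,
            excluded_samples=excluded,
        )
    )
    tag_maps.append(
        vp.fsv_select(
            records, pedigrees, fsv_maf_max=config.fsv_maf_max, excluded_samples=excluded
        )
    )
    tags = vp.merge_tags(*tag_maps)
    try:
        variant_candidates = vp.shortlist_variants(
            records,
            tags,
            pedigrees,
            maf_max=config.maf_max,
            consensus_k=config.consensus_k,
            qc=config.qc,
            excluded_samples=excluded,
        )
    except gp.SegregationError as exc:
        raise StageFailure("variant_discovery", str(exc)) from exc
    funnel.record("variant_tagging", len(records), len(tags))
    funnel.record("variant_shortlist", len(tags), len(variant_candidates))

    presence: Dict = {}
    if rep_records:
        presence = vp.cross_cohort_presence(variant_candidates, rep_records)
        n_present = sum(1 for v in presence.values() if v)
        funnel.record("variant_replication_presence", len(variant_candidates), n_present)

    # --- association ------------------------------------------------------
    association: Optional[pd.DataFrame] = None
    if config.counts_table:
        counts = read_counts_table(config.counts_table)
        association = association_from_counts(
            counts, pairs=config.association_pairs, method=config.ci_method
        )

    result = PipelineResult(
        kinship=kin,
        exclusions=exclusions,
        gene_candidates=gene_candidates,
        replicated=replicated,
        variant_candidates=variant_candidates,
        presence=presence,
        association=association,
        funnel=funnel,
        out_dir=out_dir if write_reports else None,
    )
    if write_reports:
        _write_reports(result, out_dir)
    return result


def _write_reports(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.kinship.to_csv(out_dir / "kinship.tsv", sep="\t", index=False, float_format="%.6g")
    (out_dir / "exclusions.json").write_text(
        json.dumps({"excluded_samples": result.exclusions}, indent=2) + "\n"
    )
    candidates_to_frame(result.gene_candidates).to_csv(
        out_dir / "gene_candidates.tsv", sep="\t", index=False
    )
    candidates_to_frame(result.replicated).to_csv(
        out_dir / "replicated_genes.tsv", sep="\t", index=False
    )
    candidates_to_frame(result.variant_candidates).to_csv(
        out_dir / "variant_candidates.tsv", sep="\t", index=False
    )
    if result.association is not None:
        result.association.to_csv(
            out_dir / "association.tsv", sep="\t", index=False, float_format="%.6g"
        )
    result.funnel.to_frame().to_csv(out_dir / "funnel.tsv", sep="\t", index=False)
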