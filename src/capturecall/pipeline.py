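"""One reproducible run: simulate -> prepare -> call -> annotate -> filter -> associate.

A single master seed deterministically derives an independent stream per
stage, so toggling one stage (e.g. the duplication artifact) does not perturb
another stage's draws. Identical config + seed produces byte-identical
reports and output files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from . import io as ccio
from .annotator import annotate_region, annotate_variant
from .association import allele_frequency, tabulate_association, test_perfect_association
from .candidate_filter import (
    CandidateLedger,
    build_coding_ledger,
    sanger_validate,
    select_causal_candidates,
)
from .synthetic_data import (
    GROUP_CARRIER,
    HaplotypeTruth,
    ReferenceInterval,
    RepeatAnnotation,
    TruthVariant,
    generate_reference,
    make_oracle,
    plant_genes,
    plant_repeats,
    simulate_capture_reads,
    simulate_cohort_genotypes,
    simulate_haplotypes,
    table2_cohort,
)
from .target_prep import compute_single_copy_target, target_gap_stats
from .variant_caller import build_pileup, call_variants, filter_repeat_adjacent, summarize_variants

log = logging.getLogger("capturecall")


class ReferenceCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    length_bp: int = 120_000
    gc_fraction: float = 0.42
    chrom_name: str = "chr5_critical"


class RepeatsCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fraction: float = 0.35
    mean_len: int = 400


class GenesCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_genes: int = 5
    exons_per_gene: int = 4
    include_demo_cds: bool = True


class HaplotypesCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_neutral: int = 50
    causal_cds_offset: int = 363
    include_causal: bool = True


class ReadsCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    case_mean_cov: float = 44.0
    control_mean_cov: float = 15.0
    gap_fraction: float = 0.05
    read_len: int = 76
    err_rate: float = 0.002
    depth_sigma: float = 0.3
    dup_region: Optional[Tuple[int, int]] = None
    ensure_causal_covered: bool = True


class CallerCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hom_min_cov: int = 4
    hom_min_freq: float = 75.0
    het_min_cov: int = 15
    het_low: float = 25.0
    het_high: float = 75.0
    relaxed_het_min_cov: int = 10
    coverage_cap: int = 200
    repeat_margin: int = 10


class CohortCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_affected: int = 16
    n_carriers: int = 36
    n_unrelated: int = 309
    carrier_rate: float = 0.032
    n_other_breeds: int = 75
    n_phenocopies: int = 2
    fixture: bool = True  # use the exact printed-table cohort instead of sampling


class RunConfig(BaseModel):
    """Every tunable of every stage, schema-validated; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int
    reference: ReferenceCfg = Field(default_factory=ReferenceCfg)
    repeats: RepeatsCfg = Field(default_factory=RepeatsCfg)
    genes: GenesCfg = Field(default_factory=GenesCfg)
    haplotypes: HaplotypesCfg = Field(default_factory=HaplotypesCfg)
    reads: ReadsCfg = Field(default_factory=ReadsCfg)
    caller: CallerCfg = Field(default_factory=CallerCfg)
    cohort: CohortCfg = Field(default_factory=CohortCfg)

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seeds(master_seed: int) -> Dict[str, int]:
    names = ["reference", "repeats", "genes", "haplotypes", "reads_case", "reads_control", "pileup", "cohort"]
    children = np.random.SeedSequence(master_seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


class PipelineRun:
    """Artifacts of one pipeline execution (report plus in-memory objects)."""

    def __init__(self) -> None:
        self.config: Optional[RunConfig] = None
        self.ref: Optional[ReferenceInterval] = None
        self.repeats: Optional[RepeatAnnotation] = None
        self.genes: list = []
        self.truths: Dict[str, HaplotypeTruth] = {}
        self.case_calls: list = []
        self.control_calls: list = []
        self.case_excluded: list = []
        self.control_excluded: list = []
        self.ledger: Optional[CandidateLedger] = None
        self.cohort: Optional[pd.DataFrame] = None
        self.report: Dict = {}


def run_pipeline(config: RunConfig) -> PipelineRun:
    """Execute every stage in order; deterministic for fixed config + seed."""
    seeds = _stage_seeds(config.seed)
    run = PipelineRun()
    run.config = config

    log.info("stage reference: %d bp", config.reference.length_bp)
    ref = generate_reference(
        config.reference.length_bp,
        config.reference.gc_fraction,
        seeds["reference"],
        chrom_name=config.reference.chrom_name,
    )
    repeats = plant_repeats(ref, config.repeats.fraction, config.repeats.mean_len, seeds["repeats"])
    genes = plant_genes(
        ref,
        repeats,
        config.genes.n_genes,
        config.genes.exons_per_gene,
        seeds["genes"],
        include_demo_cds=config.genes.include_demo_cds,
    )
    target = compute_single_copy_target(ref, repeats)
    log.info(
        "stage target: %d bp single-copy of %d bp", target.total_single_copy_bp, ref.length
    )

    truths = simulate_haplotypes(
        ref,
        genes,
        config.haplotypes.n_neutral,
        config.haplotypes.causal_cds_offset,
        seeds["haplotypes"],
        repeats=repeats,
        include_causal=config.haplotypes.include_causal,
    )
    run.ref, run.repeats, run.genes, run.truths = ref, repeats, genes, truths
    case_id, control_id = "case_calf", "carrier_cow"
    case_truth, control_truth = truths[case_id], truths[control_id]
    causal = next((v for v in case_truth.hap_a if v.causal), None)
    ensure = [causal.pos] if (causal and config.reads.ensure_causal_covered) else []

    pileups = {}
    for animal, mean_cov, rseed in [
        (case_truth, config.reads.case_mean_cov, seeds["reads_case"]),
        (control_truth, config.reads.control_mean_cov, seeds["reads_control"]),
    ]:
        reads = simulate_capture_reads(
            animal,
            ref,
            mean_cov=mean_cov,
            gap_fraction=config.reads.gap_fraction,
            read_len=config.reads.read_len,
            err_rate=config.reads.err_rate,
            dup_region=config.reads.dup_region,
            seed=rseed,
            depth_sigma=config.reads.depth_sigma,
            ensure_covered=ensure,
        )
        log.info("stage reads %s: %d reads", animal.animal_id, reads.n_reads)
        pileups[animal.animal_id] = build_pileup(
            reads, ref, cap=config.caller.coverage_cap, seed=seeds["pileup"]
        )

    cc = config.caller
    raw_calls = {
        aid: call_variants(
            pileups[aid], cc.hom_min_cov, cc.hom_min_freq, cc.het_min_cov, cc.het_low, cc.het_high
        )
        for aid in (case_id, control_id)
    }
    kept_case, excl_case = filter_repeat_adjacent(raw_calls[case_id], repeats, cc.repeat_margin)
    kept_ctrl, excl_ctrl = filter_repeat_adjacent(raw_calls[control_id], repeats, cc.repeat_margin)
    run.case_calls, run.control_calls = kept_case, kept_ctrl
    run.case_excluded, run.control_excluded = excl_case, excl_ctrl
    log.info(
        "stage call: case %d kept/%d excluded, control %d kept/%d excluded",
        len(kept_case), len(excl_case), len(kept_ctrl), len(excl_ctrl),
    )
    summary = summarize_variants(kept_case, kept_ctrl)

    annotations = {}
    for c in kept_case:
        region, gene = annotate_region(c, genes)
        annotations[c.pos] = (region, gene.gene_id if gene is not None else None)
    ledger = build_coding_ledger(
        kept_case,
        pileups[control_id],
        annotations,
        hom_min_cov=cc.hom_min_cov,
        hom_min_freq=cc.hom_min_freq,
        relaxed_het_min_cov=cc.relaxed_het_min_cov,
        het_low=cc.het_low,
        het_high=cc.het_high,
    )
    pre_counts = ledger.counts()
    sanger_validate(ledger, make_oracle(control_truth, ref))
    finals = select_causal_candidates(ledger)
    run.ledger = ledger
    log.info("stage filter: %s -> %d final candidate(s)", pre_counts, len(finals))

    candidates_out: List[Dict] = []
    for e in finals:
        rec = annotate_variant(e.call, genes, ref)
        candidates_out.append(
            {
                "pos": e.call.pos,
                "ref": e.call.ref_allele,
                "alt": e.call.alt_allele,
                "gene_id": rec.gene_id,
                "cdna_hgvs": rec.cdna_hgvs,
                "protein_hgvs": rec.protein_hgvs,
                "consequence": rec.consequence,
                "mutant_protein_length": rec.mutant_protein_length,
                "is_true_causal": bool(causal and e.call.key() == causal.key()),
            }
        )

    if config.cohort.fixture:
        cohort = table2_cohort()
    else:
        cohort = simulate_cohort_genotypes(
            causal,
            config.cohort.n_affected,
            config.cohort.n_carriers,
            config.cohort.n_unrelated,
            config.cohort.carrier_rate,
            config.cohort.n_other_breeds,
            config.cohort.n_phenocopies,
            seeds["cohort"],
        )
    run.cohort = cohort
    table = tabulate_association(cohort)
    obligate = cohort.loc[cohort.group == GROUP_CARRIER, "animal_id"].tolist()
    verdict = test_perfect_association(table, cohort, obligate)
    log.info(
        "stage associate: perfect=%s, allele freq %.1f%%", verdict.perfect, verdict.allele_freq_pct
    )

    run.report = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
        },
        "target_stats": {
            "interval_length_bp": ref.length,
            "interval_length_mb": round(ref.length / 1e6, 2),
            "masked_bp": target.masked_bp,
            "single_copy_bp": target.total_single_copy_bp,
        },
        "variant_summary": {
            "case": summary.case,
            "control": summary.control,
            "shared": summary.shared,
            "case_repeat_adjacent_excluded": len(excl_case),
            "control_repeat_adjacent_excluded": len(excl_ctrl),
        },
        "ledger_counts": pre_counts,
        "ledger_counts_validated": ledger.counts(),
        "final_candidates": candidates_out,
        "no_candidate": len(candidates_out) == 0,
        "association": {
            "table": {g: list(table.row(g)) for g in ("affected", "carrier", "unrelated", "other_breed")},
            "perfect": verdict.perfect,
            "discordant_animals": [list(d) for d in verdict.discordant_animals],
            "phenocopy_suspects": sum(
                1 for _, r in verdict.discordant_animals if r == "phenocopy_suspect"
            ),
            "allele_freq_pct": verdict.allele_freq_pct,
            "carrier_count": verdict.carrier_count,
        },
        "truth": {
            "causal": None
            if causal is None
            else {"pos": causal.pos, "ref": causal.ref_allele, "alt": causal.alt_allele},
            "n_neutral": config.haplotypes.n_neutral,
        },
    }
    return run


def write_outputs(run: PipelineRun, outdir: Path) -> List[Path]:
    """Write every artifact of a completed run under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref, repeats, genes = run.ref, run.repeats, run.genes
    assert ref is not None and repeats is not None and run.config is not None
    written: List[Path] = []

    def _w(path: Path) -> Path:
        written.append(path)
        return path

    ccio.write_fasta(ref, _w(outdir / "reference.fa"))
    ccio.write_bed(repeats.intervals, ref.chrom_name, _w(outdir / "repeats.bed"))
    target = compute_single_copy_target(ref, repeats)
    ccio.write_bed(target.single_copy_intervals, ref.chrom_name, _w(outdir / "target.bed"))
    ccio.write_gff3(genes, ref.chrom_name, _w(outdir / "genes.gff3"))
    for aid, truth in run.truths.items():
        ccio.write_truth_vcf(truth, ref, _w(outdir / f"truth.{aid}.vcf"))
    ccio.write_calls_vcf(run.case_calls, ref, _w(outdir / "calls.case_calf.vcf"), "case_calf")
    ccio.write_calls_vcf(run.control_calls, ref, _w(outdir / "calls.carrier_cow.vcf"), "carrier_cow")
    ccio.write_bed(
        [(c.pos, c.pos) for c in run.case_excluded + run.control_excluded],
        ref.chrom_name,
        _w(outdir / "excluded_repeat_adjacent.bed"),
    )
    if run.ledger is not None:
        ccio.write_tsv(run.ledger.to_dataframe(), _w(outdir / "ledger.tsv"))
        finals = [e.call for e in run.ledger.final_candidates]
        info = {
            c["pos"]: ";".join(
                f"{k}={v}"
                for k, v in [
                    ("REGION", "cds"),
                    ("CHGVS", c["cdna_hgvs"]),
                    ("PHGVS", c["protein_hgvs"]),
                    ("CSQ", c["consequence"]),
                    ("MPLEN", c["mutant_protein_length"]),
                ]
                if v is not None
            )
            for c in run.report["final_candidates"]
        }
        ccio.write_calls_vcf(finals, ref, _w(outdir / "candidates.vcf"), "case_calf", info_extra=info)
    if run.cohort is not None:
        ccio.write_tsv(run.cohort, _w(outdir / "cohort.tsv"))
        table = tabulate_association(run.cohort)
        ccio.write_tsv(table.table, _w(outdir / "association.tsv"), index=True)

    # Table-1-style summary
    vs = run.report["variant_summary"]
    rows = []
    label = {
        "total": "Total variants",
        "snps": "SNPs",
        "transitions": "Transitions",
        "transversions": "Transversions",
        "indels": "InDels",
        "insertions": "Insertions",
        "deletions": "Deletions",
        "homozygous": "Homozygous (variant freq. >=75%; coverage >=4)",
        "heterozygous": "Heterozygous (25%< variant freq. <75%; coverage >=15)",
    }
    for k, lab in label.items():
        rows.append({"category": lab, "case": vs["case"][k], "control": vs["control"][k], "shared": vs["shared"][k]})
    ccio.write_tsv(pd.DataFrame(rows), _w(outdir / "summary.tsv"))

    ccio.write_json(run.report, _w(outdir / "report.json"))
    ccio.write_json(run.config.model_dump(), _w(outdir / "config.json"))
    return written
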