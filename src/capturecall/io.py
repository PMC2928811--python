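"""Readers/writers for the standard formats the pipeline exchanges.

Genomic coordinates are 1-based inclusive in memory; BED files are written
0-based half-open. VCF 4.2 is emitted with left-anchored indel records (an
insertion after pos is written at POS=pos with REF=anchor base; a deletion
of pos at POS=pos-1 with the deleted base appended to REF). Output is fully
deterministic: no timestamps or environment-dependent header lines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .synthetic_data import (
    GeneModel,
    HaplotypeTruth,
    ReferenceInterval,
    RepeatAnnotation,
    TruthVariant,
)
from .variant_caller import SiteCall

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(ref: ReferenceInterval, path: PathLike) -> None:
    rec = SeqRecord(
        Seq(ref.sequence),
        id=ref.chrom_name,
        description=f"{ref.chrom_name}:{ref.start}-{ref.end}",
    )
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: PathLike) -> ReferenceInterval:
    rec = next(SeqIO.parse(str(path), "fasta"))
    start, end = 1, len(rec.seq)
    if ":" in rec.description and "-" in rec.description.rsplit(":", 1)[-1]:
        rng = rec.description.rsplit(":", 1)[-1]
        try:
            s, e = rng.split("-")
            start, end = int(s), int(e)
        except ValueError:
            pass
    return ReferenceInterval(rec.id, start, end, str(rec.seq).upper())


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk)


def write_bed(
    intervals: Iterable[Tuple[int, int]],
    chrom: str,
    path: PathLike,
    names: Optional[Sequence[str]] = None,
) -> None:
    lines = []
    for i, (s, e) in enumerate(intervals):
        row = f"{chrom}\t{s - 1}\t{e}"
        if names is not None:
            row += f"\t{names[i]}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed(path: PathLike) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.append((int(f[1]) + 1, int(f[2])))
    return out


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(genes: Sequence[GeneModel], chrom: str, path: PathLike) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        span = (g.exons[0][0], g.exons[-1][1])
        lines.append(
            f"{chrom}\tcapturecall\tgene\t{span[0]}\t{span[1]}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
        mrna = f"{g.gene_id}.t1"
        lines.append(
            f"{chrom}\tcapturecall\tmRNA\t{span[0]}\t{span[1]}\t.\t{g.strand}\t.\t"
            f"ID={mrna};Parent={g.gene_id}"
        )
        # phase of a CDS segment: bases to skip before the first full codon
        exons = g.exons if g.strand == "+" else tuple(reversed(g.exons))
        consumed = 0
        phases: Dict[Tuple[int, int], int] = {}
        for s, e in exons:
            phases[(s, e)] = (3 - consumed % 3) % 3
            consumed += e - s + 1
        for k, (s, e) in enumerate(g.exons, 1):
            lines.append(
                f"{chrom}\tcapturecall\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mrna}.exon{k};Parent={mrna}"
            )
            lines.append(
                f"{chrom}\tcapturecall\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phases[(s, e)]}\t"
                f"ID={mrna}.cds;Parent={mrna}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VCF 4.2

_VCF_HEADER = """##fileformat=VCFv4.2
##source=capturecall {version}
##reference={refname}
##contig=<ID={chrom},length={length}>
##INFO=<ID=TRUTH,Number=1,Type=String,Description="Truth class of a simulated variant (causal or neutral)">
##INFO=<ID=REGION,Number=1,Type=String,Description="Annotated region (cds, splice_site, noncoding)">
##INFO=<ID=CHGVS,Number=1,Type=String,Description="cDNA HGVS name">
##INFO=<ID=PHGVS,Number=1,Type=String,Description="Protein HGVS name">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Predicted consequence">
##INFO=<ID=MPLEN,Number=1,Type=Integer,Description="Mutant protein length in residues">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=VF,Number=1,Type=Float,Description="Variant allele frequency (percent)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""

_GT_CODE = {"hom_var": "1/1", "het": "0/1", "low_cov_var": "./1", "hom_ref": "0/0"}


def _vcf_alleles(ref: ReferenceInterval, pos: int, ref_allele: str, alt_allele: str) -> Tuple[int, str, str]:
    """Variant-convention alleles -> left-anchored VCF (POS, REF, ALT)."""
    if ref_allele == "" and alt_allele != "":  # insertion after pos
        base = ref.base(pos)
        return (pos, base, base + alt_allele)
    if alt_allele == "" and ref_allele != "":  # deletion of pos..
        if pos - 1 < ref.start:
            raise ValueError("cannot left-anchor a deletion at the interval start")
        anchor = ref.base(pos - 1)
        return (pos - 1, anchor + ref_allele, anchor)
    return (pos, ref_allele, alt_allele)


def write_truth_vcf(
    truth: HaplotypeTruth,
    ref: ReferenceInterval,
    path: PathLike,
) -> None:
    """Truth haplotypes as a VCF with a TRUTH=causal|neutral INFO tag."""
    by_key: Dict[Tuple[int, str, str], Tuple[TruthVariant, int]] = {}
    for hap in (truth.hap_a, truth.hap_b):
        for v in hap:
            k = v.key()
            if k in by_key:
                by_key[k] = (v, by_key[k][1] + 1)
            else:
                by_key[k] = (v, 1)
    lines = []
    for (pos, _, _), (v, copies) in sorted(by_key.items()):
        vpos, vref, valt = _vcf_alleles(ref, v.pos, v.ref_allele, v.alt_allele)
        gt = "1/1" if copies == 2 else "0/1"
        info = f"TRUTH={'causal' if v.causal else 'neutral'}"
        lines.append(f"{ref.chrom_name}\t{vpos}\t.\t{vref}\t{valt}\t.\tPASS\t{info}\tGT\t{gt}")
    header = _VCF_HEADER.format(
        version=__version__,
        refname=ref.chrom_name,
        chrom=ref.chrom_name,
        length=ref.end,
        sample=truth.animal_id,
    )
    Path(path).write_text(header + "\n".join(lines) + ("\n" if lines else ""))


def write_calls_vcf(
    calls: Sequence[SiteCall],
    ref: ReferenceInterval,
    path: PathLike,
    sample: str,
    info_extra: Optional[Mapping[int, str]] = None,
) -> None:
    """Genotype calls as VCF 4.2 with GT:DP:VF; optional per-position INFO."""
    lines = []
    for c in sorted(calls, key=lambda c: c.pos):
        if c.alt_allele is None:
            continue
        vpos, vref, valt = _vcf_alleles(ref, c.pos, c.ref_allele, c.alt_allele)
        info = (info_extra or {}).get(c.pos, ".")
        gt = _GT_CODE.get(c.genotype, "./.")
        lines.append(
            f"{ref.chrom_name}\t{vpos}\t.\t{vref}\t{valt}\t.\tPASS\t{info}\t"
            f"GT:DP:VF\t{gt}:{c.depth}:{c.variant_freq:.1f}"
        )
    header = _VCF_HEADER.format(
        version=__version__,
        refname=ref.chrom_name,
        chrom=ref.chrom_name,
        length=ref.end,
        sample=sample,
    )
    Path(path).write_text(header + "\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# TSV / JSON


def write_tsv(df: pd.DataFrame, path: PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_cohort_tsv(path: PathLike) -> pd.DataFrame:
    """Cohort truth table (animal_id, group, genotype, phenotype_record)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"animal_id", "group", "genotype", "phenotype_record"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort TSV missing columns: {sorted(missing)}")
    return df


def write_json(obj: object, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
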