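"""Coding-region annotation and HGVS-style consequence prediction.

Maps called variants onto gene models (CDS / splice site / noncoding), names
them at the cDNA level (``c.363_364insG``; the historical dash dialect
``c.363-364insG`` is accepted by the parser), translates mutated coding
sequences, and predicts frameshift consequences including the truncated
mutant protein length. Protein frameshift names use three-letter amino-acid
codes with ``X`` for the stop (``Ter``/``*`` accepted on input), e.g.
``p.Ala124GlyfsX42``: first changed residue 124, stop at the 42nd altered
codon, hence a 123 + 41 = 164-residue mutant protein.

Insertion names are deliberately not 3'-shifted/normalised; the reported
position is the physical insertion point in CDS coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple, Union

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .synthetic_data import GeneModel, ReferenceInterval, TruthVariant, revcomp
from .variant_caller import SiteCall

VariantLike = Union[TruthVariant, SiteCall]


@dataclass
class ConsequenceRecord:
    gene_id: Optional[str]
    region: str  # cds | splice_site | noncoding
    cdna_hgvs: Optional[str] = None
    protein_hgvs: Optional[str] = None
    consequence: Optional[str] = None  # frameshift | missense | synonymous | nonsense | inframe_indel | intronic
    mutant_protein_length: Optional[int] = None
    stop_lost: bool = False


# ---------------------------------------------------------------------------
# region assignment


def annotate_region(
    variant: Union[VariantLike, int],
    genes: Sequence[GeneModel],
    splice_margin: int = 2,
) -> Tuple[str, Optional[GeneModel]]:
    """cds if inside a coding exon; splice_site if within ``splice_margin`` nt
    of an exon boundary on the intron side; noncoding otherwise."""
    pos = variant if isinstance(variant, int) else variant.pos
    for gene in genes:
        if gene.contains(pos):
            return ("cds", gene)
    for gene in genes:
        for i, (s, e) in enumerate(gene.exons):
            if i > 0 and s - splice_margin <= pos <= s - 1:
                return ("splice_site", gene)
            if i < len(gene.exons) - 1 and e + 1 <= pos <= e + splice_margin:
                return ("splice_site", gene)
    return ("noncoding", None)


# ---------------------------------------------------------------------------
# cDNA HGVS


def _variant_fields(variant: VariantLike) -> Tuple[int, str, str]:
    ref = variant.ref_allele or ""
    alt = variant.alt_allele or ""
    return (variant.pos, ref, alt)


def hgvs_cdna(variant: VariantLike, gene: GeneModel) -> str:
    """Name a genomic variant in 1-based CDS coordinates on the coding strand."""
    pos, ref, alt = _variant_fields(variant)
    if ref == "" and alt != "":  # insertion between pos and pos+1
        c1 = gene.genomic_to_cds(pos)
        c2 = gene.genomic_to_cds(pos + 1)
        if c1 is None or c2 is None:
            raise ValueError("insertion site outside the CDS")
        if abs(c1 - c2) != 1:
            raise ValueError("insertion spans an exon boundary")
        lo = min(c1, c2)
        seq = alt if gene.strand == "+" else revcomp(alt)
        return f"c.{lo}_{lo + 1}ins{seq}"
    c = gene.genomic_to_cds(pos)
    if c is None:
        raise ValueError(f"position {pos} outside the CDS of {gene.gene_id}")
    if alt == "":  # deletion
        if len(ref) != 1:
            raise ValueError("only single-base deletions are named")
        base = ref if gene.strand == "+" else revcomp(ref)
        return f"c.{c}del{base}"
    if gene.strand == "-":
        ref, alt = revcomp(ref), revcomp(alt)
    return f"c.{c}{ref}>{alt}"


_INS_RE = re.compile(r"^c\.(\d+)[_\-–](\d+)ins([ACGT]+)$")
_SNV_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_DEL_RE = re.compile(r"^c\.(\d+)del([ACGT]*)$")


def parse_hgvs_cdna(text: str) -> Dict[str, object]:
    """Parse a cDNA HGVS name; accepts both ``c.363_364insG`` and the dash
    dialect ``c.363-364insG`` (ASCII hyphen or en-dash)."""
    m = _INS_RE.match(text)
    if m:
        a, b = int(m.group(1)), int(m.group(2))
        if b != a + 1:
            raise ValueError(f"insertion interval must be adjacent positions: {text!r}")
        return {"kind": "ins", "cds_pos": a, "ref": "", "alt": m.group(3)}
    m = _SNV_RE.match(text)
    if m:
        return {"kind": "snv", "cds_pos": int(m.group(1)), "ref": m.group(2), "alt": m.group(3)}
    m = _DEL_RE.match(text)
    if m:
        return {"kind": "del", "cds_pos": int(m.group(1)), "ref": m.group(2), "alt": ""}
    raise ValueError(f"unparseable cDNA HGVS: {text!r}")


def cdna_to_genomic(parsed: Dict[str, object], gene: GeneModel) -> Tuple[int, str, str]:
    """Inverse of hgvs_cdna: genomic (pos, ref, alt) in plus-strand alleles."""
    cpos = int(parsed["cds_pos"])  # type: ignore[arg-type]
    kind = parsed["kind"]
    if kind == "ins":
        g1 = gene.cds_to_genomic(cpos)
        g2 = gene.cds_to_genomic(cpos + 1)
        alt = str(parsed["alt"])
        return (min(g1, g2), "", alt if gene.strand == "+" else revcomp(alt))
    g = gene.cds_to_genomic(cpos)
    ref = str(parsed["ref"])
    alt = str(parsed["alt"])
    if gene.strand == "-":
        ref, alt = (revcomp(ref) if ref else ""), (revcomp(alt) if alt else "")
    return (g, ref, alt)


# ---------------------------------------------------------------------------
# protein consequence


def apply_cds_variant(cds: str, cds_pos: int, ref: str, alt: str) -> str:
    """Apply a CDS-space variant (insertion goes after cds_pos)."""
    i = cds_pos - 1
    if ref == "" and alt != "":
        return cds[: i + 1] + alt + cds[i + 1 :]
    if alt == "":
        if cds[i : i + len(ref)] != ref:
            raise ValueError("deletion ref allele does not match the CDS")
        return cds[:i] + cds[i + len(ref) :]
    if cds[i] != ref:
        raise ValueError(f"ref allele {ref} does not match CDS base {cds[i]} at c.{cds_pos}")
    return cds[:i] + alt + cds[i + 1 :]


def _validate_cds(cds: str) -> str:
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    if not cds.startswith("ATG"):
        raise ValueError("CDS does not start with ATG")
    prot = str(Seq(cds).translate())
    if not prot.endswith("*"):
        raise ValueError("CDS does not end with a stop codon")
    if "*" in prot[:-1]:
        raise ValueError("CDS has an internal stop codon")
    return prot


def predict_protein_consequence(
    variant: Union[VariantLike, Tuple[int, str, str]],
    cds_sequence: str,
    cds_pos: Optional[int] = None,
    gene_id: Optional[str] = None,
) -> ConsequenceRecord:
    """Translate a mutated CDS and describe the protein-level consequence.

    ``variant`` may be a variant object together with ``cds_pos`` (its 1-based
    CDS coordinate, alleles already in coding-strand orientation), or a bare
    ``(cds_pos, ref, alt)`` tuple. For frameshifts the name is
    ``p.<Ref><pos><Alt>fsX<n>`` where pos is the first residue whose amino
    acid differs from wild type and n is the stop position counting that
    residue as 1; the truncated protein has (pos-1)+(n-1) residues.
    """
    if isinstance(variant, tuple):
        cpos, ref, alt = variant
    else:
        if cds_pos is None:
            raise ValueError("cds_pos is required when passing a variant object")
        cpos = cds_pos
        ref, alt = variant.ref_allele or "", variant.alt_allele or ""
    wt_prot = _validate_cds(cds_sequence)
    mutant = apply_cds_variant(cds_sequence, cpos, ref, alt)

    indel_shift = (len(alt) - len(ref)) % 3
    rec = ConsequenceRecord(gene_id=gene_id, region="cds")

    if len(ref) == len(alt) == 1:  # SNV
        ci = (cpos - 1) // 3
        wt_aa = wt_prot[ci]
        mut_aa = str(Seq(mutant[ci * 3 : ci * 3 + 3]).translate())
        if mut_aa == wt_aa:
            rec.consequence = "synonymous"
            rec.protein_hgvs = f"p.{seq3(wt_aa)}{ci + 1}="
        elif mut_aa == "*":
            rec.consequence = "nonsense"
            rec.protein_hgvs = f"p.{seq3(wt_aa)}{ci + 1}X"
            rec.mutant_protein_length = ci
        else:
            rec.consequence = "missense"
            rec.protein_hgvs = f"p.{seq3(wt_aa)}{ci + 1}{seq3(mut_aa)}"
        rec.cdna_hgvs = f"c.{cpos}{ref}>{alt}"
        return rec

    if indel_shift == 0:
        rec.consequence = "inframe_indel"
        return rec

    # frameshift: translate the mutated sequence to its first stop
    rec.consequence = "frameshift"
    trimmed = mutant[: len(mutant) - len(mutant) % 3]
    mut_prot = str(Seq(trimmed).translate())
    stop_idx = mut_prot.find("*")
    if stop_idx == -1:
        rec.stop_lost = True
        return rec
    wt_core = wt_prot[:-1]
    first_diff = None
    for i in range(min(len(wt_core), stop_idx)):
        if mut_prot[i] != wt_core[i]:
            first_diff = i
            break
    if first_diff is None:
        # frame shift whose first difference is the premature stop itself
        first_diff = stop_idx
        rec.protein_hgvs = f"p.{seq3(wt_core[first_diff])}{first_diff + 1}X"
        rec.mutant_protein_length = stop_idx
        rec.consequence = "nonsense"
        return rec
    pos1 = first_diff + 1
    n = stop_idx + 1 - pos1 + 1  # stop position counting the first changed residue as 1
    rec.protein_hgvs = f"p.{seq3(wt_core[first_diff])}{pos1}{seq3(mut_prot[first_diff])}fsX{n}"
    rec.mutant_protein_length = (pos1 - 1) + (n - 1)
    return rec


_FS_RE = re.compile(
    r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})fs(?:X|Ter|\*)(\d+)$"
)


def truncated_length_from_hgvs(protein_hgvs: str) -> int:
    """Residue count of the truncated protein implied by a frameshift name:
    (first changed position - 1) + (stop index - 1)."""
    m = _FS_RE.match(protein_hgvs)
    if not m:
        raise ValueError(f"not a frameshift protein HGVS: {protein_hgvs!r}")
    pos = int(m.group(2))
    n = int(m.group(4))
    if pos < 1 or n < 1:
        raise ValueError("positions in protein HGVS must be >= 1")
    return (pos - 1) + (n - 1)


# ---------------------------------------------------------------------------
# one-stop annotation of a called variant


def annotate_variant(
    variant: VariantLike,
    genes: Sequence[GeneModel],
    ref: ReferenceInterval,
    splice_margin: int = 2,
) -> ConsequenceRecord:
    """Region + cDNA name + protein consequence for one variant."""
    region, gene = annotate_region(variant, genes, splice_margin)
    if region == "noncoding" or gene is None:
        return ConsequenceRecord(gene_id=None, region="noncoding", consequence="intronic")
    if region == "splice_site":
        return ConsequenceRecord(gene_id=gene.gene_id, region="splice_site", consequence="intronic")
    try:
        name = hgvs_cdna(variant, gene)
    except ValueError:
        # e.g. an insertion anchored exactly on an exon/intron boundary
        return ConsequenceRecord(gene_id=gene.gene_id, region="cds")
    parsed = parse_hgvs_cdna(name)
    rec = predict_protein_consequence(
        (int(parsed["cds_pos"]), str(parsed["ref"]), str(parsed["alt"])),
        gene.cds_sequence(ref),
        gene_id=gene.gene_id,
    )
    rec.cdna_hgvs = name
    rec.gene_id = gene.gene_id
    return rec
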