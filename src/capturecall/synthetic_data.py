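"""Synthetic inputs for a capture-resequencing positional-cloning study.

This module generates every input the downstream pipeline consumes, with
known truth: a reference interval, a repeat annotation, intact gene models,
pedigree-structured haplotypes (an affected calf homozygous for a mutant
ancestral haplotype, and a healthy partially inbred cow carrying one mutant
and one wild-type copy of the *same* ancestral haplotype — identical by
descent, hence heterozygous only at the causal site), capture reads with
variable depth, capture gaps and sequencing errors, and cohort genotypes at
the candidate site.

The genetic design it emulates is the classic livestock trick: a recessive
lethal mapped to a critical interval, where a single IBD carrier re-sequenced
across the interval should show exactly one heterozygous position — the
causative mutation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._intervals import complement, merge_intervals, total_bp

# ---------------------------------------------------------------------------
# base coding

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def encode_seq(seq: str) -> np.ndarray:
    """Uppercase ACGT string -> uint8 codes 0..3."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside ACGT")
    return arr


def decode_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ReferenceInterval:
    """A critical chromosomal segment: coordinates plus its sequence.

    Coordinates are 1-based inclusive; ``sequence`` covers start..end.
    """

    chrom_name: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start")
        if len(self.sequence) != self.length:
            raise ValueError("sequence length does not match coordinates")
        encode_seq(self.sequence)  # alphabet check

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def codes(self) -> np.ndarray:
        return encode_seq(self.sequence)

    def base(self, pos: int) -> str:
        if not (self.start <= pos <= self.end):
            raise ValueError(f"position {pos} outside {self.start}..{self.end}")
        return self.sequence[pos - self.start]

    def slice(self, s: int, e: int) -> str:
        if not (self.start <= s <= e <= self.end):
            raise ValueError("slice outside reference bounds")
        return self.sequence[s - self.start : e - self.start + 1]

    def set_bases(self, pos: int, seq: str) -> None:
        """Overwrite bases starting at pos (used when planting gene ORFs)."""
        encode_seq(seq)
        i = pos - self.start
        if i < 0 or i + len(seq) > self.length:
            raise ValueError("write outside reference bounds")
        self.sequence = self.sequence[:i] + seq + self.sequence[i + len(seq) :]


@dataclass
class RepeatAnnotation:
    """Sorted, merged, non-overlapping masked intervals (1-based inclusive)."""

    intervals: List[Tuple[int, int]]

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)

    @property
    def masked_bp(self) -> int:
        return total_bp(self.intervals)


@dataclass
class GeneModel:
    """A protein-coding gene with whole-exon CDS anchored on the reference."""

    gene_id: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        ex = tuple(sorted(self.exons))
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap")
        self.exons = ex

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """1-based CDS coordinate of a genomic position, or None if intronic."""
        if self.strand == "+":
            acc = 0
            for s, e in self.exons:
                if s <= pos <= e:
                    return acc + (pos - s + 1)
                acc += e - s + 1
        else:
            acc = 0
            for s, e in reversed(self.exons):
                if s <= pos <= e:
                    return acc + (e - pos + 1)
                acc += e - s + 1
        return None

    def cds_to_genomic(self, cpos: int) -> int:
        if not (1 <= cpos <= self.cds_length):
            raise ValueError(f"CDS position {cpos} outside 1..{self.cds_length}")
        if self.strand == "+":
            acc = 0
            for s, e in self.exons:
                ln = e - s + 1
                if cpos <= acc + ln:
                    return s + (cpos - acc - 1)
                acc += ln
        else:
            acc = 0
            for s, e in reversed(self.exons):
                ln = e - s + 1
                if cpos <= acc + ln:
                    return e - (cpos - acc - 1)
                acc += ln
        raise AssertionError("unreachable")

    def cds_sequence(self, ref: ReferenceInterval) -> str:
        parts = [ref.slice(s, e) for s, e in self.exons]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass
class TruthVariant:
    """A planted variant; the empty-string allele convention marks indels.

    ``pos`` is the variant base for SNVs and deletions, and the anchor base
    (insertion occurs between pos and pos+1) for insertions.
    """

    pos: int
    ref_allele: str
    alt_allele: str
    vclass: str
    causal: bool = False

    def __post_init__(self) -> None:
        if self.vclass == "snv":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("snv alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ValueError("snv alleles identical")
        elif self.vclass == "ins":
            if self.ref_allele != "" or len(self.alt_allele) < 1:
                raise ValueError("insertion must have empty ref and non-empty alt")
        elif self.vclass == "del":
            if self.alt_allele != "" or len(self.ref_allele) < 1:
                raise ValueError("deletion must have non-empty ref and empty alt")
        else:
            raise ValueError(f"unknown variant class {self.vclass!r}")

    def key(self) -> Tuple[int, str, str]:
        return (self.pos, self.ref_allele, self.alt_allele)


@dataclass
class HaplotypeTruth:
    """Per-animal pair of haplotypes, each a variant list applied to the reference."""

    animal_id: str
    hap_a: Tuple[TruthVariant, ...]
    hap_b: Tuple[TruthVariant, ...]
    role: str

    def __post_init__(self) -> None:
        if self.role not in ("case", "carrier_control", "cohort"):
            raise ValueError(f"unknown role {self.role!r}")
        self.hap_a = tuple(sorted(self.hap_a, key=lambda v: v.pos))
        self.hap_b = tuple(sorted(self.hap_b, key=lambda v: v.pos))

    def het_positions(self) -> List[int]:
        ka = {v.key() for v in self.hap_a}
        kb = {v.key() for v in self.hap_b}
        return sorted({k[0] for k in ka.symmetric_difference(kb)})


class Haplotype:
    """A haplotype sequence with its gapless alignment back to the reference.

    For every haplotype base we record the reference position it aligns to
    (inserted bases carry their anchor position and an is_insert flag);
    deletions are recorded as "a deleted reference base sits between haplotype
    index i and i+1". This replaces an aligner: reads simulated from a
    haplotype know exactly which reference columns they cover.
    """

    def __init__(self, ref: ReferenceInterval, variants: Sequence[TruthVariant]):
        ref_codes = ref.codes()
        L = ref.length
        off = ref.start
        codes_parts: List[np.ndarray] = []
        refpos_parts: List[np.ndarray] = []
        isins_parts: List[np.ndarray] = []
        self.del_after: Dict[int, int] = {}  # hap index -> deleted ref pos
        self.ins_seq: Dict[int, str] = {}  # anchor ref pos -> inserted seq
        cur_len = 0

        def add_ref_block(a: int, b: int) -> None:
            # reference positions a..b inclusive (1-based genomic)
            nonlocal cur_len
            if b < a:
                return
            codes_parts.append(ref_codes[a - off : b - off + 1])
            refpos_parts.append(np.arange(a, b + 1, dtype=np.int64))
            isins_parts.append(np.zeros(b - a + 1, dtype=bool))
            cur_len += b - a + 1

        prev = ref.start
        for v in sorted(variants, key=lambda v: v.pos):
            p = v.pos
            if not (ref.start <= p <= ref.end):
                raise ValueError(f"variant position {p} outside reference")
            if p < prev:
                raise ValueError("overlapping variants in one haplotype")
            if v.vclass == "snv":
                add_ref_block(prev, p - 1)
                codes_parts.append(encode_seq(v.alt_allele))
                refpos_parts.append(np.array([p], dtype=np.int64))
                isins_parts.append(np.zeros(1, dtype=bool))
                cur_len += 1
                prev = p + 1
            elif v.vclass == "ins":
                add_ref_block(prev, p)
                codes_parts.append(encode_seq(v.alt_allele))
                refpos_parts.append(np.full(len(v.alt_allele), p, dtype=np.int64))
                isins_parts.append(np.ones(len(v.alt_allele), dtype=bool))
                cur_len += len(v.alt_allele)
                self.ins_seq[p] = v.alt_allele
                prev = p + 1
            elif v.vclass == "del":
                add_ref_block(prev, p - 1)
                if cur_len == 0:
                    raise ValueError("deletion at the first reference base is unsupported")
                self.del_after[cur_len - 1] = p
                prev = p + 1
        add_ref_block(prev, ref.end)

        self.codes = np.concatenate(codes_parts) if codes_parts else np.zeros(0, np.uint8)
        self.ref_pos = np.concatenate(refpos_parts) if refpos_parts else np.zeros(0, np.int64)
        self.is_ins = np.concatenate(isins_parts) if isins_parts else np.zeros(0, bool)
        # map reference pos -> haplotype index for aligned (non-deleted) bases
        self.ref2hap = np.full(ref.end + 2, -1, dtype=np.int64)
        match = ~self.is_ins
        self.ref2hap[self.ref_pos[match]] = np.flatnonzero(match)

    def __len__(self) -> int:
        return len(self.codes)

    def sequence(self) -> str:
        return decode_seq(self.codes)


@dataclass
class SimRead:
    origin_pos: int  # leftmost aligned reference position
    length: int
    sequence: str
    hap_of_origin: int


@dataclass
class ReadSet:
    """Simulated capture reads for one sample.

    Reads carry their true haplotype of origin and their start index in that
    haplotype; no alignment step exists anywhere in the pipeline. The codes
    matrix already includes substitution sequencing errors.
    """

    sample_id: str
    read_len: int
    err_rate: float
    haplotypes: Tuple[Haplotype, ...]
    hap_idx: np.ndarray  # (n,) index into haplotypes
    hap_start: np.ndarray  # (n,) 0-based start within the haplotype
    codes: np.ndarray  # (n, read_len) uint8 base codes with errors applied
    ref: ReferenceInterval

    @property
    def n_reads(self) -> int:
        return len(self.hap_idx)

    def iter_reads(self) -> Iterator[SimRead]:
        for i in range(self.n_reads):
            hap = self.haplotypes[self.hap_idx[i]]
            s = int(self.hap_start[i])
            refs = hap.ref_pos[s : s + self.read_len]
            yield SimRead(
                origin_pos=int(refs.min()),
                length=self.read_len,
                sequence=decode_seq(self.codes[i]),
                hap_of_origin=int(self.hap_idx[i]),
            )


# ---------------------------------------------------------------------------
# generators


def generate_reference(
    length_bp: int,
    gc_fraction: float,
    seed: int,
    chrom_name: str = "chr5_critical",
) -> ReferenceInterval:
    """Random reference interval with a target GC content.

    Bases are drawn i.i.d. with P(G)=P(C)=gc/2; a desk-scale stand-in for the
    critical chromosomal segment.
    """
    if length_bp < 1000:
        raise ValueError("length_bp must be >= 1000")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gc2 = gc_fraction / 2.0
    at2 = (1.0 - gc_fraction) / 2.0
    codes = rng.choice(4, size=length_bp, p=[at2, gc2, gc2, at2]).astype(np.uint8)
    return ReferenceInterval(chrom_name, 1, length_bp, decode_seq(codes))


def plant_repeats(
    ref: ReferenceInterval,
    target_repeat_fraction: float,
    mean_len: int,
    seed: int,
) -> RepeatAnnotation:
    """Place random repeat intervals until a target masked fraction is reached.

    Lengths are exponential around mean_len; placements may overlap and are
    merged. The final masked total is trimmed to the target.
    """
    if not (0.0 <= target_repeat_fraction < 0.9):
        raise ValueError("target_repeat_fraction must be in [0, 0.9): the single-copy target would vanish")
    if target_repeat_fraction == 0.0:
        return RepeatAnnotation([])
    if mean_len < 1:
        raise ValueError("mean_len must be positive")
    rng = np.random.default_rng(seed)
    L = ref.length
    target = int(round(target_repeat_fraction * L))
    mask = np.zeros(L, dtype=bool)
    covered = 0
    while covered < target:
        ln = max(30, int(round(rng.exponential(mean_len))))
        ln = min(ln, L)
        s = int(rng.integers(0, L - ln + 1))
        block = mask[s : s + ln]
        new = ln - int(block.sum())
        if new == 0:
            continue
        if covered + new > target:
            # trim: unset the excess from the tail of this placement
            excess = covered + new - target
            idx = np.flatnonzero(~block) + s
            block_set = idx[: len(idx) - excess]
            mask[block_set] = True
            covered = target
        else:
            mask[s : s + ln] = True
            covered += new
    # extract 1-based inclusive intervals
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    ivs = [(int(s) + ref.start, int(e) + ref.start) for s, e in zip(starts, ends)]
    return RepeatAnnotation(ivs)


# 10 sense codons used to fill ORFs deterministically where randomness is not needed
_SAFE_CODONS = ["GCT", "GAA", "CTG", "AAG", "GAT", "TTC", "GGA", "ATC", "CAT", "GTG"]
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
]


def demo_frameshift_cds() -> str:
    """A 545-codon CDS built so that inserting G between CDS bases 363 and 364
    shifts the frame with residues 122-123 conserved, residue 124 Ala->Gly, and
    the first shifted-frame stop at mutant codon 165 — i.e. p.Ala124GlyfsX42
    and a 164-residue truncated protein.
    """
    codons = ["ATG"]
    codons += [_SAFE_CODONS[i % len(_SAFE_CODONS)] for i in range(120)]  # residues 2..121
    codons += ["GGG", "GGG", "GCA"]  # residues 122, 123, 124 (Gly, Gly, Ala)
    codons += ["GCT"] * 40  # residues 125..164 (shifted frame reads TGC, Cys)
    codons += ["AAA"]  # residue 165 — codon 164's T plus these AA form TAA in the shifted frame
    codons += ["GCT"] * (545 - 165)  # residues 166..545
    codons += ["TGA"]
    return "".join(codons)


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + one stop; n_codons counts the stop."""
    if n_codons < 3:
        raise ValueError("n_codons must be >= 3")
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    stop = rng.choice(["TAA", "TAG", "TGA"])
    return "ATG" + "".join(body) + str(stop)


def plant_genes(
    ref: ReferenceInterval,
    repeats: RepeatAnnotation,
    n_genes: int,
    exons_per_gene: int,
    seed: int,
    cds_codons: Tuple[int, int] = (220, 420),
    include_demo_cds: bool = True,
    pad: int = 12,
) -> List[GeneModel]:
    """Embed intact multi-exon ORFs into single-copy sequence.

    The CDS bases (plus GT..AG introns) are written into the reference in
    place so that every gene model's reference-frame translation starts with
    Met, ends with a stop and has no internal stop. Gene 1 optionally carries
    the fixed frameshift-demonstration CDS; the rest are random ORFs.
    Gene bodies keep ``pad`` bp clearance from masked repeats so coding calls
    are never lost to the repeat-adjacency filter.
    """
    if n_genes < 1 or exons_per_gene < 1:
        raise ValueError("n_genes and exons_per_gene must be positive")
    rng = np.random.default_rng(seed)
    occupied: List[Tuple[int, int]] = list(repeats.intervals)
    genes: List[GeneModel] = []
    min_exon = 40

    for gi in range(n_genes):
        if gi == 0 and include_demo_cds:
            cds = demo_frameshift_cds()
        else:
            n_cod = int(rng.integers(cds_codons[0], cds_codons[1] + 1))
            cds = random_cds(rng, n_cod)
        n_ex = exons_per_gene
        if len(cds) < n_ex * min_exon:
            n_ex = max(1, len(cds) // min_exon)
        # split CDS into n_ex exon pieces, each >= min_exon, never cutting
        # between CDS bases 363|364 (keeps the demo insertion intra-exonic)
        for _attempt in range(200):
            if n_ex == 1:
                cuts: List[int] = []
            else:
                cuts = sorted(
                    int(c)
                    for c in rng.choice(
                        np.arange(min_exon, len(cds) - min_exon + 1), size=n_ex - 1, replace=False
                    )
                )
            bounds = [0] + cuts + [len(cds)]
            sizes = [b - a for a, b in zip(bounds, bounds[1:])]
            if min(sizes) >= min_exon and 363 not in cuts:
                break
        else:
            raise RuntimeError("could not split CDS into exons of the requested count")
        introns = [int(rng.integers(80, 301)) for _ in range(n_ex - 1)]
        span = len(cds) + sum(introns)

        # transcript-orientation gene sequence with canonical GT..AG introns
        pieces: List[str] = []
        t_exons: List[Tuple[int, int]] = []  # 0-based transcript offsets, inclusive
        t = 0
        for k in range(n_ex):
            a, b = bounds[k], bounds[k + 1]
            pieces.append(cds[a:b])
            t_exons.append((t, t + (b - a) - 1))
            t += b - a
            if k < n_ex - 1:
                iln = introns[k]
                mid = decode_seq(rng.integers(0, 4, size=iln - 4).astype(np.uint8))
                pieces.append("GT" + mid + "AG")
                t += iln
        gene_seq = "".join(pieces)
        assert len(gene_seq) == span

        # placement into a free single-copy gap with pad clearance
        lo, hi = ref.start + pad, ref.end - pad
        clipped = [(max(s, lo), min(e, hi)) for s, e in occupied if e >= lo and s <= hi]
        free = complement(clipped, lo, hi)
        candidates = [(s, e) for s, e in free if e - s + 1 >= span + 2 * pad]
        if not candidates:
            raise RuntimeError(
                f"insufficient single-copy space for gene {gi + 1}: "
                f"need {span + 2 * pad} bp contiguous outside repeats"
            )
        s, e = candidates[int(rng.integers(0, len(candidates)))]
        g0 = int(rng.integers(s + pad, e - span - pad + 2))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            ref.set_bases(g0, gene_seq)
            g_exons = [(g0 + a, g0 + b) for a, b in t_exons]
        else:
            ref.set_bases(g0, revcomp(gene_seq))
            n = span
            g_exons = sorted((g0 + (n - 1 - b), g0 + (n - 1 - a)) for a, b in t_exons)
        occupied = merge_intervals(occupied + [(g0 - pad, g0 + span - 1 + pad)])
        genes.append(
            GeneModel(
                gene_id=f"gene{gi + 1}",
                strand=strand,
                exons=tuple(g_exons),
                cds_start=g_exons[0][0],
                cds_end=g_exons[-1][1],
            )
        )
    return genes


def simulate_haplotypes(
    ref: ReferenceInterval,
    genes: Sequence[GeneModel],
    n_neutral: int,
    causal_cds_offset: int,
    seed: int,
    repeats: Optional[RepeatAnnotation] = None,
    include_causal: bool = True,
    snv_fraction: float = 0.85,
    ins_fraction: float = 0.08,
    case_id: str = "case_calf",
    control_id: str = "carrier_cow",
) -> Dict[str, HaplotypeTruth]:
    """Build the two study animals' truth haplotypes.

    The ancestral haplotype H carries n_neutral differences from the
    reference; the mutant haplotype H* additionally carries the causal 1-bp
    coding insertion (G between CDS positions ``causal_cds_offset`` and +1 of
    the first gene whose CDS can host it). The affected calf is H*/H*, the
    inbred carrier cow H*/H: identical by descent, heterozygous only at the
    causal site.
    """
    if n_neutral < 0:
        raise ValueError("n_neutral must be >= 0")
    rng = np.random.default_rng(seed)

    causal: Optional[TruthVariant] = None
    reserved: List[int] = []
    if include_causal:
        gene = next((g for g in genes if g.cds_length >= causal_cds_offset + 3), None)
        if gene is None:
            raise ValueError(
                f"causal_cds_offset {causal_cds_offset} lies outside every generated CDS"
            )
        if not (1 <= causal_cds_offset < gene.cds_length):
            raise ValueError("causal_cds_offset outside CDS")
        g1 = gene.cds_to_genomic(causal_cds_offset)
        g2 = gene.cds_to_genomic(causal_cds_offset + 1)
        if abs(g1 - g2) != 1:
            raise ValueError("causal insertion site spans an exon boundary")
        anchor = min(g1, g2)
        ins_seq = "G" if gene.strand == "+" else "C"
        causal = TruthVariant(anchor, "", ins_seq, "ins", causal=True)
        reserved = [anchor]

    # candidate positions: single-copy, away from edges, causal and each other
    blocked = np.zeros(ref.end + 2, dtype=bool)
    blocked[: ref.start + 5] = True
    blocked[ref.end - 4 :] = True
    if repeats is not None:
        for s, e in repeats.intervals:
            blocked[s : e + 1] = True
    for p in reserved:
        blocked[max(0, p - 5) : p + 6] = True

    neutral: List[TruthVariant] = []
    candidates = np.flatnonzero(~blocked)
    rng.shuffle(candidates)
    ci = 0
    while len(neutral) < n_neutral:
        if ci >= len(candidates):
            raise RuntimeError("not enough single-copy space for the requested neutral variants")
        p = int(candidates[ci])
        ci += 1
        if blocked[p]:
            continue
        blocked[max(0, p - 5) : p + 6] = True
        r = rng.random()
        refb = ref.base(p)
        if r < snv_fraction:
            alt = rng.choice([b for b in "ACGT" if b != refb])
            neutral.append(TruthVariant(p, refb, str(alt), "snv"))
        elif r < snv_fraction + ins_fraction:
            neutral.append(TruthVariant(p, "", str(rng.choice(list("ACGT"))), "ins"))
        else:
            neutral.append(TruthVariant(p, refb, "", "del"))
    neutral.sort(key=lambda v: v.pos)

    ancestral = tuple(neutral)
    mutant = tuple(sorted(neutral + ([causal] if causal else []), key=lambda v: v.pos))
    return {
        case_id: HaplotypeTruth(case_id, mutant, mutant, "case"),
        control_id: HaplotypeTruth(control_id, mutant, ancestral, "carrier_control"),
    }


def simulate_capture_reads(
    truth: HaplotypeTruth,
    ref: ReferenceInterval,
    mean_cov: float,
    gap_fraction: float,
    read_len: int,
    err_rate: float,
    dup_region: Optional[Tuple[int, int]] = None,
    seed: int = 0,
    window: int = 1000,
    depth_sigma: float = 0.3,
    dup_divergence: float = 0.01,
    ensure_covered: Sequence[int] = (),
) -> ReadSet:
    """Capture reads: per-window lognormal depth, capture gaps, base errors.

    Reads are drawn from the two haplotypes with equal probability. Each 1 kb
    window gets a lognormal depth multiplier (unit mean); a ``gap_fraction``
    of windows receives no reads at all, emulating capture dropout. Windows
    containing positions in ``ensure_covered`` are never gapped. When
    ``dup_region`` is set, extra reads from a diverged copy of that segment
    are added, emulating mis-mapped reads from a segmental duplication that
    produce clusters of false ~50% allele fractions.
    """
    if mean_cov <= 0:
        raise ValueError("mean_cov must be positive")
    if read_len < 20:
        raise ValueError("read_len must be >= 20")
    if not (0.0 <= gap_fraction <= 1.0) or not (0.0 <= err_rate <= 1.0):
        raise ValueError("gap_fraction and err_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    haps = [Haplotype(ref, truth.hap_a), Haplotype(ref, truth.hap_b)]

    L = ref.length
    n_win = (L + window - 1) // window
    mult = rng.lognormal(mean=-(depth_sigma**2) / 2.0, sigma=depth_sigma, size=n_win)
    gap = rng.random(n_win) < gap_fraction
    for p in ensure_covered:
        gap[(p - ref.start) // window] = False
    mult[gap] = 0.0
    win_start = ref.start + np.arange(n_win) * window
    win_len = np.minimum(window, ref.end - win_start + 1)

    all_idx: List[np.ndarray] = []
    all_start: List[np.ndarray] = []
    for hi, hap in enumerate(haps):
        lam = win_len * mean_cov * mult / (2.0 * read_len)
        n_per_win = rng.poisson(lam)
        starts_ref = np.repeat(win_start, n_per_win) + rng.integers(
            0, np.repeat(win_len, n_per_win)
        )
        hs = hap.ref2hap[starts_ref]
        deleted = hs < 0
        if deleted.any():  # start fell on a base deleted in this haplotype
            hs[deleted] = hap.ref2hap[starts_ref[deleted] + 1]
        ok = (hs >= 0) & (hs <= len(hap) - read_len)
        all_idx.append(np.full(int(ok.sum()), hi, dtype=np.int64))
        all_start.append(hs[ok])

    if dup_region is not None:
        s, e = dup_region
        if not (ref.start <= s <= e <= ref.end):
            raise ValueError("dup_region outside reference")
        dcodes = ref.codes()[s - ref.start : e - ref.start + 1].copy()
        nsub = rng.binomial(len(dcodes), dup_divergence)
        subs = rng.choice(len(dcodes), size=nsub, replace=False)
        dcodes[subs] = (dcodes[subs] + rng.integers(1, 4, size=nsub)) % 4
        dup = Haplotype.__new__(Haplotype)
        dup.codes = dcodes
        dup.ref_pos = np.arange(s, e + 1, dtype=np.int64)
        dup.is_ins = np.zeros(len(dcodes), dtype=bool)
        dup.del_after = {}
        dup.ins_seq = {}
        dup.ref2hap = np.full(ref.end + 2, -1, dtype=np.int64)
        dup.ref2hap[s : e + 1] = np.arange(len(dcodes))
        haps.append(dup)
        n_dup = rng.poisson(len(dcodes) * mean_cov / read_len)
        ds = rng.integers(0, max(1, len(dcodes) - read_len + 1), size=n_dup)
        all_idx.append(np.full(n_dup, 2, dtype=np.int64))
        all_start.append(ds.astype(np.int64))

    hap_idx = np.concatenate(all_idx) if all_idx else np.zeros(0, np.int64)
    hap_start = np.concatenate(all_start) if all_start else np.zeros(0, np.int64)

    codes = np.zeros((len(hap_idx), read_len), dtype=np.uint8)
    offs = np.arange(read_len)
    for hi, hap in enumerate(haps):
        rows = hap_idx == hi
        if rows.any():
            codes[rows] = hap.codes[hap_start[rows, None] + offs]
    if err_rate > 0 and len(codes):
        em = rng.random(codes.shape) < err_rate
        ne = int(em.sum())
        if ne:
            codes[em] = (codes[em] + rng.integers(1, 4, size=ne).astype(np.uint8)) % 4

    return ReadSet(
        sample_id=truth.animal_id,
        read_len=read_len,
        err_rate=err_rate,
        haplotypes=tuple(haps),
        hap_idx=hap_idx,
        hap_start=hap_start,
        codes=codes,
        ref=ref,
    )


# ---------------------------------------------------------------------------
# cohort + Sanger oracle

GT_WT = "wt/wt"
GT_HET = "wt/ins"
GT_HOM = "ins/ins"

GROUP_AFFECTED = "affected"
GROUP_CARRIER = "carrier"
GROUP_UNRELATED = "unrelated"
GROUP_OTHER = "other_breed"


def simulate_cohort_genotypes(
    causal: Optional[TruthVariant],
    n_affected: int,
    n_carriers: int,
    n_unrelated: int,
    carrier_rate: float,
    n_other_breeds: int,
    n_phenocopies: int,
    seed: int,
) -> pd.DataFrame:
    """Cohort truth table for the candidate-site association screen.

    Affected calves are homozygous mutant; obligate-carrier parents are
    heterozygous except ``n_phenocopies`` of them, which are wild type and
    flagged as having only an unconfirmed affected-offspring record (the
    phenocopy scenario). Unrelated within-breed animals are carriers with
    probability ``carrier_rate``; other-breed controls are wild type.
    """
    for name, v in [
        ("n_affected", n_affected),
        ("n_carriers", n_carriers),
        ("n_unrelated", n_unrelated),
        ("n_other_breeds", n_other_breeds),
        ("n_phenocopies", n_phenocopies),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if n_phenocopies > n_carriers:
        raise ValueError("n_phenocopies cannot exceed n_carriers")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_affected):
        rows.append((f"aff{i + 1}", GROUP_AFFECTED, GT_HOM, "confirmed_affected"))
    for i in range(n_carriers):
        if i < n_phenocopies:
            rows.append((f"car{i + 1}", GROUP_CARRIER, GT_WT, "unconfirmed_offspring"))
        else:
            rows.append((f"car{i + 1}", GROUP_CARRIER, GT_HET, "confirmed_offspring"))
    het = rng.random(n_unrelated) < carrier_rate
    for i in range(n_unrelated):
        rows.append((f"unr{i + 1}", GROUP_UNRELATED, GT_HET if het[i] else GT_WT, "healthy"))
    for i in range(n_other_breeds):
        rows.append((f"oth{i + 1}", GROUP_OTHER, GT_WT, "healthy"))
    return pd.DataFrame(rows, columns=["animal_id", "group", "genotype", "phenotype_record"])


def table2_cohort() -> pd.DataFrame:
    """The printed association-screen cohort: 16 affected homozygotes, 34 het
    + 2 wild-type (unconfirmed-record) carriers, 299+10 unrelated within-breed
    animals, 75 other-breed controls. Deterministic."""
    df = simulate_cohort_genotypes(None, 16, 36, 309, 0.0, 75, 2, seed=0)
    df.loc[df.index[df.group == GROUP_UNRELATED][:10], "genotype"] = GT_HET
    return df


def sanger_oracle(truth: HaplotypeTruth, pos: int, ref: Optional[ReferenceInterval] = None) -> str:
    """Error-free re-genotyping of one position from the truth haplotypes.

    Stands in for validation by PCR + capillary sequencing. Returns one of
    ``hom_ref``, ``het``, ``hom_var``.
    """
    if pos < 1 or (ref is not None and not (ref.start <= pos <= ref.end)):
        raise ValueError(f"position {pos} outside the reference interval")

    def allele(hap: Tuple[TruthVariant, ...]) -> Tuple[str, str]:
        for v in hap:
            if v.pos == pos:
                return (v.ref_allele, v.alt_allele)
        return ("", "")  # reference allele sentinel

    a, b = allele(truth.hap_a), allele(truth.hap_b)
    ref_sent = ("", "")
    if a == ref_sent and b == ref_sent:
        return "hom_ref"
    if a == b:
        return "hom_var"
    return "het"


def make_oracle(truth: HaplotypeTruth, ref: Optional[ReferenceInterval] = None) -> Callable[[int], str]:
    return lambda pos: sanger_oracle(truth, pos, ref)


# ---------------------------------------------------------------------------
# printed-table fixture (exclusion-cascade structure)


@dataclass
class Table1Fixture:
    case_calls: list
    control_pileup: object
    annotations: Dict[int, Tuple[str, str]]
    oracle: Callable[[int], str]
    het_candidate_positions: List[int]
    true_het_position: int


def table1_fixture():
    """A call-level fixture with the printed coding-block structure.

    79 case coding homozygous variants; in the control, 63 are homozygous at
    >=4x, 5 homozygous-supported at 1-3x, 8 uncovered, and 3 heterozygous at
    10-, 12- and 27-fold under the relaxed coding rule. The truth oracle marks
    all but one (the 27-fold site) homozygous mutant.
    """
    from .variant_caller import Pileup, PileupColumn, SiteCall

    positions = [1000 + 100 * i for i in range(79)]
    case_calls = [
        SiteCall(pos=p, ref_allele="A", alt_allele="T", genotype="hom_var", variant_freq=100.0, depth=30)
        for p in positions
    ]
    cols = []
    for i, p in enumerate(positions):
        if i < 63:
            cols.append(PileupColumn(pos=p, ref_allele="A", allele_counts={"T": 20}))
        elif i < 68:
            cols.append(PileupColumn(pos=p, ref_allele="A", allele_counts={"T": 2}))
        elif i < 76:
            pass  # no coverage in the control
        else:
            depth, alt = [(10, 5), (12, 6), (27, 13)][i - 76]
            cols.append(PileupColumn(pos=p, ref_allele="A", allele_counts={"A": depth - alt, "T": alt}))
    control_pileup = Pileup.from_columns(cols, length=positions[-1] + 100, ref_codes=None)
    annotations = {p: ("cds", "geneX") for p in positions}
    het_positions = positions[76:]
    true_het = positions[78]  # the 27-fold site is the real heterozygote

    def oracle(pos: int) -> str:
        return "het" if pos == true_het else "hom_var"

    return Table1Fixture(case_calls, control_pileup, annotations, oracle, het_positions, true_het)
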