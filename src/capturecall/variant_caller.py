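"""Pileup construction and raw-count threshold genotype calling.

The caller uses nothing but per-position allele counts: a homozygous variant
needs >=4-fold coverage with the variant allele at >=75% frequency; a
heterozygous variant needs >=15-fold coverage (>=10 in the relaxed coding
mode) with the variant allele strictly between 25% and 75%. Variant-bearing
sites at 1-3x are flagged low-coverage rather than called, and calls within
10 nt of masked repeats are excluded. No base qualities, mapping qualities or
realignment — raw counts only.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .synthetic_data import (
    ReadSet,
    ReferenceInterval,
    RepeatAnnotation,
    decode_seq,
    encode_seq,
)

DEL_ALLELE = "*"

GENOTYPES = ("hom_var", "het", "hom_ref", "low_cov_var", "no_call")


@dataclass
class PileupColumn:
    """Per-position allele support. Keys are bases, '*' for a deletion of this
    base, or '+SEQ' for an insertion anchored here (read shows base+SEQ)."""

    pos: int
    ref_allele: str
    allele_counts: Dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.allele_counts.values())


@dataclass
class SiteCall:
    """A genotype decision at one position.

    ``ref_allele``/``alt_allele`` follow the truth-variant convention: empty
    ref for insertions (anchored at pos), empty alt for deletions.
    """

    pos: int
    ref_allele: str
    alt_allele: Optional[str]
    genotype: str
    variant_freq: float
    depth: int

    def key(self) -> Tuple[int, str, str]:
        return (self.pos, self.ref_allele, self.alt_allele or "")


class Pileup:
    """Allele counts over a reference interval, array-backed.

    Base support lives in a dense (L+2, 4) matrix indexed by 1-based position;
    insertion and deletion events are sparse dictionaries. ``column(pos)``
    materialises a PileupColumn.
    """

    def __init__(
        self,
        length: int,
        ref_codes: Optional[np.ndarray],
        start: int = 1,
    ) -> None:
        self.start = start
        self.end = start + length - 1
        self.length = length
        self.ref_codes = ref_codes  # aligned to start..end, or None
        self.base_counts = np.zeros((start + length + 1, 4), dtype=np.int64)
        self.ins_counts: Dict[int, Dict[str, int]] = {}
        self.del_counts: Dict[int, int] = {}
        self._ref_base_override: Dict[int, str] = {}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_columns(
        cls,
        columns: Iterable[PileupColumn],
        length: int,
        ref_codes: Optional[np.ndarray] = None,
        start: int = 1,
    ) -> "Pileup":
        p = cls(length, ref_codes, start)
        code = {b: i for i, b in enumerate("ACGT")}
        for col in columns:
            p._ref_base_override[col.pos] = col.ref_allele
            for allele, n in col.allele_counts.items():
                if allele == DEL_ALLELE:
                    p.del_counts[col.pos] = p.del_counts.get(col.pos, 0) + n
                elif allele.startswith("+"):
                    p.ins_counts.setdefault(col.pos, {})[allele[1:]] = n
                else:
                    p.base_counts[col.pos, code[allele]] += n
        return p

    # -- access -------------------------------------------------------------

    def ref_base(self, pos: int) -> str:
        if pos in self._ref_base_override:
            return self._ref_base_override[pos]
        if self.ref_codes is None:
            return "N"
        return "ACGT"[self.ref_codes[pos - self.start]]

    def depth(self, pos: int) -> int:
        if not (self.start <= pos <= self.end):
            return 0
        d = int(self.base_counts[pos].sum())
        d += sum(self.ins_counts.get(pos, {}).values())
        d += self.del_counts.get(pos, 0)
        return d

    def column(self, pos: int) -> PileupColumn:
        counts: Dict[str, int] = {}
        if self.start <= pos <= self.end:
            for i in range(4):
                c = int(self.base_counts[pos, i])
                if c:
                    counts["ACGT"[i]] = c
            for seq, c in self.ins_counts.get(pos, {}).items():
                counts["+" + seq] = c
            if pos in self.del_counts:
                counts[DEL_ALLELE] = self.del_counts[pos]
        return PileupColumn(pos=pos, ref_allele=self.ref_base(pos), allele_counts=counts)

    def variant_positions(self) -> List[int]:
        """Positions with any non-reference allele support."""
        pos = set(self.ins_counts) | set(self.del_counts)
        if self.ref_codes is not None:
            tot = self.base_counts.sum(axis=1)
            idx = np.arange(self.start, self.end + 1)
            refc = self.base_counts[idx, self.ref_codes]
            pos.update(idx[tot[idx] > refc].tolist())
        else:
            nz = np.flatnonzero(self.base_counts.sum(axis=1))
            for p in nz:
                col = self.column(int(p))
                if any(a != col.ref_allele for a in col.allele_counts):
                    pos.add(int(p))
        return sorted(pos)

    def columns(self) -> Iterator[PileupColumn]:
        tot = self.base_counts.sum(axis=1)
        covered = set(np.flatnonzero(tot).tolist()) | set(self.ins_counts) | set(self.del_counts)
        for p in sorted(covered):
            yield self.column(int(p))


def build_pileup(
    reads: ReadSet,
    ref: ReferenceInterval,
    cap: int = 200,
    seed: int = 0,
) -> Pileup:
    """Project truth-placed reads into per-position allele counts.

    A read covering an insertion anchor *and* at least one inserted base
    counts once as insertion support at the anchor (not additionally for the
    anchor base); a read spanning a deleted reference base counts as a
    deletion observation there. Columns whose raw depth exceeds ``cap`` are
    deterministically subsampled to ``cap`` reads with a position-seeded
    hypergeometric draw.
    """
    if cap < 1:
        raise ValueError("cap must be positive")
    pileup = Pileup(ref.length, ref.codes(), start=ref.start)
    if reads.n_reads == 0:
        return pileup
    rl = reads.read_len
    offs = np.arange(rl)
    nbins = (ref.end + 2) * 4
    for hi, hap in enumerate(reads.haplotypes):
        rows = reads.hap_idx == hi
        if not rows.any():
            continue
        starts = reads.hap_start[rows]
        codes = reads.codes[rows]
        pos_mat = starts[:, None] + offs
        refpos = hap.ref_pos[pos_mat]
        isins = hap.is_ins[pos_mat]

        # first inserted base of a run, with the anchor inside the read
        first_ins = isins.copy()
        first_ins[:, 0] = False
        first_ins[:, 1:] &= ~isins[:, :-1]
        anchor_consumed = np.zeros_like(isins)
        anchor_consumed[:, :-1] = first_ins[:, 1:]

        keep = ~isins & ~anchor_consumed
        flat = refpos[keep] * 4 + codes[keep]
        pileup.base_counts += np.bincount(flat, minlength=nbins).reshape(-1, 4)

        anchors, counts = np.unique(refpos[first_ins], return_counts=True)
        for a, c in zip(anchors.tolist(), counts.tolist()):
            seq = hap.ins_seq[a]
            d = pileup.ins_counts.setdefault(a, {})
            d[seq] = d.get(seq, 0) + int(c)

        if hap.del_after:
            sorted_starts = np.sort(starts)
            for hidx, dpos in hap.del_after.items():
                lo = np.searchsorted(sorted_starts, hidx - rl + 2, side="left")
                hi_ = np.searchsorted(sorted_starts, hidx, side="right")
                c = int(hi_ - lo)
                if c:
                    pileup.del_counts[dpos] = pileup.del_counts.get(dpos, 0) + c

    _apply_coverage_cap(pileup, cap, seed)
    return pileup


def _apply_coverage_cap(pileup: Pileup, cap: int, seed: int) -> None:
    tot = pileup.base_counts.sum(axis=1)
    sparse_extra = set(pileup.ins_counts) | set(pileup.del_counts)
    over = set(np.flatnonzero(tot > cap).tolist())
    for p in sparse_extra:
        if pileup.depth(p) > cap:
            over.add(p)
    for p in sorted(over):
        p = int(p)
        labels: List[str] = []
        counts: List[int] = []
        for i in range(4):
            c = int(pileup.base_counts[p, i])
            if c:
                labels.append("ACGT"[i])
                counts.append(c)
        for seq, c in sorted(pileup.ins_counts.get(p, {}).items()):
            labels.append("+" + seq)
            counts.append(c)
        if p in pileup.del_counts:
            labels.append(DEL_ALLELE)
            counts.append(pileup.del_counts[p])
        total = sum(counts)
        if total <= cap:
            continue
        rng = np.random.default_rng([seed, p])
        sub = rng.multivariate_hypergeometric(counts, cap)
        pileup.base_counts[p] = 0
        pileup.ins_counts.pop(p, None)
        pileup.del_counts.pop(p, None)
        for lab, c in zip(labels, sub.tolist()):
            if c == 0:
                continue
            if lab == DEL_ALLELE:
                pileup.del_counts[p] = c
            elif lab.startswith("+"):
                pileup.ins_counts.setdefault(p, {})[lab[1:]] = c
            else:
                pileup.base_counts[p, "ACGT".index(lab)] = c


# ---------------------------------------------------------------------------
# genotype calling


def _normalise_allele(col: PileupColumn, allele_key: str) -> Tuple[str, str]:
    """Pileup allele key -> (ref_allele, alt_allele) in variant convention."""
    if allele_key == DEL_ALLELE:
        return (col.ref_allele, "")
    if allele_key.startswith("+"):
        return ("", allele_key[1:])
    return (col.ref_allele, allele_key)


def call_genotype(
    col: PileupColumn,
    hom_min_cov: int = 4,
    hom_min_freq: float = 75.0,
    het_min_cov: int = 15,
    het_low: float = 25.0,
    het_high: float = 75.0,
) -> SiteCall:
    """Threshold genotype decision from one pileup column.

    Decision order: no coverage -> no_call; variant frequency >= 75% at
    >=4-fold -> hom_var; strictly 25-75% at >=het_min_cov -> het; variant seen
    at 1-3-fold -> low_cov_var; else hom_ref when the variant frequency is
    at or below 25% at >=4-fold, otherwise no_call (the uncertain 4-14-fold
    mid-frequency zone, left for validation). The variant allele is the most
    frequent non-reference allele, ties broken lexicographically.
    """
    for name, v in [("hom_min_freq", hom_min_freq), ("het_low", het_low), ("het_high", het_high)]:
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name} must be in [0, 100]")
    if hom_min_cov < 1 or het_min_cov < 1:
        raise ValueError("coverage thresholds must be positive")

    depth = col.depth
    if depth == 0:
        return SiteCall(col.pos, col.ref_allele, None, "no_call", 0.0, 0)
    alt_items = [(k, c) for k, c in col.allele_counts.items() if k != col.ref_allele]
    if not alt_items:
        gt = "hom_ref" if depth >= hom_min_cov else "no_call"
        return SiteCall(col.pos, col.ref_allele, None, gt, 0.0, depth)
    alt_key, alt_count = max(alt_items, key=lambda kc: (kc[1], _rev(kc[0])))
    freq = 100.0 * alt_count / depth
    ref_a, alt_a = _normalise_allele(col, alt_key)
    if freq >= hom_min_freq and depth >= hom_min_cov:
        gt = "hom_var"
    elif het_low < freq < het_high and depth >= het_min_cov:
        gt = "het"
    elif 1 <= depth <= 3:
        gt = "low_cov_var"
    elif freq <= het_low and depth >= hom_min_cov:
        # the het bounds are strict: exactly 25% at adequate depth is hom_ref
        gt = "hom_ref"
    else:
        gt = "no_call"
    return SiteCall(col.pos, ref_a, alt_a, gt, freq, depth)


def _rev(key: str) -> Tuple[int, ...]:
    # lexicographic tie-break: prefer the lexicographically smaller allele key
    return tuple(-ord(c) for c in key)


def call_variants(
    pileup: Pileup,
    hom_min_cov: int = 4,
    hom_min_freq: float = 75.0,
    het_min_cov: int = 15,
    het_low: float = 25.0,
    het_high: float = 75.0,
    include_uncertain: bool = False,
) -> List[SiteCall]:
    """Scan every position with non-reference support and keep variant calls
    (hom_var / het / low_cov_var). With ``include_uncertain``, mid-frequency
    no_call sites are also returned, flagged for validation."""
    out: List[SiteCall] = []
    for pos in pileup.variant_positions():
        call = call_genotype(
            pileup.column(pos), hom_min_cov, hom_min_freq, het_min_cov, het_low, het_high
        )
        if call.genotype in ("hom_var", "het", "low_cov_var"):
            out.append(call)
        elif include_uncertain and call.genotype == "no_call" and call.alt_allele is not None:
            out.append(call)
    return out


# ---------------------------------------------------------------------------
# repeat-adjacency filter


def filter_repeat_adjacent(
    calls: Sequence[SiteCall],
    repeats: RepeatAnnotation,
    margin: int = 10,
) -> Tuple[List[SiteCall], List[SiteCall]]:
    """Partition calls by distance to masked repeats.

    A call is excluded when it lies within ``margin`` nt of a masked interval
    (boundary distance exactly ``margin`` is excluded); positions inside a
    mask are excluded as well.
    """
    ivs = repeats.intervals
    starts = [s for s, _ in ivs]
    kept: List[SiteCall] = []
    excluded: List[SiteCall] = []
    for call in calls:
        p = call.pos
        bad = False
        i = bisect.bisect_right(starts, p + margin)
        if i > 0:
            s, e = ivs[i - 1]
            if p <= e + margin:
                bad = True
        if not bad and i < len(ivs) and ivs[i][0] - margin <= p:
            bad = True
        (excluded if bad else kept).append(call)
    return kept, excluded


# ---------------------------------------------------------------------------
# classification + summary

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def classify_variant(ref_allele: str, alt_allele: str) -> str:
    """snv_transition / snv_transversion / insertion / deletion."""
    if ref_allele == alt_allele:
        raise ValueError("ref and alt alleles are identical")
    if len(alt_allele) > len(ref_allele):
        return "insertion"
    if len(alt_allele) < len(ref_allele):
        return "deletion"
    if len(ref_allele) != 1:
        raise ValueError("multi-base substitutions are not supported")
    both = {ref_allele, alt_allele}
    if both <= _PURINES or both <= _PYRIMIDINES:
        return "snv_transition"
    return "snv_transversion"


@dataclass
class VariantSummary:
    """Per-sample and shared variant category counts (printed-table layout)."""

    case: Dict[str, int]
    control: Dict[str, int]
    shared: Dict[str, int]

    CATEGORIES = (
        "total",
        "snps",
        "transitions",
        "transversions",
        "indels",
        "insertions",
        "deletions",
        "homozygous",
        "heterozygous",
    )

    def check_invariants(self) -> None:
        for d in (self.case, self.control, self.shared):
            assert d["snps"] == d["transitions"] + d["transversions"]
            assert d["indels"] == d["insertions"] + d["deletions"]
            assert d["total"] == d["snps"] + d["indels"]
            assert d["total"] == d["homozygous"] + d["heterozygous"]


def _count_calls(calls: Sequence[SiteCall]) -> Dict[str, int]:
    d = {k: 0 for k in VariantSummary.CATEGORIES}
    for c in calls:
        if c.genotype not in ("hom_var", "het") or c.alt_allele is None:
            continue
        cls = classify_variant(c.ref_allele, c.alt_allele)
        d["total"] += 1
        if cls.startswith("snv"):
            d["snps"] += 1
            d["transitions" if cls == "snv_transition" else "transversions"] += 1
        else:
            d["indels"] += 1
            d["insertions" if cls == "insertion" else "deletions"] += 1
        d["homozygous" if c.genotype == "hom_var" else "heterozygous"] += 1
    return d


def summarize_variants(
    case_calls: Sequence[SiteCall],
    control_calls: Sequence[SiteCall],
) -> VariantSummary:
    """Category counts per sample plus the shared column (same position, same
    alternative allele, both samples carrying the variant)."""
    case_keys = {c.key(): c for c in case_calls if c.genotype in ("hom_var", "het")}
    ctrl_keys = {c.key(): c for c in control_calls if c.genotype in ("hom_var", "het")}
    shared_calls = [case_keys[k] for k in case_keys.keys() & ctrl_keys.keys()]
    summary = VariantSummary(
        case=_count_calls(case_calls),
        control=_count_calls(control_calls),
        shared=_count_calls(shared_calls),
    )
    summary.check_invariants()
    return summary
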