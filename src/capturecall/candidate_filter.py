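"""Case-control exclusion cascade for recessive candidate variants.

Starting from the affected sample's homozygous coding/splice calls, each
site is routed by the IBD carrier control's status: identical homozygous
genotype excludes it; missing or thin control coverage, a heterozygous call
under the relaxed coding rule (>=10-fold instead of the genome-wide
>=15-fold), or a contradictory state send it to Sanger-style validation.
Final candidates are the validated sites that are homozygous in the case and
truly heterozygous in the obligate-carrier control — under the IBD design,
exactly the causative mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .variant_caller import Pileup, SiteCall, call_genotype

ROUTE_SHARED = "excluded_shared_hom"
ROUTE_MISSING = "control_missing_cov"
ROUTE_LOW_COV = "control_low_cov"
ROUTE_HET = "control_het_candidates"
ROUTE_OTHER = "control_other"
ROUTES = (ROUTE_SHARED, ROUTE_MISSING, ROUTE_LOW_COV, ROUTE_HET, ROUTE_OTHER)


@dataclass
class LedgerEntry:
    call: SiteCall  # the case call
    region: str
    gene_id: Optional[str]
    route: str
    control_depth: int
    control_genotype: str
    control_freq: float
    sanger: Optional[str] = None  # filled by validation


@dataclass
class CandidateLedger:
    """Bookkeeping of the exclusion cascade; entries partition the case's
    coding homozygous calls by route at every stage."""

    entries: List[LedgerEntry] = field(default_factory=list)
    validated: bool = False
    final_candidates: List[LedgerEntry] = field(default_factory=list)

    @property
    def case_coding_hom(self) -> List[LedgerEntry]:
        return list(self.entries)

    def by_route(self, route: str) -> List[LedgerEntry]:
        return [e for e in self.entries if e.route == route]

    @property
    def excluded_shared_hom(self) -> List[LedgerEntry]:
        return self.by_route(ROUTE_SHARED)

    @property
    def control_missing_cov(self) -> List[LedgerEntry]:
        return self.by_route(ROUTE_MISSING)

    @property
    def control_low_cov(self) -> List[LedgerEntry]:
        return self.by_route(ROUTE_LOW_COV)

    @property
    def control_het_candidates(self) -> List[LedgerEntry]:
        return self.by_route(ROUTE_HET)

    @property
    def control_other(self) -> List[LedgerEntry]:
        return self.by_route(ROUTE_OTHER)

    @property
    def sanger_confirmed_het(self) -> List[LedgerEntry]:
        return [e for e in self.entries if e.sanger == "het"]

    def check_partition(self) -> None:
        assert sum(len(self.by_route(r)) for r in ROUTES) == len(self.entries)
        assert all(e in self.sanger_confirmed_het for e in self.final_candidates)

    def counts(self) -> Dict[str, int]:
        """The printed-table numbers. ``shared_hom_excluded`` counts sites with
        an identical homozygous-supported control genotype at any depth (the
        >=4-fold homozygous calls plus the 1-3-fold supported ones)."""
        return {
            "case_coding_hom": len(self.entries),
            "shared_hom_excluded": len(self.excluded_shared_hom) + len(self.control_low_cov),
            "control_missing_cov": len(self.control_missing_cov),
            "control_low_cov": len(self.control_low_cov),
            "control_het_candidates": len(self.control_het_candidates),
            "control_other": len(self.control_other),
            "sanger_confirmed_het": len(self.sanger_confirmed_het),
            "final_candidates": len(self.final_candidates),
        }

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "pos": e.call.pos,
                    "ref": e.call.ref_allele,
                    "alt": e.call.alt_allele,
                    "region": e.region,
                    "gene_id": e.gene_id,
                    "case_depth": e.call.depth,
                    "case_freq": round(e.call.variant_freq, 1),
                    "control_depth": e.control_depth,
                    "control_genotype": e.control_genotype,
                    "control_freq": round(e.control_freq, 1),
                    "route": e.route,
                    "sanger": e.sanger or "",
                    "final_candidate": any(e is f for f in self.final_candidates),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "pos", "ref", "alt", "region", "gene_id", "case_depth", "case_freq",
                "control_depth", "control_genotype", "control_freq", "route",
                "sanger", "final_candidate",
            ],
        )


def build_coding_ledger(
    case_calls: Sequence[SiteCall],
    control_pileup: Pileup,
    annotations: Mapping[int, Tuple[str, Optional[str]]],
    hom_min_cov: int = 4,
    hom_min_freq: float = 75.0,
    relaxed_het_min_cov: int = 10,
    het_low: float = 25.0,
    het_high: float = 75.0,
) -> CandidateLedger:
    """Route every case homozygous coding/splice call by its control status.

    ``annotations`` maps position -> (region, gene_id); every case call must
    be annotated. The control genotype is re-derived from the control pileup:
    strict thresholds decide shared homozygosity, the relaxed >=10-fold rule
    decides heterozygous candidacy.
    """
    ledger = CandidateLedger()
    for call in case_calls:
        if call.genotype != "hom_var":
            continue
        if call.pos not in annotations:
            raise KeyError(f"case call at {call.pos} is unannotated")
        region, gene_id = annotations[call.pos]
        if region not in ("cds", "splice_site"):
            continue
        col = control_pileup.column(call.pos)
        depth = col.depth
        strict = call_genotype(col, hom_min_cov, hom_min_freq, 15, het_low, het_high)
        relaxed = call_genotype(col, hom_min_cov, hom_min_freq, relaxed_het_min_cov, het_low, het_high)
        same_alt = strict.alt_allele == call.alt_allele

        if depth == 0:
            route = ROUTE_MISSING
        elif strict.genotype == "hom_var" and same_alt:
            route = ROUTE_SHARED
        elif 1 <= depth <= 3 and strict.genotype == "low_cov_var" and same_alt:
            route = ROUTE_LOW_COV
        elif relaxed.genotype == "het" and relaxed.alt_allele == call.alt_allele:
            route = ROUTE_HET
        else:
            # control hom_ref or uncertain at a case-hom site: contradicts the
            # IBD expectation, goes to validation
            route = ROUTE_OTHER
        ledger.entries.append(
            LedgerEntry(
                call=call,
                region=region,
                gene_id=gene_id,
                route=route,
                control_depth=depth,
                control_genotype=strict.genotype,
                control_freq=relaxed.variant_freq,
            )
        )
    ledger.check_partition()
    return ledger


def sanger_validate(ledger: CandidateLedger, oracle: Callable[[int], str]) -> CandidateLedger:
    """Re-genotype every non-excluded route with the error-free oracle.

    Sites the oracle calls homozygous mutant move to the shared-homozygous
    exclusion route; true heterozygotes are recorded as confirmed.
    """
    for e in ledger.entries:
        if e.route == ROUTE_SHARED:
            continue
        g = oracle(e.call.pos)
        e.sanger = g
        if g == "hom_var":
            e.route = ROUTE_SHARED
    ledger.validated = True
    ledger.check_partition()
    return ledger


def select_causal_candidates(ledger: CandidateLedger) -> List[LedgerEntry]:
    """Validated sites homozygous in the case and truly heterozygous in the
    IBD carrier control. An empty list is the 'no candidate' outcome."""
    if not ledger.validated:
        raise ValueError("ledger must be Sanger-validated before candidate selection")
    ledger.final_candidates = [
        e for e in ledger.entries if e.sanger == "het" and e.call.genotype == "hom_var"
    ]
    ledger.check_partition()
    return ledger.final_candidates
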