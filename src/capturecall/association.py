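"""Phenotype-genotype association at the candidate site.

Builds the group x genotype count table, tests *perfect* association (exact
concordance between genotype classes and phenotype classes, with the
documented phenocopy allowance for obligate carriers whose only affected
offspring were never confirmed), and computes the mutant allele frequency.
The claim being checked is exact concordance, so the verdict is boolean;
no chi-square or exact test is computed and no p-value is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .synthetic_data import (
    GROUP_AFFECTED,
    GROUP_CARRIER,
    GROUP_OTHER,
    GROUP_UNRELATED,
    GT_HET,
    GT_HOM,
    GT_WT,
)

GROUPS = (GROUP_AFFECTED, GROUP_CARRIER, GROUP_UNRELATED, GROUP_OTHER)
GENOTYPES = (GT_WT, GT_HET, GT_HOM)


@dataclass
class AssociationTable:
    """Counts by phenotype group and genotype, plus a totals row."""

    table: pd.DataFrame  # index: groups + 'total'; columns: wt/wt, wt/ins, ins/ins

    def row(self, group: str) -> Tuple[int, int, int]:
        r = self.table.loc[group]
        return (int(r[GT_WT]), int(r[GT_HET]), int(r[GT_HOM]))

    def check_invariants(self) -> None:
        body = self.table.drop(index="total")
        assert (body.sum(axis=0) == self.table.loc["total"]).all()


@dataclass
class AssociationVerdict:
    perfect: bool
    discordant_animals: List[Tuple[str, str]]  # (animal_id, reason code)
    allele_freq_pct: float
    carrier_count: int

    def check_invariants(self) -> None:
        only_phenocopy = all(r == "phenocopy_suspect" for _, r in self.discordant_animals)
        assert self.perfect == only_phenocopy


def tabulate_association(cohort: pd.DataFrame) -> AssociationTable:
    """Count animals by group x genotype; every animal counted exactly once."""
    bad_gt = set(cohort["genotype"]) - set(GENOTYPES)
    if bad_gt:
        raise ValueError(f"unknown genotype codes: {sorted(bad_gt)}")
    bad_grp = set(cohort["group"]) - set(GROUPS)
    if bad_grp:
        raise ValueError(f"unknown groups: {sorted(bad_grp)}")
    ct = pd.crosstab(cohort["group"], cohort["genotype"])
    ct = ct.reindex(index=GROUPS, columns=GENOTYPES, fill_value=0).fillna(0).astype(int)
    ct.loc["total"] = ct.sum(axis=0)
    out = AssociationTable(ct)
    out.check_invariants()
    return out


def test_perfect_association(
    table: AssociationTable,
    records: pd.DataFrame,
    obligate_carrier_ids: Iterable[str],
) -> AssociationVerdict:
    """Exact-concordance verdict with phenocopy handling.

    Perfect iff every affected animal is homozygous mutant, no non-affected
    animal is homozygous mutant, and every obligate carrier is heterozygous —
    except carriers whose phenotype record flags only unconfirmed affected
    offspring; a wild-type genotype there marks the offspring as a phenocopy
    suspect and does not break perfection.
    """
    obligate = set(obligate_carrier_ids)
    discordant: List[Tuple[str, str]] = []
    for r in records.itertuples():
        if r.group == GROUP_AFFECTED and r.genotype != GT_HOM:
            discordant.append((r.animal_id, "genotype_discordant"))
        if r.group != GROUP_AFFECTED and r.genotype == GT_HOM:
            discordant.append((r.animal_id, "genotype_discordant"))
        if r.animal_id in obligate and r.genotype != GT_HET:
            if r.genotype == GT_WT and r.phenotype_record == "unconfirmed_offspring":
                discordant.append((r.animal_id, "phenocopy_suspect"))
            else:
                discordant.append((r.animal_id, "genotype_discordant"))
    unrelated = table.row(GROUP_UNRELATED)
    if sum(unrelated) > 0:
        freq = allele_frequency(unrelated)
    else:
        freq = 0.0
    verdict = AssociationVerdict(
        perfect=all(reason == "phenocopy_suspect" for _, reason in discordant),
        discordant_animals=discordant,
        allele_freq_pct=freq,
        carrier_count=unrelated[1],
    )
    verdict.check_invariants()
    return verdict


def allele_frequency(group_counts: Tuple[int, int, int]) -> float:
    """Mutant allele frequency in percent (1 decimal) from (wt/wt, het,
    hom-alt) counts: 100*(het + 2*hom) / (2*N)."""
    n_wt, n_het, n_hom = group_counts
    if min(n_wt, n_het, n_hom) < 0:
        raise ValueError("counts must be non-negative")
    n = n_wt + n_het + n_hom
    if n == 0:
        raise ValueError("empty group")
    return round(100.0 * (n_het + 2 * n_hom) / (2 * n), 1)
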