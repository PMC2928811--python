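"""Caller correctness: enumeration oracle, threshold boundaries, pileup
statistics, repeat-margin behaviour and summary identities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from capturecall import (
    RepeatAnnotation,
    classify_variant,
    filter_repeat_adjacent,
    simulate_capture_reads,
    summarize_variants,
)
from capturecall.variant_caller import (
    Pileup,
    PileupColumn,
    SiteCall,
    build_pileup,
    call_genotype,
    call_variants,
)


def brute_force_genotype(depth: int, alt_count: int, het_min_cov: int = 15) -> str:
    """Independent restatement of the calling rules, written from scratch:
    hom at >=75% frequency and >=4x; het strictly between 25% and 75% at
    >=het_min_cov; variant support at 1-3x is low-coverage; <=25% at >=4x is
    reference; anything else is uncalled."""
    if depth == 0:
        return "no_call"
    freq = 100.0 * alt_count / depth
    if alt_count > 0 and freq >= 75.0 and depth >= 4:
        return "hom_var"
    if alt_count > 0 and 25.0 < freq < 75.0 and depth >= het_min_cov:
        return "het"
    if alt_count > 0 and 1 <= depth <= 3:
        return "low_cov_var"
    if freq <= 25.0 and depth >= 4:
        return "hom_ref"
    return "no_call"


def _col(depth: int, alt: int, pos: int = 100) -> PileupColumn:
    counts = {}
    if depth - alt:
        counts["A"] = depth - alt
    if alt:
        counts["T"] = alt
    return PileupColumn(pos=pos, ref_allele="A", allele_counts=counts)


class TestCallGenotype:
    @pytest.mark.parametrize("het_min_cov", [15, 10])
    def test_exhaustive_against_bruteforce(self, het_min_cov):
        for depth in range(0, 31):
            for alt in range(0, depth + 1):
                call = call_genotype(_col(depth, alt), het_min_cov=het_min_cov)
                expect = brute_force_genotype(depth, alt, het_min_cov)
                assert call.genotype == expect, (depth, alt, call.genotype, expect)

    @pytest.mark.parametrize(
        "depth,alt,expected",
        [
            (4, 3, "hom_var"),  # exactly 75% at exactly 4x
            (20, 10, "het"),
            (14, 7, "no_call"),  # mid-frequency but below the het coverage floor
            (0, 0, "no_call"),
            (20, 5, "hom_ref"),  # exactly 25%: strict het bound
            (3, 3, "low_cov_var"),
        ],
    )
    def test_threshold_boundaries(self, depth, alt, expected):
        assert call_genotype(_col(depth, alt)).genotype == expected

    def test_relaxed_coding_mode(self):
        assert call_genotype(_col(10, 5), het_min_cov=10).genotype == "het"
        assert call_genotype(_col(10, 5), het_min_cov=15).genotype == "no_call"

    def test_most_frequent_alt_with_lexicographic_tie(self):
        col = PileupColumn(pos=1, ref_allele="A", allele_counts={"A": 2, "G": 9, "C": 9})
        call = call_genotype(col)
        assert call.alt_allele == "C"

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            call_genotype(_col(10, 5), hom_min_freq=120)
        with pytest.raises(ValueError):
            call_genotype(_col(10, 5), het_min_cov=0)

    def test_monotone_in_het_cov(self):
        """Raising the het coverage floor never creates additional het calls."""
        for depth in range(0, 31):
            for alt in range(0, depth + 1):
                lo = call_genotype(_col(depth, alt), het_min_cov=10).genotype
                hi = call_genotype(_col(depth, alt), het_min_cov=15).genotype
                if hi == "het":
                    assert lo == "het"


class TestBuildPileup:
    def test_hom_site_pure_alt(self, study, clean_pileups):
        truth = study["case"]
        pileup = clean_pileups["case_calf"]
        snv = next(v for v in truth.hap_a if v.vclass == "snv")
        col = pileup.column(snv.pos)
        assert set(col.allele_counts) == {snv.alt_allele}

    def test_het_site_binomial_fraction(self, study, clean_pileups):
        control = study["control"]
        causal = [v for v in control.hap_a if v.causal][0]
        col = pileup_col = clean_pileups["carrier_cow"].column(causal.pos)
        ins = col.allele_counts.get("+" + causal.alt_allele, 0)
        depth = col.depth
        lo, hi = stats.binom.ppf([0.005, 0.995], depth, 0.5)
        assert lo <= ins <= hi

    def test_coverage_cap(self, study):
        ref = study["ref"]
        reads = simulate_capture_reads(study["case"], ref, 60, 0.0, 76, 0.0, seed=4)
        pileup = build_pileup(reads, ref, cap=50)
        depths = pileup.base_counts.sum(axis=1)[1:]
        assert depths.max() <= 50

    def test_cap_is_deterministic(self, study):
        ref = study["ref"]
        reads = simulate_capture_reads(study["case"], ref, 60, 0.0, 76, 0.0, seed=4)
        a = build_pileup(reads, ref, cap=50, seed=1)
        b = build_pileup(reads, ref, cap=50, seed=1)
        assert np.array_equal(a.base_counts, b.base_counts)

    def test_from_columns_roundtrip(self):
        cols = [
            PileupColumn(pos=10, ref_allele="A", allele_counts={"A": 3, "T": 4, "+GG": 2, "*": 1}),
        ]
        p = Pileup.from_columns(cols, length=100)
        col = p.column(10)
        assert col.allele_counts == cols[0].allele_counts
        assert p.depth(10) == 10


class TestRepeatAdjacency:
    def test_boundary_at_exactly_ten(self):
        repeats = RepeatAnnotation([(100, 200)])
        calls = [
            SiteCall(pos, "A", "T", "hom_var", 100.0, 20)
            for pos in (89, 90, 150, 205, 210, 211)
        ]
        kept, excluded = filter_repeat_adjacent(calls, repeats, margin=10)
        assert [c.pos for c in excluded] == [90, 150, 205, 210]
        assert [c.pos for c in kept] == [89, 211]

    def test_no_repeats_keeps_all(self):
        calls = [SiteCall(5, "A", "T", "het", 50.0, 20)]
        kept, excluded = filter_repeat_adjacent(calls, RepeatAnnotation([]))
        assert kept == calls and excluded == []

    @given(st.integers(1, 400))
    def test_partition_matches_distance_oracle(self, pos):
        repeats = RepeatAnnotation([(50, 80), (200, 260)])
        call = SiteCall(pos, "A", "T", "hom_var", 100.0, 20)
        kept, excluded = filter_repeat_adjacent([call], repeats, margin=10)
        dist = min(
            min(abs(pos - x) for x in (s, e)) if not (s <= pos <= e) else 0
            for s, e in repeats.intervals
        )
        assert (len(excluded) == 1) == (dist <= 10)


class TestClassification:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("A", "G", "snv_transition"),
            ("C", "T", "snv_transition"),
            ("A", "T", "snv_transversion"),
            ("G", "C", "snv_transversion"),
            ("", "G", "insertion"),
            ("G", "", "deletion"),
        ],
    )
    def test_classes(self, ref, alt, expected):
        assert classify_variant(ref, alt) == expected

    def test_identical_rejected(self):
        with pytest.raises(ValueError):
            classify_variant("A", "A")


class TestSummary:
    def test_hand_counted_fixture(self):
        case = [
            SiteCall(10, "A", "G", "hom_var", 100.0, 20),
            SiteCall(20, "C", "T", "hom_var", 100.0, 20),
            SiteCall(30, "G", "A", "het", 50.0, 20),
            SiteCall(40, "A", "T", "hom_var", 100.0, 20),
            SiteCall(50, "A", "C", "het", 50.0, 20),
            SiteCall(60, "", "G", "hom_var", 100.0, 20),
        ]
        control = [
            SiteCall(10, "A", "G", "hom_var", 100.0, 18),
            SiteCall(60, "", "G", "hom_var", 100.0, 12),
            SiteCall(70, "T", "", "het", 40.0, 22),
        ]
        s = summarize_variants(case, control)
        assert s.case["snps"] == 5 and s.case["indels"] == 1 and s.case["total"] == 6
        assert s.case["transitions"] == 3 and s.case["transversions"] == 2
        assert s.shared["total"] == 2 and s.shared["insertions"] == 1

    def test_empty(self):
        s = summarize_variants([], [])
        assert all(v == 0 for v in s.case.values())

    def test_conservation_on_random_fixtures(self, study, clean_pileups):
        case_calls = call_variants(clean_pileups["case_calf"])
        ctrl_calls = call_variants(clean_pileups["carrier_cow"])
        s = summarize_variants(case_calls, ctrl_calls)
        s.check_invariants()  # snps+indels=total, ts+tv=snps, hom+het=total
        assert s.case["total"] > 0
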