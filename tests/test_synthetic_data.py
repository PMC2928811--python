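"""Generator properties: determinism, composition bounds, the IBD design,
read/pileup fidelity, cohort margins and the Sanger truth oracle."""

import numpy as np
import pytest
from scipy import stats

from capturecall import (
    RepeatAnnotation,
    TruthVariant,
    generate_reference,
    plant_genes,
    plant_repeats,
    sanger_oracle,
    simulate_capture_reads,
    simulate_cohort_genotypes,
    simulate_haplotypes,
)
from capturecall.synthetic_data import (
    GT_HET,
    Haplotype,
    demo_frameshift_cds,
    encode_seq,
    revcomp,
)
from capturecall.variant_caller import build_pileup


class TestReference:
    def test_deterministic_and_gc_bounded(self):
        a = generate_reference(200_000, 0.5, seed=3)
        b = generate_reference(200_000, 0.5, seed=3)
        assert a.sequence == b.sequence
        gc = sum(c in "GC" for c in a.sequence) / a.length
        assert 0.47 <= gc <= 0.53

    def test_gc_zero_is_at_only(self):
        ref = generate_reference(1000, 0.0, seed=1)
        assert set(ref.sequence) <= {"A", "T"}

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generate_reference(999, 0.4, seed=1)


class TestRepeats:
    def test_masked_fraction_within_tolerance(self):
        ref = generate_reference(100_000, 0.42, seed=5)
        ann = plant_repeats(ref, 0.5, 500, seed=11)
        assert 45_000 <= ann.masked_bp <= 55_000
        # merged and sorted
        for (s1, e1), (s2, e2) in zip(ann.intervals, ann.intervals[1:]):
            assert s2 > e1 + 1

    def test_zero_fraction_empty(self):
        ref = generate_reference(10_000, 0.42, seed=5)
        assert plant_repeats(ref, 0.0, 500, seed=1).intervals == []

    def test_excessive_fraction_rejected(self):
        ref = generate_reference(10_000, 0.42, seed=5)
        with pytest.raises(ValueError):
            plant_repeats(ref, 0.95, 500, seed=1)

    def test_megabase_scale_single_copy_target(self):
        # a 7,192,748 bp interval masked down to ~3.54 Mb single copy
        ref = generate_reference(7_192_748, 0.42, seed=1)
        frac = 1.0 - 3_542_013 / 7_192_748
        ann = plant_repeats(ref, frac, 800, seed=2)
        single_copy = ref.length - ann.masked_bp
        assert abs(single_copy - 3_542_013) / 3_542_013 < 0.01


class TestGenes:
    def test_orfs_valid_and_outside_repeats(self, study):
        from Bio.Seq import Seq

        mask = set()
        for s, e in study["repeats"].intervals:
            mask.update(range(s, e + 1))
        assert len(study["genes"]) == 5
        for gene in study["genes"]:
            assert len(gene.exons) == 4
            cds = gene.cds_sequence(study["ref"])
            assert len(cds) % 3 == 0
            prot = str(Seq(cds).translate())
            assert prot.startswith("M") and prot.endswith("*")
            assert "*" not in prot[:-1]
            for s, e in gene.exons:
                assert not (set(range(s, e + 1)) & mask)

    def test_single_exon_gene(self):
        ref = generate_reference(20_000, 0.42, seed=4)
        genes = plant_genes(ref, RepeatAnnotation([]), 1, 1, seed=9)
        from Bio.Seq import Seq

        prot = str(Seq(genes[0].cds_sequence(ref)).translate())
        assert prot.startswith("M") and prot.endswith("*")

    def test_long_cds_available_for_demo_insertion(self, study):
        assert any(g.cds_length >= 372 for g in study["genes"])

    def test_insufficient_space_raises(self):
        ref = generate_reference(5_000, 0.42, seed=4)
        ann = plant_repeats(ref, 0.85, 400, seed=1)
        with pytest.raises(RuntimeError, match="single-copy space"):
            plant_genes(ref, ann, 8, 4, seed=1)

    def test_coordinate_maps_are_inverse(self, study):
        for gene in study["genes"]:
            for c in [1, 2, 100, gene.cds_length // 2, gene.cds_length]:
                g = gene.cds_to_genomic(c)
                assert gene.genomic_to_cds(g) == c


class TestHaplotypes:
    def test_ibd_design(self, study):
        case, control = study["case"], study["control"]
        assert case.het_positions() == []
        hets = control.het_positions()
        causal = [v for v in control.hap_a if v.causal]
        assert len(causal) == 1
        assert hets == [causal[0].pos]

    def test_variant_counts(self, study):
        case = study["case"]
        assert len(case.hap_a) == 51  # 50 neutral + causal
        control = study["control"]
        assert len(control.hap_b) == 50

    def test_no_neutral_variants_still_one_het(self):
        ref = generate_reference(30_000, 0.42, seed=4)
        genes = plant_genes(ref, RepeatAnnotation([]), 1, 2, seed=9)
        truths = simulate_haplotypes(ref, genes, 0, 363, seed=5)
        assert len(truths["carrier_cow"].het_positions()) == 1

    def test_causal_offset_outside_cds_rejected(self):
        ref = generate_reference(30_000, 0.42, seed=4)
        genes = plant_genes(ref, RepeatAnnotation([]), 1, 2, seed=9)
        with pytest.raises(ValueError):
            simulate_haplotypes(ref, genes, 0, 10**7, seed=5)

    def test_causal_is_g_insertion_at_cds_363(self, study):
        causal = [v for v in study["case"].hap_a if v.causal][0]
        gene = study["genes"][0]
        assert causal.vclass == "ins"
        cds_alt = causal.alt_allele if gene.strand == "+" else revcomp(causal.alt_allele)
        assert cds_alt == "G"


class TestReads:
    def test_error_free_reads_match_their_haplotype(self, study):
        truth = study["case"]
        reads = simulate_capture_reads(truth, study["ref"], 5, 0.0, 50, 0.0, seed=2)
        haps = reads.haplotypes
        for i, read in zip(range(200), reads.iter_reads()):
            hap = haps[read.hap_of_origin]
            s = int(reads.hap_start[i])
            assert read.sequence == hap.sequence()[s : s + 50]

    def test_realized_depth_near_requested(self, study):
        reads = simulate_capture_reads(study["case"], study["ref"], 44, 0.04, 76, 0.002, seed=5)
        pileup = build_pileup(reads, study["ref"])
        depths = pileup.base_counts.sum(axis=1)[1:]
        assert abs(depths.mean() - 44) / 44 < 0.15

    def test_fraction_covered_at_4x_mirrors_capture_performance(self, study):
        # 15-fold mean with 9% gap windows leaves about 91% of bases >= 4x
        reads = simulate_capture_reads(study["control"], study["ref"], 15, 0.09, 76, 0.002, seed=5)
        pileup = build_pileup(reads, study["ref"])
        depths = pileup.base_counts.sum(axis=1)[1:]
        assert abs((depths >= 4).mean() - 0.91) <= 0.05

    def test_reads_within_reference(self, study):
        reads = simulate_capture_reads(study["control"], study["ref"], 8, 0.05, 76, 0.002, seed=3)
        for read, _ in zip(reads.iter_reads(), range(100)):
            assert study["ref"].start <= read.origin_pos <= study["ref"].end

    def test_determinism(self, study):
        a = simulate_capture_reads(study["case"], study["ref"], 10, 0.05, 76, 0.002, seed=8)
        b = simulate_capture_reads(study["case"], study["ref"], 10, 0.05, 76, 0.002, seed=8)
        assert np.array_equal(a.codes, b.codes)
        assert np.array_equal(a.hap_start, b.hap_start)

    def test_duplication_artifact_raises_depth_and_false_hets(self, study):
        ref = study["ref"]
        region = (40_000, 50_000)
        reads = simulate_capture_reads(
            study["case"], ref, 30, 0.0, 76, 0.0, dup_region=region, seed=6
        )
        pileup = build_pileup(reads, ref)
        depths = pileup.base_counts.sum(axis=1)
        inside = depths[region[0] + 500 : region[1] - 500].mean()
        outside = np.concatenate([depths[1:30_000], depths[60_000:]]).mean()
        assert inside > 1.5 * outside
        # diverged-copy sites show intermediate allele fractions
        from capturecall.variant_caller import call_variants

        hets = [c for c in call_variants(pileup) if c.genotype == "het"]
        assert sum(region[0] <= c.pos <= region[1] for c in hets) > 10

    def test_pileup_alleles_equal_truth_alleles_when_error_free(self, study, clean_pileups):
        """With no errors, gaps or duplications, every pileup allele at every
        truth-variant site comes from the animal's two haplotypes."""
        truth = study["control"]
        pileup = clean_pileups["carrier_cow"]
        by_pos = {}
        for hap in (truth.hap_a, truth.hap_b):
            for v in hap:
                by_pos.setdefault(v.pos, set()).add((v.ref_allele, v.alt_allele))
        hom_pos = {p for p, alleles in by_pos.items() if len({a for a in alleles}) == 1
                   and sum(1 for hap in (truth.hap_a, truth.hap_b) for v in hap if v.pos == p) == 2}
        for pos, alleles in by_pos.items():
            col = pileup.column(pos)
            for key in col.allele_counts:
                if key.startswith("+"):
                    assert ("", key[1:]) in alleles
                elif key == "*":
                    assert (col.ref_allele, "") in alleles
                else:
                    ok = any(key == alt for _, alt in alleles) or key == col.ref_allele
                    assert ok
            if pos in hom_pos:  # no reference support survives at a hom site
                ref_like = col.allele_counts.get(col.ref_allele, 0)
                alt = next(iter(alleles))
                if alt[1] != "" and len(alt[1]) == len(alt[0]):  # SNV
                    assert ref_like == 0


class TestCohort:
    def test_margins_structure(self):
        df = simulate_cohort_genotypes(None, 16, 36, 309, 0.032, 75, 2, seed=13)
        carriers = df[df.group == "carrier"]
        assert (df[df.group == "affected"].genotype == "ins/ins").all()
        assert (carriers.genotype == "wt/ins").sum() == 34
        assert (carriers.genotype == "wt/wt").sum() == 2
        assert (df[df.group == "other_breed"].genotype == "wt/wt").all()
        assert len(df) == 16 + 36 + 309 + 75

    def test_empty_cohort(self):
        df = simulate_cohort_genotypes(None, 0, 0, 0, 0.0, 0, 0, seed=1)
        assert len(df) == 0

    def test_phenocopies_capped(self):
        with pytest.raises(ValueError):
            simulate_cohort_genotypes(None, 0, 1, 0, 0.0, 0, 2, seed=1)

    def test_unrelated_het_count_binomial(self):
        df = simulate_cohort_genotypes(None, 0, 0, 1000, 0.032, 0, 0, seed=21)
        n_het = (df.genotype == GT_HET).sum()
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.032)
        assert lo <= n_het <= hi

    def test_mean_het_fraction_across_seeds(self):
        """Across 200 seeds the mean carrier fraction sits inside the 99%
        binomial CI of the configured rate."""
        rate, n = 0.05, 100
        fracs = [
            (simulate_cohort_genotypes(None, 0, 0, n, rate, 0, 0, seed=s).genotype == GT_HET).mean()
            for s in range(200)
        ]
        se = np.sqrt(rate * (1 - rate) / (n * 200))
        assert abs(np.mean(fracs) - rate) < 2.58 * se


class TestSangerOracle:
    def test_control_genotypes(self, study):
        control = study["control"]
        causal = [v for v in control.hap_a if v.causal][0]
        assert sanger_oracle(control, causal.pos) == "het"
        assert sanger_oracle(study["case"], causal.pos) == "hom_var"
        neutral = [v for v in control.hap_b if not v.causal][0]
        assert sanger_oracle(control, neutral.pos) == "hom_var"
        clean = next(
            p for p in range(study["ref"].start + 10, study["ref"].end)
            if all(v.pos != p for v in control.hap_a) and all(v.pos != p for v in control.hap_b)
        )
        assert sanger_oracle(control, clean) == "hom_ref"

    def test_out_of_range(self, study):
        with pytest.raises(ValueError):
            sanger_oracle(study["control"], 10**9, study["ref"])


class TestDemoCds:
    def test_structure(self):
        cds = demo_frameshift_cds()
        assert len(cds) == 546 * 3
        assert cds.startswith("ATG") and cds.endswith("TGA")
        encode_seq(cds)
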