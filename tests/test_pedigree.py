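"""Pseudo-sibling genotypes, Mendelian consistency, design classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famgxe.pedigree import (Design, FamilyStructureError, MendelianError,
                             classify_family, mendelian_check,
                             pseudo_sib_dosages, pseudo_sib_genotype)


def brute_force_consistent(gc: int, gf: int, gm: int) -> bool:
    """Enumerate all parental transmissions; independent of the implementation."""
    father_alleles = [1] * gf + [0] * (2 - gf)
    mother_alleles = [1] * gm + [0] * (2 - gm)
    return any(a + b == gc for a in father_alleles for b in mother_alleles)


class TestPseudoSibGenotype:
    def test_symmetric_heterozygous_trio(self):
        assert pseudo_sib_genotype(1, 1, 1) == 1

    def test_complement_of_two_transmitted_risk_alleles(self):
        assert pseudo_sib_genotype(2, 1, 1) == 0

    def test_impossible_transmission_raises(self):
        with pytest.raises(MendelianError):
            pseudo_sib_genotype(2, 0, 2)

    def test_exhaustive_hard_call_trios_match_enumeration(self):
        """All 27 trio combinations: complement on consistent trios, error on
        Mendelian-impossible ones, with allele conservation throughout."""
        for gc, gf, gm in itertools.product((0, 1, 2), repeat=3):
            if brute_force_consistent(gc, gf, gm):
                gp = pseudo_sib_genotype(gc, gf, gm)
                assert gp == gf + gm - gc
                assert gc + gp == gf + gm  # allele conservation
                assert 0 <= gp <= 2
            else:
                with pytest.raises(MendelianError):
                    pseudo_sib_genotype(gc, gf, gm)

    def test_involution_returns_original_case_dosage(self):
        for gc, gf, gm in itertools.product((0, 1, 2), repeat=3):
            if brute_force_consistent(gc, gf, gm):
                gp = pseudo_sib_genotype(gc, gf, gm)
                assert pseudo_sib_genotype(gp, gf, gm) == gc

    def test_fractional_dosages_pass_through_and_flag_out_of_range(self):
        out = pseudo_sib_dosages("f1", {"a": 1.9}, {"a": 0.1}, {"a": 0.2})
        assert out.dosages["a"] == pytest.approx(-1.6)
        assert out.out_of_range_snps == ("a",)

    def test_input_outside_dosage_range_rejected(self):
        with pytest.raises(ValueError):
            pseudo_sib_genotype(2.4, 1, 1)

    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)),
                    min_size=1, max_size=8), st.data())
    @settings(max_examples=50, deadline=None)
    def test_prs_linearity_for_mendelian_trios(self, parents, data):
        """PRS_pseudo = PRS_F + PRS_M - PRS_C exactly when no dosages miss."""
        from famgxe.prs import DosageVector, SnpWeight, SnpWeightPanel, compute_prs
        panel = SnpWeightPanel(tuple(
            SnpWeight(f"s{i}", "A", 1.0 + 0.05 * (i + 1)) for i in range(len(parents))
        ))
        child = {}
        fa, mo = {}, {}
        for i, (gf, gm) in enumerate(parents):
            fa[f"s{i}"], mo[f"s{i}"] = float(gf), float(gm)
            tf = data.draw(st.sampled_from(sorted({1} if gf == 2 else {0} if gf == 0 else {0, 1})))
            tm = data.draw(st.sampled_from(sorted({1} if gm == 2 else {0} if gm == 0 else {0, 1})))
            child[f"s{i}"] = float(tf + tm)
        pseudo = pseudo_sib_dosages("f", child, fa, mo)
        ps = compute_prs(DosageVector("p", pseudo.dosages), panel).raw
        expected = (compute_prs(DosageVector("f", fa), panel).raw
                    + compute_prs(DosageVector("m", mo), panel).raw
                    - compute_prs(DosageVector("c", child), panel).raw)
        assert ps == pytest.approx(expected, abs=1e-12)


class TestMendelianCheck:
    def test_fully_heterozygous_trio_is_clean(self):
        het = {f"s{i}": 1.0 for i in range(5)}
        report = mendelian_check("f", het, het, het)
        assert report.consistent and report.unchecked_snps == ()

    def test_single_corrupt_snp_is_pinpointed(self):
        case = {"a": 1.0, "b": 2.0, "c": 0.0}
        father = {"a": 1.0, "b": 0.0, "c": 0.0}
        mother = {"a": 1.0, "b": 2.0, "c": 1.0}
        report = mendelian_check("f", case, father, mother)
        assert report.inconsistent_snps == ("b",)

    def test_exhaustive_trios_agree_with_enumeration(self):
        for gc, gf, gm in itertools.product((0, 1, 2), repeat=3):
            report = mendelian_check("f", {"x": float(gc)}, {"x": float(gf)},
                                     {"x": float(gm)})
            assert report.consistent == brute_force_consistent(gc, gf, gm)

    def test_soft_dosage_is_skipped_and_listed_unchecked(self):
        report = mendelian_check("f", {"a": 1.4}, {"a": 1.0}, {"a": 1.0},
                                 hard_call_threshold=0.1)
        assert report.unchecked_snps == ("a",)
        assert report.inconsistent_snps == ()

    def test_near_integer_dosages_are_rounded_for_checking(self):
        report = mendelian_check("f", {"a": 1.95}, {"a": 0.05}, {"a": 1.98})
        assert report.inconsistent_snps == ("a",)  # rounds to (2, 0, 2)


class TestClassifyFamily:
    @pytest.mark.parametrize("sib_g,par_g,sib_e,expected", [
        (False, True, True, Design.CASE_PARENTS_PLUS),
        (False, True, False, Design.CASE_PARENTS),
        (True, False, True, Design.CASE_SIBLING_PLUS),
        (False, False, True, Design.CASE_PLUS),
        (True, True, True, Design.CASE_SIBLING_PLUS),  # sibling genotype precedence
        (True, True, False, Design.CASE_PARENTS),
    ])
    def test_availability_patterns_map_to_designs(self, sib_g, par_g, sib_e, expected):
        assert classify_family(True, sib_g, par_g, sib_e) == expected

    def test_case_only_family_is_rejected(self):
        with pytest.raises(FamilyStructureError):
            classify_family(True, False, False, False)

    def test_missing_case_data_is_rejected(self):
        with pytest.raises(FamilyStructureError):
            classify_family(False, True, True, True)
        with pytest.raises(FamilyStructureError):
            classify_family(True, True, True, True, case_exposure=False)

    def test_matching_ratio_by_design(self):
        assert Design.CASE_PARENTS_PLUS.matching_ratio == 3
        assert Design.CASE_SIBLING_PLUS.matching_ratio == 3
        assert Design.CASE_PARENTS.matching_ratio == 1
        assert Design.CASE_PLUS.matching_ratio == 1

    def test_simulated_trios_are_mendelian_consistent(self, sim_dataset):
        snps = sim_dataset.config.panel.snp_ids
        for fam in sim_dataset.families[:50]:
            report = mendelian_check(
                fam.family_id,
                dict(zip(snps, fam.case_dosages)),
                dict(zip(snps, fam.father_dosages)),
                dict(zip(snps, fam.mother_dosages)),
            )
            assert report.consistent
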