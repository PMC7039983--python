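"""Synthetic family generator: determinism, genetics, ascertainment, calibration."""

import math

import numpy as np
import pytest

from famgxe.pedigree import Design
from famgxe.simulate import (AscertainmentError, SimConfig, calibration_summary,
                             default_panel, simulate_families)


class TestPanelCalibration:
    @pytest.mark.parametrize("n_snps", [1, 10, 77])
    def test_population_prs_moments_are_exact(self, n_snps):
        panel, freqs = default_panel(n_snps)
        w = panel.log_ors
        mean = 2 * np.sum(freqs * w)
        var = 2 * np.sum(freqs * (1 - freqs) * w**2)
        assert mean == pytest.approx(5.0, abs=1e-9)
        assert math.sqrt(var) == pytest.approx(0.45, abs=1e-6)

    def test_frequencies_valid(self):
        _, freqs = default_panel(77)
        assert np.all((freqs > 0) & (freqs < 1))


class TestSimulateFamilies:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = dict(n_families=80, seed=9)
        p1 = simulate_families(SimConfig(**cfg)).write(tmp_path / "a")
        p2 = simulate_families(SimConfig(**cfg)).write(tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seeds_differ(self, tmp_path):
        a = simulate_families(SimConfig(n_families=50, seed=1))
        b = simulate_families(SimConfig(n_families=50, seed=2))
        assert a.families[0].case_prs != b.families[0].case_prs

    def test_exact_design_counts_are_honoured(self):
        ds = simulate_families(SimConfig(design_counts=(40, 5, 45, 30), seed=3))
        counts = ds.design_counts()
        assert counts[Design.CASE_PARENTS_PLUS] == 40
        assert counts[Design.CASE_PARENTS] == 5
        assert counts[Design.CASE_SIBLING_PLUS] == 45
        assert counts[Design.CASE_PLUS] == 30
        assert ds.n_families == 120

    def test_parent_dosage_means_match_allele_frequencies(self, sim_dataset):
        freqs = sim_dataset.config.allele_freqs
        parents = np.array([np.concatenate([f.father_dosages, f.mother_dosages])
                            for f in sim_dataset.families])
        means = parents.reshape(-1, 2, len(freqs)).mean(axis=(0, 1))
        # Monte-Carlo error ~ sqrt(2f(1-f)/2n); 5 sigma margin
        tol = 5 * np.sqrt(2 * freqs * (1 - freqs) / (2 * len(parents)))
        assert np.all(np.abs(means - 2 * freqs) < tol)

    def test_daughters_obey_mendelian_transmission(self, sim_dataset):
        for fam in sim_dataset.families[:100]:
            total = fam.father_dosages + fam.mother_dosages
            for child in (fam.case_dosages, fam.sister_dosages):
                assert np.all(child <= np.minimum(total, 2))
                assert np.all(child >= np.maximum(total - 2, 0))

    def test_ascertainment_shifts_case_prs_upward(self, sim_dataset):
        case = np.array([f.case_prs for f in sim_dataset.families])
        ctrl = np.array([f.sister_prs for f in sim_dataset.families])
        assert case.mean() > ctrl.mean()

    def test_control_sisters_more_often_elder(self, sim_dataset):
        elder_controls = sum(f.sister_profile.birth_order_rank == 1
                             for f in sim_dataset.families)
        assert elder_controls > 0.6 * sim_dataset.n_families

    def test_index_age_below_fifty(self, sim_dataset):
        ages = [f.index_age for f in sim_dataset.families]
        assert max(ages) < 50
        assert 43 < np.mean(ages) < 47

    def test_hopeless_config_raises_ascertainment_error(self):
        with pytest.raises(AscertainmentError):
            simulate_families(SimConfig(n_families=100, baseline_logit=-18.0,
                                        seed=4))

    def test_masking_matches_design(self, sim_dataset):
        from famgxe.pedigree import Role
        for fam in sim_dataset.families[:80]:
            rec = fam.family_record()
            sib = rec.member(Role.CONTROL_SISTER)
            has_parents = rec.member(Role.FATHER) is not None
            if fam.design == Design.CASE_PARENTS_PLUS:
                assert has_parents and not sib.genotyped and sib.has_exposure
            elif fam.design == Design.CASE_PARENTS:
                assert has_parents and not sib.genotyped and not sib.has_exposure
            elif fam.design == Design.CASE_SIBLING_PLUS:
                assert not has_parents and sib.genotyped and sib.has_exposure
            else:
                assert not has_parents and not sib.genotyped and sib.has_exposure


class TestMarginalCalibration:
    def test_control_prs_sd_near_046(self, sim_dataset):
        ctrl = [f.sister_prs for f in sim_dataset.families
                if f.design == Design.CASE_SIBLING_PLUS]
        assert abs(np.std(ctrl, ddof=1) - 0.46) < 0.05

    def test_premenopausal_control_proportion_near_089(self, sim_dataset):
        pre = [f.sister_profile.premenopausal for f in sim_dataset.families]
        assert abs(np.mean(pre) - 0.89) < 0.03

    def test_degenerate_prevalence_one_is_exact(self):
        ds = simulate_families(SimConfig(
            n_families=60, seed=5,
            exposure_params={"ever_hbc_p": 1 - 1e-12},
            beta_exposure={}, beta_interaction={},
        ))
        assert all(f.case_profile.ever_hbc and f.sister_profile.ever_hbc
                   for f in ds.families)

    def test_summary_table_layout(self, sim_dataset):
        table = calibration_summary(sim_dataset)
        assert list(table.columns) == ["variable", "level", "case", "control"]
        assert (table.variable == "PRS").any()
        assert (table.variable == "Parity at index age").sum() == 4
        # every case cell for categorical rows carries "count (proportion)"
        row = table[(table.variable == "Ever hormonal birth control")
                    & (table.level == "True")].iloc[0]
        assert "(" in row.case and "(" in row.control
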