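"""Conditional-logistic likelihood, Newton fit, coding rules, ROR reporting."""

import math

import numpy as np
import pytest

from conftest import make_profile, random_design
from famgxe.clr import (EstimationError, ModelSpec, UnidentifiableTermError,
                        build_design_matrix, compose_exposed_or,
                        conditional_loglik, fit_clr, fit_design,
                        wald_interaction_test)
from famgxe.pedigree import Design, FamilyRecord, Role, SubjectRecord
from famgxe.sets import build_matched_set


def _family(fid, design):
    return FamilyRecord(
        family_id=fid,
        members=[SubjectRecord(f"{fid}c", fid, Role.CASE, 2, True, True),
                 SubjectRecord(f"{fid}s", fid, Role.CONTROL_SISTER, 1, False, True)],
        index_age=44.0, design=design)


def _sets(design, n, rng, make_case=None, make_sib=None):
    out = []
    for i in range(n):
        fid = f"f{i}"
        case_e = (make_case or make_profile)(f"{fid}c", birth_order_rank=2)
        sib_e = (make_sib or make_profile)(f"{fid}s", birth_order_rank=1)
        cp = float(rng.normal(0, 0.4))
        sp = None if design == Design.CASE_PLUS else float(rng.normal(0, 0.4))
        out.append(build_matched_set(_family(fid, design), cp, sp, case_e,
                                     None if design == Design.CASE_PARENTS else sib_e))
    return out


class TestConditionalLoglik:
    def test_uniform_probability_for_size_four_set(self):
        X = np.zeros((4, 2))
        ll = conditional_loglik(np.array([0.3, -0.2]), X, np.array([0, 4]))
        assert ll == pytest.approx(-math.log(4))

    def test_pair_closed_form(self):
        # one 1:1 set, case x=1, control x=0: l(b) = b - ln(1 + e^b)
        X = np.array([[1.0], [0.0]])
        starts = np.array([0, 2])
        for b in (-1.5, 0.0, 0.7, 3.0):
            assert conditional_loglik([b], X, starts) == pytest.approx(
                b - math.log(1 + math.exp(b)))
        assert conditional_loglik([0.0], X, starts) == pytest.approx(-math.log(2))

    def test_duplicating_sets_doubles_loglik(self):
        rng = np.random.default_rng(3)
        X, starts, _ = random_design(rng, n_sets=7)
        X2 = np.vstack([X, X])
        starts2 = np.concatenate([starts, starts[1:] + starts[-1]])
        beta = rng.normal(size=X.shape[1])
        assert conditional_loglik(beta, X2, starts2) == pytest.approx(
            2 * conditional_loglik(beta, X, starts))

    def test_invariant_to_per_set_constant_shifts(self):
        rng = np.random.default_rng(4)
        X, starts, names = random_design(rng, n_sets=10)
        beta = rng.normal(size=X.shape[1])
        base = conditional_loglik(beta, X, starts)
        shifted = X.copy()
        for s in range(len(starts) - 1):
            shifted[starts[s]:starts[s + 1]] += rng.normal(size=X.shape[1])
        assert conditional_loglik(beta, shifted, starts) == pytest.approx(base)


class TestFitDesign:
    def test_matches_grid_search_on_one_parameter(self):
        rng = np.random.default_rng(11)
        X, starts, names = random_design(rng, n_sets=40, n_cols=1)
        fit = fit_design(X, starts, names)
        grid = np.linspace(-4, 4, 40001)
        lls = [conditional_loglik([b], X, starts) for b in grid]
        assert fit.params["x0"] == pytest.approx(grid[int(np.argmax(lls))], abs=5e-4)
        assert fit.converged

    def test_estimates_invariant_to_per_set_shifts(self):
        rng = np.random.default_rng(12)
        X, starts, names = random_design(rng, n_sets=40)
        base = fit_design(X, starts, names)
        shifted = X.copy()
        for s in range(len(starts) - 1):
            shifted[starts[s]:starts[s + 1]] += rng.normal(size=X.shape[1])
        moved = fit_design(shifted, starts, names)
        for k in names:
            assert moved.params[k] == pytest.approx(base.params[k], abs=1e-6)

    def test_pairs_match_intercept_free_logistic_on_differences(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(13)
        X, starts, names = random_design(rng, n_sets=60, sizes=(2,))
        fit = fit_design(X, starts, names)
        diffs = X[starts[:-1]] - X[starts[:-1] + 1]   # case minus control
        sm_fit = sm.Logit(np.ones(len(diffs)), diffs).fit(disp=0)
        np.testing.assert_allclose(
            [fit.params[k] for k in names], sm_fit.params, rtol=1e-5)

    def test_separation_is_flagged(self):
        # case always one unit above the control: monotone likelihood
        n = 20
        X = np.zeros((2 * n, 1))
        X[::2, 0] = 1.0
        starts = np.arange(0, 2 * n + 1, 2)
        fit = fit_design(X, starts, ["x0"], max_iter=60)
        assert fit.separation_flag
        assert not fit.converged

    def test_empty_input_rejected(self):
        with pytest.raises(EstimationError):
            fit_design(np.zeros((0, 1)), np.array([0]), ["x0"])

    def test_collinear_within_set_design_rejected(self):
        rng = np.random.default_rng(14)
        X, starts, _ = random_design(rng, n_sets=20, n_cols=1)
        X2 = np.hstack([X, 2 * X])
        with pytest.raises(EstimationError, match="rank deficient"):
            fit_design(X2, starts, ["a", "b"])


class TestIdentifiabilityStructure:
    def test_case_plus_sets_cannot_identify_prs_main_effect(self):
        rng = np.random.default_rng(21)
        sets = _sets(Design.CASE_PLUS, 60, rng,
                     make_sib=lambda sid, **kw: make_profile(
                         sid, ever_hbc=bool(rng.random() < 0.5), **kw))
        fit = fit_clr(sets, ModelSpec("ever_hbc"))
        assert "prs" in fit.unidentifiable
        with pytest.raises(UnidentifiableTermError):
            fit.odds_ratio("prs")

    def test_case_parents_sets_cannot_identify_exposure_main_effect(self):
        rng = np.random.default_rng(22)
        sets = _sets(Design.CASE_PARENTS, 60, rng,
                     make_case=lambda sid, **kw: make_profile(
                         sid, ever_hbc=bool(rng.random() < 0.5), **kw))
        fit = fit_clr(sets, ModelSpec("ever_hbc"))
        assert "ever_hbc" in fit.unidentifiable
        assert "elder" in fit.unidentifiable   # both members share the case's rank
        assert "prs" in fit.params             # genotype contrast is informative

    def test_zero_score_component_for_uninformative_directions(self):
        # case_plus sets: PRS column constant within each set, so the score
        # for the PRS direction is exactly zero at any beta
        rng = np.random.default_rng(23)
        sets = _sets(Design.CASE_PLUS, 30, rng,
                     make_sib=lambda sid, **kw: make_profile(
                         sid, ever_hbc=bool(rng.random() < 0.5), **kw))
        design = build_design_matrix(sets, ModelSpec("ever_hbc"))
        j = design.names.index("prs")
        X, starts = design.X, design.starts
        for beta_val in (0.0, 0.7):
            beta = np.full(X.shape[1], beta_val)
            eps = 1e-6
            up, down = beta.copy(), beta.copy()
            up[j] += eps
            down[j] -= eps
            d = (conditional_loglik(up, X, starts)
                 - conditional_loglik(down, X, starts)) / (2 * eps)
            assert abs(d) < 1e-8


class TestCodingRules:
    def test_binary_interaction_model_columns(self):
        rng = np.random.default_rng(31)
        sets = _sets(Design.CASE_SIBLING_PLUS, 5, rng)
        design = build_design_matrix(sets, ModelSpec("ever_hbc"))
        assert design.names == ["ever_hbc", "prs", "prs_x_ever_hbc", "elder"]

    def test_ordered_factor_gets_saturated_main_and_trend_product(self):
        rng = np.random.default_rng(32)
        sets = _sets(Design.CASE_SIBLING_PLUS, 5, rng)
        design = build_design_matrix(sets, ModelSpec("years_hbc"))
        assert design.names == ["years_hbc[2to10]", "years_hbc[ge10]", "prs",
                                "prs_x_years_hbc", "elder", "age_menarche"]

    def test_smoking_gets_one_product_column_per_level(self):
        rng = np.random.default_rng(33)
        sets = _sets(Design.CASE_SIBLING_PLUS, 5, rng)
        design = build_design_matrix(sets, ModelSpec("smoking"))
        assert design.names == ["smoking[former]", "smoking[current]", "prs",
                                "prs_x_smoking[former]", "prs_x_smoking[current]",
                                "elder", "alcohol_trend"]

    def test_trend_scores_are_consecutive_integers(self):
        rng = np.random.default_rng(34)
        prof = lambda sid, **kw: make_profile(sid, years_hbc=12.0, **kw)
        sets = _sets(Design.CASE_SIBLING_PLUS, 2, rng, make_case=prof, make_sib=prof)
        design = build_design_matrix(sets, ModelSpec("years_hbc"))
        j = design.names.index("prs_x_years_hbc")
        jp = design.names.index("prs")
        # every member has years >= 10 -> score 2 -> product = 2 * prs
        np.testing.assert_allclose(design.X[:, j], 2 * design.X[:, jp])

    def test_incomplete_sets_dropped_whole_and_logged(self):
        rng = np.random.default_rng(35)
        sets = _sets(Design.CASE_SIBLING_PLUS, 4, rng)
        sets += _sets(Design.CASE_SIBLING_PLUS, 2, np.random.default_rng(36),
                      make_sib=lambda sid, **kw: make_profile(sid, parity=0, **kw))
        design = build_design_matrix(sets, ModelSpec("breastfeeding"))
        assert design.n_sets == 4
        assert len(design.dropped_sets) == 2
        assert all("breastfeeding" in r or "missing" in r
                   for _, r in design.dropped_sets)


class TestReporting:
    def test_compose_exposed_or_hbc_row(self):
        assert compose_exposed_or(3.89, 0.56) == pytest.approx(2.18)

    def test_compose_exposed_or_menopause_row(self):
        assert compose_exposed_or(1.23, 2.00) == pytest.approx(2.46)

    def test_null_interaction_returns_unexposed_or(self):
        for x in (0.5, 1.0, 3.3):
            assert compose_exposed_or(x, 1.0, round_to=None) == pytest.approx(x)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            compose_exposed_or(-1.0, 0.5)
        with pytest.raises(ValueError):
            compose_exposed_or(2.0, 0.0)

    def test_wald_p_is_one_at_zero_and_005_at_196(self):
        rng = np.random.default_rng(41)
        sets = _sets(Design.CASE_SIBLING_PLUS, 30, rng,
                     make_sib=lambda sid, **kw: make_profile(
                         sid, ever_hbc=bool(rng.random() < 0.5), **kw))
        fit = fit_clr(sets, ModelSpec("ever_hbc"))
        term = "prs_x_ever_hbc"
        fit.params[term] = 0.0
        assert wald_interaction_test(fit, term) == pytest.approx(1.0)
        fit.params[term] = 1.959963985 * fit.se[term]
        assert wald_interaction_test(fit, term) == pytest.approx(0.05, abs=1e-6)

    def test_confidence_interval_brackets_estimate(self):
        rng = np.random.default_rng(42)
        sets = _sets(Design.CASE_SIBLING_PLUS, 50, rng,
                     make_sib=lambda sid, **kw: make_profile(
                         sid, ever_hbc=bool(rng.random() < 0.5), **kw))
        fit = fit_clr(sets, ModelSpec("ever_hbc"))
        for term in fit.params:
            o, lo, hi = fit.odds_ratio(term)
            assert lo < o < hi and o > 0
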