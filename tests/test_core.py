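"""Model representation, EQN parsing, restrictions, and diagnostics."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mptmem as m
from mptmem.core import EqnParseError, ModelError, RestrictionError


# ---------------------------------------------------------------------------
# EQN parsing and writing
# ---------------------------------------------------------------------------

class TestParseEqn:
    def test_minimal_binomial_tree(self):
        model = m.parse_eqn("2\n1 1 p\n1 2 (1-p)\n")
        assert [p.name for p in model.params] == ["p"]
        assert len(model.trees) == 1
        assert len(model.branches) == 2

    def test_three_term_branch_polarities(self):
        model = m.parse_eqn("1\n1 1 (1-r)*(1-f)*gr\n1 2 r\n")
        terms = model.branches[0].terms
        assert [t.param for t in terms] == ["r", "f", "gr"]
        assert [t.complement for t in terms] == [True, True, False]

    def test_full_four_states_model_file(self):
        """Both animacy sets: 12 parameters, 4 trees, 22 branches."""
        built, _ = m.build_four_states()
        reparsed = m.parse_eqn(m.write_eqn(built))
        assert len(reparsed.params) == 12
        assert len(reparsed.trees) == 4
        assert len(reparsed.branches) == 22

    def test_header_line_is_ignored(self):
        model = m.parse_eqn("any comment here\n1 1 p\n1 2 (1-p)\n")
        assert len(model.branches) == 2

    def test_duplicate_tree_category_lines_accumulate(self):
        model = m.parse_eqn("3\n1 1 a\n1 1 (1-a)*b\n1 2 (1-a)*(1-b)\n")
        assert len(model.branches_of("tree1")) == 3
        assert len(model.tree("tree1").categories) == 2

    @pytest.mark.parametrize("bad", [
        "",                       # empty content
        "header only\n",          # no branch lines
        "1\n1 1 (1-p\n1 2 p\n",   # unbalanced parenthesis
        "1\n1 1 p+q\n1 2 p\n",    # unknown token
        "1\n1 1\n",               # missing product column
    ])
    def test_malformed_input_raises(self, bad):
        with pytest.raises(EqnParseError):
            m.parse_eqn(bad)

    def test_parse_error_carries_line_number(self):
        with pytest.raises(EqnParseError, match="line 3"):
            m.parse_eqn("2\n1 1 p\n1 2 (1-p\n")


class TestWriteEqn:
    def test_minimal_tree_two_content_lines(self, binomial_model):
        text = m.write_eqn(binomial_model)
        assert len(text.strip().splitlines()) == 3  # header + 2 branches

    def test_four_states_has_22_content_lines(self):
        model, _ = m.build_four_states()
        assert len(m.write_eqn(model).strip().splitlines()) == 23

    @pytest.mark.parametrize("builder", [
        lambda: m.build_four_states()[0],
        lambda: m.build_pd_two_ht()[0],
        lambda: m.parse_eqn("2\n1 1 p\n1 2 (1-p)\n"),
    ])
    def test_round_trip_is_structurally_identical(self, builder):
        model = builder()
        once = m.parse_eqn(m.write_eqn(model))
        twice = m.parse_eqn(m.write_eqn(once))
        assert once.branches == twice.branches
        assert [t.categories for t in once.trees] == [t.categories for t in twice.trees]
        assert once.param_names == twice.param_names


# ---------------------------------------------------------------------------
# Category probabilities
# ---------------------------------------------------------------------------

FOUR_STATES_POINT = dict(
    r_animate=0.5, f_animate=0.5, gr_animate=0.1, gf_animate=0.3,
    gg_animate=0.4, d_animate=0.5,
    r_inanimate=0.5, f_inanimate=0.5, gr_inanimate=0.1, gf_inanimate=0.3,
    gg_inanimate=0.4, d_inanimate=0.5,
)


class TestCategoryProbabilities:
    def test_four_states_old_tree_hand_enumeration(self):
        model, _ = m.build_four_states()
        probs = m.category_probabilities(model, FOUR_STATES_POINT)["old_animate"]
        assert probs["recollection"] == pytest.approx(0.525, abs=1e-12)
        assert probs["familiarity"] == pytest.approx(0.3175, abs=1e-12)
        assert probs["guessing"] == pytest.approx(0.063, abs=1e-12)
        assert probs["new"] == pytest.approx(0.0945, abs=1e-12)

    def test_certain_recollection_is_degenerate(self):
        model, _ = m.build_four_states()
        point = dict(FOUR_STATES_POINT, r_animate=1.0)
        probs = m.category_probabilities(model, point)["old_animate"]
        assert probs["recollection"] == pytest.approx(1.0)

    def test_pd_exclusion_old_tree_hand_enumeration(self):
        model, _ = m.build_pd_two_ht()
        point = dict(
            r_animate=0.5, f_animate=0.4, d_animate=0.5, gi_animate=0.5,
            ge_animate=0.2,
            r_inanimate=0.5, f_inanimate=0.4, d_inanimate=0.5,
            gi_inanimate=0.5, ge_inanimate=0.2,
        )
        probs = m.category_probabilities(model, point)["exclusion_old_animate"]
        assert probs["old"] == pytest.approx(0.26, abs=1e-12)
        assert probs["new"] == pytest.approx(0.74, abs=1e-12)

    def test_missing_parameter_is_named(self):
        model, _ = m.build_four_states()
        partial = {k: v for k, v in FOUR_STATES_POINT.items() if k != "gg_inanimate"}
        with pytest.raises(KeyError, match="gg_inanimate"):
            m.category_probabilities(model, partial)

    @given(st.lists(st.floats(0.0, 1.0), min_size=12, max_size=12))
    def test_probabilities_sum_to_one_everywhere(self, values):
        """Both built-in models are structurally complete at any point of
        the unit cube."""
        for model in (m.build_four_states()[0], m.build_pd_two_ht()[0]):
            point = dict(zip(model.param_names, values))
            probs = m.category_probabilities(model, point)
            for tree, cats in probs.items():
                total = sum(cats.values())
                assert abs(total - 1.0) < 1e-12
                assert all(-1e-15 <= p <= 1 + 1e-12 for p in cats.values())

    def test_branch_probability_invariant_under_term_permutation(self):
        model, _ = m.build_four_states()
        shuffled = m.MPTModel(
            params=model.params,
            trees=model.trees,
            branches=tuple(
                dataclasses.replace(b, terms=tuple(reversed(b.terms)))
                for b in model.branches
            ),
        )
        p1 = m.category_probabilities(model, FOUR_STATES_POINT)
        p2 = m.category_probabilities(shuffled, FOUR_STATES_POINT)
        assert p1 == p2


# ---------------------------------------------------------------------------
# Restrictions
# ---------------------------------------------------------------------------

class TestApplyRestrictions:
    def test_single_equate_drops_one_parameter(self, exp1):
        reduced, _ = m.apply_restrictions(
            exp1.model, list(exp1.base_restrictions) + [m.Equate("r_animate", "r_inanimate")]
        )
        assert len(reduced.free_params) == 8

    def test_pd_identification_aliases(self, exp2):
        model, restr = m.build_pd_two_ht()
        reduced, _ = m.apply_restrictions(model, restr["RD_ALIAS"])
        assert len(reduced.free_params) == 8

    def test_empty_restrictions_are_identity(self):
        model, _ = m.build_four_states()
        reduced, expansion = m.apply_restrictions(model, [])
        assert reduced.free_params == model.param_names
        vec = {p: 0.3 for p in model.param_names}
        assert expansion.expand(vec) == vec

    def test_expansion_preserves_category_probabilities(self, exp1):
        restrictions = list(exp1.base_restrictions) + [m.Fix("d_inanimate", 0.6)]
        reduced, expansion = m.apply_restrictions(exp1.model, restrictions)
        rng = np.random.default_rng(0)
        vec = dict(zip(reduced.free_params,
                       rng.uniform(0.1, 0.9, len(reduced.free_params))))
        full = expansion.expand(vec)
        assert full["d_inanimate"] == 0.6
        assert full["gr_inanimate"] == full["gr_animate"]
        p_full = m.category_probabilities(exp1.model, full)
        p_reduced = m.category_probabilities(reduced, vec)
        for tree in p_full:
            for cat in p_full[tree]:
                assert p_full[tree][cat] == pytest.approx(p_reduced[tree][cat], abs=1e-12)

    def test_transitive_equate_chain_single_representative(self):
        model = m.parse_eqn(
            "4\n1 1 a\n1 2 (1-a)*b\n1 3 (1-a)*(1-b)*c\n1 4 (1-a)*(1-b)*(1-c)\n"
        )
        reduced, expansion = m.apply_restrictions(
            model, [m.Equate("a", "b"), m.Equate("b", "c")]
        )
        assert reduced.free_params == ("a",)
        assert expansion.expand({"a": 0.4}) == {"a": 0.4, "b": 0.4, "c": 0.4}

    def test_contradictory_fixes_raise(self):
        model = m.parse_eqn("2\n1 1 a\n1 2 (1-a)\n")
        with pytest.raises(RestrictionError):
            m.apply_restrictions(model, [m.Fix("a", 0.2), m.Fix("a", 0.3)])
        with pytest.raises(RestrictionError):
            m.apply_restrictions(
                m.parse_eqn("2\n1 1 a*b\n1 2 (1-a)*(1-b)\n"),
                [m.Equate("a", "b"), m.Fix("a", 0.2), m.Fix("b", 0.3)],
            )

    def test_unknown_parameter_raises(self):
        model = m.parse_eqn("2\n1 1 a\n1 2 (1-a)\n")
        with pytest.raises(RestrictionError):
            m.apply_restrictions(model, [m.Equate("a", "zz")])


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

class TestStructuralCheck:
    def test_complete_models_pass(self):
        for model in (m.build_four_states()[0], m.build_pd_two_ht()[0]):
            report = m.structural_check(model, n_points=100, seed=1)
            assert report.passed
            assert report.max_deviation < 1e-12

    def test_missing_branch_is_flagged(self):
        model, _ = m.build_four_states()
        broken = m.MPTModel(model.params, model.trees, model.branches[:-1])
        report = m.structural_check(broken, n_points=20, seed=1)
        assert not report.passed
        assert "new_inanimate" in report.failed_trees

    def test_same_seed_same_report(self):
        model, _ = m.build_four_states()
        a = m.structural_check(model, n_points=30, seed=42)
        b = m.structural_check(model, n_points=30, seed=42)
        assert a == b


class TestIdentifiabilityCheck:
    def test_pd_without_aliases_is_not_identifiable(self):
        model, _ = m.build_pd_two_ht()
        report = m.identifiability_check(model, n_points=3, seed=1)
        assert report.n_free == 10
        assert report.max_rank == 8
        assert not report.identified

    def test_unrestricted_four_states_is_identified(self):
        model, _ = m.build_four_states()
        report = m.identifiability_check(model, n_points=3, seed=1)
        assert report.max_rank == 12
        assert report.identified

    def test_binomial_tree_rank_one(self, binomial_model):
        report = m.identifiability_check(binomial_model, n_points=2, seed=1)
        assert report.max_rank == 1
        assert report.identified

    def test_base_restricted_models_fully_identified(self, exp1, exp2):
        for fx in (exp1, exp2):
            reduced, _ = m.apply_restrictions(fx.model, fx.base_restrictions)
            report = m.identifiability_check(reduced, n_points=3, seed=1)
            assert report.identified


# ---------------------------------------------------------------------------
# Frequency tables
# ---------------------------------------------------------------------------

class TestFrequencyTable:
    def test_rejects_negative_and_fractional_counts(self):
        with pytest.raises(ValueError):
            m.FrequencyTable({("t", "a"): -3})
        with pytest.raises(ValueError):
            m.FrequencyTable({("t", "a"): 1.5})

    def test_validation_against_model(self, exp1):
        table = m.FrequencyTable({("no_such_tree", "new"): 5})
        with pytest.raises(ModelError):
            table.validate_against(exp1.model)

    def test_totals(self, exp1):
        assert exp1.data.tree_total("old_animate") == 4400
        assert exp1.data.total == 17600
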