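"""Exclusion engine: veto categories, scopes and composition."""

import pytest

from conftest import make_instances
from ocsnlp.exclusions import (
    EXCLUSION_CATEGORIES,
    ExclusionConfig,
    apply_exclusions,
    check_experiencer,
    check_form,
    check_hedge,
    check_negation,
    check_self_diagnosis,
)


def first_instance(text, lexicons, anchor_term=None):
    instances = make_instances(text, lexicons)
    if anchor_term is None:
        return instances[0]
    return next(i for i in instances if i.anchor.matched_text.lower() == anchor_term)


def categories(results):
    return [r.category for r in results]


class TestForm:
    @pytest.mark.parametrize(
        "text,fires",
        [
            ("Obsessive Compulsive Index (OCI): 12", True),
            ("Obsessions and compulsions. None today.", True),
            ("He described intrusive obsessional thoughts.", False),
            ("C - obsessive compulsive: 3.", True),
        ],
    )
    def test_form_fragments(self, lexicons, text, fires):
        inst = first_instance(text, lexicons)
        results = check_form(inst, lexicons)
        assert bool(results) is fires
        for r in results:
            assert r.scope == "window"


class TestNegation:
    @pytest.mark.parametrize(
        "text,fires",
        [
            ("He denies any obsessions.", True),
            ("No evidence of compulsive checking.", True),
            ("He reports compulsive checking.", False),
            ("No current obsessions.", True),  # "no(t)" adjacency, gap 1
            ("It is more a keen interest than an obsession.", True),
            ("No history of rituals.", True),
        ],
    )
    def test_triggers(self, lexicons, text, fires):
        inst = first_instance(text, lexicons)
        assert bool(check_negation(inst, lexicons)) is fires

    def test_scope_is_anchor_sentence_only(self, lexicons):
        text = "He denies low mood. He reports compulsive checking."
        inst = first_instance(text, lexicons, "compulsive")
        assert check_negation(inst, lexicons) == []

    def test_bare_none_positional(self, lexicons):
        # adjacent to the keyword: veto
        near = first_instance("Obsessions: none currently.", lexicons)
        assert check_negation(near, lexicons)
        # sentence-initial: veto
        initial = first_instance("None of the rituals persist.", lexicons)
        assert check_negation(initial, lexicons)
        # far from the keyword: no veto under the default positional mode
        far = first_instance(
            "He reports obsessional thoughts most days but none of his relatives attended.",
            lexicons,
        )
        assert categories(check_negation(far, lexicons)) == []
        lenient = ExclusionConfig(bare_none_mode="anywhere")
        assert categories(check_negation(far, lexicons, lenient)) == ["negation"]


class TestExperiencer:
    @pytest.mark.parametrize(
        "text,fires",
        [
            ("His mother has OCD.", True),
            ("qqqqq hoards newspapers at home.", True),
            ("Patient reports hoarding newspapers.", False),
            ("Her partner describes her compulsive checking.", True),
        ],
    )
    def test_triggers(self, lexicons, text, fires):
        inst = first_instance(text, lexicons)
        assert bool(check_experiencer(inst, lexicons)) is fires

    def test_scope_is_anchor_sentence(self, lexicons):
        text = "His mother visited. He reports compulsive checking."
        inst = first_instance(text, lexicons, "compulsive")
        assert check_experiencer(inst, lexicons) == []


class TestHedge:
    @pytest.mark.parametrize(
        "text,fires",
        [
            ("Possible OCD.", True),
            ("It sounds like compulsive checking.", True),
            ("Diagnosed with OCD in 2010.", False),
            ("Apparently obsessional about cleaning.", True),
        ],
    )
    def test_triggers(self, lexicons, text, fires):
        inst = first_instance(text, lexicons)
        assert bool(check_hedge(inst, lexicons)) is fires

    def test_hedge_in_prior_sentence_near_keyword_fires(self, lexicons):
        text = "This is possible. OCD features were recorded."
        inst = first_instance(text, lexicons, "ocd")
        assert categories(check_hedge(inst, lexicons)) == ["hedge"]

    def test_hedge_far_before_keyword_does_not_fire(self, lexicons):
        text = (
            "It seems he slept rather poorly again last night at home. "
            "Later he reported obsessional thoughts."
        )
        inst = first_instance(text, lexicons, "obsessional")
        assert check_hedge(inst, lexicons) == []


class TestSelfDiagnosis:
    @pytest.mark.parametrize(
        "text,fires",
        [
            ("He describes himself as having OCD.", True),
            ("She says that she has OCD.", True),
            ("OCD diagnosed by Dr. Smith.", False),
            ("He told me he has OCD.", True),
        ],
    )
    def test_triggers(self, lexicons, text, fires):
        inst = first_instance(text, lexicons)
        assert bool(check_self_diagnosis(inst, lexicons)) is fires


class TestModifiers:
    def test_romantic_modifier_near_keyword(self, lexicons):
        inst = first_instance("He is obsessed with his girlfriend.", lexicons)
        cats = categories(apply_exclusions(inst, lexicons))
        assert "romantic_weight" in cats
        assert "other_experiencer" in cats  # girlfriend is also a kin term

    def test_risk_modifier_near_keyword(self, lexicons):
        inst = first_instance("Compulsive gambling was discussed.", lexicons)
        assert "risk_selfharm" in categories(apply_exclusions(inst, lexicons))

    def test_distant_trigger_does_not_modify(self, lexicons):
        text = "He reports compulsive checking and he sometimes discusses the gambling."
        inst = first_instance(text, lexicons, "compulsive")
        assert "risk_selfharm" not in categories(apply_exclusions(inst, lexicons))


class TestComposition:
    def test_fixed_category_order(self, lexicons):
        inst = first_instance("His mother denies any obsessions.", lexicons)
        cats = categories(apply_exclusions(inst, lexicons))
        assert cats == ["negation", "other_experiencer"]

    def test_clean_instance_has_no_exclusions(self, lexicons):
        inst = first_instance("He reports intrusive obsessional thoughts.", lexicons)
        assert apply_exclusions(inst, lexicons) == []

    def test_disabled_category_does_not_fire(self, lexicons):
        inst = first_instance("He denies any obsessions.", lexicons)
        cfg = ExclusionConfig(
            enabled=frozenset(EXCLUSION_CATEGORIES) - {"negation"}
        )
        assert apply_exclusions(inst, lexicons, cfg) == []

    def test_results_are_pure_functions_of_input(self, lexicons):
        inst = first_instance("Possible OCD.", lexicons)
        assert apply_exclusions(inst, lexicons) == apply_exclusions(inst, lexicons)

    def test_trigger_spans_lie_in_document_text(self, lexicons):
        text = "Filler sentence first. He denies any obsessions."
        inst = first_instance(text, lexicons)
        for r in apply_exclusions(inst, lexicons):
            assert text[r.start : r.end].lower() == r.trigger_text.lower()
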