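"""Component detectors, combination logic, and the document roll-up."""

import random

import pytest

from conftest import make_instances
from ocsnlp.detection import (
    DetectionConfig,
    classify_document,
    classify_instance,
    detect_component,
)


def anchor_instance(text, lexicons, anchor_term):
    return next(
        i
        for i in make_instances(text, lexicons)
        if i.anchor.matched_text.lower() == anchor_term
    )


class TestDetectComponent:
    @pytest.mark.parametrize(
        "text,anchor,component,positive,fired",
        [
            ("He has obsessions and compulsions.", "obsessions", "obsession",
             True, "two_plus_keywords"),
            ("He is hoarding newspapers.", "hoarding", "hoard",
             True, "hoarding_any"),
            ("He has obsessions.", "obsessions", "obsession", False, "none"),
            ("Intrusive obsessional thoughts causing distress.", "obsessional",
             "obsession", True, "keyword_plus_insight"),
            ("Reports compulsive checking.", "compulsive", "compulsion",
             True, "keyword_plus_ybocs"),
            ("Patient has OCD features.", "ocd", "ocd", True, "ocd_stated"),
            ("Diagnosed with OCD by the consultant.", "ocd", "ocd",
             True, "clinician_diagnosis"),
        ],
    )
    def test_routes(self, lexicons, text, anchor, component, positive, fired):
        inst = anchor_instance(text, lexicons, anchor)
        verdict = detect_component(inst, component, lexicons)
        assert verdict.positive is positive
        assert verdict.fired_rule == fired
        if positive:
            assert verdict.supporting_hits

    def test_repeated_tokens_of_one_family_do_not_corroborate(self, lexicons):
        inst = anchor_instance(
            "Obsessions and more obsessional thinking.", lexicons, "obsessions"
        )
        assert not detect_component(inst, "obsession", lexicons).positive
        lenient = DetectionConfig(two_plus_counts="tokens")
        assert detect_component(inst, "obsession", lexicons, lenient).positive

    def test_ybocs_anchor_requires_insight_support(self, lexicons):
        bare = anchor_instance("He was checking the locks.", lexicons, "checking")
        assert not detect_component(bare, "compulsion", lexicons).positive
        supported = anchor_instance(
            "He was checking the locks and felt unable to stop.",
            lexicons,
            "checking",
        )
        verdict = detect_component(supported, "compulsion", lexicons)
        assert verdict.positive and verdict.fired_rule == "keyword_plus_insight"

    def test_unknown_component_rejected(self, lexicons):
        inst = anchor_instance("He has OCD.", lexicons, "ocd")
        with pytest.raises(ValueError, match="unknown component"):
            detect_component(inst, "anxiety", lexicons)

    def test_disabled_route_goes_negative(self, lexicons):
        inst = anchor_instance("He is hoarding newspapers.", lexicons, "hoarding")
        cfg = DetectionConfig(
            routes=DetectionConfig().routes - {"hoarding_any"}
        )
        assert not detect_component(inst, "hoard", lexicons, cfg).positive


class TestClassifyInstance:
    @pytest.mark.parametrize(
        "text,final",
        [
            ("His mother has obsessions and compulsions.", "negative"),
            ("Diagnosed with OCD.", "positive"),
            ("Possibly obsessional, will review.", "negative"),
            ("He reports obsessions and compulsions.", "positive"),
        ],
    )
    def test_examples(self, lexicons, text, final):
        inst = make_instances(text, lexicons)[0]
        assert classify_instance(inst, lexicons).final == final

    def test_exclusion_vetoes_despite_positive_component(self, lexicons):
        inst = make_instances("His mother has obsessions and compulsions.", lexicons)[0]
        c = classify_instance(inst, lexicons)
        assert any(v.positive for v in c.verdicts)
        assert c.exclusions and c.final == "negative"

    def test_final_matches_invariant(self, lexicons):
        rng = random.Random(7)
        from conftest import random_sentence

        for _ in range(100):
            text = " ".join(random_sentence(rng) for _ in range(rng.randint(1, 4)))
            for inst in make_instances(text, lexicons):
                c = classify_instance(inst, lexicons)
                expected = any(v.positive for v in c.verdicts) and not c.exclusions
                assert (c.final == "positive") is expected


class TestClassifyDocument:
    def test_any_positive_rollup(self, lexicons):
        text = (
            "He denies any obsessions. Seen at home today. Mood was stable. "
            "Appetite remains good. He reports intrusive obsessional thoughts "
            "with marked distress."
        )
        doc, instances = classify_document("d", text, lexicons)
        assert doc.n_instances == 2
        assert doc.n_positive == 1
        assert doc.label == "positive"
        assert [c.final for c in instances] == ["negative", "positive"]

    def test_no_keywords_means_negative(self, lexicons):
        doc, instances = classify_document("d", "Sleeping well, appetite good.", lexicons)
        assert (doc.n_instances, doc.label) == (0, "negative")
        assert instances == []

    def test_empty_text(self, lexicons):
        doc, instances = classify_document("d", "", lexicons)
        assert (doc.n_instances, doc.label) == (0, "negative")

    def test_deterministic(self, lexicons):
        text = "Reports compulsive checking. His mother has OCD."
        a = classify_document("d", text, lexicons)
        b = classify_document("d", text, lexicons)
        assert a == b

    def test_permuting_far_filler_does_not_change_verdicts(self, lexicons):
        filler = [
            "Seen in the outpatient clinic today.",
            "Medication was continued at the same dose.",
            "Bloods were taken at the surgery.",
        ]
        core = "He reports intrusive obsessional thoughts with marked distress."
        text_a = " ".join(filler + [core])
        text_b = " ".join(filler[::-1] + [core])
        _, inst_a = classify_document("d", text_a, lexicons)
        _, inst_b = classify_document("d", text_b, lexicons)
        assert [c.final for c in inst_a] == [c.final for c in inst_b]
        assert [c.fired_rule for c in inst_a] == [c.fired_rule for c in inst_b]

    def test_ybocs_anchoring_toggle(self, lexicons):
        text = "He was checking the locks repeatedly."
        with_anchors, _ = classify_document("d", text, lexicons)
        cfg = DetectionConfig(ybocs_anchors=False)
        without, _ = classify_document("d", text, lexicons, cfg)
        assert with_anchors.n_instances == 2
        assert without.n_instances == 0
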