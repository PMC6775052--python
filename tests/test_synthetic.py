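"""Synthetic corpus generator: determinism, gold construction, coverage."""

import json

import pytest

from ocsnlp.detection import classify_document
from ocsnlp.exclusions import EXCLUSION_CATEGORIES
from ocsnlp.lexicons import LEXICON_NAMES, match
from ocsnlp.synthetic import (
    FILLER_SENTENCES,
    NEGATIVE_CATEGORIES,
    POSITIVE_CATEGORIES,
    TEMPLATES,
    GeneratorConfig,
    adversarial_suite,
    fill_slots,
    generate_corpus,
    perturb_corpus,
)


def serialize(corpus):
    return json.dumps(
        [
            {
                "doc": d.document.text,
                "labels": [(g.instance_id, g.label) for g in d.instance_labels],
                "doc_label": d.document_label.label,
                "prov": [(s.tag, s.text) for s in d.sentences],
            }
            for d in corpus
        ]
    )


class TestGenerate:
    def test_same_seed_byte_identical(self, lexicons):
        cfg = GeneratorConfig(n_docs=40, seed=7)
        assert serialize(generate_corpus(cfg, lexicons)) == serialize(
            generate_corpus(cfg, lexicons)
        )

    def test_different_seeds_differ(self, lexicons):
        a = generate_corpus(GeneratorConfig(n_docs=20, seed=1), lexicons)
        b = generate_corpus(GeneratorConfig(n_docs=20, seed=2), lexicons)
        assert serialize(a) != serialize(b)

    def test_prefix_stability_when_growing_corpus(self, lexicons):
        small = generate_corpus(GeneratorConfig(n_docs=10, seed=5), lexicons)
        large = generate_corpus(GeneratorConfig(n_docs=30, seed=5), lexicons)
        assert serialize(small) == serialize(large[:10])

    def test_every_document_has_instances_and_consistent_rollup(self, lexicons):
        for d in generate_corpus(GeneratorConfig(n_docs=50, seed=3), lexicons):
            assert len(d.instance_labels) >= 1
            any_pos = any(g.label == "positive" for g in d.instance_labels)
            assert d.document_label.label == (
                "positive" if any_pos else "negative"
            )

    def test_all_negated_rates_yield_only_negative_gold(self, lexicons):
        rates = {c: 0.0 for c in POSITIVE_CATEGORIES + NEGATIVE_CATEGORIES}
        rates["negated"] = 1.0
        corpus = generate_corpus(
            GeneratorConfig(n_docs=25, seed=9, rates=rates), lexicons
        )
        for d in corpus:
            assert all(g.label == "negative" for g in d.instance_labels)

    def test_zero_rates_rejected(self):
        rates = {c: 0.0 for c in POSITIVE_CATEGORIES + NEGATIVE_CATEGORIES}
        with pytest.raises(ValueError, match="rate"):
            GeneratorConfig(n_docs=5, seed=0, rates=rates)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            GeneratorConfig(n_docs=5, seed=0, rates={"bogus": 1.0})

    def test_category_coverage_in_default_corpus(self, lexicons):
        corpus = generate_corpus(GeneratorConfig(n_docs=300, seed=11), lexicons)
        tags = {s.tag for d in corpus for s in d.sentences}
        for category in POSITIVE_CATEGORIES + NEGATIVE_CATEGORIES:
            assert category in tags, f"no document exercises {category!r}"

    def test_fired_rule_coverage(self, lexicons):
        corpus = generate_corpus(GeneratorConfig(n_docs=300, seed=11), lexicons)
        fired = set()
        excl = set()
        for d in corpus:
            _, instances = classify_document(
                d.document.doc_id, d.document.text, lexicons
            )
            for c in instances:
                for v in c.verdicts:
                    if v.positive:
                        fired.add(v.fired_rule)
                for e in c.exclusions:
                    excl.add(e.category)
        assert fired >= {
            "ocd_stated", "clinician_diagnosis", "hoarding_any",
            "two_plus_keywords", "keyword_plus_ybocs", "keyword_plus_insight",
        }
        assert excl >= set(EXCLUSION_CATEGORIES)


class TestFillerBank:
    def test_fillers_match_no_lexicon(self, lexicons):
        for sentence in FILLER_SENTENCES:
            for name in LEXICON_NAMES:
                assert match(sentence, lexicons[name]) == [], (sentence, name)


class TestPerturb:
    def test_unknown_perturbation_rejected(self, lexicons):
        corpus = generate_corpus(GeneratorConfig(n_docs=2, seed=0), lexicons)
        with pytest.raises(ValueError, match="unknown perturbation"):
            perturb_corpus(corpus, "add_sarcasm")

    def test_perturbed_sentences_relabelled_negative(self, lexicons):
        corpus = generate_corpus(GeneratorConfig(n_docs=30, seed=2), lexicons)
        perturbed = perturb_corpus(corpus, "add_negation", seed=1, lexicons=lexicons)
        # every previously positive sentence was edited, so no gold
        # positives remain anywhere in the corpus
        for d in perturbed:
            for s in d.sentences:
                if s.tag.endswith("+add_negation"):
                    assert not (s.gold_ocs or s.gold_ybocs)
            assert all(g.label == "negative" for g in d.instance_labels)

    def test_zero_positive_corpus_is_identity(self, lexicons):
        rates = {c: 0.0 for c in POSITIVE_CATEGORIES + NEGATIVE_CATEGORIES}
        rates["negated"] = rates["hedged"] = 1.0
        corpus = generate_corpus(
            GeneratorConfig(n_docs=10, seed=4, rates=rates), lexicons
        )
        perturbed = perturb_corpus(corpus, "add_hedge", seed=0, lexicons=lexicons)
        assert serialize(perturbed) == serialize(corpus)


class TestStrippedTemplates:
    def test_slot_filling_is_exhaustive(self):
        for variants in TEMPLATES.values():
            for v in variants:
                assert "{" not in fill_slots(v.text)
                if v.stripped_text:
                    assert "{" not in fill_slots(v.stripped_text)


class TestAdversarial:
    def test_fixture_set_is_fixed_and_labelled(self, lexicons):
        suite = adversarial_suite(lexicons)
        assert len(suite) >= 15
        assert serialize(suite) == serialize(adversarial_suite(lexicons))
        assert any(d.document_label.label == "positive" for d in suite)
        assert any(d.document_label.label == "negative" for d in suite)

    def test_compulsory_fixture_has_no_instances(self, lexicons):
        suite = {d.document.doc_id: d for d in adversarial_suite(lexicons)}
        assert suite["adv03"].instance_labels == ()
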