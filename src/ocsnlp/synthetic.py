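"""Seeded generator of labelled pseudo-clinical notes.

Real psychiatric EHR text is access-restricted, so every rule in the
detector is exercised against synthetic notes built from templates.
Each template instantiates exactly one inclusion route (stated OCD
diagnosis, hoarding, two keyword families, keyword plus Y-BOCS
support, keyword plus insight support) or one negative pattern (bare
keyword, negation, non-patient experiencer, hedge, self-diagnosis,
questionnaire fragment, lay usage), with slot fills drawn from the same
lexicons the detector uses. Gold labels are therefore correct by
construction: templates and detector share one vocabulary source, so on
a purely template-built corpus any disagreement between prediction and
gold is a rule-engine bug ("closed-loop soundness"). This is a
correctness check on the rules, not a clinical performance claim.

The :func:`adversarial_suite` fixtures deliberately do *not* share
templates: they are hand-written edge cases (figurative "obsessed with
football", legal "compulsory", questionnaire fragments, mixed
positive/negative documents) with hand-assigned labels.

Documents are assembled so that the 5-sentence context windows of two
different template groups never overlap (at least two keyword-free
filler sentences between groups); the filler bank contains no token
matched by any lexicon.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .io import Document, GoldLabel
from .lexicons import LEXICON_NAMES, Lexicon, load_default_lexicons, match

__all__ = [
    "GeneratorConfig",
    "LabeledDocument",
    "ProvSentence",
    "TemplateVariant",
    "TEMPLATES",
    "FILLER_SENTENCES",
    "PERTURBATIONS",
    "POSITIVE_CATEGORIES",
    "NEGATIVE_CATEGORIES",
    "fill_slots",
    "generate_corpus",
    "perturb_corpus",
    "adversarial_suite",
]

# ----------------------------------------------------------------------
# Template bank
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class TemplateVariant:
    """One concrete sentence pattern with hand-assigned gold labels.

    ``gold_ocs`` / ``gold_ybocs`` label every OCS-keyword / Y-BOCS
    anchor the sentence(s) produce. ``stripped_text`` is the same
    pattern with its exclusion trigger removed, used to test that
    removing a veto restores a positive verdict exactly when an
    inclusion route remains.
    """

    text: str  # sentences separated by " "; may contain {slots}
    gold_ocs: bool
    gold_ybocs: bool = False
    stripped_text: str | None = None
    stripped_gold_ocs: bool = False
    stripped_gold_ybocs: bool = False


POSITIVE_CATEGORIES = (
    "ocd_stated",
    "hoarding_any",
    "two_plus_keywords",
    "keyword_plus_ybocs",
    "keyword_plus_insight",
)
NEGATIVE_CATEGORIES = (
    "bare_keyword",
    "negated",
    "other_experiencer",
    "hedged",
    "self_diagnosed",
    "form_fragment",
    "lay_usage",
)

SLOT_VALUES: dict[str, tuple[str, ...]] = {
    "object": ("newspapers", "old letters", "empty boxes"),
    "ybocs": ("checking", "cleaning", "counting", "washing"),
    "kin": ("mother", "father", "brother", "sister"),
    "year": ("2015", "2018", "2021"),
    "score": ("8", "12", "17"),
}


def fill_slots(text: str, rng: random.Random | None = None) -> str:
    """Substitute template slots; first value when no rng is given."""
    for slot, values in SLOT_VALUES.items():
        token = "{" + slot + "}"
        while token in text:
            value = values[0] if rng is None else rng.choice(values)
            text = text.replace(token, value, 1)
    return text


TEMPLATES: dict[str, tuple[TemplateVariant, ...]] = {
    # -- positive inclusion routes -------------------------------------
    "ocd_stated": (
        TemplateVariant("Patient has OCD features.", True),
        TemplateVariant("Diagnosed with OCD by the consultant in {year}.", True),
        TemplateVariant("He has a longstanding diagnosis of OCD.", True),
    ),
    "hoarding_any": (
        TemplateVariant("He is hoarding {object}.", True),
        TemplateVariant("There is significant hoarding of {object} in the flat.", True),
    ),
    "two_plus_keywords": (
        TemplateVariant("He reports obsessions and compulsions.", True),
        TemplateVariant(
            "She reports both obsessional thoughts and ritualistic behaviour.", True
        ),
    ),
    "keyword_plus_ybocs": (
        # Y-BOCS anchors in these windows share the positive verdict:
        # the window holds a keyword-plus-support combination, and the
        # verdict is a property of the window's evidence.
        TemplateVariant("Reports compulsive {ybocs}.", True, gold_ybocs=True),
        TemplateVariant(
            "He reports obsessional thoughts with repeated {ybocs} of the locks.",
            True,
            gold_ybocs=True,
        ),
    ),
    "keyword_plus_insight": (
        TemplateVariant(
            "She reports intrusive obsessional thoughts causing marked distress.",
            True,
        ),
        TemplateVariant(
            "He reports obsessional thoughts about contamination. "
            "He finds them intrusive and distressing.",
            True,
        ),
        TemplateVariant(
            "Compulsive {ybocs} which she finds distressing and is unable to stop.",
            True,
            gold_ybocs=True,  # Y-BOCS anchor with insight support in window
        ),
    ),
    # -- negative patterns ---------------------------------------------
    "bare_keyword": (
        TemplateVariant("He has obsessions.", False),
        TemplateVariant("Compulsive behaviour was noted on the ward.", False),
        TemplateVariant("There are rituals around bedtime.", False),
    ),
    "negated": (
        TemplateVariant(
            "He denies any obsessions.",
            False,
            stripped_text="He reports obsessions.",
            stripped_gold_ocs=False,  # bare keyword: no route remains
        ),
        TemplateVariant(
            "No evidence of compulsive {ybocs} or rituals.",
            False,
            gold_ybocs=False,
            stripped_text="Compulsive {ybocs} and rituals were present.",
            stripped_gold_ocs=True,  # two families + Y-BOCS support remain
            stripped_gold_ybocs=True,
        ),
        TemplateVariant("No history of hoarding.", False),
    ),
    "other_experiencer": (
        TemplateVariant(
            "His {kin} has OCD.",
            False,
            stripped_text="The patient has OCD.",
            stripped_gold_ocs=True,
        ),
        TemplateVariant("qqqqq hoards {object} at home.", False),
        TemplateVariant(
            "Her {kin} is always {ybocs} the locks.", False, gold_ybocs=False
        ),
    ),
    "hedged": (
        TemplateVariant(
            "Possible OCD was discussed.",
            False,
            stripped_text="OCD was discussed.",
            stripped_gold_ocs=True,
        ),
        TemplateVariant(
            "It sounds like compulsive {ybocs}.",
            False,
            gold_ybocs=False,
            stripped_text="There is compulsive {ybocs}.",
            stripped_gold_ocs=True,
            stripped_gold_ybocs=True,
        ),
        TemplateVariant("She seems obsessional about cleanliness.", False,
                        gold_ybocs=False),
    ),
    "self_diagnosed": (
        TemplateVariant(
            "He describes himself as having OCD.",
            False,
            stripped_text="He has OCD.",
            stripped_gold_ocs=True,
        ),
        TemplateVariant("She says that she has OCD.", False),
    ),
    "form_fragment": (
        TemplateVariant("Obsessive Compulsive Index (OCI): {score}.", False),
        TemplateVariant("C - obsessive compulsive: {score}.", False),
        TemplateVariant("Obsessions and compulsions. None reported on screening.", False),
    ),
    "lay_usage": (
        TemplateVariant("He is obsessed with football these days.", False),
        TemplateVariant(
            "Compulsive gambling was discussed at length.",
            False,
            stripped_text="Compulsive behaviour was discussed at length.",
            stripped_gold_ocs=False,  # trigger gone but still a bare keyword
        ),
        TemplateVariant("He is obsessed with his girlfriend.", False),
    ),
}

#: Keyword-free clinical-flavoured filler; no real patient text, and no
#: token matched by any lexicon (asserted in the test suite).
FILLER_SENTENCES = (
    "Seen in the outpatient clinic today.",
    "Sleep has been adequate of late.",
    "Medication was continued at the same dose.",
    "He attended the appointment on time.",
    "Mood was stable throughout.",
    "She is engaging well with the team.",
    "Bloods were taken at the surgery.",
    "Appetite remains good.",
    "He continues to attend college.",
    "The care plan was updated.",
    "Next appointment booked for two weeks.",
    "She reports sleeping through the night.",
    "He walked to the shops this morning.",
    "Physical observations were within range.",
)


# ----------------------------------------------------------------------
# Generator
# ----------------------------------------------------------------------


def _default_rates() -> dict[str, float]:
    return {c: 1.0 for c in POSITIVE_CATEGORIES + NEGATIVE_CATEGORIES}


@dataclass(frozen=True)
class GeneratorConfig:
    """Corpus-level knobs.

    ``rates`` are relative sampling weights per template category
    (uniform by default: every inclusion route and every exclusion
    pattern is equally represented, roughly balancing positive and
    negative instances the way a keyword-filtered note sample mixes
    genuine and spurious mentions). ``templates_per_doc`` and
    ``filler_between`` bound how many template groups a document holds
    and how many filler sentences pad each group (minimum 2, which
    keeps context windows of different groups disjoint).
    """

    n_docs: int = 100
    seed: int = 0
    rates: Mapping[str, float] = field(default_factory=_default_rates)
    templates_per_doc: tuple[int, int] = (1, 3)
    filler_between: tuple[int, int] = (2, 4)
    ybocs_anchors: bool = True

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        unknown = set(self.rates) - set(POSITIVE_CATEGORIES + NEGATIVE_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown template categories in rates: {sorted(unknown)}")
        if any(v < 0 for v in self.rates.values()):
            raise ValueError("rates must be non-negative")
        if sum(self.rates.values()) <= 0:
            raise ValueError("at least one rate must be positive")
        if self.filler_between[0] < 2:
            raise ValueError("filler_between minimum must be >= 2 "
                             "(keeps template context windows disjoint)")


@dataclass(frozen=True)
class ProvSentence:
    """One generated sentence with its provenance and gold flags."""

    text: str
    tag: str  # template category, "filler", or "category+perturbation"
    gold_ocs: bool = False
    gold_ybocs: bool = False
    is_filler: bool = False


@dataclass(frozen=True)
class LabeledDocument:
    """A synthetic document plus gold labels and sentence provenance."""

    document: Document
    sentences: tuple[ProvSentence, ...]
    instance_labels: tuple[GoldLabel, ...]
    document_label: GoldLabel


def _label_document(
    doc_id: str,
    sentences: Sequence[ProvSentence],
    lexicons: Mapping[str, Lexicon],
    ybocs_anchors: bool = True,
) -> LabeledDocument:
    """Assemble text and derive per-anchor gold labels from provenance.

    Anchors are enumerated with the shared matcher; each anchor takes
    the gold flag of the sentence it falls in (``gold_ocs`` for OCS
    keyword anchors, ``gold_ybocs`` for Y-BOCS anchors). An anchor
    inside a filler sentence means the filler bank is contaminated and
    is a hard error.
    """
    parts: list[tuple[int, int, ProvSentence]] = []
    cursor = 0
    chunks = []
    for s in sentences:
        parts.append((cursor, cursor + len(s.text), s))
        chunks.append(s.text)
        cursor += len(s.text) + 1  # single joining space
    text = " ".join(chunks)

    anchors = list(match(text, lexicons["ocs_keywords"], doc_id=doc_id))
    if ybocs_anchors:
        spans = {h.span for h in anchors}
        anchors += [
            h
            for h in match(text, lexicons["ybocs_keywords"], doc_id=doc_id)
            if h.span not in spans
        ]
    anchors.sort(key=lambda h: (h.start, h.end))

    labels = []
    any_positive = False
    for h in anchors:
        prov = next(s for (lo, hi, s) in parts if lo <= h.start < hi)
        if prov.is_filler:
            raise RuntimeError(
                f"filler sentence contains keyword {h.matched_text!r}: {prov.text!r}"
            )
        gold = prov.gold_ocs if h.lexicon == "ocs_keywords" else prov.gold_ybocs
        any_positive = any_positive or gold
        labels.append(
            GoldLabel(
                doc_id=doc_id,
                level="instance",
                label="positive" if gold else "negative",
                instance_id=f"{doc_id}:{h.start}-{h.end}",
                char_start=h.start,
                char_end=h.end,
            )
        )
    return LabeledDocument(
        document=Document(doc_id=doc_id, text=text),
        sentences=tuple(sentences),
        instance_labels=tuple(labels),
        document_label=GoldLabel(
            doc_id=doc_id,
            level="document",
            label="positive" if any_positive else "negative",
        ),
    )


def generate_corpus(
    config: GeneratorConfig, lexicons: Mapping[str, Lexicon] | None = None
) -> list[LabeledDocument]:
    """Generate a labelled corpus; deterministic given the seed.

    Each document holds 1-3 template groups separated by at least two
    filler sentences. Randomness is sub-seeded per document from
    ``(seed, doc index)``, so regenerating with more documents leaves
    earlier documents unchanged.
    """
    if lexicons is None:
        lexicons = load_default_lexicons()
    categories = [c for c in POSITIVE_CATEGORIES + NEGATIVE_CATEGORIES
                  if config.rates.get(c, 0) > 0]
    weights = [config.rates[c] for c in categories]

    corpus: list[LabeledDocument] = []
    for i in range(config.n_docs):
        rng = random.Random(f"{config.seed}:{i}")
        doc_id = f"syn{i:05d}"
        sentences: list[ProvSentence] = []
        for _ in range(rng.randint(0, 2)):
            sentences.append(
                ProvSentence(rng.choice(FILLER_SENTENCES), "filler", is_filler=True)
            )
        n_templates = rng.randint(*config.templates_per_doc)
        for _ in range(n_templates):
            category = rng.choices(categories, weights=weights, k=1)[0]
            variant = rng.choice(TEMPLATES[category])
            text = fill_slots(variant.text, rng)
            # Multi-sentence templates stay contiguous: split on ". "
            # is unsafe for dotted forms, so templates mark breaks with
            # a single space after terminal punctuation and we keep the
            # whole group as one provenance unit per sentence chunk.
            for chunk in _template_chunks(text):
                sentences.append(
                    ProvSentence(
                        chunk, category, variant.gold_ocs, variant.gold_ybocs
                    )
                )
            for _ in range(rng.randint(*config.filler_between)):
                sentences.append(
                    ProvSentence(
                        rng.choice(FILLER_SENTENCES), "filler", is_filler=True
                    )
                )
        corpus.append(
            _label_document(doc_id, sentences, lexicons, config.ybocs_anchors)
        )
    return corpus


def _template_chunks(text: str) -> list[str]:
    """Split a template's text into its sentences (provenance units)."""
    from .segmentation import split_sentences

    return [text[s.start : s.end] for s in split_sentences(text)]


# ----------------------------------------------------------------------
# Perturbations
# ----------------------------------------------------------------------

PERTURBATIONS = ("add_negation", "add_hedge", "add_experiencer", "swap_lay_usage")


def _decap(text: str) -> str:
    return text[0].lower() + text[1:] if text else text


def perturb_corpus(
    corpus: Sequence[LabeledDocument],
    perturbation: str,
    seed: int = 0,
    lexicons: Mapping[str, Lexicon] | None = None,
) -> list[LabeledDocument]:
    """Apply one exclusion-inducing edit to every gold-positive sentence.

    ``add_negation`` / ``add_hedge`` / ``add_experiencer`` prefix the
    sentence with a veto trigger; ``swap_lay_usage`` replaces it with a
    figurative lay-usage sentence. Perturbed sentences are re-labelled
    gold-negative and their provenance records the edit. Documents with
    no gold-positive sentences are returned unchanged.
    """
    if perturbation not in PERTURBATIONS:
        raise ValueError(
            f"unknown perturbation {perturbation!r}; expected one of {PERTURBATIONS}"
        )
    if lexicons is None:
        lexicons = load_default_lexicons()
    out = []
    for doc in corpus:
        if not any(s.gold_ocs or s.gold_ybocs for s in doc.sentences):
            out.append(doc)
            continue
        rng = random.Random(f"{seed}:{doc.document.doc_id}")
        new_sentences = []
        for s in doc.sentences:
            if not (s.gold_ocs or s.gold_ybocs):
                new_sentences.append(s)
                continue
            if perturbation == "add_negation":
                text = "No evidence of " + _decap(s.text)
            elif perturbation == "add_hedge":
                text = "Possibly " + _decap(s.text)
            elif perturbation == "add_experiencer":
                text = f"His {rng.choice(SLOT_VALUES['kin'])} " + _decap(s.text)
            else:  # swap_lay_usage
                text = "He is obsessed with football these days."
            new_sentences.append(
                ProvSentence(text, f"{s.tag}+{perturbation}", False, False)
            )
        out.append(
            _label_document(doc.document.doc_id, new_sentences, lexicons)
        )
    return out


# ----------------------------------------------------------------------
# Adversarial fixtures
# ----------------------------------------------------------------------

#: Hand-curated edge cases. Each entry: (doc_id, sentences, note) where
#: a sentence is (text, gold_ocs, gold_ybocs). These do NOT come from
#: the generator templates; labels are hand-assigned against the coding
#: rules, and the note says which rule the fixture probes.
_ADVERSARIAL: tuple[tuple[str, tuple[tuple[str, bool, bool], ...], str], ...] = (
    ("adv01", (("He is obsessed with football.", False, False),),
     "figurative keen-interest usage: single keyword, no support"),
    ("adv02", (("Compulsive gambling was discussed at length.", False, False),),
     "risk-taking behaviour modifying the keyword"),
    ("adv03", (("Attendance at the day centre is compulsory.", False, False),),
     "'compulsory' is an explicit non-match of the compul* stem"),
    ("adv04", (("Obsessive Compulsive Index (OCI): 14.", False, False),
               ("Please complete all items.", False, False)),
     "questionnaire fragment: form exclusion"),
    ("adv05", (("His mother has OCD and she is always cleaning.", False, False),),
     "non-patient experiencer in the keyword sentence"),
    ("adv06", (("It sounds like compulsive checking.", False, False),),
     "hedge phrase 'sounds like'"),
    ("adv07", (("He describes himself as having OCD.", False, False),),
     "self-diagnosis phrasing"),
    ("adv08", (("Possible OCD, will review in clinic.", False, False),),
     "hedge 'possible'"),
    ("adv09", (("He is obsessed with his girlfriend.", False, False),),
     "romantic modifier (and experiencer term) next to the keyword"),
    ("adv10", (("Intrusive obsessional images; unable to stop checking rituals.",
                True, True),),
     "two keyword families plus insight vocabulary: positive"),
    ("adv11", (("Diagnosed with OCD by Dr. Smith in 2019.", True, False),),
     "clinician diagnosis; abbreviation must not split the sentence"),
    ("adv12", (("He is hoarding newspapers and the flat is badly cluttered.",
                True, False),),
     "hoarding positive regardless of further examples"),
    ("adv13", (("Obsessions and compulsions: none currently.", False, False),),
     "bare 'none' adjacent to the keywords"),
    ("adv14", (("No history of obsessional rituals.", False, False),),
     "'no history' negation phrase"),
    ("adv15", (("He is compulsively checking the door locks.", True, True),
               ("He finds this distressing and is unable to stop.", False, False)),
     "keyword plus Y-BOCS support; insight in the next window sentence"),
    ("adv16", (("She washes her hands repeatedly but denies this is distressing.",
                False, False),),
     "negation in the sentence beats insight support"),
    ("adv17", (("He denies any obsessions.", False, False),
               ("Seen at home today.", False, False),
               ("Mood was stable throughout.", False, False),
               ("She reports intrusive obsessional thoughts with marked distress.",
                True, False)),
     "mixed document: negated and genuine mention two sentences apart"),
)


def adversarial_suite(
    lexicons: Mapping[str, Lexicon] | None = None,
) -> list[LabeledDocument]:
    """The fixed hand-labelled edge-case fixtures (no randomness)."""
    if lexicons is None:
        lexicons = load_default_lexicons()
    docs = []
    for doc_id, sents, note in _ADVERSARIAL:
        prov = [
            ProvSentence(text, f"adversarial:{note}", g_ocs, g_ybocs)
            for text, g_ocs, g_ybocs in sents
        ]
        docs.append(_label_document(doc_id, prov, lexicons))
    return docs
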