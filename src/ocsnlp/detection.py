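"""Component detectors and instance/document classification.

The detector is a combination of five component algorithms — one per
keyword family (obsession, compulsion, ocd, hoard, ritual) — sharing a
single exclusion engine. An instance (keyword + ≤5-sentence window) is
positive when at least one component's inclusion route holds **and** no
exclusion fires.

Inclusion routes, in precedence order:

* ``clinician_diagnosis`` / ``ocd_stated`` — the text states the patient
  has OCD (the disorder subsumes the symptoms); ``clinician_diagnosis``
  is recorded when diagnostic language ("diagnosed", "diagnosis")
  accompanies the keyword, purely for the audit trail.
* ``hoarding_any`` — hoarding counts as a symptom in its own right,
  with or without specific examples.
* ``two_plus_keywords`` — at least two distinct keyword *families* in
  the window ("obsessions and compulsions"); repeated tokens of one
  family do not self-corroborate.
* ``keyword_plus_ybocs`` — a single obsession/compulsion/ritual keyword
  supported by Y-BOCS checklist vocabulary (checking, cleaning,
  counting, ...) anywhere in the window.
* ``keyword_plus_insight`` — a single keyword supported by insight
  vocabulary (intrusive, distressing, egodystonic, unable to stop, ...).

A bare single keyword with no supporting evidence is negative: terms
like "obsession" are used far too loosely in clinical narrative (and in
lay speech) to stand alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .exclusions import ExclusionConfig, ExclusionResult, apply_exclusions
from .lexicons import (
    COMPONENTS,
    KeywordHit,
    Lexicon,
    family_of,
    load_default_lexicons,
    match,
)
from .segmentation import ContextInstance, extract_instances, split_sentences

__all__ = [
    "FIRED_RULES",
    "ComponentVerdict",
    "InstanceClassification",
    "DocumentClassification",
    "DetectionConfig",
    "detect_component",
    "classify_instance",
    "classify_document",
]

FIRED_RULES = (
    "ocd_stated",
    "hoarding_any",
    "two_plus_keywords",
    "keyword_plus_ybocs",
    "keyword_plus_insight",
    "clinician_diagnosis",
    "none",
)

_DIAGNOSIS_RE = re.compile(r"(?<!\w)diagnos\w*", re.IGNORECASE)
# Self-diagnosis phrasing is vetoed separately by the exclusion engine.


@dataclass(frozen=True)
class DetectionConfig:
    """Switches selecting which inclusion routes are active.

    Defaults reproduce the full published rule set. ``ybocs_anchors``
    also controls whether Y-BOCS keywords create instances of their own
    (a Y-BOCS-anchored instance needs insight support to be positive).
    ``two_plus_counts`` may be set to "tokens" for a lenient variant in
    which repeated tokens of one family corroborate each other.
    """

    routes: frozenset[str] = frozenset(FIRED_RULES) - {"none"}
    ybocs_anchors: bool = True
    two_plus_counts: str = "families"  # "families" | "tokens"
    include_ocs_token: bool = True
    exclusion: ExclusionConfig = field(default_factory=ExclusionConfig)


@dataclass(frozen=True)
class ComponentVerdict:
    component: str
    positive: bool
    fired_rule: str
    supporting_hits: tuple[KeywordHit, ...] = ()


@dataclass(frozen=True)
class InstanceClassification:
    """Full audit record for one instance.

    ``verdicts`` holds one verdict per component evaluated on the
    window; ``final`` is positive iff some component is positive and no
    exclusion fired.
    """

    instance: ContextInstance
    verdicts: tuple[ComponentVerdict, ...]
    exclusions: tuple[ExclusionResult, ...]
    final: str  # "positive" | "negative"

    @property
    def positive(self) -> bool:
        return self.final == "positive"

    @property
    def fired_rule(self) -> str:
        for v in self.verdicts:
            if v.positive:
                return v.fired_rule
        return "none"


@dataclass(frozen=True)
class DocumentClassification:
    doc_id: str
    n_instances: int
    n_positive: int

    @property
    def label(self) -> str:
        return "positive" if self.n_positive >= 1 else "negative"


def _window_evidence(instance: ContextInstance, lexicons: dict[str, Lexicon]):
    text = instance.window_text
    ocs = match(text, lexicons["ocs_keywords"])
    ybocs = match(text, lexicons["ybocs_keywords"])
    insight = match(text, lexicons["insight_keywords"])
    return ocs, ybocs, insight


def detect_component(
    instance: ContextInstance,
    component: str,
    lexicons: dict[str, Lexicon] | None = None,
    config: DetectionConfig = DetectionConfig(),
) -> ComponentVerdict:
    """Evaluate one component's inclusion routes on an instance window.

    The verdict is based purely on window content (plus the anchor for
    the Y-BOCS route); exclusions are applied separately.
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}")
    if lexicons is None:
        lexicons = load_default_lexicons(config.include_ocs_token)
    ocs, ybocs, insight = _window_evidence(instance, lexicons)
    families = {family_of(h.stem) for h in ocs}
    routes = config.routes

    anchor_is_ybocs = instance.anchor.lexicon == "ybocs_keywords"
    component_present = component in families

    def verdict(fired: str, support: list[KeywordHit]) -> ComponentVerdict:
        return ComponentVerdict(component, True, fired, tuple(support))

    if component_present:
        if component == "ocd":
            if _DIAGNOSIS_RE.search(instance.window_text) and "clinician_diagnosis" in routes:
                return verdict("clinician_diagnosis", ocs)
            if "ocd_stated" in routes:
                return verdict("ocd_stated", ocs)
        if component == "hoard" and "hoarding_any" in routes:
            return verdict("hoarding_any", ocs)
        n_distinct = (
            len(families) if config.two_plus_counts == "families" else len(ocs)
        )
        if n_distinct >= 2 and "two_plus_keywords" in routes:
            return verdict("two_plus_keywords", ocs)
        if component in ("obsession", "compulsion", "ritual"):
            if ybocs and "keyword_plus_ybocs" in routes:
                return verdict("keyword_plus_ybocs", ocs + ybocs)
            if insight and "keyword_plus_insight" in routes:
                return verdict("keyword_plus_insight", ocs + insight)
    elif anchor_is_ybocs and component == "compulsion" and config.ybocs_anchors:
        # Y-BOCS-anchored instance with no OCS keyword in reach: the
        # checklist term alone is not a symptom assertion; insight
        # vocabulary must mark it as egodystonic/distressing.
        if insight and "keyword_plus_insight" in routes:
            return verdict("keyword_plus_insight", [instance.anchor, *insight])
    return ComponentVerdict(component, False, "none", ())


def classify_instance(
    instance: ContextInstance,
    lexicons: dict[str, Lexicon] | None = None,
    config: DetectionConfig = DetectionConfig(),
) -> InstanceClassification:
    """Run all applicable component detectors, then the exclusion engine."""
    if lexicons is None:
        lexicons = load_default_lexicons(config.include_ocs_token)
    ocs, _, _ = _window_evidence(instance, lexicons)
    components = {family_of(h.stem) for h in ocs if family_of(h.stem) in COMPONENTS}
    if instance.anchor.lexicon == "ybocs_keywords" and config.ybocs_anchors:
        components.add("compulsion")
    verdicts = tuple(
        detect_component(instance, c, lexicons, config)
        for c in COMPONENTS
        if c in components
    )
    exclusions = tuple(apply_exclusions(instance, lexicons, config.exclusion))
    positive = any(v.positive for v in verdicts) and not exclusions
    return InstanceClassification(
        instance=instance,
        verdicts=verdicts,
        exclusions=exclusions,
        final="positive" if positive else "negative",
    )


def classify_document(
    doc_id: str,
    text: str,
    lexicons: dict[str, Lexicon] | None = None,
    config: DetectionConfig = DetectionConfig(),
) -> tuple[DocumentClassification, list[InstanceClassification]]:
    """Full pipeline for one document.

    Sentence split → keyword match → context windows → per-instance
    classification → any-positive roll-up. Deterministic: a pure
    function of (text, lexicons, config).
    """
    if lexicons is None:
        lexicons = load_default_lexicons(config.include_ocs_token)
    sentences = split_sentences(text)
    anchor_lexicons = ["ocs_keywords"]
    if config.ybocs_anchors:
        anchor_lexicons.append("ybocs_keywords")
    hits: list[KeywordHit] = []
    seen: set[tuple[int, int]] = set()
    for name in anchor_lexicons:
        for h in match(text, lexicons[name], doc_id=doc_id):
            if h.span not in seen:
                seen.add(h.span)
                hits.append(h)
    hits.sort(key=lambda h: (h.start, h.end))
    instances = extract_instances(doc_id, text, hits, sentences)
    classifications = [classify_instance(i, lexicons, config) for i in instances]
    n_pos = sum(c.positive for c in classifications)
    return (
        DocumentClassification(doc_id, len(classifications), n_pos),
        classifications,
    )
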