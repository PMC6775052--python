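"""Exclusion engine: veto rules that force an instance negative.

A candidate instance is discarded when the text around the keyword shows
it is not a definite, patient-experienced symptom mention:

* **form** — questionnaire/prompt fragments unique to structured forms
  (window-scoped);
* **negation** — negating terms in the keyword's own sentence, including
  the positional patterns "no(t) <keyword>" and "than (an) <keyword>";
* **other_experiencer** — the sentence attributes the symptom to someone
  other than the patient (family, partner, the "qqqqq" carer pseudonym);
* **hedge** — uncertainty markers (possible, seems, apparently, sounds
  like) in the keyword sentence or shortly before the keyword;
* **self_diagnosis** — the patient labels themself ("describes himself
  as having OCD", "says that she has OCD") — window-scoped;
* **romantic_weight** / **risk_selfharm** — lay usages where a romantic,
  food/weight or risk-taking word modifies the keyword ("obsessed with
  his girlfriend", "compulsive gambling"); the trigger must sit within a
  few tokens of the keyword.

Any non-empty exclusion result makes the instance negative regardless of
inclusion evidence. All categories are always evaluated (no
short-circuit) so the audit trail is complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .lexicons import KeywordHit, Lexicon, match, tokenize
from .segmentation import ContextInstance, split_sentences

__all__ = [
    "ExclusionResult",
    "ExclusionConfig",
    "EXCLUSION_CATEGORIES",
    "check_form",
    "check_negation",
    "check_experiencer",
    "check_hedge",
    "check_self_diagnosis",
    "apply_exclusions",
]

#: Fixed evaluation (and reporting) order.
EXCLUSION_CATEGORIES = (
    "form",
    "negation",
    "other_experiencer",
    "hedge",
    "self_diagnosis",
    "romantic_weight",
    "risk_selfharm",
)


@dataclass(frozen=True)
class ExclusionResult:
    """One fired veto: category, trigger text and document-level span."""

    category: str
    trigger_text: str
    start: int
    end: int
    scope: str  # "keyword_sentence" | "window"


@dataclass(frozen=True)
class ExclusionConfig:
    """Tunable scope parameters and per-category toggles.

    ``adjacency_max_gap``: max tokens between "no(t)"/"than" and the
    keyword they negate. ``bare_none_mode``: "positional" requires bare
    "none"/"nil" to open the sentence or sit within ``adjacency_max_gap``
    tokens of a keyword; "anywhere" vetoes on mere co-occurrence.
    ``hedge_pre_tokens``: how far before the keyword a hedge outside the
    anchor sentence may sit and still fire. ``modifier_max_distance``:
    token radius for the romantic/weight and risk/self-harm modifiers.
    """

    enabled: frozenset[str] = frozenset(EXCLUSION_CATEGORIES)
    adjacency_max_gap: int = 2
    bare_none_mode: str = "positional"
    hedge_pre_tokens: int = 5
    modifier_max_distance: int = 3


def _anchor_sentence(instance: ContextInstance) -> tuple[str, int]:
    """Text of the anchor's sentence and its offset in the document.

    Recovered by re-splitting the window text, which re-segments
    identically to the original document pass.
    """
    rel_anchor = instance.anchor.start - instance.window_start
    for s in split_sentences(instance.window_text):
        if s.start <= rel_anchor < s.end:
            return (
                instance.window_text[s.start : s.end],
                instance.window_start + s.start,
            )
    # Anchor is always inside the window by construction.
    raise AssertionError("anchor outside window sentences")


def _token_index(tokens: list[tuple[str, int, int]], pos: int) -> int | None:
    """Index of the token whose span contains ``pos``."""
    for i, (_, s, e) in enumerate(tokens):
        if s <= pos < e:
            return i
    return None


def _result(hit: KeywordHit, category: str, offset: int, scope: str) -> ExclusionResult:
    return ExclusionResult(
        category=category,
        trigger_text=hit.matched_text,
        start=offset + hit.start,
        end=offset + hit.end,
        scope=scope,
    )


def check_form(
    instance: ContextInstance, lexicons: dict[str, Lexicon]
) -> list[ExclusionResult]:
    """Questionnaire/form fragments anywhere in the window."""
    return [
        _result(h, "form", instance.window_start, "window")
        for h in match(instance.window_text, lexicons["excl_form"])
    ]


def check_negation(
    instance: ContextInstance,
    lexicons: dict[str, Lexicon],
    config: ExclusionConfig = ExclusionConfig(),
) -> list[ExclusionResult]:
    """Negating terms in the anchor keyword's sentence.

    Three kinds of trigger:

    * ordinary terms and phrases (deny*, "no history", "no evidence");
    * bare "none"/"nil", which under the default positional mode must be
      sentence-initial or adjacent to a keyword (so "none of his family
      attended" does not veto a distant symptom mention);
    * adjacency triggers "no"/"not" and "than", which fire only when an
      OCS or Y-BOCS keyword follows within ``adjacency_max_gap``
      intervening tokens ("no current obsessions", "than an obsession").
    """
    sent_text, offset = _anchor_sentence(instance)
    tokens = tokenize(sent_text)
    keyword_hits = match(sent_text, lexicons["ocs_keywords"]) + match(
        sent_text, lexicons["ybocs_keywords"]
    )
    keyword_token_idx = sorted(
        i for h in keyword_hits if (i := _token_index(tokens, h.start)) is not None
    )

    results: list[ExclusionResult] = []
    for h in match(sent_text, lexicons["excl_negation"]):
        if h.stem in ("none", "nil") and config.bare_none_mode == "positional":
            ti = _token_index(tokens, h.start)
            sentence_initial = ti == 0
            near_keyword = ti is not None and any(
                abs(ti - k) - 1 <= config.adjacency_max_gap
                for k in keyword_token_idx
            )
            if not (sentence_initial or near_keyword):
                continue
        results.append(_result(h, "negation", offset, "keyword_sentence"))

    # Adjacency triggers: trigger token strictly before a keyword token.
    adjacency = [
        p for p in lexicons["excl_negation"].patterns if p.match_mode == "adjacency"
    ]
    trigger_forms = {
        form: p.stem for p in adjacency for form in (p.stem, *p.variants)
    }
    for i, (tok, s, e) in enumerate(tokens):
        if tok.lower() not in trigger_forms:
            continue
        if any(i < k and (k - i - 1) <= config.adjacency_max_gap
               for k in keyword_token_idx):
            results.append(
                ExclusionResult(
                    category="negation",
                    trigger_text=tok,
                    start=offset + s,
                    end=offset + e,
                    scope="keyword_sentence",
                )
            )
    results.sort(key=lambda r: r.start)
    return results


def check_experiencer(
    instance: ContextInstance, lexicons: dict[str, Lexicon]
) -> list[ExclusionResult]:
    """Non-patient experiencer terms in the anchor sentence."""
    sent_text, offset = _anchor_sentence(instance)
    return [
        _result(h, "other_experiencer", offset, "keyword_sentence")
        for h in match(sent_text, lexicons["excl_experiencer"])
    ]


def check_hedge(
    instance: ContextInstance,
    lexicons: dict[str, Lexicon],
    config: ExclusionConfig = ExclusionConfig(),
) -> list[ExclusionResult]:
    """Uncertainty markers referring to the keyword.

    A hedge fires if it lies in the anchor sentence, or anywhere in the
    window at most ``hedge_pre_tokens`` tokens before the keyword.
    """
    sent_text, sent_offset = _anchor_sentence(instance)
    sent_span = (sent_offset, sent_offset + len(sent_text))
    win_tokens = tokenize(instance.window_text)
    rel_anchor = instance.anchor.start - instance.window_start
    anchor_idx = _token_index(win_tokens, rel_anchor)

    results = []
    for h in match(instance.window_text, lexicons["excl_hedge"]):
        doc_start = instance.window_start + h.start
        in_sentence = sent_span[0] <= doc_start < sent_span[1]
        precedes = False
        if not in_sentence and anchor_idx is not None:
            hi = _token_index(win_tokens, h.start)
            precedes = hi is not None and hi < anchor_idx and (
                anchor_idx - hi
            ) <= config.hedge_pre_tokens
        if in_sentence or precedes:
            scope = "keyword_sentence" if in_sentence else "window"
            results.append(
                ExclusionResult(
                    category="hedge",
                    trigger_text=h.matched_text,
                    start=doc_start,
                    end=instance.window_start + h.end,
                    scope=scope,
                )
            )
    return results


def check_self_diagnosis(
    instance: ContextInstance, lexicons: dict[str, Lexicon]
) -> list[ExclusionResult]:
    """Self-description / self-diagnosis phrasing anywhere in the window."""
    return [
        _result(h, "self_diagnosis", instance.window_start, "window")
        for h in match(instance.window_text, lexicons["excl_self_description"])
    ]


def _check_modifier(
    instance: ContextInstance,
    lexicon: Lexicon,
    category: str,
    config: ExclusionConfig,
) -> list[ExclusionResult]:
    """Triggers that must modify the keyword: within a small token radius."""
    win_tokens = tokenize(instance.window_text)
    rel_anchor = instance.anchor.start - instance.window_start
    anchor_idx = _token_index(win_tokens, rel_anchor)
    if anchor_idx is None:
        return []
    results = []
    for h in match(instance.window_text, lexicon):
        hi = _token_index(win_tokens, h.start)
        if hi is None or abs(hi - anchor_idx) > config.modifier_max_distance:
            continue
        results.append(_result(h, category, instance.window_start, "window"))
    return results


def apply_exclusions(
    instance: ContextInstance,
    lexicons: dict[str, Lexicon],
    config: ExclusionConfig = ExclusionConfig(),
) -> list[ExclusionResult]:
    """Run every enabled exclusion check in fixed category order.

    Non-empty output means the instance is negative no matter what the
    inclusion rules find.
    """
    checks = {
        "form": lambda: check_form(instance, lexicons),
        "negation": lambda: check_negation(instance, lexicons, config),
        "other_experiencer": lambda: check_experiencer(instance, lexicons),
        "hedge": lambda: check_hedge(instance, lexicons, config),
        "self_diagnosis": lambda: check_self_diagnosis(instance, lexicons),
        "romantic_weight": lambda: _check_modifier(
            instance, lexicons["excl_romantic_weight"], "romantic_weight", config
        ),
        "risk_selfharm": lambda: _check_modifier(
            instance, lexicons["excl_risk_selfharm"], "risk_selfharm", config
        ),
    }
    results: list[ExclusionResult] = []
    for category in EXCLUSION_CATEGORIES:
        if category in config.enabled:
            results.extend(checks[category]())
    return results
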