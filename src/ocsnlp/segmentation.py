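"""Sentence segmentation and keyword-anchored context windows.

The unit the detector classifies is an *instance*: one keyword hit plus
the sentence containing it and up to two sentences either side (at most
five sentences; fewer at document edges). Windows this size carry the
contextual evidence the inclusion and exclusion rules need — supporting
symptom vocabulary, negations, experiencer mentions — without dragging
in unrelated parts of the note.

The splitter is a small deterministic rule engine, not a statistical
model, so segmentation is bit-reproducible everywhere: sentences end at
terminal punctuation (``. ! ?``) followed by whitespace or end-of-text,
with a protected-abbreviation list so "Dr. Smith" and "e.g." do not
split.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .lexicons import KeywordHit

__all__ = ["Sentence", "ContextInstance", "split_sentences", "extract_instances"]

#: Lowercased tokens after which a period never ends a sentence.
PROTECTED_ABBREVIATIONS = frozenset(
    {
        "dr", "mr", "mrs", "ms", "prof", "st", "rev",
        "e.g", "i.e", "etc", "vs", "cf", "approx", "no",
        "o.c.d", "o.c.i", "a.m", "p.m",
    }
)

_TERMINAL_RE = re.compile(r"[.!?]+")
_PRECEDING_TOKEN_RE = re.compile(r"[\w.]+$")


@dataclass(frozen=True)
class Sentence:
    """A sentence span in the original document text."""

    index: int
    start: int
    end: int

    def text_of(self, doc_text: str) -> str:
        return doc_text[self.start : self.end]


@dataclass(frozen=True)
class ContextInstance:
    """A keyword anchor plus its surrounding sentence window.

    ``sentence_range`` is inclusive on both ends and spans at most five
    sentences; the anchor's sentence is always inside it. ``window_text``
    is the verbatim slice of the document covering the window.
    """

    instance_id: str
    doc_id: str
    anchor: KeywordHit
    sentence_range: tuple[int, int]
    window_start: int
    window_end: int
    window_text: str

    @property
    def n_sentences(self) -> int:
        return self.sentence_range[1] - self.sentence_range[0] + 1


def split_sentences(text: str) -> list[Sentence]:
    """Split ``text`` into ordered, non-overlapping sentences.

    A sentence boundary is terminal punctuation followed by whitespace
    or end-of-text, unless the token before the period is a protected
    abbreviation or a single letter (initials, "O.C.D"-style dotted
    acronyms). Text without terminal punctuation is one sentence. Empty
    or all-whitespace text yields no sentences.
    """
    boundaries: list[int] = []  # end offsets (exclusive of trailing ws)
    for m in _TERMINAL_RE.finditer(text):
        end = m.end()
        if end < len(text) and not text[end].isspace():
            continue  # mid-token punctuation ("3.5", "O.C.D.x" never arises)
        if m.group(0) == "." and _protected(text, m.start()):
            continue
        boundaries.append(end)
    sentences: list[Sentence] = []
    cursor = 0
    for end in boundaries:
        seg = _trim(text, cursor, end)
        if seg is not None:
            sentences.append(Sentence(len(sentences), *seg))
        cursor = end
    seg = _trim(text, cursor, len(text))
    if seg is not None:
        sentences.append(Sentence(len(sentences), *seg))
    return sentences


def _protected(text: str, dot_pos: int) -> bool:
    """True when the period at ``dot_pos`` follows a protected token."""
    m = _PRECEDING_TOKEN_RE.search(text, 0, dot_pos)
    if not m:
        return False
    token = m.group(0).rstrip(".").lower()
    if not token:
        return False
    if token in PROTECTED_ABBREVIATIONS:
        return True
    # Single letters: initials ("J. Smith") and dotted acronyms while
    # still being spelled out ("O.C.D" keeps its internal periods).
    return len(token) == 1 and token.isalpha()


def _trim(text: str, start: int, end: int) -> tuple[int, int] | None:
    while start < end and text[start].isspace():
        start += 1
    while end > start and text[end - 1].isspace():
        end -= 1
    if start >= end:
        return None
    return (start, end)


def extract_instances(
    doc_id: str,
    text: str,
    hits: list[KeywordHit],
    sentences: list[Sentence],
    context_sentences: int = 2,
) -> list[ContextInstance]:
    """Build one context instance per anchor hit.

    The window is the anchor's sentence plus ``context_sentences``
    sentences either side, clipped at document bounds. Instance ids are
    ``{doc_id}:{start}-{end}`` from the anchor span, so they are stable
    across runs and directly auditable against the source text.
    """
    instances: list[ContextInstance] = []
    for hit in hits:
        sent_idx = _sentence_of(hit, sentences)
        if sent_idx is None:
            raise ValueError(
                f"hit {hit.matched_text!r} at {hit.span} in doc {doc_id!r} "
                "falls outside every sentence span"
            )
        anchored = KeywordHit(
            doc_id=doc_id,
            lexicon=hit.lexicon,
            stem=hit.stem,
            matched_text=hit.matched_text,
            start=hit.start,
            end=hit.end,
            sentence_index=sent_idx,
        )
        lo = max(0, sent_idx - context_sentences)
        hi = min(len(sentences) - 1, sent_idx + context_sentences)
        w_start = sentences[lo].start
        w_end = sentences[hi].end
        instances.append(
            ContextInstance(
                instance_id=f"{doc_id}:{hit.start}-{hit.end}",
                doc_id=doc_id,
                anchor=anchored,
                sentence_range=(lo, hi),
                window_start=w_start,
                window_end=w_end,
                window_text=text[w_start:w_end],
            )
        )
    return instances


def _sentence_of(hit: KeywordHit, sentences: list[Sentence]) -> int | None:
    for s in sentences:
        if s.start <= hit.start < s.end:
            return s.index
    return None
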