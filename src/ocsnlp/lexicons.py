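"""Keyword lexicons and wildcard-stem matching.

Every term list the detector uses lives here as data: the three keyword
sets that identify candidate mentions of obsessive-compulsive symptoms
(OCS keywords, Y-BOCS checklist vocabulary, patient-insight vocabulary)
and the exclusion term sets (form/questionnaire fragments, negations,
non-patient experiencers, self-description phrasing, hedges, plus two
user-editable seed lists for romantic/weight and risk/self-harm modifiers).

Matching semantics
------------------
* ``prefix`` — case-insensitive token-prefix match at a word boundary
  (``obses*`` matches "obsessive", "obsessional", never "disobsess...");
  per-pattern exception tokens are whole tokens that are never matched
  (``compul*`` excludes "compulsory").
* ``exact`` — whole-token match. Stems may contain ``.`` or ``-``
  ("o.c.d", "self-harm"); these are matched literally.
* ``phrase`` — a token sequence separated by arbitrary whitespace
  ("unable to stop", "no evidence"). Chunks may carry punctuation
  ("obsessions and compulsions. none").
* ``adjacency`` — a trigger token that only negates when it precedes an
  OCS keyword within a small token window ("no(t) ...", "than (an) ...").
  These patterns are resolved by the exclusion engine, not by
  :func:`match`, because they need the keyword positions.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml

__all__ = [
    "TermPattern",
    "Lexicon",
    "KeywordHit",
    "LexiconError",
    "LEXICON_NAMES",
    "KEYWORD_LEXICONS",
    "family_of",
    "load_default_lexicons",
    "load_lexicons",
    "match",
    "match_all",
    "tokenize",
]

MATCH_MODES = ("prefix", "exact", "phrase", "adjacency")

#: The closed set of lexicon names.
LEXICON_NAMES = (
    "ocs_keywords",
    "ybocs_keywords",
    "insight_keywords",
    "excl_form",
    "excl_negation",
    "excl_experiencer",
    "excl_self_description",
    "excl_hedge",
    "excl_romantic_weight",
    "excl_risk_selfharm",
)

#: The lexicons whose hits count as keyword evidence (and drive the
#: document pre-filter).
KEYWORD_LEXICONS = ("ocs_keywords", "ybocs_keywords", "insight_keywords")

_TOKEN_RE = re.compile(r"\w+")


class LexiconError(ValueError):
    """Raised for malformed lexicon configuration."""


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Split ``text`` into word tokens with character spans.

    Tokens are maximal ``\\w+`` runs; punctuation and whitespace separate
    tokens. Returns ``(token, start, end)`` triples in document order.
    """
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


@dataclass(frozen=True)
class TermPattern:
    """One matchable term: a stem plus its matching mode.

    ``exceptions`` lists whole tokens a prefix pattern must never match;
    ``variants`` lists literal alternate surface forms (matched like
    ``exact`` stems, so they may contain ``.`` or ``-``).
    """

    stem: str
    match_mode: str = "prefix"
    exceptions: tuple[str, ...] = ()
    variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.stem:
            raise LexiconError("pattern stem must be non-empty")
        if self.match_mode not in MATCH_MODES:
            raise LexiconError(
                f"unknown match_mode {self.match_mode!r} for stem {self.stem!r}"
            )
        object.__setattr__(self, "stem", self.stem.lower())
        object.__setattr__(
            self, "exceptions", tuple(e.lower() for e in self.exceptions)
        )
        object.__setattr__(
            self, "variants", tuple(v.lower() for v in self.variants)
        )

    def regexes(self) -> list[re.Pattern[str]]:
        """Compiled case-insensitive regexes for this pattern.

        Adjacency patterns compile their trigger token(s) only; the
        positional constraint is applied by the exclusion engine.
        """
        out: list[re.Pattern[str]] = []
        if self.match_mode == "prefix":
            out.append(
                re.compile(rf"(?<!\w){re.escape(self.stem)}\w*", re.IGNORECASE)
            )
        elif self.match_mode in ("exact", "adjacency"):
            out.append(_literal_regex(self.stem))
        elif self.match_mode == "phrase":
            chunks = self.stem.split()
            body = r"\s+".join(re.escape(c) for c in chunks)
            out.append(re.compile(rf"(?<!\w){body}(?!\w)", re.IGNORECASE))
        for v in self.variants:
            if " " in v:
                body = r"\s+".join(re.escape(c) for c in v.split())
                out.append(re.compile(rf"(?<!\w){body}(?!\w)", re.IGNORECASE))
            else:
                out.append(_literal_regex(v))
        return out


def _literal_regex(form: str) -> re.Pattern[str]:
    # Whole-token match; "." and "-" inside the form are literal, so
    # "o.c.d" matches "O.C.D" (and "O.C.D." before the trailing period).
    return re.compile(rf"(?<!\w){re.escape(form)}(?!\w)", re.IGNORECASE)


@dataclass(frozen=True)
class Lexicon:
    """A named set of term patterns."""

    name: str
    patterns: tuple[TermPattern, ...]

    def __post_init__(self) -> None:
        if self.name not in LEXICON_NAMES:
            raise LexiconError(f"unknown lexicon name {self.name!r}")
        stems = [p.stem for p in self.patterns]
        dupes = {s for s in stems if stems.count(s) > 1}
        if dupes:
            raise LexiconError(
                f"duplicate stems in lexicon {self.name!r}: {sorted(dupes)}"
            )
        object.__setattr__(self, "patterns", tuple(self.patterns))

    def __iter__(self) -> Iterator[TermPattern]:
        return iter(self.patterns)


@dataclass(frozen=True)
class KeywordHit:
    """A single pattern match in a document."""

    doc_id: str
    lexicon: str
    stem: str
    matched_text: str
    start: int
    end: int
    sentence_index: int = -1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


# --- default rule pack -------------------------------------------------

#: Maps OCS keyword stems to their component family. User-added stems
#: fall back to being their own family.
_FAMILY = {
    "obses": "obsession",
    "compul": "compulsion",
    "ocd": "ocd",
    "ocs": "ocd",
    "hoard": "hoard",
    "ritual": "ritual",
}

COMPONENTS = ("obsession", "compulsion", "ocd", "hoard", "ritual")


def family_of(stem: str) -> str:
    """Component family for an OCS keyword stem."""
    return _FAMILY.get(stem, stem)


def _p(stem: str, mode: str = "prefix", exc: Iterable[str] = (), var: Iterable[str] = ()) -> TermPattern:
    return TermPattern(stem, mode, tuple(exc), tuple(var))


def load_default_lexicons(include_ocs_token: bool = True) -> dict[str, Lexicon]:
    """The shipped rule pack: all ten lexicons.

    ``include_ocs_token`` controls whether the bare token "ocs" counts as
    a member of the ocd keyword family (on by default; the acronym is
    standard in psychiatric notes but is not itself a Y-BOCS term).

    The romantic/weight and risk/self-harm lists are seed lists: the
    categories are part of the coding rules but no canonical enumeration
    exists, so these are deliberately small and user-editable.
    """
    ocs = [
        _p("obses"),
        _p("compul", exc=["compulsory"]),
        _p("ocd", var=["o.c.d"]),
        _p("hoard"),
        _p("ritual"),
    ]
    if include_ocs_token:
        ocs.append(_p("ocs", "exact"))
    lexicons = {
        "ocs_keywords": ocs,
        "ybocs_keywords": [
            _p("clean"),
            _p("wash"),
            _p("check"),
            _p("repeat"),
            _p("count"),
            _p("counting", "exact"),
            _p("order"),
            _p("rearrange"),
        ],
        "insight_keywords": [
            _p("distres"),
            _p("unwanted", "exact"),
            _p("repugnant", "exact"),
            _p("repulsive", "exact"),
            _p("egodystonic", "exact", var=["ego-dystonic"]),
            _p("intrusive", "exact"),
            _p("intruding", "exact"),
            _p("unable to stop", "phrase"),
        ],
        "excl_negation": [
            _p("none", "exact"),
            _p("nil", "exact"),
            _p("deny", exc=[], var=["denies", "denied", "denying"]),
            _p("no history", "phrase"),
            _p("no evidence", "phrase"),
            # Trigger tokens that veto only adjacent to an OCS keyword.
            _p("no", "adjacency", var=["not"]),
            _p("than", "adjacency"),
        ],
        "excl_experiencer": [
            _p("mother", "exact", var=["mothers"]),
            _p("father", "exact", var=["fathers"]),
            _p("sister", "exact", var=["sisters"]),
            _p("brother", "exact", var=["brothers"]),
            _p("parent", "exact", var=["parents"]),
            _p("son", "exact", var=["sons"]),
            _p("daughter", "exact", var=["daughters"]),
            _p("sibling", "exact", var=["siblings"]),
            _p("family", "exact"),
            _p("boyfriend", "exact", var=["boyfriends"]),
            _p("girlfriend", "exact", var=["girlfriends"]),
            _p("partner", "exact", var=["partners"]),
            _p("husband", "exact"),
            _p("wife", "exact"),
            # Masking pseudonym for a family member or carer in
            # de-identified corpora.
            _p("qqqqq", "exact"),
        ],
        "excl_self_description": [
            _p("self-described", "exact", var=["self described"]),
            _p("describes himself", "phrase"),
            _p("described himself", "phrase"),
            _p("describe himself", "phrase"),
            _p("describes herself", "phrase"),
            _p("described herself", "phrase"),
            _p("describe herself", "phrase"),
            _p("says that", "phrase"),
            _p("say that", "phrase"),
            _p("said that", "phrase"),
            _p("told me", "phrase"),
            _p("tells me", "phrase"),
        ],
        "excl_hedge": [
            _p("seem"),
            _p("possib"),
            _p("apparent"),
            _p("sounds like", "phrase"),
            _p("sound like", "phrase"),
        ],
        "excl_form": [
            _p("c - obsessive compulsive", "phrase"),
            _p("hoarded materials blocking passages", "phrase"),
            _p("obsessions and compulsions. none", "phrase"),
            _p("obsessive compulsive index", "phrase"),
            _p("oci", "exact", var=["o.c.i"]),
        ],
        # Seed lists (non-canonical, user-editable): terms that disqualify
        # a keyword they modify — romantic or food/weight usage ...
        "excl_romantic_weight": [
            _p("girlfriend", "exact"),
            _p("boyfriend", "exact"),
            _p("love", "exact", var=["loves", "loved"]),
            _p("crush", "exact"),
            _p("romantic", "exact", var=["romance"]),
            _p("food", "exact"),
            _p("eating", "exact"),
            _p("weight", "exact"),
            _p("diet", "exact", var=["dieting"]),
        ],
        # ... or risk-taking / self-harm usage.
        "excl_risk_selfharm": [
            _p("gambl"),
            _p("risk"),
            _p("self-harm", "exact", var=["self harm"]),
        ],
    }
    return {name: Lexicon(name, tuple(pats)) for name, pats in lexicons.items()}


def load_lexicons(path: str | Path, include_ocs_token: bool = True) -> dict[str, Lexicon]:
    """Load a YAML/JSON rule-pack override and merge it into the defaults.

    Schema: ``{lexicon_name: [{stem, match_mode?, exceptions?, variants?}]}``.
    A configured pattern replaces a default pattern with the same stem,
    otherwise it is appended. Unknown lexicon names or fields are errors.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    base = load_default_lexicons(include_ocs_token=include_ocs_token)
    if raw is None:
        return base
    if not isinstance(raw, Mapping):
        raise LexiconError(f"{path}: top level must be a mapping of lexicon names")
    for name, entries in raw.items():
        if name not in LEXICON_NAMES:
            raise LexiconError(
                f"{path}: unknown lexicon name {name!r} "
                f"(expected one of {', '.join(LEXICON_NAMES)})"
            )
        if entries is None:
            continue
        if not isinstance(entries, list):
            raise LexiconError(f"{path}: lexicon {name!r} must map to a list")
        patterns = {p.stem: p for p in base[name].patterns}
        for i, entry in enumerate(entries):
            if not isinstance(entry, Mapping):
                raise LexiconError(f"{path}: {name}[{i}] must be a mapping")
            unknown = set(entry) - {"stem", "match_mode", "exceptions", "variants"}
            if unknown:
                raise LexiconError(
                    f"{path}: {name}[{i}] has unknown field(s) {sorted(unknown)}"
                )
            if "stem" not in entry:
                raise LexiconError(f"{path}: {name}[{i}] missing required field 'stem'")
            stem = str(entry["stem"]).rstrip("*")
            pat = TermPattern(
                stem=stem,
                match_mode=str(entry.get("match_mode", "prefix")),
                exceptions=tuple(entry.get("exceptions") or ()),
                variants=tuple(entry.get("variants") or ()),
            )
            patterns[pat.stem] = pat
        base[name] = Lexicon(name, tuple(patterns.values()))
    return base


# --- matching ----------------------------------------------------------


def match(text: str, lexicon: Lexicon, doc_id: str = "") -> list[KeywordHit]:
    """All hits of ``lexicon`` in ``text``, sorted by character start.

    Case-insensitive; every hit starts at a word boundary; prefix
    exceptions are honoured; identical spans from overlapping patterns
    (e.g. ``count*`` and ``counting``) are reported once. Adjacency
    patterns are skipped — they are positional and belong to the
    exclusion engine.
    """
    hits: list[KeywordHit] = []
    seen: set[tuple[int, int]] = set()
    for pattern in lexicon.patterns:
        if pattern.match_mode == "adjacency":
            continue
        for rx in pattern.regexes():
            for m in rx.finditer(text):
                matched = m.group(0)
                if (
                    pattern.match_mode == "prefix"
                    and matched.lower() in pattern.exceptions
                ):
                    continue
                span = (m.start(), m.end())
                if span in seen:
                    continue
                seen.add(span)
                hits.append(
                    KeywordHit(
                        doc_id=doc_id,
                        lexicon=lexicon.name,
                        stem=pattern.stem,
                        matched_text=matched,
                        start=m.start(),
                        end=m.end(),
                    )
                )
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def match_all(
    text: str, lexicons: Mapping[str, Lexicon], names: Iterable[str], doc_id: str = ""
) -> list[KeywordHit]:
    """Hits from several lexicons, merged and sorted by start offset."""
    hits: list[KeywordHit] = []
    for name in names:
        hits.extend(match(text, lexicons[name], doc_id=doc_id))
    hits.sort(key=lambda h: (h.start, h.end, h.lexicon))
    return hits
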