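"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's regex machinery: the
matcher oracle hand-scans characters and tokens, and the binomial-CI
oracle inverts the binomial tail sums by bisection using math.comb.
They exist so the implementation can be checked against something that
cannot share its bugs.
"""

from __future__ import annotations

import math
import random

import pytest

from ocsnlp.lexicons import Lexicon, load_default_lexicons


@pytest.fixture(scope="session")
def lexicons():
    return load_default_lexicons()


# ----------------------------------------------------------------------
# Brute-force matcher oracle
# ----------------------------------------------------------------------


def _hand_tokens(text: str) -> list[tuple[str, int, int]]:
    """Character-scan tokenizer: maximal alnum/underscore runs."""
    toks = []
    i = 0
    n = len(text)
    while i < n:
        if text[i].isalnum() or text[i] == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            toks.append((text[i:j].lower(), i, j))
            i = j
        else:
            i += 1
    return toks


def _is_word(ch: str) -> bool:
    return ch.isalnum() or ch == "_"


def _literal_spans(text: str, form: str) -> set[tuple[int, int]]:
    """All boundary-delimited literal occurrences of ``form``."""
    low = text.lower()
    spans = set()
    start = 0
    while True:
        i = low.find(form, start)
        if i < 0:
            return spans
        j = i + len(form)
        before_ok = i == 0 or not _is_word(low[i - 1])
        after_ok = j == len(low) or not _is_word(low[j])
        if before_ok and after_ok:
            spans.add((i, j))
        start = i + 1


def _phrase_spans(
    text: str, toks: list[tuple[str, int, int]], words: list[str]
) -> set[tuple[int, int]]:
    """Token n-grams equal to ``words`` with only whitespace between."""
    spans = set()
    k = len(words)
    for i in range(len(toks) - k + 1):
        window = toks[i : i + k]
        if [t for t, _, _ in window] != words:
            continue
        if all(
            text[window[m][2] : window[m + 1][1]].isspace()
            for m in range(k - 1)
        ):
            spans.add((window[0][1], window[-1][2]))
    return spans


def oracle_match_spans(text: str, lexicon: Lexicon) -> set[tuple[int, int]]:
    """Independent re-derivation of match(): the set of hit spans."""
    toks = _hand_tokens(text)
    spans: set[tuple[int, int]] = set()
    for p in lexicon.patterns:
        if p.match_mode == "adjacency":
            continue
        if p.match_mode == "prefix":
            for t, s, e in toks:
                if t.startswith(p.stem) and t not in p.exceptions:
                    spans.add((s, e))
        elif p.match_mode == "exact":
            if any(c in p.stem for c in ".-"):
                spans |= _literal_spans(text, p.stem)
            else:
                spans |= {(s, e) for t, s, e in toks if t == p.stem}
        elif p.match_mode == "phrase":
            if any(not w.isalnum() for w in p.stem.split()):
                spans |= _literal_spans(text, p.stem)
            else:
                spans |= _phrase_spans(text, toks, p.stem.split())
        for v in p.variants:
            if " " in v:
                spans |= _phrase_spans(text, toks, v.split())
            elif any(c in v for c in ".-"):
                spans |= _literal_spans(text, v)
            else:
                spans |= {(s, e) for t, s, e in toks if t == v}
    return spans


#: Vocabulary for randomized matcher sentences: neutral words, keyword
#: inflections, exception tokens, phrase fragments, dotted variants.
ORACLE_VOCAB = (
    "the patient was seen in clinic today and reviewed by the team "
    "garden walk lunch quiet settled calm".split()
    + "obsessions obsessional obsessive compulsive compulsions compulsory "
      "compelled ocd o.c.d ocs hoarding hoarded rituals ritualistic".split()
    + "checking cleaned cleanliness washing counted counting ordering "
      "rearranging repeatedly unstoppable".split()
    + "intrusive intruding unwanted repugnant egodystonic distressing "
      "unable to stop".split()
    + "none nil denies denied no not evidence history than seems possible "
      "possibly apparently sounds sound like mother father qqqqq partner "
      "says say that told me self-described oci o.c.i".split()
)


def random_sentence(rng: random.Random, n_words: tuple[int, int] = (4, 14)) -> str:
    words = [rng.choice(ORACLE_VOCAB) for _ in range(rng.randint(*n_words))]
    sentence = " ".join(words)
    return sentence[0].upper() + sentence[1:] + "."


# ----------------------------------------------------------------------
# Instance construction helper
# ----------------------------------------------------------------------


def make_instances(text: str, lexicons, ybocs_anchors: bool = True, doc_id: str = "d"):
    """Split + match + window extraction, mirroring the pipeline front end."""
    from ocsnlp.lexicons import match
    from ocsnlp.segmentation import extract_instances, split_sentences

    sentences = split_sentences(text)
    hits = list(match(text, lexicons["ocs_keywords"], doc_id=doc_id))
    if ybocs_anchors:
        spans = {h.span for h in hits}
        hits += [
            h
            for h in match(text, lexicons["ybocs_keywords"], doc_id=doc_id)
            if h.span not in spans
        ]
    hits.sort(key=lambda h: (h.start, h.end))
    return extract_instances(doc_id, text, hits, sentences)


# ----------------------------------------------------------------------
# Binomial tail-sum CI oracle
# ----------------------------------------------------------------------


def _binom_cdf(k: int, n: int, p: float) -> float:
    return sum(
        math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(0, k + 1)
    )


def oracle_clopper_pearson(
    k: int, n: int, level: float = 0.95, tol: float = 1e-12
) -> tuple[float, float]:
    """Exact CI by bisecting the binomial tail sums directly."""
    alpha = 1 - level

    def bisect(f, lo, hi):
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid) > 0:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return 0.5 * (lo + hi)

    # lower: largest p with P(X >= k | p) <= alpha/2
    lower = 0.0 if k == 0 else bisect(
        lambda p: alpha / 2 - (1 - _binom_cdf(k - 1, n, p)), 0.0, 1.0
    )
    # upper: smallest p with P(X <= k | p) <= alpha/2
    upper = 1.0 if k == n else bisect(
        lambda p: _binom_cdf(k, n, p) - alpha / 2, 0.0, 1.0
    )
    return (lower, upper)
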