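"""Corpus, annotation and gold-label I/O, plus the document pre-filter.

Documents travel as JSONL (``{"doc_id": ..., "text": ...}``, one record
per line) or as a directory of ``*.txt`` files whose stem is the
doc_id. Text is preserved verbatim — no normalisation at read time —
so every downstream character span refers to the original note.

The pre-filter mirrors the corpus-extraction step of the detection
pipeline: keep exactly the documents containing at least one OCS,
Y-BOCS or patient-insight keyword. It uses the same matcher as
detection, which guarantees that any document producing instances
downstream survives the filter.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .detection import DocumentClassification, InstanceClassification
from .lexicons import KEYWORD_LEXICONS, Lexicon, match

__all__ = [
    "Document",
    "AnnotationRecord",
    "GoldLabel",
    "CorpusError",
    "read_corpus",
    "prefilter_corpus",
    "annotation_from_classification",
    "write_annotations",
    "read_annotations",
    "write_gold",
    "read_gold",
    "write_summary",
]

COMPONENT_SET = frozenset({"obsession", "compulsion", "ocd", "hoard", "ritual"})


class CorpusError(ValueError):
    """Malformed corpus, annotation or gold-label input."""


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str
    meta: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusError("doc_id must be non-empty")


@dataclass(frozen=True)
class AnnotationRecord:
    """Serialisable per-instance verdict with its audit trail."""

    doc_id: str
    instance_id: str
    char_start: int
    char_end: int
    keyword_term: str
    component: str
    verdict: str  # "positive" | "negative"
    fired_rule: str
    exclusions: tuple[dict, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.char_start < self.char_end):
            raise CorpusError(
                f"invalid span [{self.char_start}, {self.char_end}) "
                f"for instance {self.instance_id!r}"
            )
        if self.component not in COMPONENT_SET:
            raise CorpusError(f"unknown component {self.component!r}")
        if self.verdict not in ("positive", "negative"):
            raise CorpusError(f"unknown verdict {self.verdict!r}")
        object.__setattr__(
            self, "exclusions", tuple(dict(e) for e in self.exclusions)
        )


@dataclass(frozen=True)
class GoldLabel:
    doc_id: str
    level: str  # "instance" | "document"
    label: str  # "positive" | "negative"
    instance_id: str | None = None
    char_start: int | None = None
    char_end: int | None = None

    def __post_init__(self) -> None:
        if self.level not in ("instance", "document"):
            raise CorpusError(f"unknown gold level {self.level!r}")
        if self.label not in ("positive", "negative"):
            raise CorpusError(f"unknown gold label {self.label!r}")


# --- corpus ------------------------------------------------------------


def read_corpus(path: str | Path, format: str | None = None) -> list[Document]:
    """Read a corpus from JSONL or a directory of text files.

    ``format`` is "jsonl" or "textdir"; inferred from the path when
    omitted. Documents are returned sorted by doc_id; duplicates are an
    error; text is verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"corpus path does not exist: {path}")
    if format is None:
        format = "textdir" if path.is_dir() else "jsonl"
    if format == "textdir":
        docs = [
            Document(doc_id=p.stem, text=p.read_text())
            for p in sorted(path.glob("*.txt"))
        ]
    elif format == "jsonl":
        docs = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusError(f"{path}:{lineno}: malformed JSON ({exc})")
                if not isinstance(rec, dict) or "doc_id" not in rec or "text" not in rec:
                    raise CorpusError(
                        f"{path}:{lineno}: record must have 'doc_id' and 'text' fields"
                    )
                docs.append(
                    Document(
                        doc_id=str(rec["doc_id"]),
                        text=str(rec["text"]),
                        meta=rec.get("meta"),
                    )
                )
    else:
        raise CorpusError(f"unknown corpus format {format!r}")
    ids = [d.doc_id for d in docs]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise CorpusError(f"duplicate doc_id(s): {sorted(dupes)}")
    docs.sort(key=lambda d: d.doc_id)
    return docs


def write_corpus(docs: Iterable[Document], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for d in docs:
            rec = {"doc_id": d.doc_id, "text": d.text}
            if d.meta:
                rec["meta"] = dict(d.meta)
            fh.write(json.dumps(rec) + "\n")


def prefilter_corpus(
    docs: Sequence[Document], lexicons: Mapping[str, Lexicon]
) -> list[Document]:
    """Keep documents containing ≥1 keyword from any keyword lexicon.

    Context is ignored at this stage — "He denies obsessions." survives
    the filter; the instance classifier sorts it out later. Original
    order is preserved, and the operation is idempotent.
    """
    kept = []
    for doc in docs:
        if any(match(doc.text, lexicons[name]) for name in KEYWORD_LEXICONS):
            kept.append(doc)
    return kept


# --- annotations -------------------------------------------------------


def annotation_from_classification(c: InstanceClassification) -> AnnotationRecord:
    """Flatten a classified instance into its exchange record."""
    inst = c.instance
    component = (
        c.verdicts[0].component if len(c.verdicts) == 1 else _anchor_component(c)
    )
    return AnnotationRecord(
        doc_id=inst.doc_id,
        instance_id=inst.instance_id,
        char_start=inst.anchor.start,
        char_end=inst.anchor.end,
        keyword_term=inst.anchor.matched_text,
        component=component,
        verdict=c.final,
        fired_rule=c.fired_rule,
        exclusions=tuple(
            {"category": e.category, "trigger": e.trigger_text} for e in c.exclusions
        ),
    )


def _anchor_component(c: InstanceClassification) -> str:
    from .lexicons import family_of

    if c.instance.anchor.lexicon == "ybocs_keywords":
        return "compulsion"
    fam = family_of(c.instance.anchor.stem)
    return fam if fam in COMPONENT_SET else "obsession"


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for r in records:
            fh.write(json.dumps(asdict(r)) + "\n")


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    path = Path(path)
    records = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: malformed JSON ({exc})")
            try:
                records.append(AnnotationRecord(**rec))
            except TypeError as exc:
                raise CorpusError(f"{path}:{lineno}: bad record ({exc})")
    return records


# --- gold labels -------------------------------------------------------


def write_gold(labels: Iterable[GoldLabel], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for g in labels:
            rec = {k: v for k, v in asdict(g).items() if v is not None}
            fh.write(json.dumps(rec) + "\n")


def read_gold(path: str | Path) -> list[GoldLabel]:
    """Read gold labels; duplicate document-level labels are an error."""
    path = Path(path)
    labels = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: malformed JSON ({exc})")
            try:
                labels.append(GoldLabel(**rec))
            except TypeError as exc:
                raise CorpusError(f"{path}:{lineno}: bad record ({exc})")
    doc_level = [g.doc_id for g in labels if g.level == "document"]
    dupes = {d for d in doc_level if doc_level.count(d) > 1}
    if dupes:
        raise CorpusError(f"duplicate document-level gold labels for: {sorted(dupes)}")
    return labels


# --- summary -----------------------------------------------------------


def write_summary(
    doc_classifications: Iterable[DocumentClassification], path: str | Path
) -> pd.DataFrame:
    """Spreadsheet-friendly per-document summary CSV."""
    frame = pd.DataFrame(
        [
            {
                "doc_id": d.doc_id,
                "n_instances": d.n_instances,
                "n_positive": d.n_positive,
                "document_label": d.label,
            }
            for d in doc_classifications
        ],
        columns=["doc_id", "n_instances", "n_positive", "document_label"],
    )
    frame.to_csv(path, index=False)
    return frame
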