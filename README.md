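# ocsnlp

Rule-based detection of obsessive-compulsive symptom (OCS) mentions in
psychiatric clinical free text.

Obsessions (persistent, intrusive, distressing thoughts) and compulsions
(repetitive, goal-directed rituals) are common but under-recorded in the
structured fields of psychiatric records: they mostly surface in narrative
notes and correspondence, phrased in ways that overlap heavily with lay usage
("obsessed with football", "compulsive gambling") and with symptoms reported
about relatives rather than the patient. `ocsnlp` implements a transparent,
auditable rules pipeline for finding *definite, patient-experienced* OCS
mentions in such text, for researchers who need case-finding or phenotyping
over free-text mental-health records without a machine-learning training set.

## The algorithm

1. **Keyword pre-filter.** Keep documents containing at least one term from
   three wildcard-stem lexicons: OCS keywords (`obses*`, `compul*` excluding
   "compulsory", `ocd`/`o.c.d`, `hoard*`, `ritual*`), Y-BOCS checklist
   vocabulary (`clean*`, `wash*`, `check*`, `repeat*`, `count*`, `order*`,
   `rearrange*`), and patient-insight vocabulary (`distres*`, *unwanted*,
   *egodystonic*, *intrusive*, "unable to stop", ...).
2. **Context windows.** Sentence-split each document and build one *instance*
   per keyword hit: the keyword's sentence plus two sentences either side
   (≤5 sentences, clipped at document edges). The instance is the unit of
   classification and evaluation.
3. **Inclusion rules** (any one suffices): the text states the patient has
   OCD (with or without explicit clinician diagnosis); hoarding is mentioned
   (counted as OCS regardless of examples); at least two distinct OCS keyword
   *families* co-occur in the window; or a single obsession/compulsion/ritual
   keyword is supported by Y-BOCS or insight vocabulary in the window. A bare
   single keyword is never enough.
4. **Exclusion rules** (any one vetoes, regardless of inclusion evidence):
   questionnaire/form fragments; negation in the keyword sentence (including
   the positional patterns "no(t) …" and "than (an) …" next to the keyword);
   a non-patient experiencer (family, partner, carer pseudonym) in the
   keyword sentence; hedging (possible, seems, apparently, sounds like) in or
   just before the keyword; self-diagnosis phrasing; and romantic/weight or
   risk/self-harm words directly modifying the keyword.
5. **Roll-up.** A document is positive when at least one instance is positive.

An evaluation layer computes instance- and document-level precision (positive
predictive value) and recall (sensitivity) with exact binomial
(Clopper-Pearson) 95% confidence intervals, and Cohen's κ for double
annotation. Because real psychiatric EHR corpora are access-restricted, the
package ships a seeded synthetic-note generator whose templates exercise
every inclusion route and exclusion category, plus a hand-labelled
adversarial fixture set for the hard cases.

## Worked example

```bash
cat > note.jsonl <<'EOF'
{"doc_id": "note01", "text": "He denies any obsessions. Seen at home today. Mood was stable. She reports intrusive obsessional thoughts with marked distress. His mother has OCD."}
EOF
ocsnlp detect --in note.jsonl --out ann.jsonl --summary summary.csv --explain "note01:14-24"
```

prints the audit trail for the first instance and a run summary:

```
instance note01:14-24
  anchor: 'obsessions' (ocs_keywords:obses) at (14, 24)
  sentences 0-2
  window: 'He denies any obsessions. Seen at home today. Mood was stable.'
  component obsession: negative (none)
  exclusion negation: 'denies' [keyword_sentence]
  final: negative
3 instances in 1 documents; 1 positive
```

`ann.jsonl` then holds one record per instance: the "obsessions" mention is
negative (negated), the "obsessional" mention is positive (its window
contains corroborating keyword evidence and insight vocabulary, and no
exclusion fires), and the "OCD" mention is negative — the inclusion evidence
is there, but the experiencer is the patient's mother, not the patient. The
summary CSV rolls this up to `note01,3,1,positive`: the document mentions OCS
at least once.

The same pipeline from Python:

```python
from ocsnlp import classify_document

doc, instances = classify_document("note01", "He denies any obsessions. ...")
print(doc.label, [c.final for c in instances])
```

Synthetic corpora and evaluation:

```bash
ocsnlp simulate --n-docs 500 --seed 13 --out corpus.jsonl --gold gold.jsonl
ocsnlp filter   --in corpus.jsonl --out kept.jsonl
ocsnlp detect   --in kept.jsonl --out ann.jsonl
ocsnlp evaluate --pred ann.jsonl --gold gold.jsonl --level instance --out report.json
```

On a template-generated corpus this reports precision 1.000 and recall 1.000
with degenerate upper CIs at 1 — by design: generator templates and detector
share one lexicon source, so closed-loop scores below 1 indicate rule-engine
defects, not clinical performance. Performance on real notes is a different
question and requires annotated clinical text.

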