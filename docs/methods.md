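# Methods

## Problem and unit of analysis

The package classifies mentions of obsessive-compulsive symptoms (OCS) in
clinical free text. The unit is the *instance*: one keyword occurrence plus
its context window of at most five sentences (the keyword's sentence and two
either side, clipped at document bounds). Windows this size carry the
supporting or disqualifying context a clinician would read — the symptom
vocabulary around the keyword, negations, who the sentence is about — while
excluding unrelated parts of the note. Document classification is an
any-positive roll-up over instances: in practice a patient with OCS is
mentioned repeatedly, so missing one instance matters less than asserting a
false one, and the rules throughout prefer precision over recall.

## Lexicons and matching semantics

All term lists are data (ten named lexicons, overridable from YAML/JSON).
Matching is case-insensitive and word-boundary anchored. `prefix` patterns
(`obses*`) match any token beginning with the stem, with per-pattern
exception tokens that are never matched — `compul*` excludes "compulsory",
which is the legal/administrative sense, not the clinical one. `phrase`
patterns match token sequences across arbitrary whitespace, which lets form
fragments like "obsessions and compulsions. none" match across a sentence
boundary inside a window. Literal variants may contain `.` or `-`
("o.c.d", "self-described") and are matched as whole dotted/hyphenated
forms. No stemming, lemmatization or spelling correction is applied beyond
the listed variants: the rules are meant to be auditable term-by-term.

Three lexicon entries deserve comment:

* The bare acronym "ocs" is included in the OCD keyword family by default
  (toggle `include_ocs_token`); it is standard shorthand in psychiatric
  notes but is not a Y-BOCS term, so a site whose notes use "OCS" for
  something else can switch it off.
* The experiencer list contains `qqqqq`, the masking pseudonym that
  de-identified mental-health corpora substitute for names of family
  members and carers.
* The romantic/weight and risk/self-harm exclusion categories are part of
  the coding rules but have no canonical term enumeration; the shipped
  lists (girlfriend/boyfriend/love/food/weight/…, gambl*/risk*/self-harm)
  are deliberately small seed lists, flagged non-canonical and editable.
* The self-description category keys on reflexive and reported-speech
  phrasing ("describes himself", "says that", "told me"). A bare
  "he describes …" collocation is *not* a trigger: clinicians routinely
  write "he described intrusive thoughts" for mentions that should count.

## Sentence splitting

A deterministic rule splitter (terminal `.!?` followed by whitespace or end
of text, with a protected-abbreviation list covering titles, Latin
abbreviations and dotted acronyms) rather than a statistical model. The
cost is occasional under-splitting of unusual abbreviations; the benefit is
bit-identical segmentation across environments, which the determinism and
audit-trail guarantees depend on. Sentences cover all non-whitespace text,
so every keyword hit falls in exactly one sentence.

## Inclusion rules

A component verdict is computed per keyword family present in the window
(obsession, compulsion, ocd, hoard, ritual), in precedence order:

1. *OCD stated / clinician diagnosis* — an OCD-family keyword in the
   window; diagnostic language ("diagnos…") upgrades the audit label to
   `clinician_diagnosis` without changing the verdict. The disorder
   subsumes the symptoms.
2. *Hoarding* — any hoard* keyword; hoarding counts as OCS with or without
   specific examples.
3. *Two keyword families* — at least two distinct OCS keyword families in
   the window. Families, not tokens: "obsessions and obsessional" is one
   family twice and must not self-corroborate.
4. *Keyword plus support* — exactly one obsession/compulsion/ritual family
   backed by Y-BOCS vocabulary or by insight vocabulary anywhere in the
   window. Support is searched window-wide, not sentence-wide: the window
   exists precisely to capture context in neighbouring sentences.

A bare single keyword fires nothing: "obsession" and "compulsion" are used
too loosely in clinical and lay language for an unsupported mention to be
evidence.

Y-BOCS keywords also anchor instances of their own (configurable,
`ybocs_anchors`, on by default). A Y-BOCS-anchored instance whose window
contains no OCS keyword is positive only with insight support, and the
verdict is attributed to the compulsion component (Y-BOCS items describe
concrete compulsive behaviours). Without insight support "she was checking
the locks" is routine narrative, not a symptom assertion — the conservative
reading, consistent with precision-first design. The instance verdict is a
property of the window's evidence: every anchor whose window holds a valid
keyword-plus-support combination shares the positive verdict.

## Exclusion rules

Exclusions veto unconditionally; all categories are evaluated (no
short-circuit) so the audit trail is complete. Scopes differ by category
and were chosen to bound over-exclusion:

* **form** (window-scoped): questionnaire fragments ("Obsessive Compulsive
  Index", "OCI", "c - obsessive compulsive", …). Prompt text mentions
  symptoms without asserting them.
* **negation** (keyword sentence): deny*, nil, "no history", "no
  evidence"; the positional patterns "no(t)" and "than (an)" fire only
  with an OCS/Y-BOCS keyword at most two tokens downstream ("no current
  obsessions", "than an obsession"). Bare "none"/"nil" must open the
  sentence or sit within two tokens of a keyword (configurable to
  "anywhere"); an unconstrained "none" would veto sentences like "none of
  his relatives attended" that say nothing about the symptom.
* **other_experiencer** (keyword sentence): kin/partner terms and the
  `qqqqq` pseudonym. Sentence-scoped because a relative mentioned two
  sentences away does not re-attribute the symptom.
* **hedge**: in the keyword sentence, or at most five tokens before the
  keyword elsewhere in the window. Hedges attach forward onto what they
  qualify; a "seems" ten tokens earlier about sleep should not veto.
* **self_diagnosis** (window-scoped): reflexive/reported-speech phrasing.
* **romantic_weight** and **risk_selfharm**: trigger within three tokens
  of the anchor keyword, either side. These words disqualify a keyword
  they *modify* ("obsessed with his girlfriend", "compulsive gambling"),
  not any co-occurrence in the window.

Monotonicity holds by construction: inserting a veto trigger into the
anchor sentence of a positive instance always flips it negative, and
removing all triggers restores positive exactly when an inclusion route
remains.

## Evaluation statistics

Precision and recall are binomial proportions of small validation sets, so
confidence intervals use the exact Clopper-Pearson construction via beta
quantiles (`scipy.stats.beta.ppf`), with the boundary identities lower=0 at
k=0 and upper=1 at k=n returned exactly. Undefined metrics (zero
denominator) are reported as nulls, never coerced to 0. Inter-annotator
agreement is Cohen's κ computed directly from the contingency table; κ is
flagged undefined when chance agreement is 1. For span-based instance
evaluation, predicted and gold instances align by anchor-span overlap
within a document (greedy, leftmost-first, one-to-one); unmatched predicted
positives count as false positives, unmatched gold positives as false
negatives.

## Synthetic corpus generator

The generator emulates a keyword-filtered sample of psychiatric notes: each
document is one to three template groups (a single inclusion route or
negative pattern, slot-filled from the shared lexicons) embedded in
keyword-free clinical-flavoured filler. Defaults: uniform weight over all
twelve template categories (five positive routes, seven negative patterns,
giving roughly balanced positive/negative instances), 2–4 filler sentences
after each group. Group padding of at least two fillers keeps the context
windows of different groups disjoint, which is what makes the hand-assigned
per-template labels correct by construction. Gold labels are assigned per
anchor from template metadata — not by running the classifier — so the
closed-loop property (precision = recall = 1 on a purely template-built
corpus) is a genuine two-sided check between two independent encodings of
the same rules. Randomness is sub-seeded per document from (seed, index),
so growing a corpus never reshuffles existing documents, and identical
seeds give byte-identical corpora.

What the generator does **not** emulate: real note length and section
structure, misspellings, clinician style variation, temporal qualification
("had rituals as a child"), and symptom descriptions that avoid the keyword
vocabulary entirely. Perfect closed-loop scores therefore say the rule
engine implements its own rules exactly; they say nothing about recall on
real clinical text, where the published experience with rules of this kind
is precision well above recall.

The adversarial fixtures are the opposite contract: hand-written sentences
that do not reuse templates (figurative usage, "compulsory", questionnaire
fragments, mixed documents), each with a hand-assigned label and a note
naming the rule it probes. They are asserted in the test suite; scores on
them are a regression guard for the hard cases, not a performance estimate.

## Numerical and design choices

* Character offsets are 0-based half-open on the raw text; no
  normalization at read time, so every span is auditable against the
  source note.
* Instance ids are `{doc_id}:{start}-{end}`, stable across runs.
* Identical match spans from overlapping patterns (count*/counting) are
  reported once; hits sort by start offset.
* The document pre-filter reuses the detection matcher, which guarantees
  any document yielding instances survives filtering.
* Detection is RNG-free; all randomness lives in the generator.
* Problem sizes in the acceptance script (500-document corpus, 1,000
  oracle sentences, 1,000 fuzz documents, exhaustive CI check to n=30)
  are chosen to exercise every template category and rule combination
  multiple times while the whole script runs in seconds.

## Known limitations

Temporality is not modelled: a historical mention classifies the same as a
current one. Windows clip only at document bounds, not paragraph or section
bounds, so evidence can bleed across section headers in heavily structured
notes. The lexical rules cannot separate OCS from phenomenologically
similar psychotic repetition beyond the listed vocabulary. The
romantic/weight and risk/self-harm seed lists are minimal and should be
extended per corpus.
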