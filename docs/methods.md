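# Methods

## Problem and model

Spontaneous adverse-event reporting databases accept unstructured drug-name
entry, so one drug entity accumulates many string representations. The
package treats normalization as assignment of raw strings to concepts of a
drug lexicon — each concept an (integer id, standardized name, synonyms)
triple, the id playing the RxCUI role of RxNorm. The assignment contract is
the one a terminology-service client sees: candidates are ranked by a
closeness score, and only the top-ranked concepts are accepted; everything
below an acceptance floor is unmatched, and top-rank ties across distinct
concepts are surfaced as ambiguous rather than resolved silently, because
residual ambiguity belongs to human curation (the overrides table).

### Tiered matching

1. **Exact tier** — case-insensitive, whitespace-trimmed verbatim lookup.
2. **Canonical tier** — lookup after canonicalization, which is designed to
   be an exact inverse of the systematic (non-typographic) variation classes
   observed in real reports: letter case, ingredient order, conjunction
   wording, separator choice, salt abbreviation, bracketed qualifiers,
   trailing periods. Canonicalization lowercases, removes balanced
   `(...)`/`[...]` qualifiers (innermost-out, to a fixed point), expands
   abbreviations (`hcl`, `asa`, `w/`, `apap` by default), collapses
   `/ - + ?` to spaces, strips stray brackets and trailing periods from
   tokens, drops the stopwords {and, with, de}, and sorts the remaining
   tokens. Token sorting makes ingredient order canonical-alphabetical,
   which matches how multi-ingredient standardized names are written
   ("aspirin/oxycodone"). The function is idempotent; a property test
   checks this on adversarial inputs (unbalanced brackets, separator runs).
3. **Approximate tier** — the query's canonical form is scored against every
   synonym's canonical form with
   `score = w_tok·J + w_edit·(1 − D/maxlen)` (token-set Jaccard `J`,
   Levenshtein `D`); per concept the best synonym score is kept, candidates
   below `min_score` are discarded, and all concepts attaining the maximum
   surviving score are accepted. Scores of 1 occur exactly at canonical
   equality, so the tier ordering is consistent: anything the canonical tier
   would catch also tops the approximate ranking.

Levenshtein distance is computed with `edlib`; the test suite checks the
scorer against an independent dynamic-programming implementation.

### Parameters

| parameter | default | role |
|---|---|---|
| `min_score` | 0.40 | approximate-tier acceptance floor (dimensionless, [0,1]) |
| `weight_token` / `weight_edit` | 0.5 / 0.5 | blend of token-set vs character similarity; must sum to 1 |
| `abbreviations` | hcl, asa, w/, apap | expansion table applied during canonicalization |
| `stopwords` | and, with, de | connective tokens dropped during canonicalization |
| `min_count` (statistics) | 3 | variant names used fewer times are excluded from concept summaries, screening out one-off spelling errors |
| `ks` (threshold table) | 1, 3, 5, 10 | usage-frequency thresholds |

The 0.40 floor is derived from the score formula rather than tuned: a
single-character edit on a one-token name of length L scores
0.5·(1 − 1/L) (the token sets become disjoint, so the Jaccard term
vanishes), which is 0.40 for the shortest names in the bundled lexicon
(5 letters: "actiq", "norco", "opana") and at most 0.44 for longer ones. A
floor above that range silently rejects most misspelled one-token names —
and one-token brand/generic names dominate usage. The floor can sit this
low because acceptance is *top-rank only*: the floor decides when no
concept is credible, not which of several wins. The nearest cross-concept
pairs in the bundled lexicon ("methadone"/"methadose" edit distance 1)
score ≈ 0.44 against each other's variants, but the true concept virtually
always outranks them, and ties are flagged ambiguous instead of being
mis-assigned.

### Counting rules

Usage frequencies are counted on verbatim strings (case- and
punctuation-sensitive), so "methadone hydrochloride" (1,261 uses in the
bundled table) and "methadone hydrochloride." (2,117) are distinct variant
rows; the preferred-name frequency of a concept counts the exact
standardized string only, case-insensitively. Matching operates on
canonical forms, counting never does. In the threshold table, the
preferred-name columns (count of standardized names in the reference and
their summed usage) are computed without applying the threshold k, so they
are constant across k while the distinct-name columns shrink — the
signature of long-tail name heterogeneity. Percentages and heterogeneity
ratios are rounded half-up to one decimal (exact `Decimal` arithmetic, the
convention of printed summary tables); variant listings sort by count
descending with name-ascending tie-break, a deterministic choice since no
natural tie order exists. Ambiguous and unmatched names are excluded from
all concept statistics and written to audit files. Degenerate inputs are
defined, not errors: empty corpus → zero-row tables, concept with no mapped
names → empty listing with total 0, `freq_all = 0` → 0.0%.

## Bundled reference data

The packaged lexicon holds 67 FDA-approved prescription-opioid concepts in
13 classes (buprenorphine, codeine, dihydrocodeine, fentanyl, hydrocodone,
hydromorphone, meperidine, methadone, morphine, oxycodone, oxymorphone,
tapentadol, tramadol), each with its concept id and standardized name; two
concepts — 214256 (aspirin/oxycodone) and 218337 (methadone hydrochloride)
— additionally carry their complete observed FAERS variant listings (12 and
14 strings), giving the matcher real variant synonymy to exercise. Concepts
without curated variants carry only their standardized name; variant
coverage for those comes from the synthetic generator. A per-concept usage
summary (variant counts, preferred/total usage frequencies, preferred-name
percentage) ships alongside for end-to-end verification: the recomputed
percentage cells agree with the stored ones for all 67 concepts under
half-up rounding. One curiosity is preserved as published: concept 214256's
summary row records zero preferred-name usage although its variant listing
shows "aspirin/oxycodone" used 4 times; the pipeline computed from the
listing therefore reports 4 (3.6%), and tests pin the stored-row convention
only where they assert the stored table.

## Synthetic corpora

The generator emulates the documented variant classes as independent
corruption operators on standardized names: ingredient-order inversion,
conjunction form ("X and Y"), separator swap ("-", " + ", " w/"), salt
abbreviation (hydrochloride↔hcl, aspirin↔asa), trailing period, case
jitter, and single-edit misspelling (one character, never the first —
keeping the failure modes analyzable). Concept usage is Zipf-skewed
(exponent 1.5 by default, rank = concept-id order) because a handful of
variants dominate real usage tables; reports carry 1–3 mentions and 0–3
placeholder reaction terms. Default operator probabilities (0.10–0.25,
misspelling 0.05) are chosen so every operator is well represented in a
corpus of a few thousand mentions; real FAERS mixture proportions are
unknown and not claimed. Identical seeds give byte-identical corpora.

Two recovery properties anchor validation: with misspelling off, every
operator is exactly inverted by canonicalization, so the matcher recovers
100% of mentions (verified on 2,000 reports ≈ 4,000 mentions, seed 42);
with 10% single-edit misspelling the matcher must recover ≥ 95% (verified
on 5,500 reports ≈ 11,000 mentions, seed 7 — in that run it recovers all
mentions). These corpora do not emulate: out-of-lexicon drugs, follow-up
report duplication, dosage/route text, country fields, compound free-text
entries ("oxycodone and aspirin/00554201/"-style codes), or real MedDRA
coding — so passing recovery shows the matcher inverts the modeled variant
classes at realistic scale, not that FAERS-wide accuracy would be 100%.

## Known limitations

- **Vocabulary-limited false positives.** Against a lexicon restricted to a
  study's reference drugs, an out-of-vocabulary drug sharing a salt token
  can clear the approximate floor (e.g. "metformin hydrochloride" scores
  ≈ 0.56 against "methadone hydrochloride" when no metformin concept
  exists). In scope-limited use the audit outputs and overrides are the
  mitigation; the principled fix is a fuller lexicon, not a higher floor.
- Misspellings in the *first* character, multi-edit typos, phonetic
  variants and slang are out of the corruption model and not claimed to be
  recovered.
- The scoring formula is a pragmatic blend, not a learned ranker; weights
  other than ½/½ are untested defaults left configurable.
- Reaction terms are carried through verbatim; no MedDRA hierarchy logic.
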