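# drugnorm

Drug-name normalization for spontaneous adverse-event reporting data.

Spontaneous reporting systems such as the FDA Adverse Event Reporting System
(FAERS) accept free-text drug names from companies, clinicians and the
public, so the same drug appears under many strings: brand and generic names,
reordered ingredients ("oxycodone/aspirin" vs "aspirin/oxycodone"),
conjunction and separator variants ("oxycodone and aspirin",
"aspirin w/oxycodone"), salt abbreviations ("methadone hcl"), trailing
punctuation ("methadone hydrochloride.") and outright misspellings
("methadon hcl"). Analyses that retrieve reports by the standardized name
alone can miss the overwhelming majority of reports for a drug — for some
combination opioids more than 99% of usage hides behind non-standard names.

`drugnorm` maps heterogeneous name strings to unique concept identifiers
(the RxCUI role in RxNorm) with a local tiered matcher, intersects the
mapped concepts with a curated reference set of drugs under study (bundled:
67 FDA-approved prescription opioids in 13 classes), and computes the
statistics that quantify name heterogeneity: frequency-threshold tables,
per-concept variant summaries, ranked variant listings, and fold-reduction
ratios. A synthetic-corpus generator with known ground truth supports
end-to-end validation without any external download.

## The matching model

A raw name *r* is resolved against a lexicon of concepts
\(c\) with synonym sets \(S_c\) in three tiers:

1. **exact** — case-insensitive verbatim hit in some \(S_c\) (score 1);
2. **canonical** — hit after canonicalization \(\kappa\) (score 1), where
   \(\kappa\) lowercases, strips bracketed qualifiers and trailing periods,
   collapses the separators `/ - + ?`, expands abbreviations
   (`hcl → hydrochloride`, `asa → aspirin`, `w/ → with`), drops the
   stopwords {and, with, de}, and sorts tokens — so every
   ingredient-order/conjunction/separator/salt variant of one name collapses
   to a single string;
3. **approximate** — every synonym is scored against the query,

   score(a, b) = w_tok · J(a, b) + w_edit · (1 − D(a, b) / max(|a|, |b|)),

   with token-set Jaccard similarity *J*, character-level Levenshtein
   distance *D* and default weights ½/½; candidates scoring at least
   `min_score` (default 0.40) are ranked and **only the concepts attaining
   the highest score are accepted**. A tie between distinct concepts is
   reported as `ambiguous`; curated overrides (a raw-name → concept table)
   realize manual correction.

Per-concept statistics count verbatim strings: the preferred-name usage
`freq_preferred` counts the exact standardized string (case-insensitively),
so "methadone hydrochloride." and "methadone hydrochloride" remain distinct
variants. The heterogeneity ratio is (distinct raw names)/(distinct
concepts), the fold-reduction achieved by normalization.

## Worked example

```python
import drugnorm as dn

lex = dn.bundled_opioid_lexicon()          # 67 opioid concepts, 13 classes
for raw in ["OXYCODONE AND ASPIRIN", "methadone hcl", "Naloxone/Buprenorphine",
            "methadnne hcl", "zzzzqx"]:
    r = dn.match_name(raw, lex)
    print(raw, r.status, r.concept_id, r.candidates[0].tier if r.candidates else "-")
```

```
OXYCODONE AND ASPIRIN    matched   214256   aspirin/oxycodone        exact       1.000
methadone hcl            matched   218337   methadone hydrochloride  exact       1.000
Naloxone/Buprenorphine   matched   352364   buprenorphine/naloxone   canonical   1.000
methadnne hcl            matched   218337   methadone hydrochloride  approximate 0.645
zzzzqx                   unmatched None     -                        -           0.000
```

Each line shows the raw string, the match status, the accepted concept id
and its standardized name, the tier that resolved it, and the ranking score.
The misspelled "methadnne hcl" is recovered by the approximate tier; a
string unrelated to any synonym stays unmatched.

Summarizing the bundled variant-frequency table for concept 218337
(methadone hydrochloride, 14 observed name strings):

```python
freqs = dn.fixtures.variant_frequency_table(218337)
mapping = dn.map_batch(list(freqs["raw_name"]), lex)
ref = dn.build_reference_set(dn.bundled_approved_list(), lex)
print(dn.concept_summaries(mapping, freqs, ref, min_count=3).to_string(index=False))
```

```
 concept_id          preferred_name     class  n_variants  freq_preferred  freq_all  pct_preferred
     218337 methadone hydrochloride methadone          14            1261     14717            8.6
```

Fourteen distinct strings carry 14,717 usages, but the standardized name
accounts for only 1,261 of them (8.6%) — retrieving reports by the standard
name alone would miss over 91% of this drug's reports.

## Command line

```sh
drugnorm simulate --n-reports 1000 --seed 42 --out-corpus corpus.xml --out-truth truth.tsv
drugnorm pipeline --corpus corpus.xml --out reports/
drugnorm lexicon validate src/drugnorm/data/opioid_lexicon.txt
```

`pipeline` chains parse → count → map → reference-filter → statistics and
writes TSV reports (threshold table, concept summaries, variant listings),
audit files for unmatched/ambiguous/out-of-reference names, and a run
summary. `normalize` and `analyze` expose the intermediate stages on TSVs.

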