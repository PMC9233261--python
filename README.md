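# sensiterm

Sensitive-term identification in pediatric clinical notes: lexicon
expansion from expert seed keywords, two-annotator adjudication, exact
string matching, and stratified prevalence analytics.

## The problem

Patient portals now release most clinical notes to patients, parents, and
guardians. A note can contain *sensitive* content — mental health,
substance use, reproductive health, or home-environment documentation —
whose disclosure to the wrong party breaches confidentiality (a parent
reading an adolescent's confidential history, or an older child reading
maternal history recorded in their infant chart). Before any protection
policy can be designed, one needs to know **how prevalent** such content
is across ages, note types, and clinical settings.

`sensiterm` implements a dictionary-based protocol for that measurement:

1. **Seed terms.** Experts name 5–10 keywords per category
   (`substance_use`, `mental_health`, `reproductive_health`,
   `home_environment`).
2. **Expansion.** Corpus-trained distributional embeddings (windowed
   co-occurrence → PPMI → truncated SVD) expand each seed into up to
   *k* = 60 candidate related terms, abbreviations ("etoh" for alcohol),
   and misspellings ("alchol"), ranked by
   `max(cosine, 0.8 · edit_similarity)`.
3. **Annotation.** Two annotators label each unique candidate
   sensitive / not-sensitive; agreement is quantified with Cohen's
   κ = (p₀ − pₑ)/(1 − pₑ) and disagreements are adjudicated explicitly.
4. **Matching.** Notes are flagged by exact, casefolded string matching of
   the final lexicon — negation-agnostic ("denies etoh" counts), with
   boundary-aware *token* mode (default) and literal *substring* mode.
5. **Prevalence.** Note-level flags are stratified by age, note type,
   provider type, setting, specialty, and category; pairwise group
   contrasts use the two-sided Fisher exact test
   (p = Σ hypergeometric probabilities ≤ that of the observed table).

Because real EHR corpora cannot be shipped, the package includes a
first-class synthetic corpus generator with *exact* planting ground truth:
every sensitive term is planted at configured per-stratum rates into
template text whose filler vocabulary provably contains no lexicon
surface, so matcher precision and recall are exactly measurable.

## Worked example

```python
from sensiterm import (default_config, generate_corpus, default_lexicon,
                       compile_matcher, match_corpus, flag_notes,
                       prevalence, stratified_prevalence, top_terms,
                       compare_groups)

cfg = default_config(n_patients=1500, rng_seed=1)
notes, truth = generate_corpus(cfg)                   # 5141 notes
matcher = compile_matcher(default_lexicon(), mode="token")
records, aggregates = match_corpus(notes, matcher)
flags = flag_notes(records, notes)
print(prevalence(int(flags["any"].sum()), len(notes)).formatted)
print(stratified_prevalence(notes, flags, by=["note_type"]))
print(top_terms(aggregates, "mental_health", n=5))
print(compare_groups((5701, 6707), (2128, 2589)))
```

prints

```
38.14%
note_type  n_notes  n_flagged  proportion
      apn     3512       1453    0.413724
      epn     1340        388    0.289552
       hp       80         46    0.575000
      icn       38         12    0.315789
      ids       44         14    0.318182
      ipn      127         48    0.377953
          surface  term_frequency  note_frequency
         suicidal             240             238
             ptsd             134             134
suicidal ideation             132             132
          suicide             132             132
             mood             130             130
(0.00096442634664497, True)
```

Reading: 38.14% of the 5141 synthetic notes contain at least one
sensitive term (the generator's configured marginal is 37.51%, so the
pipeline recovers it within one standard error); history & physical notes
are flagged most often (57.5%), mirroring the configured screening-heavy
H&P documentation; "suicidal" appears 240 times across 238 distinct
notes; and an 85.0%-vs-82.2% specialty contrast at n = 6707 vs 2589 is
significant by Fisher exact test (p ≈ 0.001).

The same pipeline is scriptable from the shell:

```bash
sensiterm simulate --n-patients 1500 --seed 1 --out-dir run/
sensiterm match --corpus run/corpus.jsonl --lexicon run/lexicon.csv \
    --mode token --out-matches run/matches.jsonl --out-aggregates run/agg.csv
sensiterm report --corpus run/corpus.jsonl --matches run/matches.jsonl \
    --out-dir run/report/
```

Each stage writes a `.provenance.json` sidecar (parameters, seeds,
lexicon size, matcher mode) sufficient to re-run it.

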