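# Methods

## Protocol overview

The package measures the prevalence of sensitive content in clinical
notes with a fully dictionary-based protocol: expert seed keywords are
expanded into a categorized lexicon using corpus statistics, the lexicon
is validated by two human annotators, and notes are classified by exact
string matching — deliberately without negation detection, stemming, or
context modeling. A screening question ("denies alcohol use") counts as
sensitive documentation exactly like an assertion, because the presence
of the question itself can reveal what was discussed. The unit of
analysis is the note; a note is *flagged* when it contains at least one
lexicon surface, and per-category flags record which of the four content
categories (substance use, mental health, reproductive health, home
environment) appear.

## Matching semantics

Matching is casefolded with a per-character offset map, so reported spans
are 0-based half-open offsets into the verbatim note text even when
Unicode casefolding changes string length ("ß" → "ss"). Two modes:

- **token** (default): a surface matches where both flanks are
  non-alphanumeric or the text boundary; internal single spaces of a
  phrase match any whitespace run (notes wrap lines mid-sentence). This
  is the defensible default because short abbreviations ("si", "sti")
  would otherwise fire inside ordinary words ("basin").
- **substring**: any casefolded substring occurrence, mirroring a literal
  direct-string-match reading. Token-mode flags are a subset of
  substring-mode flags.

Each surface is matched independently (spans of "suicidal" and "suicidal
ideation" may overlap); same-surface spans are found left-to-right
without overlap (after a match at [i, j) scanning resumes at j, so
"coco" occurs once in "cococo"). Both modes are recorded in output
provenance. Correctness is established against an independent
brute-force scan oracle, property-tested over random texts and lexicons.

## Embedding model for term expansion

The expansion stage needs distributional similarity plus surface-variant
detection. The embedding model is count-based and closed-form: windowed
token co-occurrence (default window 5, windows do not cross line
boundaries), PPMI reweighting, truncated SVD (default 64 dims, rows
scaled by √σ), with a deterministic sign convention. Multi-token phrases
(up to 4 tokens, counted per line) receive the mean of their component
token vectors. Determinism was preferred over a trained skip-gram
objective: identical corpus and parameters reproduce identical vectors,
which makes expansion regression-testable; the `rng_seed` argument is
recorded in provenance only.

Candidates are ranked by `max(cosine, 0.8 · edit_similarity)` and cut at
k = 60 after a floor (cosine < 0.2 and edit similarity < 0.75 excludes).
The blend exists because cosine alone misses rare misspellings and edit
distance alone misses related terms. Kind classification:

- **abbreviation**: a small conventional map (etoh, thc, si, sti, hiv,
  cps, …) keyed to the seed, or an initials/subsequence heuristic —
  abbreviations are domain conventions, not derivable from surface form;
- **misspelling**: edit similarity ≥ 0.75 (restricted Damerau–Levenshtein,
  counting adjacent transposition as one edit), corpus count below 10%
  of the seed's count (misspellings are rare variants of common terms),
  and not a filler-dictionary word;
- **related** otherwise.

All thresholds are configurable (`ExpansionConfig`); the defaults above
are package choices, since no published reference fixes them.

## Annotation and agreement

Labels are term-level and binary. Cohen's κ = (p₀ − pₑ)/(1 − pₑ) with pₑ
from the annotators' marginal frequencies. In the degenerate case pₑ = 1
(both annotators used one identical label throughout) κ is undefined; the
package returns 1.0 for perfect agreement and 0.0 otherwise, with a
warning — a convention fixed so downstream code is total. Disagreements
must be resolved explicitly; unresolved surfaces raise an error naming
them. The implementation is cross-checked against scikit-learn's kappa
on random label pairs.

## Fisher exact test

Two-sided p by enumeration of the hypergeometric distribution with fixed
margins, summing probabilities of all tables whose probability does not
exceed the observed table's. Tie comparison uses exact integer
arithmetic (products of binomial coefficients) and the final sum is an
exact rational converted to float, so there is no tie tolerance at all;
agreement with scipy's implementation is ~1e-15 on random tables and
exact-to-1e-10 on the full sweep of tables with margins ≤ 30. No
multiple-testing correction is applied by default, matching the
protocol's pairwise P < .05 usage; `bonferroni_m` opts in.

## Percent rounding

Printed percentages use half-away-from-zero rounding at the table's
precision (2 decimals for the cohort summary, 1 elsewhere, 0 for
annotation fractions), implemented with exact decimal arithmetic. This
reproduces e.g. 501,762/1,338,297 → 37.49% and 478/1620 → 30%.

## Synthetic corpus: what it emulates and what it does not

The generator draws patients (ages 0–21; 74.8% under 13, with age 0
double-weighted for the birth cohort), encounters (ambulatory/emergency/
inpatient ≈ 0.703/0.247/0.051), notes per encounter (mean 1.75), note
types (APN for ambulatory, EPN for emergency; H&P, consult, discharge
summary, progress within inpatient), provider types, and specialties.
For each note and category, a term is planted with probability
`plant_rates[(category, age_band, note_type)]`, optionally boosted for
high-signal specialties (behavioral health, ob/gyn, pain management,
child-abuse pediatrics) and capped at 0.97. Planted terms are emitted
via carrier sentences; at age 0, substance-use and reproductive-health
terms ride maternal-history lines, reproducing the infancy elevation of
those categories. A planted term is swapped for its abbreviation variant
with probability 0.10 or its misspelling variant with probability 0.05;
variants are themselves lexicon entries, as in the real protocol whose
lexicon contains abbreviations and misspellings.

The plant-rate table was calibrated once, at design time, so that the
exactly enumerated expected any-flag marginal under the default mix is
0.375 (the headline prevalence scale); age shapes rise for mental health
from age 10 through adolescence and peak in infancy for substance use
and reproductive health, and H&P factors exceed APN factors at every
age. `expected_flag_rate` / `expected_rate_by` compute the implied
marginals exactly by stratum enumeration, which is what recovery tests
compare against (within 3 binomial standard errors).

**Exactness guarantee.** Filler and carrier text is validated at
generation time to contain no lexicon surface in token mode, and the
default lexicon avoids cross-category token containment; therefore the
token-mode matcher recovers exactly the planted note set and per-note
categories (precision = recall = 1). This guarantee is what makes the
generator a usable oracle for the matcher, and it is the main way the
synthetic corpus differs from real notes: real filler text *does*
contain incidental lexicon words, real notes contain templated
screening batteries, copy-forward duplication, and section structure,
and real term frequency distributions are far heavier-tailed. Passing
recovery tests therefore validates the pipeline's mechanics, not its
real-world yield.

Default problem sizes (1500 patients ≈ 5100 notes for prevalence
recovery; 350 patients for expansion experiments; embedding training on
vocabularies of a few thousand entries) were chosen as the smallest
scales at which the stochastic checks are statistically meaningful.

## Design choices on open points

- **Age bands** print as "<13", "13–18", "18–21" in the emulated cohort
  table; the package uses the partition [0,13), [13,18), [18,21] since
  bands must partition and the 18 boundary is ambiguous in print.
- **Duplicate notes** (addenda, copy-forward) are not deduplicated; each
  record is one note.
- **60 candidates per seed** is treated as a post-ranking cap, not a
  pre-threshold pool size.
- **One category per surface**: a surface assigned to two categories is a
  load-time conflict requiring manual resolution.
- An external term list can be loaded through `load_lexicon`'s
  configurable column mapping; no third-party list ships with the
  package, and the built-in lexicon is a synthetic stand-in.

## Known limitations

- Exact matching has no concept of negation, hedging, or who the subject
  is (maternal vs patient history) — by protocol design, all mentions
  count.
- The misspelling/abbreviation classifier needs adequate corpus counts;
  at very small corpus scales the count-ratio test is unstable.
- PPMI-SVD embeddings capture second-order co-occurrence; on template
  corpora, frequent template n-grams rank high among related candidates,
  which annotators are expected to reject (exactly as the real protocol
  rejected ~32% of candidates).
- Fisher enumeration is exact but O(support) with big-integer weights;
  for tables with margins in the millions a normal-approximation test
  would be the practical choice.
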