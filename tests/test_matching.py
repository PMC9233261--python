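"""Exact-match semantics, checked span-for-span against a brute-force oracle.

The oracle is an independent O(text x lexicon) scan: it folds the text one
character at a time, tries every start offset, and walks phrase tokens
across whitespace runs by hand. It shares no code with the compiled
matcher.
"""

import pytest
from hypothesis import given, settings, strategies as st

from sensiterm.lexicon import CATEGORIES, LexiconEntry
from sensiterm.matching import (MatcherError, compile_matcher, match_corpus,
                                match_note)
from .conftest import make_note


# ------------------------------------------------------------------- oracle

def _fold(text):
    chars, src = [], []
    for i, ch in enumerate(text):
        for f in ch.casefold():
            chars.append(f)
            src.append(i)
    return chars, src


def _try_match_at(chars, start, tokens):
    """Match tokens separated by >=1 whitespace chars; return end or None."""
    pos = start
    for ti, tok in enumerate(tokens):
        if ti > 0:
            ws_start = pos
            while pos < len(chars) and chars[pos].isspace():
                pos += 1
            if pos == ws_start:
                return None
        for ch in tok:
            if pos >= len(chars) or chars[pos] != ch:
                return None
            pos += 1
    return pos


def oracle_spans(text, surface, mode):
    chars, src = _fold(text)
    tokens = surface.split(" ")
    spans = []
    i = 0
    while i <= len(chars):
        end = _try_match_at(chars, i, tokens)
        if end is None:
            i += 1
            continue
        if mode == "token":
            left = i == 0 or not chars[i - 1].isalnum()
            right = end == len(chars) or not chars[end].isalnum()
            if not (left and right):
                i += 1
                continue
        spans.append((src[i], src[end - 1] + 1))
        i = end if end > i else i + 1
    return spans


def _as_dict(records):
    return {r.surface: r.positions for r in records}


def _oracle_dict(text, lexicon, mode):
    out = {}
    for e in lexicon:
        spans = oracle_spans(text, e.surface, mode)
        if spans:
            out[e.surface] = spans
    return out


# ----------------------------------------------------------------- examples

def test_empty_text_no_matches(tiny_lexicon):
    m = compile_matcher(tiny_lexicon)
    assert match_note("", m) == []


def test_empty_lexicon_rejected():
    with pytest.raises(MatcherError):
        compile_matcher([])


def test_negated_mention_still_counts(tiny_lexicon):
    m = compile_matcher(tiny_lexicon, mode="token")
    recs = match_note("Patient denies ETOH use.", m)
    assert _as_dict(recs) == {"etoh": [(15, 19)]}


def test_short_abbreviation_token_vs_substring():
    lex = [LexiconEntry("si", "mental_health")]
    text = "She sits by the basin"
    token = match_note(text, compile_matcher(lex, mode="token"))
    sub = match_note(text, compile_matcher(lex, mode="substring"))
    assert token == []
    assert [r.count for r in sub] == [2]
    assert sub[0].positions == [(4, 6), (18, 20)]


def test_overlapping_surfaces_matched_independently(tiny_lexicon):
    m = compile_matcher(tiny_lexicon)
    recs = _as_dict(match_note("suicidal ideation noted", m))
    assert recs["suicidal"] == [(0, 8)]
    assert recs["suicidal ideation"] == [(0, 17)]


def test_same_surface_spans_do_not_overlap():
    lex = [LexiconEntry("coco", "substance_use")]
    recs = match_note("cococo", compile_matcher(lex, mode="substring"))
    assert recs[0].positions == [(0, 4)]


def test_phrase_matches_across_whitespace_runs(tiny_lexicon):
    m = compile_matcher(tiny_lexicon)
    recs = _as_dict(match_note("suicidal \n   ideation", m))
    assert "suicidal ideation" in recs


def test_length_changing_casefold_offsets_stay_verbatim():
    lex = [LexiconEntry("strasse", "home_environment")]
    text = "STRAßE"  # casefolds to 'strasse', shorter original
    recs = match_note(text, compile_matcher(lex, mode="token"))
    assert recs[0].positions == [(0, 6)]
    assert text[0:6] == "STRAßE"


def test_corpus_aggregates_term_vs_note_frequency(tiny_lexicon):
    notes = [
        make_note("N1", "anxiety then anxiety again"),
        make_note("N2", "anxiety once"),
        make_note("N3", "nothing here"),
    ]
    _, agg = match_corpus(notes, compile_matcher(tiny_lexicon))
    row = agg.set_index("surface").loc["anxiety"]
    assert (row["term_frequency"], row["note_frequency"]) == (3, 2)


def test_monotonicity_adding_terms_keeps_existing_matches(three_notes,
                                                          tiny_lexicon):
    m_small = compile_matcher(tiny_lexicon[:2])
    m_big = compile_matcher(tiny_lexicon)
    for n in three_notes:
        small = _as_dict(match_note(n.text, m_small))
        big = _as_dict(match_note(n.text, m_big))
        for surface, spans in small.items():
            assert big[surface] == spans


# ------------------------------------------------------------ property test

_word = st.text(alphabet="abs", min_size=1, max_size=4)
_surface = st.builds(" ".join,
                     st.lists(_word, min_size=1, max_size=3))
_text_strat = st.text(alphabet="abs AB\n.,-ßé", max_size=120)


@settings(max_examples=250, deadline=None)
@given(text=_text_strat,
       surfaces=st.sets(_surface, min_size=1, max_size=8),
       mode=st.sampled_from(["token", "substring"]))
def test_matcher_agrees_with_bruteforce_oracle(text, surfaces, mode):
    lexicon = [LexiconEntry(s, CATEGORIES[i % 4])
               for i, s in enumerate(sorted(surfaces))]
    # normalization may collapse distinct inputs; drop duplicates
    seen, entries = set(), []
    for e in lexicon:
        if e.surface not in seen:
            seen.add(e.surface)
            entries.append(e)
    matcher = compile_matcher(entries, mode=mode)
    assert _as_dict(matcher.match_text(text)) == \
        _oracle_dict(text, entries, mode)
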